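"""Majority-rules family assignment and family-level abundance rollup.

A vOTU is assigned to a viral family when at least half of its proteins
have a qualifying best hit to that family: bitscore >= 50 in the primary
(RefSeq-style) pass, or percent identity >= 50 in the fallback
(Demovir-style) pass applied only to vOTUs the primary pass left
unassigned. Ties at the voting threshold leave the vOTU unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

UNCLASSIFIED = "unclassified"


@dataclass
class FamilyCall:
    votu_id: str
    family: str
    supporting_fraction: float
    pass_label: str  # 'primary_db' | 'fallback_db' | 'none'


def _best_hit_per_protein(hits: pd.DataFrame) -> pd.DataFrame:
    # One vote per protein: highest score wins, ties broken by family name.
    ordered = hits.sort_values(["protein_id", "score", "family"],
                               ascending=[True, False, True])
    return ordered.drop_duplicates("protein_id", keep="first")


def _majority(best: pd.DataFrame, n_proteins: int,
              min_fraction: float) -> tuple[Optional[str], float]:
    if best.empty:
        return None, 0.0
    counts = best.groupby("family").size()
    top = counts.max()
    fraction = top / n_proteins
    if fraction < min_fraction:
        return None, fraction
    winners = counts[counts == top].index.tolist()
    if len(winners) > 1:
        return None, fraction  # no unique majority
    return winners[0], fraction


def assign_family(
    votu_id: str,
    proteins: Sequence[str],
    hits: pd.DataFrame,
    min_fraction: float = 0.5,
    min_bitscore: float = 50.0,
    min_identity: float = 50.0,
) -> FamilyCall:
    """Assign a family to one vOTU by per-protein majority vote.

    ``hits`` has columns (protein_id, family, score, pass) where ``pass``
    is 'primary_db' (score is a bitscore) or 'fallback_db' (score is a
    percent identity). The fallback pass is consulted only if the primary
    pass leaves the vOTU unassigned.
    """
    if not proteins:
        raise ValueError(f"vOTU {votu_id!r} has no proteins")
    protein_set = set(proteins)
    unknown = set(hits["protein_id"]) - protein_set
    if unknown:
        raise ValueError(
            f"hits reference proteins outside vOTU {votu_id!r}: "
            f"{sorted(unknown)[:5]}")
    n = len(protein_set)

    for pass_label, threshold in (("primary_db", min_bitscore),
                                  ("fallback_db", min_identity)):
        sub = hits[(hits["pass"] == pass_label) & (hits["score"] >= threshold)]
        family, fraction = _majority(_best_hit_per_protein(sub), n, min_fraction)
        if family is not None:
            return FamilyCall(votu_id, family, fraction, pass_label)
    return FamilyCall(votu_id, UNCLASSIFIED, 0.0, "none")


def summarize_family_abundance(
    calls: Mapping[str, str],
    relative: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sum per-sample relative abundances by family.

    ``relative`` is a vOTU x sample matrix; every vOTU must have a call
    (possibly 'unclassified'). Returns (family x sample table, classified
    fraction per sample); column sums are preserved.
    """
    missing = [v for v in relative.index if v not in calls]
    if missing:
        raise ValueError(f"vOTUs without a family call: {missing[:5]}")
    families = pd.Series({v: calls[v] for v in relative.index}, name="family")
    table = relative.groupby(families).sum()
    totals = relative.sum(axis=0)
    unclassified = (table.loc[UNCLASSIFIED] if UNCLASSIFIED in table.index
                    else pd.Series(0.0, index=relative.columns))
    with np.errstate(invalid="ignore", divide="ignore"):
        classified = (1.0 - unclassified / totals).where(totals > 0, 0.0)
    return table, classified
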