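"""Auxiliary-metabolic-gene (AMG) screening.

Annotation rows from VIBRANT/DRAM-v style callers are screened with the
published retention rules: drop candidates carrying a T or B flag, with
auxiliary score above 3, absent from the manually curated function list,
or lacking viral genomic context. The context check verifies position on
the contig: in strict mode a retained AMG must have at least one
virus-specific gene on each side; lenient mode requires one anywhere on
the contig.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Set

import pandas as pd

from .config import RunConfig
from .io import GeneRecord
from .triage import classify_gene_product

VERDICTS = ("retained", "removed_flag", "removed_score",
            "removed_not_curated", "removed_context")


def _viral_gene_positions(genes: Sequence[GeneRecord],
                          cfg: RunConfig) -> list[tuple[int, int]]:
    spans = []
    for g in genes:
        category = g.category or classify_gene_product(
            g.product, cfg.viral_keywords, cfg.unknown_patterns,
            cfg.prokaryote_patterns)
        if category == "viral_specific":
            spans.append((g.start, g.end))
    return spans


def _context_ok(cand_start: int, cand_end: int,
                viral_spans: Sequence[tuple[int, int]], mode: str) -> bool:
    if mode == "lenient":
        return len(viral_spans) > 0
    left = any(end <= cand_start for _, end in viral_spans)
    right = any(start >= cand_end for start, _ in viral_spans)
    return left and right


def filter_amg_candidates(
    candidates: pd.DataFrame,
    genes: Sequence[GeneRecord],
    curated_functions: Set[str],
    mode: str = "strict",
    max_auxiliary_score: int = 3,
    remove_flags: Sequence[str] = ("T", "B"),
    cfg: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """Assign a verdict to every AMG candidate row.

    ``candidates`` columns: gene_id, contig_id, function_id, description,
    source, auxiliary_score (may be empty), flags (comma-joined or empty),
    category. Rules are applied in order — flag, score, curated list,
    viral context — and the first failing rule becomes the verdict.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be 'strict' or 'lenient'")
    cfg = cfg or RunConfig()
    gene_by_id = {g.gene_id: g for g in genes}
    genes_by_contig: dict[str, list[GeneRecord]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig_id, []).append(g)
    viral_spans = {cid: _viral_gene_positions(gs, cfg)
                   for cid, gs in genes_by_contig.items()}
    remove_flags = set(remove_flags)

    verdicts = []
    for _, row in candidates.iterrows():
        contig = row["contig_id"]
        if contig not in genes_by_contig:
            raise ValueError(f"AMG candidate on unknown contig {contig!r}")
        flags = {f for f in str(row.get("flags", "")).split(",") if f}
        raw_score = str(row.get("auxiliary_score", "")).strip()
        score = int(float(raw_score)) if raw_score else None
        if flags & remove_flags:
            verdicts.append("removed_flag")
            continue
        if score is not None and score > max_auxiliary_score:
            verdicts.append("removed_score")
            continue
        if row["function_id"] not in curated_functions:
            verdicts.append("removed_not_curated")
            continue
        cand = gene_by_id.get(row["gene_id"])
        if cand is not None and cand.contig_id == contig:
            start, end = cand.start, cand.end
        else:
            raise ValueError(f"AMG candidate gene {row['gene_id']!r} not in "
                             f"gene table")
        spans = [s for s in viral_spans[contig]
                 if not (s[0] == start and s[1] == end)]
        if not _context_ok(start, end, spans, mode):
            verdicts.append("removed_context")
            continue
        verdicts.append("retained")
    out = candidates.copy()
    out["verdict"] = verdicts
    out["context_mode"] = mode
    return out


def summarize_amgs(
    screened: pd.DataFrame,
    relative: Optional[pd.DataFrame] = None,
    groups: Optional[Mapping[str, str]] = None,
) -> tuple[pd.Series, Optional[pd.Series]]:
    """Category histogram of retained AMGs and per-group abundance sums.

    The histogram total equals the number of retained rows. If a relative
    abundance matrix (contig x sample) and group labels are given, the
    per-group mean summed relative abundance of AMG-bearing contigs is
    also returned.
    """
    retained = screened[screened["verdict"] == "retained"]
    histogram = retained.groupby("category").size().sort_index()
    group_abundance = None
    if relative is not None and groups is not None:
        carriers = [c for c in retained["contig_id"].unique()
                    if c in relative.index]
        share = relative.loc[carriers].sum(axis=0)
        labels = pd.Series({s: groups[s] for s in relative.columns})
        group_abundance = share.groupby(labels).mean()
    return histogram, group_abundance
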