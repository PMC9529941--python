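"""Rule-based viral-contig triage.

Implements the per-contig decision layer applied after the upstream phage
predictors (whose calls are inputs): keyword classification of gene
products, the retain/reject quorum rules, direct-terminal-repeat detection,
CheckV-style quality-tier assignment from externally supplied completeness,
and blank-control decontamination.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .config import (PROKARYOTE_PATTERNS, UNKNOWN_PATTERNS, VIRAL_KEYWORDS,
                     RunConfig)
from .io import GeneRecord

log = logging.getLogger("hadalvir")

CATEGORIES = ("viral_specific", "unknown", "prokaryote_specific", "other")

TIERS = ("complete", "high", "medium", "low", "undetermined")

# reason codes
VIRAL_GENE_QUORUM = "VIRAL_GENE_QUORUM"
UNKNOWN_MAJORITY = "UNKNOWN_MAJORITY"
PROKARYOTE_GENE = "PROKARYOTE_GENE"
NO_EVIDENCE = "NO_EVIDENCE"
CONSERVATIVE_SIGNAL_MISSING = "CONSERVATIVE_SIGNAL_MISSING"
BLANK_CONTAMINANT = "BLANK_CONTAMINANT"


@dataclass
class TriageDecision:
    contig_id: str
    retained: bool
    reasons: list
    n_genes: int
    n_viral_specific: int
    n_unknown: int
    n_prokaryote: int


@dataclass
class QualityTier:
    contig_id: str
    completeness: Optional[float]
    dtr: bool
    tier: str


def _keyword_regex(keywords: Sequence[str]) -> re.Pattern:
    # Token/phrase match on word boundaries: 'head' must not hit 'overhead',
    # multi-word keywords match across any whitespace/hyphen run.
    parts = []
    for kw in sorted(keywords, key=len, reverse=True):
        tokens = [re.escape(t) for t in kw.lower().split()]
        parts.append(r"[\s\-]+".join(tokens))
    body = "|".join(parts)
    return re.compile(rf"(?<![a-z0-9])(?:{body})(?![a-z0-9])")


_DEFAULT_VIRAL_RE = _keyword_regex(VIRAL_KEYWORDS)


def classify_gene_product(
    product: str,
    keywords: Sequence[str] = VIRAL_KEYWORDS,
    unknown_patterns: Sequence[str] = UNKNOWN_PATTERNS,
    prokaryote_patterns: Sequence[str] = PROKARYOTE_PATTERNS,
) -> str:
    """Map a free-text product string to a triage category.

    Precedence: prokaryote_specific > viral_specific > unknown > other.
    Viral keywords match case-insensitively on word boundaries; unknown and
    prokaryote patterns are case-insensitive substring matches.
    """
    text = product.lower()
    if any(p.lower() in text for p in prokaryote_patterns):
        return "prokaryote_specific"
    viral_re = (_DEFAULT_VIRAL_RE if keywords is VIRAL_KEYWORDS
                else _keyword_regex(keywords))
    if viral_re.search(text):
        return "viral_specific"
    if any(p.lower() in text for p in unknown_patterns):
        return "unknown"
    return "other"


def _categorize(genes: Sequence[GeneRecord], cfg: RunConfig) -> list[str]:
    cats = []
    for g in genes:
        if g.category:
            cats.append(g.category)
        else:
            cats.append(classify_gene_product(
                g.product, cfg.viral_keywords, cfg.unknown_patterns,
                cfg.prokaryote_patterns))
    return cats


def triage_contig(
    genes: Sequence[GeneRecord],
    predictor_calls: Mapping[str, bool],
    completeness: Optional[float] = None,
    cfg: Optional[RunConfig] = None,
) -> TriageDecision:
    """Apply the retain/reject rules to one contig.

    Retained iff [ >=2 virus-specific genes OR (>=1 predictor call AND
    unknown fraction >= 0.70) ] AND no prokaryote-specific gene AND
    [ completeness known OR >=1 virus-specific gene OR >=1 call from the
    conservative-tool subset ]. Every rule that fires is recorded.
    """
    cfg = cfg or RunConfig()
    if genes:
        ids = {g.contig_id for g in genes}
        if len(ids) > 1:
            raise ValueError(f"genes span multiple contigs: {sorted(ids)}")
        contig_id = genes[0].contig_id
    else:
        contig_id = ""

    cats = _categorize(genes, cfg)
    n = len(genes)
    n_viral = sum(c == "viral_specific" for c in cats)
    n_unknown = sum(c == "unknown" for c in cats)
    n_prok = sum(c == "prokaryote_specific" for c in cats)

    reasons: list[str] = []
    if n == 0:
        return TriageDecision(contig_id, False, [NO_EVIDENCE], 0, 0, 0, 0)

    any_call = any(bool(v) for v in predictor_calls.values())
    quorum = n_viral >= cfg.min_viral_genes
    unknown_majority = any_call and (n_unknown / n) >= cfg.unknown_fraction_min
    if quorum:
        reasons.append(VIRAL_GENE_QUORUM)
    if unknown_majority:
        reasons.append(UNKNOWN_MAJORITY)

    rejected = False
    if n_prok > 0:
        reasons.append(PROKARYOTE_GENE)
        rejected = True
    if not (quorum or unknown_majority):
        reasons.append(NO_EVIDENCE)
        rejected = True
    if completeness is None and n_viral == 0:
        conservative = any(bool(predictor_calls.get(t, False))
                           for t in cfg.conservative_tools)
        if not conservative:
            reasons.append(CONSERVATIVE_SIGNAL_MISSING)
            rejected = True

    return TriageDecision(contig_id, not rejected, reasons,
                          n, n_viral, n_unknown, n_prok)


def detect_dtr(sequence: str, min_repeat: int = 20) -> tuple[bool, int]:
    """Detect a direct terminal repeat: longest exact prefix == suffix.

    Returns (found, maximal repeat length); the repeat is capped at half the
    sequence length. Sequences of length <= 2 * min_repeat are an error.
    """
    n = len(sequence)
    if n <= 2 * min_repeat:
        raise ValueError(
            f"sequence of {n} nt too short for DTR detection at "
            f"min_repeat={min_repeat}")
    for L in range(n // 2, min_repeat - 1, -1):
        if sequence[:L] == sequence[-L:]:
            return True, L
    return False, 0


def assign_quality_tier(completeness: Optional[float], dtr: bool) -> str:
    """Map (completeness %, DTR flag) to a genome-quality tier.

    complete: 100% with a DTR; high: >90%; medium: 50-90% inclusive;
    low: <50%; undetermined: completeness unknown.
    """
    if completeness is None:
        return "undetermined"
    if not 0 <= completeness <= 100:
        raise ValueError(f"completeness {completeness} outside [0, 100]")
    if completeness == 100 and dtr:
        return "complete"
    if completeness > 90:
        return "high"
    if completeness >= 50:
        return "medium"
    return "low"


def decontaminate(
    retained: Sequence[str],
    blank_hits: Mapping[str, int],
) -> tuple[list[str], list[str]]:
    """Remove contigs with >= 1 read mapped from the blank controls.

    Returns (kept ids in input order, removed ids). Blank-table entries for
    unknown contigs are warned about and ignored.
    """
    known = set(retained)
    for cid, count in blank_hits.items():
        if count < 0:
            raise ValueError(f"negative blank read count for {cid!r}")
        if cid not in known:
            log.warning("blank-hit table references unknown contig %r", cid)
    contaminated = {cid for cid, count in blank_hits.items()
                    if count >= 1 and cid in known}
    kept = [cid for cid in retained if cid not in contaminated]
    removed = [cid for cid in retained if cid in contaminated]
    return kept, removed
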