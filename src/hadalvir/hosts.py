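"""Virus-host linkage from four evidence types.

Evidence collectors mirror the published in silico screens: (1) nucleotide
homology between viral contigs and host genomes (prophage-like segments),
(2) CRISPR spacer matches, (3) shared tRNA genes, and (4) k-mer
composition similarity scored with an order-k Markov model trained on each
host genome. Per-pair evidence is integrated into a confidence score; the
published decision boundary (score >= 3) marks high-confidence predictions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import AlignmentRow, ContigRecord

log = logging.getLogger("hadalvir")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CrisprArray:
    host_id: str
    start: int
    end: int
    repeat: str
    spacers: list
    n_repeats: int


@dataclass
class HostEvidence:
    virus_id: str
    host_id: str
    method: str  # 'homology' | 'crispr' | 'trna' | 'kmer'
    detail: dict


@dataclass
class HostPrediction:
    virus_id: str
    host_id: str
    score: float
    high_confidence: bool
    methods: list


# ---------------------------------------------------------------------------
# 1. homology

def filter_homology_matches(
    alignments: Sequence[AlignmentRow],
    host_lengths: Mapping[str, int],
    min_length: int = 2_500,
    min_identity: float = 70.0,
    max_host_coverage: float = 0.90,
) -> list[HostEvidence]:
    """Keep virus-vs-host alignments consistent with an integrated segment.

    A row qualifies if alignment length >= 2500 nt and identity >= 70%, and
    the pair's total aligned host bases (union of subject intervals) cover
    < 90% of the host sequence — near-total coverage indicates the "viral"
    contig is simply part of the host assembly, not an inserted segment.
    """
    qualifying: dict[tuple[str, str], list[AlignmentRow]] = {}
    for row in alignments:
        if row.subject_id not in host_lengths:
            raise ValueError(f"unknown host id {row.subject_id!r}")
        if row.aln_length >= min_length and row.pct_identity >= min_identity:
            qualifying.setdefault((row.query_id, row.subject_id), []).append(row)

    evidence: list[HostEvidence] = []
    for (virus, host), rows in qualifying.items():
        intervals = sorted((min(r.s_start, r.s_end) - 1, max(r.s_start, r.s_end))
                           for r in rows)
        covered, cur_start, cur_end = 0, *intervals[0]
        for start, end in intervals[1:]:
            if start > cur_end:
                covered += cur_end - cur_start
                cur_start, cur_end = start, end
            else:
                cur_end = max(cur_end, end)
        covered += cur_end - cur_start
        coverage = covered / host_lengths[host]
        if coverage < max_host_coverage:
            for r in rows:
                evidence.append(HostEvidence(virus, host, "homology", {
                    "aln_length": r.aln_length, "pct_identity": r.pct_identity,
                    "host_coverage": round(coverage, 4),
                }))
    return evidence


# ---------------------------------------------------------------------------
# 2. CRISPR arrays and spacer matching

def detect_crispr_arrays(
    host_seq: str,
    host_id: str = "",
    min_repeats: int = 3,
    repeat_range: tuple[int, int] = (23, 47),
    spacer_range: tuple[int, int] = (26, 50),
) -> list[CrisprArray]:
    """Find CRISPR arrays as runs of >= 3 exact repeat copies.

    Repeats are seeded with exact 23-mers recurring at spacings compatible
    with one repeat plus one spacer, extended to the maximal repeat length
    for which all copies stay identical and all spacers stay within the
    legal length band. Spacers must be mutually distinct (a tandem repeat is
    not an array).
    """
    if len(host_seq) < 200:
        raise ValueError("host sequence shorter than 200 nt")
    rmin, rmax = repeat_range
    smin, smax = spacer_range
    seed = rmin
    positions: dict[str, list[int]] = {}
    for i in range(len(host_seq) - seed + 1):
        positions.setdefault(host_seq[i:i + seed], []).append(i)

    gap_min, gap_max = rmin + smin, rmax + smax
    arrays: list[CrisprArray] = []
    claimed: list[tuple[int, int]] = []

    for kmer, pos_list in positions.items():
        if len(pos_list) < min_repeats:
            continue
        # chain positions with legal consecutive gaps
        chain = [pos_list[0]]
        chains = []
        for p in pos_list[1:]:
            if gap_min <= p - chain[-1] <= gap_max:
                chain.append(p)
            else:
                chains.append(chain)
                chain = [p]
        chains.append(chain)
        for chain in chains:
            if len(chain) < min_repeats:
                continue
            if any(s <= chain[0] < e for s, e in claimed):
                continue
            # extend the repeat as far as all copies agree and spacers stay legal
            min_gap = min(b - a for a, b in zip(chain, chain[1:]))
            max_r = min(rmax, min_gap - smin,
                        len(host_seq) - chain[-1])
            best_r = 0
            for r in range(max_r, seed - 1, -1):
                ref = host_seq[chain[0]:chain[0] + r]
                if all(host_seq[p:p + r] == ref for p in chain[1:]):
                    best_r = r
                    break
            if best_r < rmin:
                continue
            spacers = [host_seq[a + best_r:b] for a, b in zip(chain, chain[1:])]
            if not all(smin <= len(s) <= smax for s in spacers):
                continue
            if len(set(spacers)) != len(spacers):
                continue
            start, end = chain[0], chain[-1] + best_r
            arrays.append(CrisprArray(host_id, start, end,
                                      host_seq[chain[0]:chain[0] + best_r],
                                      spacers, len(chain)))
            claimed.append((start, end))
    arrays.sort(key=lambda a: a.start)
    return arrays


def _find_approx(pattern: str, text: str, max_mm: int) -> Optional[int]:
    """Minimal Hamming distance (<= max_mm) of pattern over all windows.

    Pigeonhole: any window with <= max_mm mismatches contains an exact copy
    of one of max_mm+1 pattern pieces; candidate windows are enumerated via
    exact piece search, then verified.
    """
    m, n = len(pattern), len(text)
    if m > n:
        return None
    pieces = max_mm + 1
    bounds = [round(i * m / pieces) for i in range(pieces + 1)]
    best: Optional[int] = None
    seen: set[int] = set()
    for i in range(pieces):
        lo, hi = bounds[i], bounds[i + 1]
        piece = pattern[lo:hi]
        at = text.find(piece)
        while at != -1:
            w = at - lo
            if 0 <= w <= n - m and w not in seen:
                seen.add(w)
                mm = 0
                window = text[w:w + m]
                for x, y in zip(pattern, window):
                    if x != y or x == "N":
                        mm += 1
                        if mm > max_mm:
                            break
                else:
                    if best is None or mm < best:
                        best = mm
                        if best == 0:
                            return 0
            at = text.find(piece, at + 1)
    return best


def match_spacers(
    arrays: Sequence[CrisprArray],
    viral_contigs: Sequence[ContigRecord],
    max_mismatches: int = 1,
    min_spacer_length: int = 20,
) -> list[HostEvidence]:
    """Link hosts to viruses through CRISPR spacer matches.

    A spacer matches a viral contig iff it (or its reverse complement)
    occurs at full length with Hamming distance <= 1. Strand-symmetric.
    """
    evidence: list[HostEvidence] = []
    for array in arrays:
        for spacer in array.spacers:
            if len(spacer) < min_spacer_length:
                continue
            rc = revcomp(spacer)
            for contig in viral_contigs:
                hits = [mm for mm in (
                    _find_approx(spacer, contig.sequence, max_mismatches),
                    _find_approx(rc, contig.sequence, max_mismatches),
                ) if mm is not None]
                if hits:
                    evidence.append(HostEvidence(
                        contig.contig_id, array.host_id, "crispr",
                        {"spacer": spacer, "mismatches": min(hits)}))
    return evidence


# ---------------------------------------------------------------------------
# 3. shared tRNAs

def match_trna(
    trna_by_host: Mapping[str, Sequence[str]],
    viral_contigs: Sequence[ContigRecord],
) -> list[HostEvidence]:
    """Evidence iff a host tRNA occurs exactly (either strand) in a virus."""
    evidence = []
    for host_id, trnas in trna_by_host.items():
        for idx, trna in enumerate(trnas):
            trna = trna.upper()
            rc = revcomp(trna)
            for contig in viral_contigs:
                if trna in contig.sequence or rc in contig.sequence:
                    evidence.append(HostEvidence(
                        contig.contig_id, host_id, "trna",
                        {"trna_index": idx, "length": len(trna)}))
    return evidence


# ---------------------------------------------------------------------------
# 4. k-mer composition (Markov scorer)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=np.int64)


@dataclass
class MarkovModel:
    """Order-k model of base probability given the preceding k-mer."""

    order: int
    log_prob: np.ndarray  # shape (4**k, 4)

    @classmethod
    def train(cls, genome: str, order: int = 3) -> "MarkovModel":
        k = order
        counts = np.ones((4 ** k if k else 1, 4))  # add-one pseudocounts
        for strand in (genome.upper(), revcomp(genome.upper())):
            enc = _encode(strand)
            valid = enc >= 0
            if k == 0:
                counts[0] += np.bincount(enc[valid], minlength=4)
                continue
            # rolling context index over windows free of invalid bases
            powers = 4 ** np.arange(k - 1, -1, -1)
            n = len(enc)
            if n <= k:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(enc, k + 1)
            ok = (windows >= 0).all(axis=1)
            ctx = windows[ok, :k] @ powers
            nxt = windows[ok, k]
            np.add.at(counts, (ctx, nxt), 1)
        log_prob = np.log(counts / counts.sum(axis=1, keepdims=True))
        return cls(order, log_prob)

    def score(self, seq: str) -> float:
        """Mean log-probability per scored nt (always <= 0)."""
        k = self.order
        enc = _encode(seq.upper())
        if len(enc) <= k:
            raise ValueError(f"sequence of {len(enc)} nt too short for order {k}")
        if k == 0:
            valid = enc >= 0
            if not valid.any():
                raise ValueError("no scorable bases")
            return float(self.log_prob[0, enc[valid]].mean())
        powers = 4 ** np.arange(k - 1, -1, -1)
        windows = np.lib.stride_tricks.sliding_window_view(enc, k + 1)
        ok = (windows >= 0).all(axis=1)
        if not ok.any():
            raise ValueError("no scorable positions")
        ctx = windows[ok, :k] @ powers
        nxt = windows[ok, k]
        return float(self.log_prob[ctx, nxt].mean())


def markov_score(
    viral_contig: ContigRecord,
    host_models: Mapping[str, MarkovModel],
) -> tuple[pd.DataFrame, HostEvidence]:
    """Rank hosts by per-nt log-likelihood of the contig; top host is evidence."""
    if not host_models:
        raise ValueError("no host models")
    scores = {host: model.score(viral_contig.sequence)
              for host, model in host_models.items()}
    table = (pd.DataFrame({"host_id": list(scores), "loglik_per_nt":
                           list(scores.values())})
             .sort_values(["loglik_per_nt", "host_id"],
                          ascending=[False, True])
             .reset_index(drop=True))
    top = table.iloc[0]
    gap = (float(top["loglik_per_nt"] - table.iloc[1]["loglik_per_nt"])
           if len(table) > 1 else math.inf)
    evidence = HostEvidence(viral_contig.contig_id, str(top["host_id"]), "kmer",
                            {"loglik_per_nt": float(top["loglik_per_nt"]),
                             "rank_gap": gap})
    return table, evidence


# ---------------------------------------------------------------------------
# integration

def integrate_host_evidence(
    evidence: Iterable[HostEvidence],
    points: Optional[Mapping[str, float]] = None,
    method_bonus: float = 0.5,
    cap: float = 5.0,
    high_confidence_min: float = 3.0,
) -> list[HostPrediction]:
    """Integrate per-pair evidence into a confidence score.

    Base points per evidence: CRISPR 0-mismatch 5, CRISPR 1-mismatch 3,
    homology 3, tRNA 2, k-mer top rank 1. The pair score is the best base
    plus 0.5 per additional distinct supporting method, capped at 5. The
    point table is this package's documented surrogate for a scored
    integrator; only the high-confidence boundary (>= 3) is externally
    fixed.
    """
    points = dict(points or {"crispr0": 5.0, "crispr1": 3.0, "homology": 3.0,
                             "trna": 2.0, "kmer": 1.0})
    by_pair: dict[tuple[str, str], list[HostEvidence]] = {}
    for ev in evidence:
        by_pair.setdefault((ev.virus_id, ev.host_id), []).append(ev)
    predictions = []
    for (virus, host), rows in sorted(by_pair.items()):
        bases = []
        methods = sorted({ev.method for ev in rows})
        for ev in rows:
            if ev.method == "crispr":
                key = f"crispr{min(int(ev.detail.get('mismatches', 0)), 1)}"
            else:
                key = ev.method
            bases.append(points[key])
        score = min(max(bases) + method_bonus * (len(methods) - 1), cap)
        predictions.append(HostPrediction(virus, host, score,
                                          score >= high_confidence_min,
                                          methods))
    return predictions


def predictions_to_frame(predictions: Sequence[HostPrediction]) -> pd.DataFrame:
    return pd.DataFrame([{
        "virus_id": p.virus_id, "host_id": p.host_id, "score": p.score,
        "high_confidence": int(p.high_confidence),
        "methods": ";".join(p.methods),
    } for p in predictions], columns=["virus_id", "host_id", "score",
                                      "high_confidence", "methods"])


def evidence_to_frame(evidence: Sequence[HostEvidence]) -> pd.DataFrame:
    return pd.DataFrame([{
        "virus_id": e.virus_id, "host_id": e.host_id, "method": e.method,
        "detail": ";".join(f"{k}={v}" for k, v in e.detail.items()),
    } for e in evidence], columns=["virus_id", "host_id", "method", "detail"])
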