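"""Coverage-based community ecology.

Depth estimation applies the read filters used by CoverM-style mappers
(read identity >= 95%, aligned length >= 50 nt) and zeroes contigs whose
covered fraction is below 10%. Depths are normalized per gigabase of
sample sequencing, relativized per sample, and transformed into
pseudo-counts (x10, ceiled) for the rare-frequency richness estimators
(Chao1, ACE). Shannon and inverse Simpson are computed on relative
abundances with natural logs. Beta diversity uses Bray-Curtis
dissimilarity with principal-coordinate ordination, group differences are
tested by PERMANOVA (free label permutation) plus classic two-sided
two-sample t and exact Wilcoxon rank-sum tests on the alpha indices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu, ttest_ind
from skbio import DistanceMatrix
from skbio.diversity.alpha import ace as _skbio_ace
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.ordination import pcoa as _skbio_pcoa

log = logging.getLogger("hadalvir")


# ---------------------------------------------------------------------------
# depth

def depth_from_reads(
    reads: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    covered_fraction: pd.DataFrame,
    min_identity: float = 0.95,
    min_aligned_length: int = 50,
    min_covered_fraction: float = 0.10,
) -> pd.DataFrame:
    """Mean sequencing depth per (contig, sample) from read summaries.

    ``reads`` has one row per mapped read (contig_id, sample_id, identity,
    aligned_length); mean depth = qualifying aligned bases / contig length.
    ``covered_fraction`` has columns (contig_id, sample_id,
    covered_fraction); pairs below the coverage floor are reported as zero
    depth.
    """
    if (reads["aligned_length"] < 0).any():
        raise ValueError("negative aligned length")
    ok = ((reads["identity"] >= min_identity)
          & (reads["aligned_length"] >= min_aligned_length))
    bases = (reads[ok].groupby(["contig_id", "sample_id"])["aligned_length"]
             .sum())
    cov = covered_fraction.set_index(["contig_id", "sample_id"])[
        "covered_fraction"]
    rows = []
    for (contig, sample), frac in cov.items():
        if contig not in contig_lengths:
            raise ValueError(f"unknown contig {contig!r} in coverage table")
        total = float(bases.get((contig, sample), 0.0))
        depth = total / contig_lengths[contig]
        if frac < min_covered_fraction:
            depth = 0.0
        rows.append({"contig_id": contig, "sample_id": sample,
                     "mean_depth": depth, "covered_fraction": frac})
    return pd.DataFrame(rows)


def apply_coverage_filter(
    depth: pd.DataFrame,
    min_covered_fraction: float = 0.10,
) -> pd.DataFrame:
    """Zero the depth of rows whose covered fraction is below the floor."""
    if (depth["mean_depth"] < 0).any():
        raise ValueError("negative depth input")
    out = depth.copy()
    out.loc[out["covered_fraction"] < min_covered_fraction, "mean_depth"] = 0.0
    return out


def trimmed_mean_depth(per_base: np.ndarray, trim: float = 0.05) -> float:
    """Mean per-base depth after trimming ``trim`` of positions per tail."""
    if not 0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    ordered = np.sort(np.asarray(per_base, dtype=float))
    k = int(len(ordered) * trim)
    kept = ordered[k:len(ordered) - k] if k else ordered
    return float(kept.mean())


def depth_matrix(depth: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long depth table to contig x sample, zero-filled."""
    return (depth.pivot_table(index="contig_id", columns="sample_id",
                              values="mean_depth", fill_value=0.0,
                              aggfunc="sum")
            .rename_axis(index=None, columns=None))


def normalize_and_relativize(
    depths: pd.DataFrame,
    sample_gb: Mapping[str, float],
    pseudo_multiplier: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list]:
    """Per-Gb normalized, relative, and pseudo-count abundance matrices.

    normalized = depth / Gb of the sample; relative = per-sample share of
    the normalized column (all-zero columns stay zero and are flagged);
    pseudo-counts = ceil(multiplier x normalized), non-negative integers.
    Returns (normalized, relative, pseudo_counts, zero_total_samples).
    """
    missing = [s for s in depths.columns if s not in sample_gb]
    if missing:
        raise ValueError(f"missing Gb size for sample(s) {missing}")
    gb = pd.Series({s: float(sample_gb[s]) for s in depths.columns})
    if (gb <= 0).any():
        raise ValueError("sample Gb sizes must be positive")
    normalized = depths.div(gb, axis=1)
    totals = normalized.sum(axis=0)
    zero_samples = list(totals.index[totals == 0])
    safe = totals.replace(0, np.nan)
    relative = normalized.div(safe, axis=1).fillna(0.0)
    pseudo = np.ceil(pseudo_multiplier * normalized).astype(int)
    return normalized, relative, pseudo, zero_samples


# ---------------------------------------------------------------------------
# alpha diversity

def shannon_index(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def inverse_simpson(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    p = p / p.sum()
    return float(1.0 / (p ** 2).sum())


def _ace(counts: np.ndarray, rare_threshold: int = 10) -> float:
    counts = counts[counts > 0]
    rare = counts[counts <= rare_threshold]
    if rare.size == 0 or (rare == 1).all():
        # no rare species, or coverage undefined: the estimator degenerates
        return float((counts > 0).sum())
    return float(_skbio_ace(counts.astype(int), rare_threshold=rare_threshold))


def alpha_diversity(counts: Sequence[int],
                    rare_threshold: int = 10) -> dict:
    """Observed richness, Chao1 (bias-corrected), ACE, Shannon, inv. Simpson.

    Chao1 = S_obs + F1(F1-1) / (2(F2+1)); Shannon uses natural logs on the
    count proportions.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("all-zero count vector")
    positive = counts[counts > 0]
    return {
        "observed": int(positive.size),
        "chao1": float(_skbio_chao1(counts.astype(int), bias_corrected=True)),
        "ace": _ace(counts.astype(int), rare_threshold),
        "shannon": shannon_index(counts),
        "inv_simpson": inverse_simpson(counts),
    }


def sample_diversity(
    pseudo: pd.DataFrame,
    relative: pd.DataFrame,
    rare_threshold: int = 10,
) -> pd.DataFrame:
    """Per-sample alpha-diversity table.

    Richness estimators (observed, Chao1, ACE) are computed on the integer
    pseudo-counts; Shannon and inverse Simpson directly on the relative
    abundances.
    """
    rows = []
    for sample in pseudo.columns:
        counts = pseudo[sample].to_numpy()
        rel = relative[sample].to_numpy()
        entry = {"sample_id": sample}
        if counts.sum() == 0:
            entry.update({"observed": 0, "chao1": 0.0, "ace": 0.0,
                          "shannon": 0.0, "inv_simpson": 0.0})
        else:
            a = alpha_diversity(counts, rare_threshold)
            entry.update({"observed": a["observed"], "chao1": a["chao1"],
                          "ace": a["ace"],
                          "shannon": shannon_index(rel),
                          "inv_simpson": inverse_simpson(rel)})
        rows.append(entry)
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# beta diversity / ordination

def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (columns of the matrix)."""
    totals = matrix.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with zero total abundance: {zero}")
    condensed = pdist(matrix.T.to_numpy(), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(matrix.columns))


def principal_coordinates(dm: DistanceMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """PCoA of a distance matrix; axes with negative eigenvalues dropped.

    Coordinates are scaled by the square root of each eigenvalue, so
    Euclidean distances among the retained coordinates reconstruct a
    Euclidean input matrix exactly.
    """
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # negative eigenvalues
        result = _skbio_pcoa(dm, method="eigh")
    eigvals = result.eigvals
    keep = [axis for axis, ev in eigvals.items() if ev > 1e-12]
    coords = result.samples[keep]
    return coords, eigvals


def beta_ordination(
    relative: pd.DataFrame,
) -> tuple[DistanceMatrix, pd.DataFrame, pd.Series]:
    """Bray-Curtis matrix, PCoA coordinates and the full eigenvalue series."""
    if relative.shape[1] < 3:
        raise ValueError("ordination needs at least 3 samples")
    dm = bray_curtis(relative)
    coords, eigvals = principal_coordinates(dm)
    return dm, coords, eigvals


# ---------------------------------------------------------------------------
# group tests

def permanova_test(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """PERMANOVA pseudo-F and permutation p on a distance matrix.

    Labels are permuted freely; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    grouping = [groups[s] for s in dm.ids]
    sizes = pd.Series(grouping).value_counts()
    if (sizes < 2).any():
        raise ValueError("each group needs n >= 2")
    result = _skbio_permanova(dm, grouping, permutations=n_perm, seed=seed)
    return float(result["test statistic"]), float(result["p-value"])


def alpha_group_tests(
    diversity: pd.DataFrame,
    groups: Mapping[str, str],
    indices: Sequence[str] = ("observed", "chao1", "ace", "shannon",
                              "inv_simpson"),
) -> pd.DataFrame:
    """Two-sided classic t and Wilcoxon rank-sum p-values per alpha index.

    The t-test is the classic pooled-variance two-sample test; the rank-sum
    test uses the exact null distribution when both groups have n <= 10.
    """
    labels = pd.Series({s: groups[s] for s in diversity.index})
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    ga = diversity.loc[labels == names[0]]
    gb = diversity.loc[labels == names[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs n >= 2")
    rows = []
    for index in indices:
        x, y = ga[index].to_numpy(), gb[index].to_numpy()
        t_stat, t_p = ttest_ind(x, y, equal_var=True)
        method = "exact" if max(len(x), len(y)) <= 10 else "asymptotic"
        _, w_p = mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append({"index": index,
                     "mean_" + names[0]: float(x.mean()),
                     "mean_" + names[1]: float(y.mean()),
                     "t_statistic": float(t_stat), "t_p": float(t_p),
                     "wilcoxon_p": float(w_p)})
    return pd.DataFrame(rows)


def group_tests(
    relative: pd.DataFrame,
    groups: Mapping[str, str],
    diversity: Optional[pd.DataFrame] = None,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """PERMANOVA on Bray-Curtis plus per-index alpha-diversity tests."""
    dm = bray_curtis(relative)
    pseudo_f, p = permanova_test(dm, groups, n_perm=n_perm, seed=seed)
    out = {"permanova_F": pseudo_f, "permanova_p": p}
    if diversity is not None:
        out["alpha_tests"] = alpha_group_tests(diversity, groups)
    return out


# ---------------------------------------------------------------------------
# metatranscriptomic activity

def transcribed_activity(
    gene_counts: pd.DataFrame,
    votu_of_contig: Mapping[str, str],
    min_reads: int = 2,
    min_gene_fraction: float = 0.20,
) -> pd.DataFrame:
    """Flag vOTUs as transcriptionally active.

    A gene counts as expressed iff it is mapped by more than one
    metatranscriptomic read (>= 2); a vOTU is active iff at least 20% of
    its genes are expressed.
    """
    missing = [c for c in gene_counts["contig_id"].unique()
               if c not in votu_of_contig]
    if missing:
        raise ValueError(f"contigs without a vOTU: {missing[:5]}")
    df = gene_counts.assign(
        votu_id=[votu_of_contig[c] for c in gene_counts["contig_id"]])
    grouped = df.groupby("votu_id")["reads"]
    n_genes = grouped.size()
    if (n_genes == 0).any():
        raise ValueError("vOTU with zero genes")
    expressed = grouped.apply(lambda s: int((s >= min_reads).sum()))
    fraction = expressed / n_genes
    return pd.DataFrame({
        "votu_id": n_genes.index,
        "n_genes": n_genes.to_numpy(),
        "n_expressed": expressed.to_numpy(),
        "expressed_fraction": fraction.to_numpy(),
        "active": (fraction >= min_gene_fraction).astype(int).to_numpy(),
    }).reset_index(drop=True)
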