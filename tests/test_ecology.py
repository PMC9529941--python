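import itertools
import math

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from hadalvir.ecology import (alpha_diversity, alpha_group_tests,
                              apply_coverage_filter, bray_curtis,
                              beta_ordination, depth_from_reads, depth_matrix,
                              inverse_simpson, normalize_and_relativize,
                              permanova_test, principal_coordinates,
                              sample_diversity, shannon_index,
                              transcribed_activity, trimmed_mean_depth)


class TestDepth:
    def _reads(self, n, identity=0.99, aln=100):
        return pd.DataFrame({"contig_id": ["c1"] * n, "sample_id": ["s1"] * n,
                             "identity": [identity] * n,
                             "aligned_length": [aln] * n})

    def _cov(self, frac):
        return pd.DataFrame({"contig_id": ["c1"], "sample_id": ["s1"],
                             "covered_fraction": [frac]})

    def test_mean_depth_arithmetic(self):
        out = depth_from_reads(self._reads(100), {"c1": 1000}, self._cov(0.95))
        assert out.loc[0, "mean_depth"] == pytest.approx(10.0)

    def test_low_identity_reads_excluded(self):
        out = depth_from_reads(self._reads(100, identity=0.90), {"c1": 1000},
                               self._cov(0.95))
        assert out.loc[0, "mean_depth"] == 0.0

    def test_short_alignments_excluded(self):
        out = depth_from_reads(self._reads(100, aln=49), {"c1": 1000},
                               self._cov(0.95))
        assert out.loc[0, "mean_depth"] == 0.0

    def test_coverage_floor_zeroes_depth(self):
        out = depth_from_reads(self._reads(100), {"c1": 1000}, self._cov(0.09))
        assert out.loc[0, "mean_depth"] == 0.0

    def test_coverage_boundary_toggle(self):
        depth = pd.DataFrame({"contig_id": ["c1", "c2"],
                              "sample_id": ["s1", "s1"],
                              "mean_depth": [5.0, 5.0],
                              "covered_fraction": [0.099, 0.10]})
        out = apply_coverage_filter(depth)
        assert out["mean_depth"].tolist() == [0.0, 5.0]

    def test_negative_depth_is_error(self):
        depth = pd.DataFrame({"contig_id": ["c1"], "sample_id": ["s1"],
                              "mean_depth": [-1.0], "covered_fraction": [0.5]})
        with pytest.raises(ValueError):
            apply_coverage_filter(depth)

    def test_trimmed_mean_drops_tails(self):
        per_base = np.array([0.0] * 5 + [10.0] * 90 + [1000.0] * 5)
        assert trimmed_mean_depth(per_base, trim=0.05) == pytest.approx(10.0)


class TestNormalization:
    def test_per_gb_and_pseudocounts(self):
        depths = pd.DataFrame({"s1": [10.0, 0.115]}, index=["v1", "v2"])
        normalized, relative, pseudo, zero = normalize_and_relativize(
            depths, {"s1": 5.0})
        assert normalized.loc["v1", "s1"] == pytest.approx(2.0)
        # 0.115/5 = 0.023 -> x10 = 0.23 -> ceil = 1
        assert pseudo.loc["v2", "s1"] == 1
        assert pseudo.loc["v1", "s1"] == 20
        assert relative["s1"].sum() == pytest.approx(1.0)
        assert zero == []

    def test_ceiling_worked_example(self):
        depths = pd.DataFrame({"s1": [0.23]}, index=["v1"])
        _, _, pseudo, _ = normalize_and_relativize(depths, {"s1": 1.0})
        assert pseudo.loc["v1", "s1"] == 3  # ceil(2.3)

    def test_zero_column_flagged_not_divided(self):
        depths = pd.DataFrame({"s1": [1.0], "s2": [0.0]}, index=["v1"])
        _, relative, _, zero = normalize_and_relativize(
            depths, {"s1": 1.0, "s2": 1.0})
        assert zero == ["s2"] and relative.loc["v1", "s2"] == 0.0

    def test_missing_gb_is_error(self):
        depths = pd.DataFrame({"s1": [1.0]}, index=["v1"])
        with pytest.raises(ValueError, match="s1"):
            normalize_and_relativize(depths, {})


class TestAlphaDiversity:
    def test_uniform_closed_forms(self):
        a = alpha_diversity([5] * 10)
        assert a["observed"] == 10
        assert a["shannon"] == pytest.approx(math.log(10))
        assert a["inv_simpson"] == pytest.approx(10.0)
        assert a["chao1"] == pytest.approx(10.0)
        assert a["ace"] == pytest.approx(10.0)

    def test_chao1_formula_with_singletons(self):
        # S + F1(F1-1)/(2(F2+1)) = 3 + 2*1/(2*2) = 3.5
        assert alpha_diversity([1, 1, 2])["chao1"] == pytest.approx(3.5)

    def test_estimators_degenerate_without_rare_species(self):
        a = alpha_diversity([12, 15, 20])
        assert a["chao1"] == a["ace"] == a["observed"] == 3

    def test_all_zero_vector_is_error(self):
        with pytest.raises(ValueError):
            alpha_diversity([0, 0, 0])

    def test_index_inequalities(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 30, size=25)
            if counts.sum() == 0:
                continue
            a = alpha_diversity(counts)
            assert a["shannon"] <= math.log(a["observed"]) + 1e-12
            assert 1 - 1e-12 <= a["inv_simpson"] <= a["observed"] + 1e-12
            assert a["chao1"] >= a["observed"] - 1e-12


class TestBetaOrdination:
    def test_bray_curtis_bounds_and_worked_example(self):
        mat = pd.DataFrame({"same1": [2.0, 2.0], "same2": [2.0, 2.0],
                            "mix": [1.0, 3.0], "disjoint": [0.0, 4.0]},
                           index=["v1", "v2"])
        mat.loc["v3"] = [0.0, 0.0, 0.0, 1.0]
        mat.loc["v1", "disjoint"] = 0.0
        dm = bray_curtis(mat)
        assert dm["same1", "same2"] == 0.0
        # BC([2,2,0],[1,3,0]) = (1+1)/8
        assert dm["same1", "mix"] == pytest.approx(0.25)
        data = dm.data
        assert np.allclose(data, data.T) and np.all(np.diag(data) == 0)
        assert (data >= 0).all() and (data <= 1).all()

    def test_fully_disjoint_samples_at_distance_one(self):
        mat = pd.DataFrame({"a": [1.0, 2.0, 0.0, 0.0],
                            "b": [0.0, 0.0, 3.0, 1.0]})
        assert bray_curtis(mat)["a", "b"] == 1.0

    def test_zero_total_sample_error_names_it(self):
        mat = pd.DataFrame({"ok": [1.0], "empty": [0.0]})
        with pytest.raises(ValueError, match="empty"):
            bray_curtis(mat)

    def test_pcoa_reconstructs_euclidean_distances(self, rng):
        points = rng.normal(size=(12, 4))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(points))
        ids = [f"s{i}" for i in range(12)]
        coords, eigvals = principal_coordinates(DistanceMatrix(d, ids=ids))
        recon = squareform(pdist(coords.to_numpy()))
        assert np.abs(recon - d).max() < 1e-8

    def test_negative_eigenvalue_axes_dropped(self, rng):
        rel = pd.DataFrame(rng.dirichlet(np.ones(8), size=6).T,
                           columns=[f"s{i}" for i in range(6)])
        _, coords, eigvals = beta_ordination(rel)
        assert (eigvals < 0).any() or len(coords.columns) <= len(eigvals)
        kept = eigvals[coords.columns]
        assert (kept > 0).all()


def brute_force_permanova_p(dm, labels):
    """Exhaustive-permutation PERMANOVA oracle for tiny designs.

    Computes the pseudo-F for every distinct assignment of the group
    labels and returns the exact permutation p-value.
    """
    labels = np.asarray(labels)
    n = len(labels)

    def pseudo_f(lab):
        groups = {}
        for i, g in enumerate(lab):
            groups.setdefault(g, []).append(i)
        d2 = dm.data ** 2
        sst = d2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        for idx in groups.values():
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ssa = sst - ssw
        a = len(groups)
        return (ssa / (a - 1)) / (ssw / (n - a))

    observed = pseudo_f(labels)
    n_a = int((labels == labels[0]).sum())
    count = total = 0
    for combo in itertools.combinations(range(n), n_a):
        lab = np.array(["B"] * n, dtype=object)
        lab[list(combo)] = "A"
        total += 1
        if pseudo_f(lab) >= observed - 1e-12:
            count += 1
    return count / total


class TestGroupTests:
    def _relative(self, rng, n_votus=20, n=5, effect=1.0):
        cols = {}
        for i in range(n):
            cols[f"a{i}"] = rng.lognormal(0, 1, n_votus)
            cols[f"b{i}"] = rng.lognormal(0, 1, n_votus) * np.where(
                np.arange(n_votus) < n_votus // 2, effect, 1.0)
        mat = pd.DataFrame(cols)
        return mat / mat.sum(axis=0), {f"a{i}": "A" for i in range(n)} | \
            {f"b{i}": "B" for i in range(n)}

    def test_t_test_reference_value(self):
        diversity = pd.DataFrame({"shannon": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]},
                                 index=list("abcdef"))
        groups = {s: ("A" if s in "abc" else "B") for s in "abcdef"}
        out = alpha_group_tests(diversity, groups, indices=("shannon",))
        # classic two-sample t on {1,2,3} vs {4,5,6}: t = -3.674, df = 4
        assert out.loc[0, "t_statistic"] == pytest.approx(-3.674, abs=1e-3)
        assert out.loc[0, "t_p"] == pytest.approx(0.0213, abs=1e-3)

    def test_wilcoxon_exact_for_small_groups(self):
        diversity = pd.DataFrame({"shannon": [1, 2, 3, 10, 11, 12]},
                                 index=list("abcdef"))
        groups = {s: ("A" if s in "abc" else "B") for s in "abcdef"}
        out = alpha_group_tests(diversity, groups, indices=("shannon",))
        # exact two-sided rank-sum p for complete separation at 3+3
        assert out.loc[0, "wilcoxon_p"] == pytest.approx(0.1, abs=1e-9)

    def test_permanova_matches_exhaustive_enumeration(self, rng):
        # perfectly separated 3+3 design: exact p = 2/C(6,3) = 0.1
        mat = pd.DataFrame({
            "a0": [1.0, 1.0, 0, 0], "a1": [0.9, 1.1, 0, 0],
            "a2": [1.1, 0.9, 0, 0],
            "b0": [0, 0, 1.0, 1.0], "b1": [0, 0, 0.9, 1.1],
            "b2": [0, 0, 1.1, 0.9]})
        groups = {s: s[0].upper() for s in mat.columns}
        dm = bray_curtis(mat)
        exact = brute_force_permanova_p(dm, [groups[s] for s in dm.ids])
        assert exact == pytest.approx(2 / 20)
        _, p = permanova_test(dm, groups, n_perm=999, seed=1)
        assert abs(p - exact) < 0.04  # sampled permutations vs exact null

    def test_permanova_detects_planted_separation(self):
        from hadalvir.synthetic import make_communities
        comm = make_communities(40, 8, group_effect=0.5, group_factor=10.0,
                                seed=33)
        mat = depth_matrix(apply_coverage_filter(comm.depth))
        gb = dict(zip(comm.samples["sample_id"], comm.samples["gb"]))
        _, rel, _, _ = normalize_and_relativize(mat, gb)
        groups = dict(zip(comm.samples["sample_id"], comm.samples["group"]))
        _, p = permanova_test(bray_curtis(rel), groups, n_perm=999, seed=2)
        assert p <= 0.05

    def test_permanova_deterministic_under_seed(self, rng):
        rel, groups = self._relative(rng)
        dm = bray_curtis(rel)
        assert permanova_test(dm, groups, seed=5) == \
            permanova_test(dm, groups, seed=5)

    def test_group_too_small_is_error(self, rng):
        rel, groups = self._relative(rng, n=2)
        groups["a1"] = "B"
        with pytest.raises(ValueError):
            permanova_test(bray_curtis(rel), groups)


class TestActivity:
    def _counts(self, reads):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(reads))],
            "contig_id": ["c1"] * len(reads),
            "reads": reads,
        })

    def test_twenty_percent_boundary_is_active(self):
        out = transcribed_activity(self._counts([2, 2] + [0] * 8),
                                   {"c1": "v1"})
        assert out.loc[0, "active"] == 1
        assert out.loc[0, "expressed_fraction"] == pytest.approx(0.2)

    def test_single_read_does_not_count_as_expressed(self):
        out = transcribed_activity(self._counts([1] * 10), {"c1": "v1"})
        assert out.loc[0, "n_expressed"] == 0 and out.loc[0, "active"] == 0

    def test_small_votu_boundary(self):
        out = transcribed_activity(self._counts([3, 0, 0, 0, 0]),
                                   {"c1": "v1"})
        assert out.loc[0, "active"] == 1

    def test_below_boundary_inactive(self):
        out = transcribed_activity(self._counts([5] + [0] * 9 + [1] * 0),
                                   {"c1": "v1"})
        assert out.loc[0, "active"] == 0


class TestSampleDiversity:
    def test_rich_sample_scores_higher(self, rng):
        pseudo = pd.DataFrame({"rich": rng.integers(1, 20, 30),
                               "poor": [0] * 28 + [10, 10]})
        relative = pseudo / pseudo.sum(axis=0)
        div = sample_diversity(pseudo, relative)
        assert div.loc["rich", "observed"] > div.loc["poor", "observed"]
        assert div.loc["rich", "shannon"] > div.loc["poor", "shannon"]
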