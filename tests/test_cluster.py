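import math

import numpy as np
import pytest

from hadalvir.cluster import (gene_sharing_edges, genus_clusters,
                              greedy_species_cluster, pairwise_ani,
                              shared_pc_pvalue)
from hadalvir.io import ContigRecord
from hadalvir.synthetic import (make_pc_families, make_species_set,
                                make_variants, random_seq)
from tests.conftest import dp_identity


class TestPairwiseAni:
    def test_identical_sequences(self, rng):
        seq = random_seq(rng, 3137)
        assert pairwise_ani(seq, seq) == (100.0, 1.0)

    def test_agrees_with_dp_oracle_on_substitution_pairs(self, rng,
                                                         dp_aligner):
        for i in range(8):
            seed = random_seq(rng, 3000)
            target = float(rng.uniform(0.88, 1.0))
            variant, (realized, _) = make_variants(seed, target, 1.0, seed=i)
            ani, af = pairwise_ani(seed, variant)
            oracle = dp_identity(dp_aligner, seed, variant)
            assert abs(ani - oracle) <= 0.5
            assert af == 1.0

    def test_unrelated_sequences_do_not_align(self, rng):
        a, b = random_seq(rng, 3000), random_seq(rng, 3000)
        ani, af = pairwise_ani(a, b)
        assert af == 0.0

    def test_symmetry(self, rng):
        a = random_seq(rng, 4000)
        b, _ = make_variants(a, 0.96, 0.9, seed=3, length_offset=50)
        assert pairwise_ani(a, b) == pairwise_ani(b, a)

    def test_short_sequence_falls_back_to_full_alignment(self, rng):
        a = random_seq(rng, 300)
        ani, af = pairwise_ani(a, a + random_seq(rng, 2000))
        assert ani == 100.0 and af == 1.0

    def test_n_bases_count_as_mismatches(self, rng):
        a = random_seq(rng, 800)
        b = a[:100] + "N" * 8 + a[108:]
        ani, _ = pairwise_ani(a, b)
        assert ani < 100.0
        # N never matches, not even another N
        ani_nn, _ = pairwise_ani(b, b)
        assert ani_nn < 100.0


class TestGreedyClustering:
    def test_variant_above_thresholds_joins_representative(self, rng):
        a_seq = random_seq(rng, 4000)
        b_seq, _ = make_variants(a_seq, 0.96, 1.0, seed=1, length_offset=200)
        votus = greedy_species_cluster([ContigRecord("A", a_seq),
                                        ContigRecord("B", b_seq)])
        assert len(votus) == 1
        assert votus[0].representative == "A"

    def test_low_aligned_fraction_splits(self, rng):
        a_seq = random_seq(rng, 4000)
        b_seq, _ = make_variants(a_seq, 0.96, 0.80, seed=2, length_offset=200)
        votus = greedy_species_cluster([ContigRecord("A", a_seq),
                                        ContigRecord("B", b_seq)])
        assert len(votus) == 2

    def test_greedy_chain_splits_at_the_representative(self, rng, dp_aligner):
        # A ~ B ~ C where B sits between: B joins A, C fails against the
        # representative A and founds its own cluster
        a_seq = random_seq(rng, 3000)
        b_seq, _ = make_variants(a_seq, 0.97, 1.0, seed=3, length_offset=500)
        c_seq, _ = make_variants(b_seq, 0.96, 1.0, seed=4, length_offset=500)
        ab = dp_identity(dp_aligner, a_seq[:2500], b_seq)
        ac = dp_identity(dp_aligner, a_seq[:2000], c_seq)
        assert ab >= 95.0 and ac < 95.0  # planted chain structure
        votus = greedy_species_cluster([ContigRecord("A", a_seq),
                                        ContigRecord("B", b_seq),
                                        ContigRecord("C", c_seq)])
        members = sorted(tuple(sorted(v.members)) for v in votus)
        assert members == [("A", "B"), ("C",)]

    def test_input_order_invariance(self, rng):
        bench = make_species_set(2, seed=7)
        votus = greedy_species_cluster(bench.contigs)
        reversed_votus = greedy_species_cluster(bench.contigs[::-1])
        as_sets = lambda vs: sorted(tuple(sorted(v.members)) for v in vs)
        assert as_sets(votus) == as_sets(reversed_votus)

    def test_member_metrics_respect_thresholds(self, rng):
        bench = make_species_set(2, seed=8)
        for votu in greedy_species_cluster(bench.contigs):
            for member, (ani, af) in votu.member_metrics.items():
                assert ani >= 95.0 and af >= 0.85

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            greedy_species_cluster([])


def exact_tail(m, a, b, c):
    """Brute-force hypergeometric tail by direct enumeration."""
    total = math.comb(m, a)
    return sum(math.comb(b, i) * math.comb(m - b, a - i)
               for i in range(c, min(a, b) + 1)) / total


class TestGeneSharingEdges:
    def test_small_worked_example(self):
        # M=4 PCs, both genomes hold 2, sharing both: P = 1/C(4,2) = 1/6
        assert shared_pc_pvalue(4, 2, 2, 2) == pytest.approx(1 / 6, abs=1e-12)

    def test_matches_enumeration_for_all_small_universes(self):
        for m in range(1, 13):
            for a in range(1, m + 1):
                for b in range(1, m + 1):
                    for c in range(max(0, a + b - m), min(a, b) + 1):
                        assert shared_pc_pvalue(m, a, b, c) == pytest.approx(
                            exact_tail(m, a, b, c), rel=1e-9, abs=1e-12)

    def test_inconsistent_share_count_is_error(self):
        with pytest.raises(ValueError):
            shared_pc_pvalue(10, 3, 3, 4)

    def test_full_sharing_in_large_universe_always_edges(self):
        pc = {f"p{i}": f"PC{i % 30}" for i in range(60)}
        genome = {f"p{i}": ("g1" if i < 30 else "g2") for i in range(60)}
        # both genomes carry the same 30 PCs out of a 300-PC universe
        for i in range(300 - 30):
            pc[f"bg{i}"] = f"BG{i}"
            genome[f"bg{i}"] = f"filler{i}"
        edges = gene_sharing_edges(pc, genome, score_min=10.0)
        pair = edges[(edges["genome_a"] == "g1") & (edges["genome_b"] == "g2")]
        assert len(pair) == 1 and pair["score"].iloc[0] >= 10.0

    def test_no_sharing_no_edge(self):
        pc = {"p1": "PC1", "p2": "PC2"}
        genome = {"p1": "g1", "p2": "g2"}
        assert len(gene_sharing_edges(pc, genome)) == 0


class TestGenusClusters:
    def test_no_edges_gives_singletons(self):
        import pandas as pd
        clusters, singletons = genus_clusters(
            pd.DataFrame(columns=["genome_a", "genome_b"]),
            [f"g{i}" for i in range(5)])
        assert len(singletons) == 5 and len(clusters) == 5

    def test_singletons_can_be_excluded(self):
        import pandas as pd
        clusters, singletons = genus_clusters(
            pd.DataFrame(columns=["genome_a", "genome_b"]),
            ["g1", "g2"], count_singletons=False)
        assert clusters == [] and len(singletons) == 2

    def test_complete_graph_is_one_genus(self):
        import pandas as pd
        genomes = ["a", "b", "c", "d"]
        edges = pd.DataFrame([{"genome_a": x, "genome_b": y}
                              for i, x in enumerate(genomes)
                              for y in genomes[i + 1:]])
        clusters, _ = genus_clusters(edges, genomes)
        assert len(clusters) == 1 and clusters[0].members == genomes

    def test_planted_pc_families_recovered(self):
        pc, genome_of, truth = make_pc_families(n_families=2, seed=3)
        edges = gene_sharing_edges(pc, genome_of, score_min=1.0)
        clusters, _ = genus_clusters(edges, sorted(set(genome_of.values())))
        multi = [c for c in clusters if len(c.members) > 1]
        assert len(multi) == 2
        for cluster in multi:
            families = {truth.set_index("genome_id").loc[m, "family"]
                        for m in cluster.members}
            assert len(families) == 1  # no family mixing
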