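import math

import numpy as np
import pytest

from hadalvir.hosts import (HostEvidence, MarkovModel, detect_crispr_arrays,
                            filter_homology_matches, integrate_host_evidence,
                            markov_score, match_spacers, match_trna, revcomp)
from hadalvir.io import AlignmentRow, ContigRecord
from hadalvir.synthetic import _substitute, make_genomes, random_seq


def _aln(length, identity, s_start=1001, virus="v1", host="h1"):
    return AlignmentRow(virus, host, identity, length, 0, 0, 1, length,
                        s_start, s_start + length - 1, 1e-30, 100.0)


class TestHomologyFilter:
    HOST_LEN = {"h1": 100_000}

    def test_qualifying_row_kept(self):
        ev = filter_homology_matches([_aln(3000, 85.0)], self.HOST_LEN)
        assert len(ev) == 1 and ev[0].method == "homology"

    def test_short_alignment_dropped(self):
        assert filter_homology_matches([_aln(2000, 99.0)], self.HOST_LEN) == []

    def test_low_identity_dropped(self):
        assert filter_homology_matches([_aln(3000, 69.9)], self.HOST_LEN) == []

    def test_near_total_host_coverage_dropped(self):
        # the "viral" contig covers 95% of the host: binned host sequence
        ev = filter_homology_matches([_aln(95_000, 85.0, s_start=1)],
                                     self.HOST_LEN)
        assert ev == []

    def test_coverage_union_not_double_counted(self):
        rows = [_aln(50_000, 85.0, s_start=1),
                _aln(50_000, 85.0, s_start=1)]  # same interval twice
        ev = filter_homology_matches(rows, self.HOST_LEN)
        assert len(ev) == 2  # 50% coverage, both rows kept

    def test_unknown_host_is_error(self):
        with pytest.raises(ValueError):
            filter_homology_matches([_aln(3000, 85.0, host="ghost")],
                                    self.HOST_LEN)


class TestCrisprDetection:
    def _array(self, rng, n_repeats=4, repeat_len=30, spacer_len=32):
        repeat = random_seq(rng, repeat_len)
        spacers = [random_seq(rng, spacer_len) for _ in range(n_repeats - 1)]
        return repeat + repeat.join(spacers) + repeat, repeat, spacers

    def test_planted_array_recovered_verbatim(self, rng):
        array, repeat, spacers = self._array(rng)
        seq = random_seq(rng, 2000) + array + random_seq(rng, 2000)
        found = detect_crispr_arrays(seq, "h1")
        assert len(found) == 1
        assert found[0].repeat == repeat
        assert found[0].spacers == spacers
        assert found[0].n_repeats == 4

    def test_random_sequence_has_no_arrays(self, rng):
        assert detect_crispr_arrays(random_seq(rng, 10_000), "h1") == []

    def test_two_repeat_array_below_minimum(self, rng):
        repeat = random_seq(rng, 30)
        seq = (random_seq(rng, 1000) + repeat + random_seq(rng, 32)
               + repeat + random_seq(rng, 1000))
        assert detect_crispr_arrays(seq, "h1") == []

    def test_tandem_repeat_rejected_for_duplicate_spacers(self, rng):
        repeat = random_seq(rng, 30)
        spacer = random_seq(rng, 32)
        seq = (random_seq(rng, 500)
               + (repeat + spacer) * 3 + repeat + random_seq(rng, 500))
        assert detect_crispr_arrays(seq, "h1") == []


class TestSpacerMatching:
    def _setup(self, rng, mismatches, rc=False):
        from hadalvir.hosts import CrisprArray
        spacer = random_seq(rng, 32)
        planted = spacer
        if mismatches:
            positions = rng.choice(32, size=mismatches, replace=False)
            planted = _substitute(rng, spacer, positions)
        if rc:
            planted = revcomp(planted)
        contig_seq = random_seq(rng, 3000)
        at = 1500
        contig = ContigRecord("v1", contig_seq[:at] + planted
                              + contig_seq[at + 32:])
        array = CrisprArray("h1", 0, 0, "R" * 0 + "ACGT" * 8, [spacer], 3)
        return array, contig

    def test_exact_match_zero_mismatches(self, rng):
        array, contig = self._setup(rng, 0)
        ev = match_spacers([array], [contig])
        assert len(ev) == 1 and ev[0].detail["mismatches"] == 0

    def test_single_substitution_tolerated(self, rng):
        array, contig = self._setup(rng, 1)
        ev = match_spacers([array], [contig])
        assert len(ev) == 1 and ev[0].detail["mismatches"] == 1

    def test_two_substitutions_rejected(self, rng):
        array, contig = self._setup(rng, 2)
        assert match_spacers([array], [contig]) == []

    def test_strand_symmetry(self, rng):
        array, contig = self._setup(rng, 0, rc=True)
        ev = match_spacers([array], [contig])
        assert len(ev) == 1 and ev[0].detail["mismatches"] == 0
        flipped = ContigRecord("v1", revcomp(contig.sequence))
        assert len(match_spacers([array], [flipped])) == 1

    def test_short_spacers_skipped(self, rng):
        from hadalvir.hosts import CrisprArray
        contig = ContigRecord("v1", random_seq(rng, 1000))
        array = CrisprArray("h1", 0, 0, "ACGT" * 8,
                            [contig.sequence[100:115]], 3)  # 15 nt < 20
        assert match_spacers([array], [contig]) == []


class TestTrnaMatching:
    def test_exact_copy_links(self, rng):
        trna = random_seq(rng, 75)
        contig = ContigRecord("v1", random_seq(rng, 1000) + trna
                              + random_seq(rng, 1000))
        ev = match_trna({"h1": [trna]}, [contig])
        assert len(ev) == 1 and ev[0].host_id == "h1"

    def test_reverse_complement_counts_as_exact(self, rng):
        trna = random_seq(rng, 75)
        contig = ContigRecord("v1", random_seq(rng, 500) + revcomp(trna)
                              + random_seq(rng, 500))
        assert len(match_trna({"h1": [trna]}, [contig])) == 1

    def test_single_mismatch_is_not_exact(self, rng):
        trna = random_seq(rng, 75)
        mutated = _substitute(rng, trna, [40])
        contig = ContigRecord("v1", random_seq(rng, 500) + mutated
                              + random_seq(rng, 500))
        assert match_trna({"h1": [trna]}, [contig]) == []

    def test_trna_only_in_host_no_evidence(self, rng):
        trna = random_seq(rng, 75)
        contig = ContigRecord("v1", random_seq(rng, 1000))
        assert match_trna({"h1": [trna]}, [contig]) == []


class TestMarkovScorer:
    def test_order0_uniform_genome_closed_form(self, rng):
        model = MarkovModel.train(random_seq(rng, 200_000, 0.5), order=0)
        score = model.score(random_seq(rng, 2000, 0.5))
        assert score == pytest.approx(math.log(0.25), abs=0.01)

    def test_scores_are_nonpositive(self, rng):
        model = MarkovModel.train(random_seq(rng, 50_000, 0.6), order=3)
        assert model.score(random_seq(rng, 2000, 0.6)) <= 0

    def test_composition_distinct_hosts_ranked_correctly(self):
        hits = 0
        for s in range(10):
            r = np.random.default_rng(100 + s)
            models = {
                "gc30": MarkovModel.train(random_seq(r, 60_000, 0.30), 3),
                "gc70": MarkovModel.train(random_seq(r, 60_000, 0.70), 3),
            }
            contig = ContigRecord("v", random_seq(r, 5000, 0.70))
            _, ev = markov_score(contig, models)
            hits += ev.host_id == "gc70"
        assert hits == 10

    def test_contig_shorter_than_order_is_error(self, rng):
        model = MarkovModel.train(random_seq(rng, 10_000), order=3)
        with pytest.raises(ValueError):
            model.score("AC")


class TestIntegration:
    def test_exact_crispr_alone_is_high_confidence(self):
        ev = [HostEvidence("v", "h", "crispr", {"mismatches": 0})]
        pred = integrate_host_evidence(ev)[0]
        assert pred.score == 5.0 and pred.high_confidence

    def test_one_mismatch_crispr_scores_three(self):
        ev = [HostEvidence("v", "h", "crispr", {"mismatches": 1})]
        pred = integrate_host_evidence(ev)[0]
        assert pred.score == 3.0 and pred.high_confidence

    def test_kmer_alone_is_low_confidence(self):
        ev = [HostEvidence("v", "h", "kmer", {"rank_gap": 0.1})]
        pred = integrate_host_evidence(ev)[0]
        assert pred.score == 1.0 and not pred.high_confidence

    def test_homology_plus_trna_crosses_the_boundary(self):
        ev = [HostEvidence("v", "h", "homology", {}),
              HostEvidence("v", "h", "trna", {})]
        pred = integrate_host_evidence(ev)[0]
        assert pred.score == 3.5 and pred.high_confidence
        assert pred.methods == ["homology", "trna"]

    def test_score_capped_at_five(self):
        ev = [HostEvidence("v", "h", "crispr", {"mismatches": 0}),
              HostEvidence("v", "h", "homology", {}),
              HostEvidence("v", "h", "trna", {}),
              HostEvidence("v", "h", "kmer", {})]
        assert integrate_host_evidence(ev)[0].score == 5.0


class TestPlantedLinks:
    def test_planted_crispr_links_recovered_exactly(self, cfg):
        truth = make_genomes(10, 10, seed=21)
        arrays = []
        for h in truth.host_contigs:
            arrays += detect_crispr_arrays(h.sequence, h.contig_id)
        found = {(e.virus_id, e.host_id)
                 for e in match_spacers(arrays, truth.viral_contigs)}
        planted = {(r.virus_id, r.host_id)
                   for r in truth.host_links.itertuples()
                   if r.method == "crispr"}
        assert found == planted  # precision = recall = 1

    def test_no_high_confidence_without_planted_evidence(self, cfg):
        truth = make_genomes(6, 3, seed=22,
                             evidence_plan=(("trna",),))  # tRNA only: score 2
        evidence = []
        models = {h.contig_id: MarkovModel.train(h.sequence, 3)
                  for h in truth.host_contigs}
        for v in truth.viral_contigs:
            _, ev = markov_score(v, models)
            evidence.append(ev)
        evidence += match_trna(truth.trna_by_host, truth.viral_contigs)
        preds = integrate_host_evidence(evidence)
        assert all(not p.high_confidence for p in preds)
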