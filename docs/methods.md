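# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic generators do and do not emulate, and the open
design points we had to settle.

## Viral triage

Gene products are classified by case-insensitive token/phrase matching
against a configurable keyword list (capsid, phage, terminase, base
plate, baseplate, prohead, virion, virus, viral, tape measure,
tapemeasure, neck, tail, head, bacteriophage, prophage, portal, DNA
packaging, T4, p22, holin). Matching is on word boundaries so that
"head" does not hit "overhead" and "virus" does not hit "viruses" (the
taxon string "Viruses" is instead an *unknown*-category pattern, pooled
with "hypothetical protein" and "unknown function"). Precedence is
prokaryote_specific > viral_specific > unknown > other, so a single
ribosomal-protein annotation vetoes a contig regardless of its viral
genes.

A contig is retained iff

```
( n_viral_specific >= 2
  OR (>=1 predictor call AND n_unknown / n_genes >= 0.70) )
AND n_prokaryote_specific == 0
AND ( completeness known OR n_viral_specific >= 1
      OR >=1 call from the conservative-tool subset )
```

Two readings were genuinely open. "Contained viral sequences" in the
second retain rule is operationalized as ≥1 upstream predictor call —
the most literal reading available, and the predictor calls are the only
step-1 signal this pipeline consumes. The ≥70% unknown fraction pools
hypothetical, unknown-function and Viruses-annotated proteins, since the
rule lists all three. Both choices are config-visible, not hard-coded.

Direct terminal repeats are detected as the longest exact
prefix == suffix overlap, ≥20 nt by default and capped at half the
contig. Quality tiers partition every (completeness, DTR) pair:
complete = 100% with DTR; high > 90%; medium 50–90% inclusive on both
ends; low < 50%; undetermined when completeness is absent. The 90% and
50% boundaries are read as stated ("50–90%" inclusive, ">90%" strict).

Decontamination removes exactly the contigs with ≥1 blank-control read;
it is monotone (a larger blank table never enlarges the retained set).

## vOTU and genus clustering

Species-level clustering uses the consensus thresholds for uncultivated
viruses: ≥95% ANI over ≥85% of the shorter contig. Rather than wrapping
a clustering binary, ANI is measured fragment-wise: the shorter sequence
is tiled into 500 nt fragments (the final window right-anchored so the
whole sequence is covered), each placed at its best window in the longer
sequence by infix edit-distance alignment (edlib). A fragment counts as
aligned at ≥80% identity; ANI is the mean identity of aligned fragments
and AF their covered share of the shorter sequence. The alignment band
is set to (1 − 0.80) × fragment so the 80% inclusion rule is decided
exactly — a narrower band would silently censor fragments between 80 and
90% identity. `N` is masked to mismatch everything, including another
`N`. On substitution-only pairs ≤5 kb the fragment ANI stays within
±0.5 identity points of a full dynamic-programming alignment oracle
(asserted in the test suite at 50 random pairs).

Greedy clustering sorts contigs by length descending (ties by id), joins
each contig to the first cluster whose representative passes both
thresholds, and re-asserts the thresholds for every member on every run.
The representative is therefore always the longest member and the result
is independent of input file order.

Genus-level clusters use a gene-sharing network: for genomes holding
`a` and `b` protein clusters (PCs) of an `M`-PC universe and sharing
`c`, the edge p-value is the hypergeometric tail
P = Σ_{i≥c} C(b,i)·C(M−b,a−i)/C(M,a), Bonferroni-scaled by the number of
genome pairs; edges with −log10(P·n_pairs) ≥ 1 are kept and clusters are
connected components. This is a deliberate simplification of
gene-sharing network taxonomy (no ClusterONE/MCL); only the decision
structure is exercised here. Singleton genomes are reported separately
and counted as genera by default (configurable), since published genus
counts are ambiguous on that point. PC membership is an input table;
protein clustering itself is out of scope.

## Taxonomy

One vote per protein, each protein voting only for its best hit (higher
score, ties broken lexicographically by family). A family is assigned
when its qualifying votes reach ≥50% of the vOTU's proteins — qualifying
means bitscore ≥50 in the primary pass, percent identity ≥50 in the
fallback pass, which is consulted only when the primary pass assigns
nothing. An exact tie between two families at the threshold leaves the
vOTU unclassified ("majority" must be unique). The fallback's published
description is ambiguous about whether its 50% is per-protein identity
or the voting fraction; we apply both (identity qualifies a protein,
the voting fraction assigns). Family abundance is a per-sample sum of
relative abundances, so column totals are conserved to 1e−9.

## Host linkage

Homology evidence keeps virus-vs-host alignments with length ≥2500 nt
and identity ≥70%, provided the pair's aligned host bases (union of
subject intervals, so stacked rows are not double-counted) cover <90% of
the host — near-total coverage means the "viral" contig is part of the
host assembly, not an inserted segment.

CRISPR arrays are detected on assembled host sequences as runs of ≥3
exact repeat copies (repeat 23–47 nt, spacers 26–50 nt, mutually
distinct), seeded by recurring 23-mers and extended to the maximal
repeat length consistent with the spacer band. Spacer matching requires
the full spacer (≥20 nt) at Hamming distance ≤1 on either strand,
implemented by pigeonhole exact-piece search. The published screens
phrase the spacer rule as a BLAST E-value cutoff; for 26–50 nt spacers
the ≤1-mismatch full-length rule is strictly more conservative and,
unlike an E-value, independent of database size. tRNA evidence requires
an exact full-length occurrence on either strand.

Composition evidence is an order-k Markov model (default k = 3,
configurable to 7) of each host genome: conditional next-base
probabilities given the preceding k-mer, estimated on both strands with
add-one pseudocounts. A viral contig is scored by mean log-probability
per scored position; hosts are ranked and the top host becomes k-mer
evidence. k = 3 is stable on the ~60 kb synthetic hosts used throughout;
higher orders need proportionally more host sequence.

The integration score table — CRISPR exact 5, CRISPR 1-mismatch 3,
homology 3, tRNA 2, k-mer top rank 1; pair score = best base + 0.5 per
additional distinct method, capped at 5 — is this package's documented
surrogate for a scored host-prediction integrator whose exact point
scheme is not published; only the high-confidence boundary (≥3) is
externally fixed, and the table is a config override, not code.

## Ecology

Depths come from read summaries filtered at identity ≥0.95 and aligned
length ≥50 nt (mean depth = qualifying aligned bases / contig length) or
from precomputed depth tables; either way a (contig, sample) pair with
covered fraction <10% is zeroed. A trimmed-mean depth (5% per tail,
configurable — intended for host genomes) is also provided. Depths are
normalized per Gb of sample sequencing; relative abundances divide by
the per-sample total (all-zero samples stay zero and are flagged);
pseudo-counts are ceil(10 × normalized) and feed only the
rare-frequency richness estimators (Chao1 bias-corrected,
S + F1(F1−1)/(2(F2+1)); ACE with rare cutoff 10). Shannon (natural log;
base configurable) and inverse Simpson are computed on relative
abundances directly. ACE degenerates to observed richness when no rare
species exist and is guarded against the all-singleton case where its
coverage estimate is undefined.

Beta diversity is Bray–Curtis between samples; PCoA eigendecomposes the
double-centered −½D² matrix, scales coordinates by √eigenvalue, and
drops negative-eigenvalue axes (reported, not silently discarded).
PERMANOVA permutes labels freely with p = (1 + #{F* ≥ F}) / (1 + n_perm)
and 999 permutations by default, making the smallest attainable p 0.001.
Alpha-diversity group tests are the classic pooled-variance two-sample
t-test (two-sided) and the Wilcoxon rank-sum test with the exact null
when both groups have n ≤ 10.

Transcriptional activity: a gene is expressed iff mapped by more than
one metatranscriptomic read (strictly >1, i.e., ≥2 — the published
wording is read literally); a vOTU is active iff ≥20% of its genes are
expressed.

## AMG screening

Rules apply in a fixed order — T/B flag, auxiliary score >3, curated
function list, viral genomic context — and the first failing rule is the
verdict. Context has two modes: strict (default) needs ≥1
virus-specific gene on each side of the candidate on the same contig;
lenient needs one anywhere on the contig. Strict-retained is provably a
subset of lenient-retained, and re-screening a retained set is the
identity. The curated list is a user-supplied file; the packaged example
covers sulfate-assimilation, LPS/lipid-A and rhamnose functions typical
of sediment viromes.

## Synthetic data: what it does and does not emulate

The generators plant every feature a stage consumes, and record it in
truth tables keyed to the emitted records: keyword/hypothetical/
ribosomal gene annotations with per-tool Bernoulli predictor calls
(sensitivity 0.8, specificity 0.9 per tool); exact DTRs; host genomes
with CRISPR arrays whose first spacer is lifted verbatim from the linked
virus, shared tRNAs, a ~90%-identity integrated segment, and distinct GC
(0.30–0.70) for composition scoring, with planted intervals protected
from being overwritten by later insertions; substitution-only ANI/AF
variants (uniform over the three alternative bases, no indels, so the
planted identity is exactly recoverable by alignment — the
non-homologous remainder is fresh random sequence so the aligned
fraction of the shorter contig realizes the target); two-group lognormal
communities (σ = 1.5 between vOTUs — a standard rank-abundance shape, as
no empirical value is available — and σ = 0.5 per-sample noise) with a
group effect multiplying a chosen fraction of vOTUs in one group,
planted sub-floor coverage pairs, blank-contaminated contigs, and
metatranscriptome counts placed on either side of the activity rule; AMG
rows spanning the full rule grid with intended verdicts derived by an
independent restatement of the rules.

None of this emulates read-level error, assembly artifacts, chimeras,
real predictor-tool biases, or phylogenetic correlation among genomes.
Passing tests therefore demonstrate that the decision layer implements
its rules exactly and recovers planted structure at the stated noise
levels — not that the upstream tools whose outputs it consumes are
accurate on real data.

## Problem sizes and calibration

The test and acceptance runs use desk-scale sizes chosen to exercise
every rule: ~50 assembly contigs (15–30 kb), 5–10 host genomes of 60 kb,
communities of 40–60 vOTUs over 8+8 samples, 500-case rule suites, 500
null simulations for type-I calibration (99 permutations each) and 100
effect simulations for power (999 permutations, the config default).
Under the null the PERMANOVA/t/Wilcoxon rejection rates at α = 0.05 are
5.0%/3.4%/4.6%; at the planted effect (factor 10 on half the vOTUs,
8+8 samples, 60 vOTUs) PERMANOVA power is 96%. Headline counts from
cluster-scale field studies (thousands of vOTUs from dozens of deep-sea
metagenomes) are not reproducible at these sizes and are not targets of
the synthetic runs; what is preserved is every decision boundary and the
qualitative two-group structure.

## Known limitations

- The genus stand-in (connected components over hypergeometric edges)
  will chain clusters that ClusterONE-style methods would split.
- The CRISPR detector requires exact repeat copies; real arrays with
  degenerate repeats need a dedicated tool upstream.
- The Markov scorer assumes compositionally distinct hosts; closely
  related hosts are not distinguishable by composition alone (by
  design, such evidence scores only 1 point).
- Read mapping, assembly, gene calling, protein clustering and HMM
  annotation are consumed as inputs, never recomputed.
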