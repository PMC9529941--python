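"""Ground-truthed synthetic inputs for every pipeline stage.

The generators emulate the statistical structure the pipeline assumes in
real hadal-sediment data — annotated viral and non-viral contigs with
per-tool predictor calls, planted species clusters at controlled
ANI/aligned fraction, host genomes carrying CRISPR arrays, shared tRNAs,
prophage-like homologous segments and distinct base composition, two-group
lognormal community profiles with a tunable group effect, blank-control
contamination, and AMG annotation rows with known intended verdicts. Every
planted feature is recorded in a truth table and recoverable from the
emitted records by exact search. All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import CONSERVATIVE_TOOLS, PREDICTOR_TOOLS
from .hosts import revcomp
from .io import AlignmentRow, ContigRecord, GeneRecord

BASES = np.array(list("ACGT"))

VIRAL_PRODUCTS = (
    "major capsid protein", "phage terminase large subunit", "portal protein",
    "tail fiber protein", "baseplate wedge protein", "tape measure protein",
    "prohead protease", "holin", "virion structural protein",
    "head-tail connector protein", "DNA packaging protein",
)
HYPOTHETICAL_PRODUCT = "hypothetical protein"
OTHER_PRODUCTS = (
    "DNA helicase", "ATP-dependent protease", "glycosyltransferase",
    "methyltransferase", "thymidylate synthase", "exonuclease",
)
RIBOSOMAL_PRODUCTS = ("30S ribosomal protein S3", "50S ribosomal protein L2")

CURATED_AMG_FUNCTIONS = {
    "K00860": "adenylylsulfate kinase (cysC)",
    "K00390": "phosphoadenosine phosphosulfate reductase (cysH)",
    "K00979": "3-deoxy-manno-octulosonate cytidylyltransferase (kdsB)",
    "K01710": "dTDP-glucose 4,6-dehydratase (rmlB)",
    "K02536": "UDP-3-O-acyltransferase (lpxA)",
}
UNCURATED_FUNCTIONS = {
    "K99901": "putative oxidoreductase",
    "K99902": "putative transporter",
}


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def _substitute(rng: np.random.Generator, seq: str, positions) -> str:
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(3)]
    return "".join(out)


def _free_position(rng: np.random.Generator, contig, width: int,
                   protected: dict, tries: int = 200) -> int:
    """A start position for a planted feature avoiding protected intervals."""
    taken = protected.get(contig.contig_id, [])
    for _ in range(tries):
        at = int(rng.integers(0, contig.length - width))
        if all(at + width <= s or at >= e for s, e in taken):
            return at
    raise ValueError(f"cannot place a {width} nt feature in "
                     f"{contig.contig_id}: constraints infeasible")


# ---------------------------------------------------------------------------
# genomes, genes, predictor calls, host features

@dataclass
class GenomeTruth:
    """Everything make_genomes planted, keyed to the emitted records."""

    viral_contigs: list
    decoy_contigs: list
    host_contigs: list
    genes: list                    # GeneRecord
    predictor_calls: pd.DataFrame  # contig_id, tool, call
    completeness: dict             # contig_id -> float or None
    trna_by_host: dict             # host_id -> [sequence]
    alignment_rows: list           # planted + decoy homology evidence
    contig_truth: pd.DataFrame     # per-contig planted labels
    host_links: pd.DataFrame       # virus_id, host_id, method, detail

    @property
    def assembly_contigs(self) -> list:
        return list(self.viral_contigs) + list(self.decoy_contigs)


def _make_gene_table(rng, contig: ContigRecord,
                     products: Sequence[str]) -> list[GeneRecord]:
    # evenly tiled slots so every product is guaranteed a gene
    n = len(products)
    slot = contig.length // n
    genes = []
    for i, product in enumerate(products):
        start = i * slot + int(rng.integers(0, max(1, min(40, slot // 4))))
        end = min(start + max(90, slot - int(rng.integers(10, 60))),
                  contig.length)
        genes.append(GeneRecord(f"{contig.contig_id}_g{i + 1}",
                                contig.contig_id, start, end,
                                "+" if rng.random() < 0.5 else "-", product))
    return genes


def make_genomes(
    n_viral: int,
    n_host: int,
    length_range: tuple[int, int] = (15_000, 30_000),
    seed: int = 0,
    n_decoy: int = 0,
    host_length: int = 60_000,
    gene_count_range: tuple[int, int] = (20, 60),
    keyword_gene_range: tuple[int, int] = (2, 6),
    hypothetical_fraction: float = 0.5,
    dtr_fraction: float = 0.3,
    dtr_length: int = 30,
    completeness_missing_fraction: float = 0.15,
    tool_sensitivity: float = 0.8,
    tool_specificity: float = 0.9,
    spacer_length: int = 32,
    homology_segment: int = 3_000,
    homology_identity: float = 0.90,
    trna_length: int = 75,
    evidence_plan: Sequence[Sequence[str]] = (
        ("crispr",), ("crispr", "trna"), ("homology", "trna"),
        ("homology",), ("trna",),
    ),
) -> GenomeTruth:
    """Generate viral genomes, decoys and host genomes with planted features.

    Viral genomes carry 20-60 genes (>= 2 virus-keyword products so their
    intended triage verdict is "retain"), optional exact direct terminal
    repeats, and base composition matching their true host. Decoy contigs
    carry a ribosomal gene (intended verdict "reject"). Host genomes get a
    CRISPR array whose first spacer is lifted verbatim from the linked
    virus, shared tRNAs, an integrated homologous segment, and a
    host-specific GC bias for composition scoring.
    """
    if n_viral < 0 or n_host < 0:
        raise ValueError("counts must be >= 0")
    if length_range[0] < 1_000:
        raise ValueError("genomes must be >= 1 kb")
    if n_viral and spacer_length > length_range[0]:
        raise ValueError("spacer longer than the shortest possible virus")
    if n_viral and n_host and homology_segment > length_range[0]:
        raise ValueError("homologous segment longer than the shortest virus")
    rng = np.random.default_rng(seed)

    host_gc = (np.linspace(0.30, 0.70, n_host) if n_host
               else np.array([]))
    viral_contigs: list[ContigRecord] = []
    decoy_contigs: list[ContigRecord] = []
    genes: list[GeneRecord] = []
    completeness: dict[str, Optional[float]] = {}
    truth_rows = []

    for i in range(n_viral):
        vid = f"virus_{i + 1:04d}"
        true_host = i % n_host if n_host else None
        gc = float(host_gc[true_host]) if n_host else 0.5
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = random_seq(rng, length, gc)
        has_dtr = rng.random() < dtr_fraction
        if has_dtr:
            seq = seq[:-dtr_length] + seq[:dtr_length]
        contig = ContigRecord(vid, seq, source_set="assembly")
        viral_contigs.append(contig)

        n_genes = int(rng.integers(*gene_count_range))
        n_kw = int(rng.integers(keyword_gene_range[0],
                                keyword_gene_range[1] + 1))
        n_hyp = int(round(hypothetical_fraction * (n_genes - n_kw)))
        products = ([str(rng.choice(VIRAL_PRODUCTS)) for _ in range(n_kw)]
                    + [HYPOTHETICAL_PRODUCT] * n_hyp
                    + [str(rng.choice(OTHER_PRODUCTS))
                       for _ in range(n_genes - n_kw - n_hyp)])
        rng.shuffle(products)
        genes.extend(_make_gene_table(rng, contig, products))

        if has_dtr:
            comp: Optional[float] = 100.0
        elif rng.random() < completeness_missing_fraction:
            comp = None
        else:
            comp = float(np.round(rng.uniform(0, 99.9), 1))
        completeness[vid] = comp
        truth_rows.append({
            "contig_id": vid, "viral": 1, "expected_retained": 1,
            "dtr": int(has_dtr), "dtr_length": dtr_length if has_dtr else 0,
            "true_host": f"host_{true_host + 1:03d}" if n_host else "",
            "gc": gc,
        })

    for i in range(n_decoy):
        did = f"decoy_{i + 1:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        contig = ContigRecord(did, random_seq(rng, length, 0.5),
                              source_set="assembly")
        decoy_contigs.append(contig)
        n_genes = int(rng.integers(8, 20))
        products = [str(rng.choice(RIBOSOMAL_PRODUCTS))
                    for _ in range(int(rng.integers(1, 3)))]
        products += [HYPOTHETICAL_PRODUCT if rng.random() < 0.5
                     else str(rng.choice(OTHER_PRODUCTS))
                     for _ in range(n_genes - len(products))]
        rng.shuffle(products)
        genes.extend(_make_gene_table(rng, contig, products))
        completeness[did] = (None if rng.random() <
                             completeness_missing_fraction
                             else float(np.round(rng.uniform(0, 99.9), 1)))
        truth_rows.append({"contig_id": did, "viral": 0,
                           "expected_retained": 0, "dtr": 0, "dtr_length": 0,
                           "true_host": "", "gc": 0.5})

    # predictor calls: Bernoulli sensitivity on virals, 1-specificity on decoys
    call_rows = []
    for contig, is_viral in ([(c, True) for c in viral_contigs]
                             + [(c, False) for c in decoy_contigs]):
        calls = {}
        for tool in PREDICTOR_TOOLS:
            p = tool_sensitivity if is_viral else 1 - tool_specificity
            calls[tool] = int(rng.random() < p)
        if not any(calls.values()):  # pipeline admission: >=1 step-1 call
            calls[str(rng.choice(PREDICTOR_TOOLS))] = 1
        if is_viral and not any(calls[t] for t in CONSERVATIVE_TOOLS):
            calls[str(rng.choice(CONSERVATIVE_TOOLS))] = 1
        for tool, call in calls.items():
            call_rows.append({"contig_id": contig.contig_id, "tool": tool,
                              "call": call})

    # hosts with planted linkage features; planted intervals (and DTR ends)
    # are protected from being overwritten by later insertions
    protected: dict[str, list[tuple[int, int]]] = {}
    for row in truth_rows:
        if row.get("dtr"):
            contig = next(c for c in viral_contigs
                          if c.contig_id == row["contig_id"])
            protected[contig.contig_id] = [
                (0, dtr_length), (contig.length - dtr_length, contig.length)]
    host_contigs: list[ContigRecord] = []
    trna_by_host: dict[str, list[str]] = {}
    alignment_rows: list[AlignmentRow] = []
    link_rows = []
    for h in range(n_host):
        hid = f"host_{h + 1:03d}"
        gc = float(host_gc[h])
        blocks = [random_seq(rng, host_length // 2, gc)]
        trna_by_host[hid] = []
        plan = evidence_plan[h % len(evidence_plan)] if n_viral else ()
        linked = viral_contigs[h % n_viral] if n_viral else None

        if linked is not None and "crispr" in plan:
            repeat = random_seq(rng, 30, gc)
            start = _free_position(rng, linked, spacer_length, protected)
            planted_spacer = linked.sequence[start:start + spacer_length]
            protected.setdefault(linked.contig_id, []).append(
                (start, start + spacer_length))
            spacers = [planted_spacer]
            while len(spacers) < 3:
                s = random_seq(rng, spacer_length, gc)
                if s not in spacers:
                    spacers.append(s)
            array = repeat + repeat.join(spacers) + repeat
            blocks.append(array)
            link_rows.append({"virus_id": linked.contig_id, "host_id": hid,
                              "method": "crispr", "detail": planted_spacer})
        if linked is not None and "trna" in plan:
            trna = random_seq(rng, trna_length, 0.5)
            trna_by_host[hid].append(trna)
            blocks.append(trna)
            insert_at = _free_position(rng, linked, trna_length, protected)
            protected.setdefault(linked.contig_id, []).append(
                (insert_at, insert_at + trna_length))
            seq = (linked.sequence[:insert_at] + trna
                   + linked.sequence[insert_at + trna_length:])
            idx = viral_contigs.index(linked)
            linked = ContigRecord(linked.contig_id, seq,
                                  source_set=linked.source_set)
            viral_contigs[idx] = linked
            link_rows.append({"virus_id": linked.contig_id, "host_id": hid,
                              "method": "trna", "detail": trna})
        if linked is not None and "homology" in plan:
            seg_start = int(rng.integers(0, linked.length - homology_segment))
            segment = linked.sequence[seg_start:seg_start + homology_segment]
            n_sub = int(round((1 - homology_identity) * homology_segment))
            positions = rng.choice(homology_segment, size=n_sub, replace=False)
            mutated = _substitute(rng, segment, positions)
            offset = sum(len(b) for b in blocks)
            blocks.append(mutated)
            alignment_rows.append(AlignmentRow(
                linked.contig_id, hid, round(100 * homology_identity, 2),
                homology_segment, n_sub, 0,
                seg_start + 1, seg_start + homology_segment,
                offset + 1, offset + homology_segment, 1e-50,
                2.0 * homology_segment))
            link_rows.append({"virus_id": linked.contig_id, "host_id": hid,
                              "method": "homology", "detail":
                              f"{homology_segment}nt@{homology_identity:.2f}"})
        blocks.append(random_seq(rng, host_length // 2, gc))
        host_contigs.append(ContigRecord(hid, "".join(blocks),
                                         source_set="host_mag"))

    # decoy alignment rows that must fail the homology filters
    if n_viral and n_host:
        for _ in range(min(n_viral, 5)):
            v = viral_contigs[int(rng.integers(n_viral))]
            h = host_contigs[int(rng.integers(n_host))]
            alignment_rows.append(AlignmentRow(
                v.contig_id, h.contig_id,
                float(np.round(rng.uniform(75, 95), 2)),
                int(rng.integers(100, 2000)), 10, 0, 1, 500, 1, 500,
                1e-10, 300.0))

    truth = pd.DataFrame(truth_rows)
    return GenomeTruth(viral_contigs, decoy_contigs, host_contigs, genes,
                       pd.DataFrame(call_rows), completeness, trna_by_host,
                       alignment_rows, truth,
                       pd.DataFrame(link_rows, columns=["virus_id", "host_id",
                                                        "method", "detail"]))


# ---------------------------------------------------------------------------
# controlled-ANI variants and species benchmarks

def make_variants(
    seed_seq: str,
    target_ani: float,
    target_af: float,
    seed: int = 0,
    length_offset: int = 0,
) -> tuple[str, tuple[float, float]]:
    """A substitution-only variant at controlled ANI and aligned fraction.

    The variant keeps a homologous block of ``target_af`` of its length —
    the seed's prefix with positions substituted at exactly rate
    (1 - target_ani) — and replaces the remainder with fresh random
    sequence, so the aligned fraction of the shorter sequence realizes the
    target (a plain truncation would always align fully). No indels, so a
    full alignment of the homologous block recovers the planted identity.
    ``length_offset`` shortens the variant relative to the seed, which
    keeps greedy-clustering representatives deterministic. Returns
    (variant, (realized_ani, realized_af)).
    """
    if not 0 < target_ani <= 1 or not 0 < target_af <= 1:
        raise ValueError("target_ani and target_af must be in (0, 1]")
    if target_ani < 0.5:
        raise ValueError("target_ani < 0.5 is outside the model's validity")
    if length_offset < 0 or length_offset >= len(seed_seq):
        raise ValueError("length_offset out of range")
    rng = np.random.default_rng(seed)
    total = len(seed_seq) - length_offset
    block_len = max(1, int(round(target_af * total)))
    block = seed_seq[:block_len]
    n_sub = int(round((1 - target_ani) * block_len))
    positions = rng.choice(block_len, size=n_sub, replace=False)
    variant = _substitute(rng, block, positions)
    variant += random_seq(rng, total - block_len, 0.5)
    return variant, (1 - n_sub / block_len, block_len / total)


@dataclass
class SpeciesBenchmark:
    contigs: list
    truth: pd.DataFrame         # contig_id, species_id, target_ani, target_af
    expected_clusters: int


def make_species_set(
    n_species: int,
    seed_length: int = 4_000,
    ani_values: Sequence[float] = (0.90, 0.96, 0.99),
    af_values: Sequence[float] = (0.8, 0.9, 1.0),
    ani_min: float = 95.0,
    af_min: float = 0.85,
    seed: int = 0,
) -> SpeciesBenchmark:
    """Planted species clusters over an (ANI, AF) grid.

    Each species seed gets one variant per (ani, af) combination; the
    expected cluster count under the thresholds is derived analytically:
    a variant joins its seed iff 100*ani >= ani_min and af >= af_min.
    """
    rng = np.random.default_rng(seed)
    contigs: list[ContigRecord] = []
    rows = []
    expected = 0
    for s in range(n_species):
        sid = f"sp{s + 1:03d}"
        seed_seq = random_seq(rng, seed_length, 0.5)
        contigs.append(ContigRecord(f"{sid}_seed", seed_seq))
        rows.append({"contig_id": f"{sid}_seed", "species_id": sid,
                     "target_ani": 1.0, "target_af": 1.0})
        expected += 1
        offset = 0
        for ani in ani_values:
            for af in af_values:
                offset += 8  # distinct lengths keep the seed as representative
                variant, _ = make_variants(seed_seq, ani, af,
                                           seed=int(rng.integers(2 ** 31)),
                                           length_offset=offset)
                cid = f"{sid}_a{int(ani * 100)}_f{int(af * 100)}"
                contigs.append(ContigRecord(cid, variant))
                rows.append({"contig_id": cid, "species_id": sid,
                             "target_ani": ani, "target_af": af})
                if not (100 * ani >= ani_min and af >= af_min):
                    expected += 1
    return SpeciesBenchmark(contigs, pd.DataFrame(rows), expected)


def make_pc_families(
    n_families: int = 2,
    genomes_per_family: int = 4,
    pcs_per_genome: int = 20,
    shared_fraction: float = 0.8,
    n_background_pcs: int = 200,
    seed: int = 0,
) -> tuple[dict, dict, pd.DataFrame]:
    """Protein-cluster memberships with planted gene-sharing families.

    Genomes within a family share ``shared_fraction`` of their PCs; the
    rest are private draws from a large background universe. Returns
    (pc_membership, genome_of, truth frame with family per genome).
    """
    rng = np.random.default_rng(seed)
    pc_membership: dict[str, str] = {}
    genome_of: dict[str, str] = {}
    rows = []
    protein_idx = 0
    background = [f"bgPC{i:04d}" for i in range(n_background_pcs)]
    for f in range(n_families):
        n_shared = int(round(shared_fraction * pcs_per_genome))
        core = [f"fam{f}_PC{i:03d}" for i in range(n_shared)]
        for g in range(genomes_per_family):
            genome = f"fam{f}_genome{g}"
            rows.append({"genome_id": genome, "family": f"fam{f}"})
            private = rng.choice(background, size=pcs_per_genome - n_shared,
                                 replace=False)
            for pc in core + list(private):
                protein = f"p{protein_idx:06d}"
                protein_idx += 1
                pc_membership[protein] = str(pc)
                genome_of[protein] = genome
    return pc_membership, genome_of, pd.DataFrame(rows)


FAMILIES = ("Siphoviridae", "Myoviridae", "Podoviridae")


def make_family_hits(
    votu_ids: Sequence[str],
    seed: int = 0,
    classified_fraction: float = 0.4,
    proteins_per_votu: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein-hit tables with a planted family per classified vOTU.

    Classified vOTUs get qualifying best hits (bitscore >= 50) to one
    family for >= 50% of their proteins; the rest get sub-threshold or no
    hits. Returns (hits frame, truth frame with intended family).
    """
    rng = np.random.default_rng(seed)
    hit_rows, truth_rows = [], []
    for votu in votu_ids:
        classified = rng.random() < classified_fraction
        family = str(rng.choice(FAMILIES)) if classified else "unclassified"
        n_support = (int(rng.integers(math.ceil(proteins_per_votu / 2),
                                      proteins_per_votu + 1))
                     if classified else int(rng.integers(0, 3)))
        for p in range(proteins_per_votu):
            pid = f"{votu}_p{p + 1}"
            if p < n_support:
                hit_rows.append({
                    "protein_id": pid, "votu_id": votu,
                    "family": family if classified
                    else str(rng.choice(FAMILIES)),
                    "score": float(np.round(rng.uniform(55, 200), 1))
                    if classified else float(np.round(rng.uniform(20, 49), 1)),
                    "pass": "primary_db"})
        truth_rows.append({"votu_id": votu, "intended_family": family,
                           "n_proteins": proteins_per_votu})
    return (pd.DataFrame(hit_rows, columns=["protein_id", "votu_id", "family",
                                            "score", "pass"]),
            pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# communities

@dataclass
class CommunityTruth:
    depth: pd.DataFrame          # contig_id, sample_id, mean_depth, covered_fraction
    samples: pd.DataFrame        # sample_id, gb, group
    blank_hits: pd.DataFrame     # contig_id, reads
    transcripts: pd.DataFrame    # gene_id, contig_id, reads
    biased_votus: list
    active_votus: list
    zeroed_pairs: list           # (contig_id, sample_id) below coverage floor
    blank_contaminated: list
    base_abundance: pd.Series
    group_names: tuple = ("slope", "bottom-axis")


def make_communities(
    n_votus: int,
    n_samples_per_group: int,
    group_effect: float = 0.5,
    group_factor: float = 10.0,
    sigma: float = 1.5,
    sample_sigma: float = 0.5,
    seed: int = 0,
    gb_range: tuple[float, float] = (5.0, 15.0),
    lowcov_fraction: float = 0.05,
    absent_fraction: float = 0.10,
    blank_fraction: float = 0.05,
    genes_per_votu: int = 10,
    active_fraction: float = 0.3,
) -> CommunityTruth:
    """Two-group lognormal community profiles with planted structure.

    Base vOTU abundances are lognormal(0, sigma); per-sample depths add
    lognormal(0, sample_sigma) noise; a ``group_effect`` fraction of vOTUs
    is multiplied by ``group_factor`` in the bottom-axis group. Random
    (vOTU, sample) pairs are planted below the 10% coverage floor or absent
    entirely, a subset of vOTUs receives blank-control reads, and
    metatranscriptomic read counts are planted so known vOTUs meet or fail
    the >=20%-of-genes-expressed rule.
    """
    if n_votus < 2 or n_samples_per_group < 2:
        raise ValueError("need >= 2 vOTUs and >= 2 samples per group")
    if sigma <= 0 or sample_sigma < 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    votus = [f"votu_{i + 1:04d}" for i in range(n_votus)]
    samples = ([f"slope_{i + 1:02d}" for i in range(n_samples_per_group)]
               + [f"axis_{i + 1:02d}" for i in range(n_samples_per_group)])
    group = {s: ("slope" if s.startswith("slope") else "bottom-axis")
             for s in samples}

    base = pd.Series(rng.lognormal(0.0, sigma, n_votus), index=votus)
    n_biased = int(round(group_effect * n_votus))
    biased = sorted(rng.choice(votus, size=n_biased, replace=False).tolist())

    depth_rows = []
    zeroed_pairs = []
    for votu in votus:
        for sample in samples:
            depth = float(base[votu] * rng.lognormal(0.0, sample_sigma))
            if votu in biased and group[sample] == "bottom-axis":
                depth *= group_factor
            r = rng.random()
            if r < absent_fraction:
                depth, cov = 0.0, 0.0
            elif r < absent_fraction + lowcov_fraction:
                cov = float(rng.uniform(0.0, 0.0999))
                zeroed_pairs.append((votu, sample))
            else:
                cov = float(rng.uniform(0.30, 1.0))
            depth_rows.append({"contig_id": votu, "sample_id": sample,
                               "mean_depth": depth, "covered_fraction": cov})

    sample_table = pd.DataFrame({
        "sample_id": samples,
        "gb": np.round(rng.uniform(*gb_range, len(samples)), 3),
        "group": [group[s] for s in samples],
    })

    contaminated = sorted(rng.choice(
        votus, size=max(1, int(round(blank_fraction * n_votus))),
        replace=False).tolist())
    blank = pd.DataFrame({
        "contig_id": votus,
        "reads": [int(rng.integers(1, 6)) if v in contaminated else 0
                  for v in votus],
    })

    n_active = int(round(active_fraction * n_votus))
    active = sorted(rng.choice(votus, size=n_active, replace=False).tolist())
    need = math.ceil(0.20 * genes_per_votu)
    transcript_rows = []
    for votu in votus:
        n_expr = (int(rng.integers(need, genes_per_votu + 1))
                  if votu in active else int(rng.integers(0, need)))
        for g in range(genes_per_votu):
            reads = (int(rng.integers(2, 11)) if g < n_expr
                     else int(rng.integers(0, 2)))
            transcript_rows.append({"gene_id": f"{votu}_g{g + 1}",
                                    "contig_id": votu, "reads": reads})

    return CommunityTruth(pd.DataFrame(depth_rows), sample_table, blank,
                          pd.DataFrame(transcript_rows), biased, active,
                          zeroed_pairs, contaminated, base)


# ---------------------------------------------------------------------------
# AMG annotation rows with intended verdicts

@dataclass
class AmgTruth:
    candidates: pd.DataFrame
    genes: list
    curated_functions: set
    intended: pd.DataFrame  # gene_id, intended_strict, intended_lenient


_POSITION_CLASSES = ("interior_flanked", "left_only", "right_only", "unflanked")


def make_amg_table(n_rows: int, seed: int = 0) -> AmgTruth:
    """AMG annotation rows spanning the full rule grid, with known verdicts.

    Rows vary auxiliary score (1-5 or absent), flags (none/T/B), curated
    membership and genomic position (viral genes on both sides, one side,
    or neither). The intended verdict per row is derived by an explicit
    restatement of the screening rules, independent of the screening code.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    rng = np.random.default_rng(seed)
    curated_ids = list(CURATED_AMG_FUNCTIONS)
    uncurated_ids = list(UNCURATED_FUNCTIONS)
    categories = ("amino acid metabolism", "carbohydrate metabolism",
                  "sulfur metabolism", "cofactor and vitamin metabolism")

    cand_rows, genes, intended_rows = [], [], []
    for i in range(n_rows):
        contig = f"amgctg_{i + 1:05d}"
        gene_id = f"{contig}_amg"
        score = int(rng.integers(1, 6)) if rng.random() < 0.85 else None
        flag = str(rng.choice(["", "T", "B"], p=[0.6, 0.2, 0.2]))
        curated = rng.random() < 0.7
        function_id = str(rng.choice(curated_ids if curated else uncurated_ids))
        description = (CURATED_AMG_FUNCTIONS.get(function_id)
                       or UNCURATED_FUNCTIONS[function_id])
        position = str(rng.choice(_POSITION_CLASSES))

        # neighbourhood: candidate at [2000, 2900); viral genes as planted
        left_viral = position in ("interior_flanked", "left_only")
        right_viral = position in ("interior_flanked", "right_only")
        genes.append(GeneRecord(f"{contig}_g1", contig, 100, 1000, "+",
                                "major capsid protein" if left_viral
                                else HYPOTHETICAL_PRODUCT))
        genes.append(GeneRecord(gene_id, contig, 2000, 2900, "+", description))
        genes.append(GeneRecord(f"{contig}_g3", contig, 3100, 4000, "-",
                                "phage terminase large subunit" if right_viral
                                else HYPOTHETICAL_PRODUCT))

        cand_rows.append({
            "gene_id": gene_id, "contig_id": contig,
            "function_id": function_id, "description": description,
            "source": str(rng.choice(["vibrant", "dramv"])),
            "auxiliary_score": "" if score is None else str(score),
            "flags": flag,
            "category": str(rng.choice(categories)),
        })

        # independent restatement of the rule order
        if flag in ("T", "B"):
            strict = lenient = "removed_flag"
        elif score is not None and score > 3:
            strict = lenient = "removed_score"
        elif not curated:
            strict = lenient = "removed_not_curated"
        else:
            lenient = ("retained" if (left_viral or right_viral)
                       else "removed_context")
            strict = ("retained" if (left_viral and right_viral)
                      else "removed_context")
        intended_rows.append({"gene_id": gene_id, "position": position,
                              "intended_strict": strict,
                              "intended_lenient": lenient})

    return AmgTruth(pd.DataFrame(cand_rows), genes,
                    set(CURATED_AMG_FUNCTIONS),
                    pd.DataFrame(intended_rows))


# ---------------------------------------------------------------------------
# per-rule case generators for exactness suites

def make_triage_cases(n_cases: int, seed: int = 0) -> list[dict]:
    """Random gene tables + predictor calls with independently derived intent."""
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        cid = f"case_{i:05d}"
        n_genes = int(rng.integers(1, 16))
        n_viral = int(rng.integers(0, min(5, n_genes + 1)))
        n_prok = int(rng.integers(0, min(3, n_genes - n_viral + 1)))
        n_unknown = int(rng.integers(0, n_genes - n_viral - n_prok + 1))
        products = ([str(rng.choice(VIRAL_PRODUCTS)) for _ in range(n_viral)]
                    + [str(rng.choice(RIBOSOMAL_PRODUCTS))
                       for _ in range(n_prok)]
                    + [HYPOTHETICAL_PRODUCT] * n_unknown
                    + [str(rng.choice(OTHER_PRODUCTS))
                       for _ in range(n_genes - n_viral - n_prok - n_unknown)])
        rng.shuffle(products)
        genes = [GeneRecord(f"{cid}_g{j}", cid, j * 1000, j * 1000 + 900, "+",
                            p) for j, p in enumerate(products)]
        calls = {tool: bool(rng.random() < 0.4) for tool in PREDICTOR_TOOLS}
        if not any(calls.values()):
            calls[str(rng.choice(PREDICTOR_TOOLS))] = True
        completeness = (float(np.round(rng.uniform(0, 100), 1))
                        if rng.random() < 0.7 else None)

        any_call = any(calls.values())
        conservative = any(calls.get(t, False) for t in CONSERVATIVE_TOOLS)
        retain = (n_viral >= 2
                  or (any_call and n_unknown / n_genes >= 0.70))
        retain = retain and n_prok == 0
        if completeness is None and n_viral == 0:
            retain = retain and conservative
        cases.append({"contig_id": cid, "genes": genes, "calls": calls,
                      "completeness": completeness,
                      "intended_retained": bool(retain)})
    return cases


def make_tier_cases(n_cases: int, seed: int = 0) -> list[dict]:
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n_cases):
        if rng.random() < 0.15:
            comp: Optional[float] = None
        elif rng.random() < 0.3:  # hit the boundaries often
            comp = float(rng.choice([0.0, 49.9, 50.0, 90.0, 90.1, 100.0]))
        else:
            comp = float(np.round(rng.uniform(0, 100), 1))
        dtr = bool(rng.random() < 0.5)
        if comp is None:
            tier = "undetermined"
        elif comp == 100 and dtr:
            tier = "complete"
        elif comp > 90:
            tier = "high"
        elif comp >= 50:
            tier = "medium"
        else:
            tier = "low"
        cases.append({"completeness": comp, "dtr": dtr, "intended_tier": tier})
    return cases


def make_homology_cases(n_cases: int, seed: int = 0) -> list[dict]:
    """Alignment rows straddling the homology-filter thresholds."""
    rng = np.random.default_rng(seed)
    host_len = 100_000
    cases = []
    for i in range(n_cases):
        length = int(rng.choice([1000, 2000, 2499, 2500, 2501, 5000, 95_000]))
        identity = float(rng.choice([50.0, 69.9, 70.0, 70.1, 85.0, 99.0]))
        start = int(rng.integers(1, host_len - length))
        row = AlignmentRow(f"v{i}", "host", identity, length, 0, 0,
                           1, length, start, start + length - 1, 1e-20, 100.0)
        kept = (length >= 2500 and identity >= 70.0
                and length / host_len < 0.90)
        cases.append({"row": row, "host_length": host_len,
                      "intended_kept": kept})
    return cases


def make_spacer_cases(n_cases: int, seed: int = 0,
                      spacer_length: int = 32) -> list[dict]:
    """Spacers planted into contigs at 0, 1 or 2 mismatches, or absent."""
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        spacer = random_seq(rng, spacer_length)
        contig_seq = random_seq(rng, 3000)
        n_mm = int(rng.choice([0, 1, 2, -1]))  # -1: not planted at all
        if n_mm >= 0:
            planted = spacer
            if n_mm:
                positions = rng.choice(spacer_length, size=n_mm, replace=False)
                planted = _substitute(rng, spacer, positions)
            if rng.random() < 0.5:
                planted = revcomp(planted)
            at = int(rng.integers(0, 3000 - spacer_length))
            contig_seq = (contig_seq[:at] + planted
                          + contig_seq[at + spacer_length:])
        cases.append({"spacer": spacer,
                      "contig": ContigRecord(f"sp_case_{i}", contig_seq),
                      "planted_mismatches": n_mm,
                      "intended_match": 0 <= n_mm <= 1})
    return cases


def make_trna_cases(n_cases: int, seed: int = 0,
                    trna_length: int = 75) -> list[dict]:
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        trna = random_seq(rng, trna_length)
        contig_seq = random_seq(rng, 3000)
        mode = str(rng.choice(["exact", "exact_rc", "mismatch", "absent"]))
        if mode != "absent":
            planted = trna
            if mode == "mismatch":
                planted = _substitute(rng, trna, [int(rng.integers(trna_length))])
            if mode == "exact_rc":
                planted = revcomp(trna)
            at = int(rng.integers(0, 3000 - trna_length))
            contig_seq = contig_seq[:at] + planted + contig_seq[at + trna_length:]
        cases.append({"trna": trna,
                      "contig": ContigRecord(f"trna_case_{i}", contig_seq),
                      "mode": mode,
                      "intended_match": mode in ("exact", "exact_rc")})
    return cases


def make_decontamination_cases(n_cases: int, seed: int = 0) -> list[dict]:
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        reads = int(rng.choice([0, 0, 0, 1, 2, 10]))
        cases.append({"contig_id": f"dc_{i:05d}", "blank_reads": reads,
                      "intended_removed": reads >= 1})
    return cases
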