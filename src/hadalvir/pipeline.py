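"""Stage drivers over a file workspace.

Each stage is a pure function of (input files, config, seed): it reads the
workspace TSV/FASTA inputs, runs the corresponding library operations and
writes its output tables plus a machine-readable provenance file (config
echo, input checksums, version). The CLI and the numbered analysis scripts
are thin wrappers around these functions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .amg import filter_amg_candidates, summarize_amgs
from .cluster import (gene_sharing_edges, genus_clusters,
                      greedy_species_cluster, votus_to_frame)
from .config import RunConfig
from .ecology import (alpha_group_tests, apply_coverage_filter, bray_curtis,
                      beta_ordination, depth_matrix, normalize_and_relativize,
                      permanova_test, sample_diversity, transcribed_activity)
from .hosts import (MarkovModel, detect_crispr_arrays, evidence_to_frame,
                    filter_homology_matches, integrate_host_evidence,
                    markov_score, match_spacers, match_trna,
                    predictions_to_frame)
from .io import (AMG_SCHEMA, BLANK_SCHEMA, COMPLETENESS_SCHEMA, DEPTH_SCHEMA,
                 GENE_SCHEMA, PC_SCHEMA, PREDICTOR_SCHEMA, PROTEIN_HIT_SCHEMA,
                 SAMPLE_SCHEMA, TRANSCRIPT_SCHEMA, GeneRecord, parse_fasta,
                 parse_outfmt6, parse_table, write_fasta, write_outfmt6,
                 write_table)
from .report import summarize
from .synthetic import (make_amg_table, make_communities, make_family_hits,
                        make_genomes, make_pc_families)
from .taxonomy import assign_family, summarize_family_abundance
from .triage import assign_quality_tier, decontaminate, detect_dtr, triage_contig

log = logging.getLogger("hadalvir")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_provenance(outdir: Path, stage: str, cfg: RunConfig,
                     inputs: list[Path]) -> None:
    record = {
        "stage": stage,
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in cfg.asdict().items()},
        "inputs": {str(p): _checksum(p) for p in inputs if p.exists()},
    }
    (outdir / f"provenance_{stage}.json").write_text(
        json.dumps(record, indent=1, sort_keys=True))


def _genes_from_table(df: pd.DataFrame) -> list[GeneRecord]:
    return [GeneRecord(r.gene_id, r.contig_id, int(r.start), int(r.end),
                       r.strand, r.product,
                       category=getattr(r, "category", None) or None)
            for r in df.itertuples()]


def genes_to_table(genes) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": g.gene_id, "contig_id": g.contig_id, "start": g.start,
        "end": g.end, "strand": g.strand, "product": g.product,
    } for g in genes])


# ---------------------------------------------------------------------------

def run_simulate(outdir: str | Path, cfg: Optional[RunConfig] = None,
                 n_viral: int = 40, n_host: int = 5, n_decoy: int = 10,
                 n_votus: int = 60, n_samples_per_group: int = 8,
                 group_effect: float = 0.5, n_amg_rows: int = 60) -> Path:
    """Write a complete ground-truthed synthetic workspace."""
    cfg = cfg or RunConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed

    genomes = make_genomes(n_viral, n_host, n_decoy=n_decoy, seed=seed)
    write_fasta(genomes.assembly_contigs, out / "contigs.fasta")
    write_fasta(genomes.host_contigs, out / "hosts.fasta")
    write_table(genes_to_table(genomes.genes), out / "genes.tsv")
    write_table(genomes.predictor_calls, out / "predictor_calls.tsv")
    comp = pd.DataFrame(
        [{"contig_id": cid, "completeness": value}
         for cid, value in genomes.completeness.items() if value is not None])
    write_table(comp, out / "completeness.tsv")
    write_outfmt6(genomes.alignment_rows, out / "alignments.tsv")
    trna_rows = [{"host_id": hid, "trna_id": f"{hid}|trna{i + 1}",
                  "sequence": seq}
                 for hid, seqs in genomes.trna_by_host.items()
                 for i, seq in enumerate(seqs)]
    write_table(pd.DataFrame(trna_rows,
                             columns=["host_id", "trna_id", "sequence"]),
                out / "trna.tsv")

    community = make_communities(n_votus, n_samples_per_group,
                                 group_effect=group_effect, seed=seed + 1)
    write_table(community.depth, out / "depth.tsv")
    write_table(community.samples, out / "samples.tsv")
    write_table(community.blank_hits, out / "community_blank_hits.tsv")
    write_table(community.transcripts, out / "transcripts.tsv")

    # blank hits for the genome axis: a small planted subset of assembly contigs
    rng = np.random.default_rng(seed + 2)
    assembly_ids = [c.contig_id for c in genomes.assembly_contigs]
    n_blank = max(1, len(assembly_ids) // 20)
    contaminated = sorted(rng.choice(assembly_ids, size=n_blank,
                                     replace=False).tolist())
    write_table(pd.DataFrame({
        "contig_id": assembly_ids,
        "reads": [int(rng.integers(1, 6)) if c in contaminated else 0
                  for c in assembly_ids]}), out / "blank_hits.tsv")

    hits, family_truth = make_family_hits(
        sorted(community.depth["contig_id"].unique()), seed=seed + 3)
    write_table(hits, out / "protein_hits.tsv")

    pc_membership, genome_of, pc_truth = make_pc_families(seed=seed + 4)
    write_table(pd.DataFrame([
        {"protein_id": p, "genome_id": genome_of[p], "pc_id": pc}
        for p, pc in pc_membership.items()]), out / "pc_membership.tsv")

    amg = make_amg_table(n_amg_rows, seed=seed + 5)
    write_table(amg.candidates, out / "amg_candidates.tsv")
    write_table(genes_to_table(amg.genes), out / "amg_genes.tsv")
    (out / "curated_functions.txt").write_text(
        "\n".join(sorted(amg.curated_functions)) + "\n")

    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    write_table(genomes.contig_truth, truth_dir / "contigs.tsv")
    write_table(genomes.host_links, truth_dir / "host_links.tsv")
    write_table(pd.DataFrame({"contig_id": contaminated}),
                truth_dir / "blank_contaminated.tsv")
    write_table(family_truth, truth_dir / "families.tsv")
    write_table(pc_truth, truth_dir / "pc_families.tsv")
    write_table(amg.intended, truth_dir / "amg_verdicts.tsv")
    write_table(pd.DataFrame({"votu_id": community.biased_votus}),
                truth_dir / "biased_votus.tsv")
    write_table(pd.DataFrame({"votu_id": community.active_votus}),
                truth_dir / "active_votus.tsv")

    write_provenance(out, "simulate", cfg, [])
    return out


def run_triage(workdir: str | Path, cfg: Optional[RunConfig] = None) -> Path:
    """Per-contig triage, DTR detection, tiering and decontamination."""
    cfg = cfg or RunConfig()
    work = Path(workdir)
    contigs = {c.contig_id: c for c in parse_fasta(work / "contigs.fasta",
                                                   min_length=0)}
    genes = parse_table(work / "genes.tsv", GENE_SCHEMA)
    calls = parse_table(work / "predictor_calls.tsv", PREDICTOR_SCHEMA)
    comp = parse_table(work / "completeness.tsv", COMPLETENESS_SCHEMA)
    blank = parse_table(work / "blank_hits.tsv", BLANK_SCHEMA)

    comp_by = dict(zip(comp["contig_id"], comp["completeness"]))
    calls_by = {cid: dict(zip(sub["tool"], sub["call"].astype(bool)))
                for cid, sub in calls.groupby("contig_id")}
    genes_by = {cid: _genes_from_table(sub)
                for cid, sub in genes.groupby("contig_id")}

    decision_rows = []
    retained_ids = []
    for cid, contig in contigs.items():
        decision = triage_contig(genes_by.get(cid, []), calls_by.get(cid, {}),
                                 comp_by.get(cid), cfg)
        decision_rows.append({
            "contig_id": cid, "retained": int(decision.retained),
            "reasons": ";".join(decision.reasons),
            "n_genes": decision.n_genes,
            "n_viral_specific": decision.n_viral_specific,
            "n_unknown": decision.n_unknown,
            "n_prokaryote": decision.n_prokaryote,
        })
        if decision.retained:
            retained_ids.append(cid)

    retained_set = set(retained_ids)
    blank_by = {}
    for cid, n in zip(blank["contig_id"], blank["reads"]):
        if cid in retained_set:
            blank_by[cid] = n
        elif cid not in contigs:
            log.warning("blank-hit table references unknown contig %r", cid)
    kept, removed = decontaminate(retained_ids, blank_by)
    for row in decision_rows:
        if row["contig_id"] in removed:
            row["retained"] = 0
            row["reasons"] += ";BLANK_CONTAMINANT"

    tier_rows = []
    for cid in kept:  # quality tiers are assigned to the retained virome
        contig = contigs[cid]
        dtr, dtr_len = detect_dtr(contig.sequence, cfg.dtr_min_repeat)
        tier_rows.append({
            "contig_id": cid,
            "completeness": comp_by.get(cid, ""),
            "dtr": int(dtr), "dtr_length": dtr_len,
            "tier": assign_quality_tier(comp_by.get(cid), dtr),
        })

    write_table(pd.DataFrame(decision_rows), work / "triage_decisions.tsv")
    write_table(pd.DataFrame(tier_rows), work / "quality_tiers.tsv")
    write_fasta([contigs[c] for c in kept], work / "retained_contigs.fasta")
    write_provenance(work, "triage", cfg,
                     [work / "contigs.fasta", work / "genes.tsv",
                      work / "predictor_calls.tsv", work / "blank_hits.tsv"])
    return work / "triage_decisions.tsv"


def run_cluster(workdir: str | Path, cfg: Optional[RunConfig] = None) -> Path:
    """vOTU clustering of retained contigs; genus network if PCs present."""
    cfg = cfg or RunConfig()
    work = Path(workdir)
    contigs = parse_fasta(work / "retained_contigs.fasta", min_length=0)
    votus = greedy_species_cluster(contigs, ani_min=cfg.ani_min,
                                   af_min=cfg.af_min,
                                   fragment=cfg.ani_fragment,
                                   fragment_identity_min=cfg.fragment_identity_min)
    write_table(votus_to_frame(votus), work / "votus.tsv")
    by_id = {c.contig_id: c for c in contigs}
    write_fasta([by_id[v.representative] for v in votus],
                work / "votu_representatives.fasta")

    pc_path = work / "pc_membership.tsv"
    if pc_path.exists():
        pcs = parse_table(pc_path, PC_SCHEMA)
        pc_membership = dict(zip(pcs["protein_id"], pcs["pc_id"]))
        genome_of = dict(zip(pcs["protein_id"], pcs["genome_id"]))
        edges = gene_sharing_edges(pc_membership, genome_of,
                                   score_min=cfg.edge_score_min)
        write_table(edges, work / "genus_edges.tsv")
        clusters, singletons = genus_clusters(
            edges, sorted(set(genome_of.values())),
            count_singletons=cfg.count_singleton_genera)
        write_table(pd.DataFrame([
            {"cluster_id": c.cluster_id, "genome_id": g}
            for c in clusters for g in c.members]), work / "genera.tsv")
        write_table(pd.DataFrame({"genome_id": singletons}),
                    work / "genus_singletons.tsv")
    write_provenance(work, "cluster", cfg, [work / "retained_contigs.fasta"])
    return work / "votus.tsv"


def run_classify(workdir: str | Path, cfg: Optional[RunConfig] = None) -> Path:
    """Majority-rules family calls, plus family abundance if available."""
    cfg = cfg or RunConfig()
    work = Path(workdir)
    hits = parse_table(work / "protein_hits.tsv", PROTEIN_HIT_SCHEMA)
    votu_ids = sorted(set(hits["votu_id"]))
    rel_path = work / "abundance_relative.tsv"
    if rel_path.exists():
        relative = pd.read_csv(rel_path, sep="\t", index_col=0)
        votu_ids = sorted(set(votu_ids) | set(relative.index))
    else:
        relative = None

    rows = []
    for votu in votu_ids:
        sub = hits[hits["votu_id"] == votu]
        # proteins without any hit still vote; infer the roster from the
        # synthetic id convention (votu_pN)
        n_proteins = _roster_size(sub["protein_id"], votu)
        roster = sorted(set(sub["protein_id"])
                        | {f"{votu}_p{i + 1}" for i in range(n_proteins)})
        call = assign_family(votu, roster, sub[["protein_id", "family",
                                                "score", "pass"]],
                             min_fraction=cfg.family_vote_fraction,
                             min_bitscore=cfg.family_min_bitscore,
                             min_identity=cfg.family_min_identity)
        rows.append({"votu_id": votu, "family": call.family,
                     "supporting_fraction": round(call.supporting_fraction, 4),
                     "pass": call.pass_label})
    calls = pd.DataFrame(rows)
    write_table(calls, work / "family_calls.tsv")

    if relative is not None:
        mapping = dict(zip(calls["votu_id"], calls["family"]))
        for votu in relative.index:
            mapping.setdefault(votu, "unclassified")
        table, classified = summarize_family_abundance(mapping, relative)
        table.index.name = "family"
        table.reset_index().to_csv(work / "family_abundance.tsv", sep="\t",
                                   index=False)
        classified.rename("classified_fraction").to_frame().reset_index(
            names="sample_id").to_csv(work / "classified_fraction.tsv",
                                      sep="\t", index=False)
    write_provenance(work, "classify", cfg, [work / "protein_hits.tsv"])
    return work / "family_calls.tsv"


def _roster_size(protein_ids: pd.Series, votu: str,
                 default: int = 10) -> int:
    # synthetic protein ids are votu_pN; infer the full roster size
    sizes = [int(p.rsplit("_p", 1)[1]) for p in protein_ids
             if "_p" in p and p.rsplit("_p", 1)[1].isdigit()]
    return max(sizes, default=default)


def run_host(workdir: str | Path, cfg: Optional[RunConfig] = None) -> Path:
    """Collect the four evidence types and integrate host predictions."""
    cfg = cfg or RunConfig()
    work = Path(workdir)
    viral = parse_fasta(work / "retained_contigs.fasta", min_length=0)
    hosts = parse_fasta(work / "hosts.fasta", min_length=0,
                        source_set="host_mag")
    host_lengths = {h.contig_id: h.length for h in hosts}

    evidence = []
    alignments = parse_outfmt6(work / "alignments.tsv")
    viral_ids = {v.contig_id for v in viral}
    alignments = [a for a in alignments if a.query_id in viral_ids]
    evidence += filter_homology_matches(
        alignments, host_lengths, min_length=cfg.homology_min_length,
        min_identity=cfg.homology_min_identity,
        max_host_coverage=cfg.homology_max_host_coverage)

    arrays = []
    for h in hosts:
        arrays += detect_crispr_arrays(
            h.sequence, h.contig_id, min_repeats=cfg.crispr_min_repeats,
            repeat_range=cfg.crispr_repeat_range,
            spacer_range=cfg.crispr_spacer_range)
    evidence += match_spacers(arrays, viral,
                              max_mismatches=cfg.spacer_max_mismatches,
                              min_spacer_length=cfg.spacer_min_length)

    trna_path = work / "trna.tsv"
    if trna_path.exists():
        trna = pd.read_csv(trna_path, sep="\t", dtype=str)
        trna_by_host = {hid: sub["sequence"].tolist()
                        for hid, sub in trna.groupby("host_id")}
        evidence += match_trna(trna_by_host, viral)

    models = {h.contig_id: MarkovModel.train(h.sequence, cfg.markov_order)
              for h in hosts}
    kmer_rows = []
    for v in viral:
        table, ev = markov_score(v, models)
        evidence.append(ev)
        kmer_rows.append({"virus_id": v.contig_id,
                          "top_host": ev.host_id,
                          "loglik_per_nt": ev.detail["loglik_per_nt"]})

    predictions = integrate_host_evidence(
        evidence, points=cfg.host_score_points,
        method_bonus=cfg.host_score_method_bonus, cap=cfg.host_score_cap,
        high_confidence_min=cfg.host_high_confidence_min)
    write_table(evidence_to_frame(evidence), work / "host_evidence.tsv")
    write_table(predictions_to_frame(predictions),
                work / "host_predictions.tsv")
    write_table(pd.DataFrame(kmer_rows), work / "kmer_ranks.tsv")
    write_provenance(work, "host", cfg,
                     [work / "retained_contigs.fasta", work / "hosts.fasta",
                      work / "alignments.tsv"])
    return work / "host_predictions.tsv"


def run_ecology(workdir: str | Path, cfg: Optional[RunConfig] = None,
                community_blanks: bool = True) -> Path:
    """Abundance matrices, diversity, ordination, group tests, activity."""
    cfg = cfg or RunConfig()
    work = Path(workdir)
    depth = parse_table(work / "depth.tsv", DEPTH_SCHEMA)
    samples = parse_table(work / "samples.tsv", SAMPLE_SCHEMA)

    blank_path = work / "community_blank_hits.tsv"
    if community_blanks and blank_path.exists():
        blank = parse_table(blank_path, BLANK_SCHEMA)
        ids = sorted(set(depth["contig_id"]))
        kept, removed = decontaminate(ids, dict(zip(blank["contig_id"],
                                                    blank["reads"])))
        depth = depth[depth["contig_id"].isin(kept)]
        write_table(pd.DataFrame({"contig_id": removed}),
                    work / "ecology_decontaminated.tsv")

    filtered = apply_coverage_filter(depth, cfg.min_covered_fraction)
    matrix = depth_matrix(filtered)
    gb = dict(zip(samples["sample_id"], samples["gb"]))
    normalized, relative, pseudo, zero_samples = normalize_and_relativize(
        matrix, gb, cfg.pseudo_count_multiplier)
    for name, df in (("abundance_normalized", normalized),
                     ("abundance_relative", relative),
                     ("pseudo_counts", pseudo)):
        df.rename_axis(index="votu_id").reset_index().to_csv(
            work / f"{name}.tsv", sep="\t", index=False)

    diversity = sample_diversity(pseudo, relative, cfg.ace_rare_threshold)
    diversity.reset_index().to_csv(work / "diversity.tsv", sep="\t",
                                   index=False)

    groups = dict(zip(samples["sample_id"], samples["group"]))
    dm, coords, eigvals = beta_ordination(relative)
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).rename_axis(
        index="sample_id").reset_index().to_csv(work / "bray_curtis.tsv",
                                                sep="\t", index=False)
    coords.rename_axis(index="sample_id").reset_index().to_csv(
        work / "pcoa.tsv", sep="\t", index=False)

    pseudo_f, p = permanova_test(dm, groups, n_perm=cfg.n_permutations,
                                 seed=cfg.seed)
    alpha = alpha_group_tests(diversity, groups)
    write_table(alpha.assign(permanova_F=pseudo_f, permanova_p=p),
                work / "group_tests.tsv")

    transcripts = parse_table(work / "transcripts.tsv", TRANSCRIPT_SCHEMA)
    votu_of = {c: c for c in transcripts["contig_id"].unique()}
    activity = transcribed_activity(transcripts, votu_of,
                                    min_reads=cfg.active_min_reads,
                                    min_gene_fraction=cfg.active_gene_fraction)
    write_table(activity, work / "activity.tsv")
    write_provenance(work, "ecology", cfg,
                     [work / "depth.tsv", work / "samples.tsv",
                      work / "transcripts.tsv"])
    return work / "group_tests.tsv"


def run_amg(workdir: str | Path, cfg: Optional[RunConfig] = None) -> Path:
    """Screen AMG candidate rows against the retention rules."""
    cfg = cfg or RunConfig()
    work = Path(workdir)
    candidates = parse_table(work / "amg_candidates.tsv", AMG_SCHEMA)
    genes = _genes_from_table(parse_table(work / "amg_genes.tsv", GENE_SCHEMA))
    curated = {line.strip() for line in
               (work / "curated_functions.txt").read_text().splitlines()
               if line.strip()}
    screened = filter_amg_candidates(
        candidates, genes, curated, mode=cfg.amg_context_mode,
        max_auxiliary_score=cfg.amg_max_auxiliary_score,
        remove_flags=cfg.amg_remove_flags, cfg=cfg)
    write_table(screened, work / "amg_verdicts.tsv")
    histogram, _ = summarize_amgs(screened)
    histogram.rename("n_retained").to_frame().reset_index().to_csv(
        work / "amg_summary.tsv", sep="\t", index=False)
    write_provenance(work, "amg", cfg, [work / "amg_candidates.tsv"])
    return work / "amg_verdicts.tsv"


def run_report(workdir: str | Path, cfg: Optional[RunConfig] = None) -> Path:
    """Aggregate stage outputs into the summary-percentage table."""
    cfg = cfg or RunConfig()
    work = Path(workdir)

    def maybe(name):
        path = work / name
        return pd.read_csv(path, sep="\t") if path.exists() else None

    summary = summarize(
        tiers=maybe("quality_tiers.tsv"),
        activity=maybe("activity.tsv"),
        family_calls=maybe("family_calls.tsv"),
        predictions=maybe("host_predictions.tsv"),
        votus=maybe("votus.tsv"),
        genera=maybe("genera.tsv"),
        triage=maybe("triage_decisions.tsv"),
    )
    write_table(summary, work / "report.tsv")
    write_provenance(work, "report", cfg, [])
    return work / "report.tsv"
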