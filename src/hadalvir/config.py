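"""Run configuration.

Every threshold used anywhere in the pipeline is surfaced here with its
published default, so a run is fully described by (inputs, config, seed).
The config round-trips through YAML without loss.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Virus-specific annotation keywords (case-insensitive token/phrase match).
VIRAL_KEYWORDS = (
    "capsid", "phage", "terminase", "base plate", "baseplate", "prohead",
    "virion", "virus", "viral", "tape measure", "tapemeasure", "neck",
    "tail", "head", "bacteriophage", "prophage", "portal", "DNA packaging",
    "T4", "p22", "holin",
)

#: Substring patterns marking a product as functionally unknown.
UNKNOWN_PATTERNS = (
    "hypothetical protein", "unknown function", "uncharacterized protein",
    "viruses",
)

#: Substring patterns marking a product as prokaryote-specific.
PROKARYOTE_PATTERNS = ("ribosomal protein", "ribosomal RNA")

#: Predictors whose calls count as conservative viral signatures.
CONSERVATIVE_TOOLS = (
    "DeepVirFinder", "VirSorter", "VirSorter2", "MARVEL", "VIBRANT",
)

#: All wrapped phage predictors whose per-contig calls are pipeline inputs.
PREDICTOR_TOOLS = (
    "MARVEL", "VirFinder", "PPR-Meta", "VirSorter", "MetaPhinder",
    "DeepVirFinder", "VIBRANT", "VirNet", "Phigaro", "VirSorter2", "Seeker",
)


@dataclass
class RunConfig:
    # admission
    min_contig_length: int = 10_000          # strictly-greater-than filter, nt

    # triage
    viral_keywords: tuple = VIRAL_KEYWORDS
    unknown_patterns: tuple = UNKNOWN_PATTERNS
    prokaryote_patterns: tuple = PROKARYOTE_PATTERNS
    conservative_tools: tuple = CONSERVATIVE_TOOLS
    min_viral_genes: int = 2
    unknown_fraction_min: float = 0.70
    dtr_min_repeat: int = 20                 # nt of exact terminal repeat

    # vOTU / genus clustering
    ani_min: float = 95.0                    # percent identity
    af_min: float = 0.85                     # aligned fraction of the shorter
    ani_fragment: int = 500                  # nt
    fragment_identity_min: float = 80.0      # percent; fragment counts as aligned
    edge_score_min: float = 1.0              # -log10(P * n_pairs) threshold
    count_singleton_genera: bool = True

    # taxonomy
    family_vote_fraction: float = 0.5
    family_min_bitscore: float = 50.0
    family_min_identity: float = 50.0        # fallback pass, percent

    # host linkage
    homology_min_length: int = 2_500         # nt
    homology_min_identity: float = 70.0      # percent
    homology_max_host_coverage: float = 0.90
    spacer_max_mismatches: int = 1
    spacer_min_length: int = 20              # nt
    crispr_min_repeats: int = 3
    crispr_repeat_range: tuple = (23, 47)    # nt, inclusive
    crispr_spacer_range: tuple = (26, 50)    # nt, inclusive
    markov_order: int = 3
    host_score_points: dict = field(default_factory=lambda: {
        "crispr0": 5.0, "crispr1": 3.0, "homology": 3.0, "trna": 2.0,
        "kmer": 1.0,
    })
    host_score_method_bonus: float = 0.5
    host_score_cap: float = 5.0
    host_high_confidence_min: float = 3.0

    # ecology
    depth_min_read_identity: float = 0.95
    depth_min_aligned_length: int = 50       # nt
    min_covered_fraction: float = 0.10
    pseudo_count_multiplier: float = 10.0
    ace_rare_threshold: int = 10
    shannon_log_base: float = 0.0            # 0.0 -> natural log
    n_permutations: int = 999
    trimmed_mean_fraction: float = 0.05      # per tail, host depth mode
    active_min_reads: int = 2                # '>1 read' means >= 2
    active_gene_fraction: float = 0.20

    # AMG screening
    amg_max_auxiliary_score: int = 3         # scores > 3 are removed
    amg_remove_flags: tuple = ("T", "B")
    amg_context_mode: str = "strict"         # 'strict' | 'lenient'

    # plumbing
    seed: int = 0
    outdir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 <= self.min_covered_fraction <= 1:
            raise ValueError("min_covered_fraction must be in [0, 1]")
        if not 0 < self.af_min <= 1:
            raise ValueError("af_min must be in (0, 1]")
        if not 0 < self.ani_min <= 100:
            raise ValueError("ani_min must be in (0, 100]")
        if self.amg_context_mode not in ("strict", "lenient"):
            raise ValueError("amg_context_mode must be 'strict' or 'lenient'")
        if self.markov_order < 0:
            raise ValueError("markov_order must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in data.items():
            if key not in fields:
                raise ValueError(f"unknown config key: {key}")
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)
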