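"""Triage contigs into the bona-fide virome.

Applies the keyword/quorum retain rules, removes contigs carrying
prokaryote-specific genes, requires a conservative predictor signature
where completeness and viral genes are both absent, drops blank-control
contaminants, and assigns DTR-aware quality tiers to what survives.
"""

import argparse
from pathlib import Path

import pandas as pd

from hadalvir import pipeline
from hadalvir.config import RunConfig

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--workdir", type=Path, default=Path("results/workspace"))
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

pipeline.run_triage(args.workdir, RunConfig(seed=args.seed))
decisions = pd.read_csv(args.workdir / "triage_decisions.tsv", sep="\t")
tiers = pd.read_csv(args.workdir / "quality_tiers.tsv", sep="\t")
retained = int(decisions["retained"].sum())
print(f"retained {retained}/{len(decisions)} contigs as bona-fide viral")
blank = decisions["reasons"].str.contains("BLANK_CONTAMINANT").sum()
print(f"  {blank} removed as blank-control contaminants")
print("  quality tiers:",
      tiers["tier"].value_counts().sort_index().to_dict())
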