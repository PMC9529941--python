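"""Community ecology of the two-group vOTU abundance profiles.

Coverage-filtered depths are normalized per gigabase, relativized and
pseudo-counted; alpha diversity (observed, Chao1, ACE, Shannon, inverse
Simpson), Bray-Curtis PCoA, PERMANOVA and per-index t/Wilcoxon group
tests follow, plus the >=20%-of-genes-expressed transcription flags.
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

pipeline.run_ecology(args.workdir, RunConfig(seed=args.seed))
tests = pd.read_csv(args.workdir / "group_tests.tsv", sep="\t")
print(f"PERMANOVA: pseudo-F = {tests['permanova_F'].iloc[0]:.2f}, "
      f"p = {tests['permanova_p'].iloc[0]:.3f}")
print(tests[["index", "t_p", "wilcoxon_p"]].to_string(index=False))
activity = pd.read_csv(args.workdir / "activity.tsv", sep="\t")
print(f"transcriptionally active vOTUs: {int(activity['active'].sum())}"
      f"/{len(activity)}")
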