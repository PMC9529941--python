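"""Aggregate every stage's output into the headline summary table."""

import argparse
from pathlib import Path

import pandas as pd

from hadalvir import pipeline
from hadalvir.config import RunConfig

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--workdir", type=Path, default=Path("results/workspace"))
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

pipeline.run_report(args.workdir, RunConfig(seed=args.seed))
report = pd.read_csv(args.workdir / "report.tsv", sep="\t")
print(report.to_string(index=False))
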