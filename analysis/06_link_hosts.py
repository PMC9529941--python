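"""Predict virus-host linkages from four evidence types.

Collects prophage-like homology, CRISPR spacer matches (<=1 mismatch),
exact shared tRNAs and Markov-model composition ranks, then integrates
them into per-pair confidence scores; scores >= 3 are high confidence.
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

pipeline.run_host(args.workdir, RunConfig(seed=args.seed))
evidence = pd.read_csv(args.workdir / "host_evidence.tsv", sep="\t")
predictions = pd.read_csv(args.workdir / "host_predictions.tsv", sep="\t")
print("evidence rows by method:",
      evidence["method"].value_counts().to_dict())
high = predictions[predictions["high_confidence"] == 1]
print(f"{len(high)} high-confidence predictions "
      f"({high['virus_id'].nunique()} viruses, "
      f"{high['host_id'].nunique()} hosts)")
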