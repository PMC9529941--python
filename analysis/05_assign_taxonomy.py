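"""Majority-rules family assignment and family-level abundance.

A vOTU gets a family when >=50% of its proteins have a qualifying best
hit (bitscore >= 50 primary pass; percent identity >= 50 fallback pass);
family shares are then summed per sample from the relative abundances.
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

pipeline.run_classify(args.workdir, RunConfig(seed=args.seed))
calls = pd.read_csv(args.workdir / "family_calls.tsv", sep="\t")
classified = calls[calls["family"] != "unclassified"]
print(f"classified {len(classified)}/{len(calls)} vOTUs")
print("  by family:", classified["family"].value_counts().to_dict())
frac_path = args.workdir / "classified_fraction.tsv"
if frac_path.exists():
    frac = pd.read_csv(frac_path, sep="\t")
    print(f"  classified share of community: "
          f"{frac['classified_fraction'].min():.2f}"
          f"-{frac['classified_fraction'].max():.2f} across samples")
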