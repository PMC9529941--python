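"""Screen auxiliary-metabolic-gene candidates.

Removes rows with a T/B flag or auxiliary score > 3, rows absent from
the curated function list, and rows without viral genomic context
(strict mode: a virus-specific gene on each side of the candidate).
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

pipeline.run_amg(args.workdir, RunConfig(seed=args.seed))
verdicts = pd.read_csv(args.workdir / "amg_verdicts.tsv", sep="\t")
print("verdicts:", verdicts["verdict"].value_counts().to_dict())
retained = verdicts[verdicts["verdict"] == "retained"]
print("retained AMGs by category:",
      retained["category"].value_counts().to_dict())
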