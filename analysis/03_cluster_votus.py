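"""Cluster the retained contigs into species-level vOTUs and genera.

Greedy longest-first clustering at >=95% ANI over >=85% of the shorter
contig, then a gene-sharing network over protein clusters with
hypergeometric edge significance for genus-level grouping.
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

pipeline.run_cluster(args.workdir, RunConfig(seed=args.seed))
votus = pd.read_csv(args.workdir / "votus.tsv", sep="\t")
print(f"{votus['votu_id'].nunique()} vOTUs from {len(votus)} contigs")
genera_path = args.workdir / "genera.tsv"
if genera_path.exists():
    genera = pd.read_csv(genera_path, sep="\t")
    sizes = genera.groupby("cluster_id").size()
    print(f"{sizes.size} genus-level clusters "
          f"({int((sizes > 1).sum())} with >1 genome)")
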