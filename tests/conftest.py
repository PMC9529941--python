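import numpy as np
import pytest
from Bio import Align

from hadalvir.config import RunConfig
from hadalvir.synthetic import random_seq


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def cfg():
    return RunConfig(seed=0)


@pytest.fixture(scope="session")
def dp_aligner():
    """Independent full dynamic-programming alignment oracle.

    Global alignment with unit match score and heavy gap penalties: for
    substitution-only pairs the optimal alignment is gap-free, so
    score / length is the exact identity.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def dp_identity(aligner, a: str, b: str) -> float:
    """Percent identity of a substitution-only pair from the DP oracle."""
    assert len(a) == len(b)
    return 100.0 * aligner.score(a, b) / len(a)


@pytest.fixture(scope="session")
def workspace(tmp_path_factory):
    """A small, fully simulated workspace shared by pipeline-level tests."""
    from hadalvir import pipeline

    out = tmp_path_factory.mktemp("ws")
    cfg = RunConfig(seed=11)
    pipeline.run_simulate(out, cfg, n_viral=12, n_host=5, n_decoy=4,
                          n_votus=30, n_samples_per_group=6)
    return out
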