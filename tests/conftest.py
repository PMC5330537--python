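from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from parsbias import ParsParams, SimConfig, StartCountTrack, simulate_study

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# the three-organism study design: low / medium / high GC strains
STUDY_GC = (("lowgc", 0.32), ("midgc", 0.485), ("highgc", 0.73))


def study_configs(n_transcripts: int = 60, seed: int = 20170228) -> list[SimConfig]:
    return [
        SimConfig(target_gc=gc, n_transcripts=n_transcripts, seed=seed + i, strain_id=sid)
        for i, (sid, gc) in enumerate(STUDY_GC)
    ]


@pytest.fixture(scope="session")
def three_strain_study():
    """Full simulated study at the default generative parameters:
    three strains, 60 genes each, fixed seed."""
    return simulate_study(study_configs())


@pytest.fixture(scope="session")
def default_params() -> ParsParams:
    return ParsParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)


def random_track(rng: np.random.Generator, max_len: int = 200) -> StartCountTrack:
    """A small random count track with plenty of zeros, for oracle checks."""
    n = int(rng.integers(5, max_len + 1))
    draw = lambda: rng.poisson(rng.choice([0.3, 2.0, 20.0]), n)
    return StartCountTrack(
        transcript_id="rand",
        counts_v1=draw(),
        counts_s1=draw(),
        counts_control=draw(),
    )
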