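import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lineatime.model import EmbryoRecording, build_lineage
from lineatime.simulate import make_template, simulate_cohort, simulate_embryo
from lineatime.timing import analysis_cutoff_frame, cycle_lengths

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template():
    return make_template()


@pytest.fixture(scope="session")
def wt_embryo(template):
    return simulate_embryo(template, seed=3, recording_id="wt_fix")


@pytest.fixture(scope="session")
def wt_tree(wt_embryo):
    return build_lineage(wt_embryo)


@pytest.fixture(scope="session")
def wt_cohort(template):
    """Small wild-type cohort shared across tests (12 embryos)."""
    return simulate_cohort(template, n=12, seed=11)


@pytest.fixture(scope="session")
def wt_trees(wt_cohort):
    return [build_lineage(r) for r in wt_cohort]


@pytest.fixture(scope="session")
def wt_cycle_tables(wt_trees):
    return [
        cycle_lengths(t, cutoff_frame=analysis_cutoff_frame(t)) for t in wt_trees
    ]


def toy_recording(rows, **meta) -> EmbryoRecording:
    """Recording from (cell, frame, x, y, z[, intensity]) tuples."""
    cols = ["cell", "frame", "x", "y", "z", "intensity"]
    df = pd.DataFrame([list(r) + [np.nan] * (6 - len(r)) for r in rows], columns=cols)
    meta.setdefault("id", "toy")
    return EmbryoRecording(observations=df, **meta)


@pytest.fixture
def make_toy():
    return toy_recording
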