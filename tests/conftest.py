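import numpy as np
import pandas as pd
import pytest

from pendulumtest.pipeline import run_study
from pendulumtest.simulator import CohortSpec, PendulumModel, simulate_cohort, simulate_trace


@pytest.fixture()
def damped_trace():
    """Noiseless underdamped trace (ζ=0.2, rest 70°, release 0°)."""
    return simulate_trace(PendulumModel(zeta=0.2, duration_s=20.0))


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """3-subject cohort on disk: (out_dir, trial metadata, ground truth)."""
    out = tmp_path_factory.mktemp("small_cohort")
    spec = CohortSpec(n_subjects=3, seed=7)
    meta, truth = simulate_cohort(spec, out)
    return out, meta, truth


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """Default 20-subject cohort processed end to end (records, tables, truth)."""
    out = tmp_path_factory.mktemp("default_cohort")
    spec = CohortSpec(seed=0)
    meta, truth = simulate_cohort(spec, out)
    records, tables = run_study(out / "trial_table.csv")
    return records, tables, truth
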