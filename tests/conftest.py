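"""Shared fixtures: head model, cheap test media, and a pooled standard run.

The heavy transport work is done once per session: a replicated
standard-configuration campaign (1 mm emitter at the volume centre, every
top-face exit recorded) whose records serve all separation- and
diameter-resolved checks through virtual detectors.
"""

import pytest
from hypothesis import HealthCheck, settings

from widefnirs.experiments import ExperimentConfig, replicate_shift
from widefnirs.fixtures import make_homogeneous_halfspace
from widefnirs.head_model import OpticalProperties, build_head_model
from widefnirs.mc_engine import (
    DetectorSpec,
    RECORD_TOP_EXITS,
    SourceSpec,
    run_simulation,
)

settings.register_profile(
    "ci", max_examples=25, derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: a cheap, weakly scattering homogeneous medium for fast transport tests
FAST_PROPS = OpticalProperties(mua=0.01, mus=1.0, g=0.5, n=1.0)


@pytest.fixture(scope="session")
def head_model():
    return build_head_model()


@pytest.fixture(scope="session")
def fast_medium():
    return make_homogeneous_halfspace(FAST_PROPS)


@pytest.fixture(scope="session")
def standard_records(head_model):
    """Replicated standard-emitter runs with all top exits recorded.

    1 mm emitter centred on the volume so ring detectors at 30/40/50 mm
    separations can be evaluated from the same records; replicates differ by
    seed and a 1 mm positional shift along the optode axis.
    """
    cfg = ExperimentConfig(master_seed=20240901)
    n_reps, n_packets = 6, 70_000
    results = []
    for i in range(n_reps):
        shift = replicate_shift(i)
        src = SourceSpec(center=(75.0, 75.0 + shift), diameter=1.0)
        det = DetectorSpec(center=(75.0, 105.0 + shift), diameter=1.0)
        res = run_simulation(
            head_model, src, det, n_packets, seed=cfg.seed_for(i),
            record_mode=RECORD_TOP_EXITS,
        )
        res.meta["shift"] = shift
        results.append(res)
    return results
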