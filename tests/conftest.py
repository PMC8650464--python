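"""Shared fixtures: small phantoms and simulated series, built once.

Everything is generated programmatically; no binary fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from braintransport.phantom import (
    ArtifactSpec,
    GroundTruth,
    build_phantom,
    default_spec,
    injection_location_mm,
    simulate_truth,
    synthesize_signal,
)
from braintransport.relaxometry import AcquisitionParams
from braintransport.solver import SolverConfig, SourceSpec, TransportParams

FRAME_TIMES = np.arange(0.0, 90.0, 10.0)
TRUTH = (0.10, 95.0, 60.0)  # (BT, PAS_Surf, PAS_Branch) mm²/min


@pytest.fixture(scope="session")
def small_spec():
    return default_spec(grid_shape=(32, 32, 24), voxel_size=0.2, seed=11)


@pytest.fixture(scope="session")
def small_gt(small_spec) -> GroundTruth:
    return build_phantom(small_spec)


@pytest.fixture(scope="session")
def true_params() -> TransportParams:
    return TransportParams(deff={1: TRUTH[0], 2: TRUTH[1], 3: TRUTH[2]})


@pytest.fixture(scope="session")
def small_source(small_spec) -> SourceSpec:
    return SourceSpec(location=tuple(injection_location_mm(small_spec)))


@pytest.fixture(scope="session")
def small_conc(small_gt, true_params, small_source):
    return simulate_truth(
        small_gt, true_params, small_source, FRAME_TIMES, SolverConfig(dt=1.0)
    )


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams(frame_times=FRAME_TIMES)


@pytest.fixture(scope="session")
def clean_signal(small_conc, small_gt, acq):
    """Noiseless, dropout-free synthesized signal."""
    art = ArtifactSpec(
        noise_sigma=0.0, surface_dropout_voxels=0, injection_dropout=np.inf, seed=0
    )
    return synthesize_signal(small_conc, small_gt.t1_map, acq, art, small_gt.brain_mask)


def uniform_block_gt(n=(20, 20, 20), voxel_size=0.15, label=1) -> GroundTruth:
    """Ground truth whose 'brain' is a solid uniform block (for oracle tests)."""
    from braintransport.phantom import PhantomSpec

    spec = PhantomSpec(grid_shape=tuple(n), voxel_size=voxel_size)
    labels = np.full(n, label, dtype=np.int8)
    t1 = np.full(n, 1800.0)
    return GroundTruth(spec=spec, labels=labels, t1_map=t1)
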