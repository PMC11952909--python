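"""Shared fixtures: one coarse phantom, its FEA model, and trained networks.

Session scope keeps the expensive artifacts (dataset sweeps, network
training) shared across test modules; everything is seeded, so the fixtures
are deterministic.
"""

import numpy as np
import pytest

from spinepinn.dataset import (
    LoadSweep,
    SamplingRanges,
    build_dataset,
    split_and_normalize,
)
from spinepinn.fea import FEAModel
from spinepinn.geometry import PhantomSpec, build_phantom
from spinepinn.network import NetConfig, fine_tune, train


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(mesh_resolution=8.0)


@pytest.fixture(scope="session")
def phantom_mesh(phantom_spec):
    return build_phantom(phantom_spec)


@pytest.fixture(scope="session")
def fea_model(phantom_mesh):
    return FEAModel(phantom_mesh)


@pytest.fixture(scope="session")
def ranges():
    return SamplingRanges()


@pytest.fixture(scope="session")
def load_sweep():
    return LoadSweep()


@pytest.fixture(scope="session")
def dataset406(phantom_mesh, fea_model, ranges, load_sweep):
    """29 material draws x 14 magnitudes = 406 rows, split and normalized."""
    ds = build_dataset(
        phantom_mesh, ranges, load_sweep, n_materials=29, seed=11, model=fea_model
    )
    return split_and_normalize(ds, seed=1)


@pytest.fixture(scope="session")
def calib672(phantom_mesh, fea_model, ranges, load_sweep):
    """48 material draws x 14 magnitudes = 672 rows (calibration-scale set)."""
    ds = build_dataset(
        phantom_mesh, ranges, load_sweep, n_materials=48, seed=23, model=fea_model
    )
    return split_and_normalize(ds, seed=29)


@pytest.fixture(scope="session")
def trained_net(dataset406):
    return train(dataset406, NetConfig(epochs=3000, seed=0))


@pytest.fixture(scope="session")
def tuned_net(trained_net, calib672):
    return fine_tune(trained_net, calib672, epochs=3000)


@pytest.fixture(scope="session")
def recovery_runs(phantom_mesh, fea_model, tuned_net, ranges):
    """Hybrid-loop calibrations against five fresh ground truths."""
    from spinepinn.calibration import LoopConfig, run_loop
    from spinepinn.dataset import sample_materials

    truths = sample_materials(ranges, 5, seed=37)
    recs = [
        run_loop(phantom_mesh, tuned_net, LoopConfig(), ground_truth=gt, model=fea_model)
        for gt in truths
    ]
    return truths, recs
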