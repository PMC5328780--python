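import numpy as np
import pytest

from stickwalk import ModelConfig, build_model


@pytest.fixture(scope="session")
def cfg():
    return ModelConfig.default()


@pytest.fixture(scope="session")
def tetrapod_traj(cfg):
    """20 s tetrapod control run at the committed calibration."""
    model = build_model(cfg, mode="tetrapod")
    return model.run(20000.0)


@pytest.fixture(scope="session")
def tripod_traj(cfg):
    """20 s tripod control run at the committed calibration."""
    model = build_model(cfg, mode="tripod")
    return model.run(20000.0)


def liftoffs(traj, leg, skip_ms=4000.0):
    lo = np.array([e.t for e in traj.events(leg) if e.kind == "liftoff"])
    return lo[lo > skip_ms]


@pytest.fixture(scope="session")
def tetrapod_period(tetrapod_traj):
    return float(np.diff(liftoffs(tetrapod_traj, "HL")).mean())


@pytest.fixture(scope="session")
def tripod_period(tripod_traj):
    return float(np.diff(liftoffs(tripod_traj, "HL")).mean())
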