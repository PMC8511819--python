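import numpy as np
import pytest

import fracenv as fe


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = fe.PhantomSpec(noise_sd=0.0)
    vol, gt = fe.generate_phantom(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = fe.PhantomSpec()  # default 5 HU noise
    vol, gt = fe.generate_phantom(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def noiseless_calibration(noiseless_phantom):
    spec, vol, gt = noiseless_phantom
    stats = fe.extract_rod_stats(vol, gt.labels, spec.rod_densities)
    return fe.fit_hu_to_density(stats)


def reduced_spec(**overrides) -> fe.PhantomSpec:
    """A coarse phantom for fast end-to-end tests (not the committed
    default conditions)."""
    base = dict(
        volume_shape=(24, 21, 20),
        voxel_spacing=(2.0, 2.0, 3.0),
        screw_spec=((10.0, 4.0), (20.0, 4.0), (40.0, 4.0), (50.0, 4.0)),
        gap_center_z=30.0,
    )
    base.update(overrides)
    return fe.PhantomSpec(**base)


@pytest.fixture()
def reduced_config():
    def make(**overrides) -> fe.ScenarioConfig:
        phantom = overrides.pop("phantom", None) or reduced_spec()
        return fe.ScenarioConfig(name="reduced", phantom=phantom, **overrides)

    return make


@pytest.fixture(scope="session")
def default_pair_reports(tmp_path_factory):
    """The committed 8 mm vs 9 mm scenario pair, run once per session."""
    out = tmp_path_factory.mktemp("pair")
    failed, revision = fe.default_scenario_pair(seed=1, out_root=str(out))
    return fe.run_pipeline(failed), fe.run_pipeline(revision)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
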