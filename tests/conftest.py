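import numpy as np
import pytest

import hbstateflux as hb


@pytest.fixture(scope="session")
def geometry():
    return hb.GeometryConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_breast():
    """One simulated breast series (20 voxels x 810 frames, seed 7)."""
    cfg = hb.SimulationConfig(n_voxels=20, n_frames=810, seed=7)
    dD, dO, states = hb.simulate_breast(cfg)
    return cfg, dD, dO, states


@pytest.fixture(scope="session")
def fitted(small_breast):
    cfg, dD, dO, _ = small_breast
    model = hb.HbStateModel(dD, dO, geometry=cfg.geometry,
                            sampling_rate=cfg.sampling_rate, detrend=False)
    return model.fit()


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """A small on-disk bilateral cohort with a disease effect."""
    outdir = tmp_path_factory.mktemp("cohort")
    cfg = hb.SimulationConfig(
        n_voxels=12, n_frames=400, seed=42,
        disease_effect=hb.DiseaseEffect(dwell_multiplier=0.7,
                                        amplitude_multiplier=1.5))
    manifest = hb.simulate_cohort(cfg, n_cancer=6, n_noncancer=8, outdir=outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def cohort(cohort_dir):
    from hbstateflux.cli import load_cohort
    outdir, _ = cohort_dir
    return load_cohort(outdir / "manifest.csv", quantities=("k", "P", "phi_S"))
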