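import numpy as np
import pytest

from pskel.phantom import (
    PhantomSpec,
    Tract,
    make_gradient_scheme,
)


@pytest.fixture(scope="session")
def dti_scheme():
    """A small single-shell scheme adequate for tensor fitting."""
    return make_gradient_scheme(2, [(750, 20)], seed=11)


@pytest.fixture(scope="session")
def two_shell_scheme():
    """A reduced two-shell scheme for NODDI tests (low + high b)."""
    return make_gradient_scheme(4, [(750, 30), (2500, 30)], seed=7)


@pytest.fixture()
def single_tube():
    """One straight tube along x with a Gaussian FA cross-section."""
    return PhantomSpec(
        grid_shape=(16, 12, 12),
        tracts=[Tract(axis=0, center=(6.0, 6.0), radius=3.0)],
        signal_model="tensor",
    )


@pytest.fixture()
def parallel_tubes():
    """Two parallel tubes along x, centerlines 8 voxels apart."""
    return PhantomSpec(
        grid_shape=(16, 20, 12),
        tracts=[
            Tract(axis=0, center=(5.0, 6.0), radius=3.0, name="a"),
            Tract(axis=0, center=(13.0, 6.0), radius=3.0, name="b",
                  eigvals=(1.5, 0.35, 0.35)),
        ],
        signal_model="tensor",
    )


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full phantom-demo pipeline run, shared across tests."""
    from pskel.pipeline import PipelineConfig, run_demo

    out = tmp_path_factory.mktemp("demo_a")
    cfg = PipelineConfig(out_dir=str(out), seed=20)
    ps_df, report = run_demo(cfg)
    return out, ps_df, report
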