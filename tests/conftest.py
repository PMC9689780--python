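import numpy as np
import pytest

from brainwave.geometry import build_array
from brainwave.phantom import BrainPhantom, build_base_phantom, voxel_centers
from brainwave.tissues import default_tissue_table


@pytest.fixture(scope="session")
def array():
    return build_array()


@pytest.fixture(scope="session")
def base_phantom_64():
    return build_base_phantom(grid_n=64, seed=7)


@pytest.fixture(scope="session")
def base_phantom_32():
    return build_base_phantom(grid_n=32, seed=7)


def make_sphere_phantom(n, side=0.24, eps=1.5, sigma=0.01, radius=0.05, center=(0, 0, 0)):
    """Homogeneous dielectric sphere in air, bypassing the surface model."""
    pts = voxel_centers(n, side)
    r = np.linalg.norm(pts - np.asarray(center, float), axis=-1)
    lab = (r < radius).astype(np.uint8)
    epsg = np.where(lab, eps, 1.0).astype(float)
    sigg = np.where(lab, sigma, 0.0).astype(float)
    t = default_tissue_table()
    return BrainPhantom(
        label_grid=lab,
        eps_grid=epsg,
        sigma_grid=sigg,
        domain_side_m=side,
        voxel_size_m=side / n,
        table=t,
        surfaces=np.zeros((len(t), 13, 24)),
        tissue_eps=np.asarray(t.eps_r),
        tissue_sigma=np.asarray(t.sigma),
    )


@pytest.fixture(scope="session")
def sphere_phantom():
    """Factory fixture for homogeneous-sphere phantoms."""
    return make_sphere_phantom


@pytest.fixture(scope="session")
def smoke_run(tmp_path_factory):
    """One desk-scale end-to-end training run shared by every test that
    needs trained models (grid 24^3, 100 training phantoms)."""
    from brainwave.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("smoke") / "run"
    cfg = RunConfig(out_dir=str(out), seed=1)
    return cfg, run_pipeline(cfg)
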