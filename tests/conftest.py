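"""Shared fixtures: expensive pipeline runs are computed once per session."""
from __future__ import annotations

import numpy as np
import pytest

import implantac as ia

#: seed for the seeded simulation fixtures
STUDY_SEED = 7


@pytest.fixture(scope="session")
def default_study() -> ia.StudyResult:
    """One full four-strategy comparison on the default seeded phantom."""
    return ia.run_experiment(ia.default_run_config(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def noiseless_truth_fit():
    """Noiseless acquisition reconstructed with the true mu map (extra iterations).

    Returns (study config, ground truth, ReconstructionResult).
    """
    cfg = ia.default_run_config(seed=STUDY_SEED)
    labels, activity, truth = ia.build_knee_phantom(cfg.phantom)
    mu = ia.mumap_from_labels(labels, cfg.materials)
    sino = ia.forward_project(activity, mu, cfg.geometry, cfg.acquisition_scale)
    result = ia.EmissionModel(sino, mu).fit(
        ia.ReconConfig(n_subsets=21, n_iterations=6)
    )
    return cfg, truth, result


@pytest.fixture(scope="session")
def misregistration_report() -> ia.MisregistrationReport:
    return ia.misregistration_experiment(ia.default_run_config(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def default_phantom():
    """Default-resolution phantom (labels, activity, ground truth)."""
    return ia.build_knee_phantom(ia.PhantomConfig())


@pytest.fixture()
def coarse_phantom_config() -> ia.PhantomConfig:
    """Coarse grid over the same 200 x 200 x 120 mm field, for fast tests."""
    return ia.PhantomConfig(
        grid_shape=(64, 64, 20), voxel_size_mm=(3.125, 3.125, 6.0)
    )


def brute_force_ray_sums(image2d, voxel_size2d, angles, offsets):
    """Independent parallel-beam line integrals by per-pixel segment clipping.

    For every ray and every pixel, the intersection of the ray with the
    pixel's axis-aligned box is computed by slab clipping; the line integral
    is the sum of pixel value times chord length.  O(n_rays * n_pixels),
    intended for tiny grids only.
    """
    nx, ny = image2d.shape
    dx, dy = voxel_size2d
    out = np.zeros((len(angles), len(offsets)))
    for ai, theta in enumerate(angles):
        ux, uy = -np.sin(theta), np.cos(theta)
        for ri, s in enumerate(offsets):
            px, py = s * np.cos(theta), s * np.sin(theta)
            total = 0.0
            for i in range(nx):
                x0, x1 = (i - nx / 2.0) * dx, (i + 1 - nx / 2.0) * dx
                for j in range(ny):
                    y0, y1 = (j - ny / 2.0) * dy, (j + 1 - ny / 2.0) * dy
                    tmin, tmax = -np.inf, np.inf
                    for p, u, lo, hi in ((px, ux, x0, x1), (py, uy, y0, y1)):
                        if abs(u) > 1e-12:
                            t0, t1 = (lo - p) / u, (hi - p) / u
                            tmin = max(tmin, min(t0, t1))
                            tmax = min(tmax, max(t0, t1))
                        elif not (lo <= p < hi):
                            # half-open so an axis-parallel ray on a pixel
                            # boundary is counted for exactly one pixel
                            tmin, tmax = np.inf, -np.inf
                    if tmax > tmin:
                        total += image2d[i, j] * (tmax - tmin)
            out[ai, ri] = total
    return out
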