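import numpy as np
import pytest

import painmorph as pm


@pytest.fixture(scope="session")
def small_atlas():
    """10-ROI mirrored atlas, enough structure for distance-based tests."""
    return pm.build_default_atlas(n_per_hemisphere=5, seed=0)


@pytest.fixture(scope="session")
def atlas82():
    return pm.build_default_atlas(seed=0)


@pytest.fixture(scope="session")
def small_cohort(small_atlas):
    """Compact four-group cohort on the 10-ROI atlas."""
    cfg = pm.default_config(
        small_atlas,
        seed=0,
        group_sizes={"healthy": 12, "CBP": 10, "CRPS": 8, "OA": 6},
    )
    return pm.simulate_cohort(small_atlas, cfg)


@pytest.fixture(scope="session")
def cohort82(atlas82):
    """Default-size cohort on the full 82-ROI atlas (one simulation per session)."""
    cfg = pm.default_config(atlas82, seed=1)
    return pm.simulate_cohort(atlas82, cfg)


@pytest.fixture(scope="session")
def corrected82(cohort82):
    return pm.residualize_gm(cohort82)


@pytest.fixture(scope="session")
def corrected_small(small_cohort):
    return pm.residualize_gm(small_cohort)


def depth_oracle(pts):
    """Independent brute-force Tukey depth: scan directions built from all
    pairwise difference normals (nudged both ways) plus a fine angular grid."""
    pts = np.asarray(pts, float)
    angles = [
        np.arctan2(p[1] - q[1], p[0] - q[0])
        for p in pts
        for q in pts
        if not np.allclose(p, q)
    ]
    cand = []
    for a in angles:
        for da in (-1e-6, 1e-6):
            cand.append(a + np.pi / 2 + da)
    cand.extend(np.linspace(0, 2 * np.pi, 720, endpoint=False))
    u = np.column_stack([np.cos(cand), np.sin(cand)])
    depths = []
    for p in pts:
        proj = (pts - p) @ u.T
        depths.append(int((proj >= -1e-9).sum(axis=0).min()))
    return np.array(depths)


def holm_oracle(p):
    """Brute-force Holm step-down: sort, scale by (m - rank), running max, cap at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
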