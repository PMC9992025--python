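import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lesionqol import SimulationConfig, build_toy_atlas

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Small but fully featured simulation: 12 subjects, coarse grid."""
    return SimulationConfig(
        n_subjects=12,
        grid_shape=(28, 32, 28),
        voxel_size_mm=(4.0, 4.0, 4.0),
        n_nodes_per_hemisphere=10,
        n_networks=2,
        n_tracts_per_hemisphere=6,
        n_midline_tracts=1,
        lesion_radii_mm={"flair": 25.0, "cavity": 14.0, "t1ce": 12.0, "fet": 16.0},
        n_timepoints=60,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_atlases(small_config):
    return build_toy_atlas(small_config)


# ------------------------------------------------------------- oracles

def kendall_tau_b_brute(x, y):
    """All-pairs enumeration of tau-b with the tie-corrected denominator."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    C = D = n1 = n2 = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0:
                n1 += 1
            if dy == 0:
                n2 += 1
            if dx * dy > 0:
                C += 1
            elif dx * dy < 0:
                D += 1
    n0 = n * (n - 1) // 2
    denom = np.sqrt(float(n0 - n1) * float(n0 - n2))
    if denom == 0:
        return float("nan")
    return (C - D) / denom


def overlap_brute(mask, labels, voxel_volume_mm3, region_ids):
    """Per-voxel triple-loop intersection count for every region."""
    out_ml = {}
    for rid in region_ids:
        count = 0
        for idx in np.ndindex(mask.shape):
            if mask[idx] and labels[idx] == rid:
                count += 1
        out_ml[rid] = count * voxel_volume_mm3 / 1000.0
    return out_ml


def wnc_brute(z, node_ids, pool_of):
    """Mean within-pool z per node by explicit pair enumeration."""
    out = {}
    for i, ni in enumerate(node_ids):
        vals = [
            z[i, j]
            for j, nj in enumerate(node_ids)
            if j != i and pool_of[nj] == pool_of[ni]
        ]
        out[ni] = float(np.mean(vals)) if vals else float("nan")
    return out
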