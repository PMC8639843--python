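import numpy as np
import pytest

from cifu import (
    AngularGrid,
    ProfileSet,
    SyntheticSpec,
    normalize,
    simulate_profiles,
)


def constant_profiles(levels, grid=None, ages=None):
    """ProfileSet of constant curves at the given levels (µm)."""
    if grid is None:
        grid = AngularGrid()
    levels = np.asarray(levels, dtype=float)
    n = len(levels)
    return ProfileSet(
        grid=grid,
        values=np.tile(levels[:, None], (1, grid.n_points)),
        sample_id=np.array([f"s{i}" for i in range(n)], dtype=object),
        eye=np.array(["OD"] * n, dtype=object),
        age=np.asarray(ages if ages is not None else [45.0] * n, dtype=float),
    )


def harmonic_profiles(coefs_list, grid=None, constant=90.0):
    """Curves constant + Σ_m a_m·cos(mθ) + b_m·sin(mθ) from (a, b) dicts."""
    if grid is None:
        grid = AngularGrid()
    th = np.deg2rad(grid.angles)
    rows = []
    for coefs in coefs_list:
        row = np.full(grid.n_points, constant)
        for m, (a, b) in coefs.items():
            row = row + a * np.cos(m * th) + b * np.sin(m * th)
        rows.append(row)
    values = np.array(rows)
    n = len(rows)
    return ProfileSet(
        grid=grid,
        values=values,
        sample_id=np.array([f"h{i}" for i in range(n)], dtype=object),
        eye=np.array(["OS"] * n, dtype=object),
        age=np.full(n, 52.0),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Session-shared synthetic 3-cluster cohort under the default conditions."""
    profiles, labels = simulate_profiles(SyntheticSpec(seed=0))
    return profiles, labels


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    profiles, labels = default_cohort
    return normalize(profiles), labels
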