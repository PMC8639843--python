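"""Circular profile and covariate containers, CSV readers/writers, age stratification.

The central object is a :class:`ProfileSet`: ``n`` neuroretinal-rim (NRR)
thickness curves sampled on a shared angular grid around the optic nerve
head.  The scanner exports 180 thickness values in TSNIT order, labelled
2°..360°; internally the grid is the canonical ``t_l = 2(l-1)`` for
``l = 1..180`` (0°, 2°, ..., 358°), the exported 360° column being the same
circular position as 0°.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The nine clinical covariates used for metaclustering, with units.
COVARIATE_NAMES: tuple[str, ...] = (
    "iop",            # intraocular pressure, mmHg
    "cct",            # central corneal thickness, µm
    "axial_length",   # mm
    "rim_area",       # mm²
    "disc_area",      # mm²
    "disc_diameter",  # mm
    "vertical_cdr",   # cup-to-disc ratio (vertical)
    "average_cdr",    # cup-to-disc ratio (average)
    "cup_volume",     # mm³
)

#: Age strata: 1 = [40, 50), 2 = [50, 60), 3 = [60, inf).
AGE_STRATA: Mapping[int, tuple[float, float]] = {
    1: (40.0, 50.0),
    2: (50.0, 60.0),
    3: (60.0, np.inf),
}


class ProfileFormatError(ValueError):
    """Raised when a profiles/covariates CSV does not match the expected layout."""


@dataclass(frozen=True)
class AngularGrid:
    """Evenly spaced periodic angular grid on [0, 360).

    Parameters
    ----------
    n_points
        Number of angular positions ``L``; the step is ``360 / L`` degrees.
    """

    n_points: int = 180

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("grid needs at least one angular position")

    @property
    def step(self) -> float:
        return 360.0 / self.n_points

    @property
    def angles(self) -> np.ndarray:
        """Grid angles ``t_l = step * (l - 1)`` in degrees, in [0, 360)."""
        return np.arange(self.n_points) * self.step

    @property
    def period(self) -> float:
        return 360.0


@dataclass
class ProfileSet:
    """A set of circular curves on a common grid with per-sample metadata.

    ``values`` holds thickness in µm before normalization and a dimensionless
    circular density afterwards (``normalized`` flag).
    """

    grid: AngularGrid
    values: np.ndarray            # (n, L)
    sample_id: np.ndarray         # (n,) str
    eye: np.ndarray               # (n,) "OD" | "OS"
    age: np.ndarray               # (n,) float, years
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.eye = np.asarray(self.eye, dtype=object)
        self.age = np.asarray(self.age, dtype=float)
        n, L = self.values.shape
        if L != self.grid.n_points:
            raise ValueError(
                f"values have {L} angular columns, grid has {self.grid.n_points}"
            )
        for name, arr in (("sample_id", self.sample_id), ("eye", self.eye),
                          ("age", self.age)):
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} != n={n}")
        if not np.all(np.isfinite(self.values)):
            bad = self.sample_id[~np.isfinite(self.values).all(axis=1)]
            raise ValueError(f"non-finite thickness values in samples {list(bad)}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, mask: np.ndarray) -> "ProfileSet":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return replace(
            self,
            values=self.values[idx],
            sample_id=self.sample_id[idx],
            eye=self.eye[idx],
            age=self.age[idx],
        )

    def circular_integrals(self) -> np.ndarray:
        """Rectangle-rule circular integral of each curve (Δt = grid step)."""
        return self.values.sum(axis=1) * self.grid.step


@dataclass
class CovariateTable:
    """Per-sample clinical covariates (a subset of :data:`COVARIATE_NAMES`)."""

    data: pd.DataFrame  # index = sample_id, columns ⊆ COVARIATE_NAMES

    def __post_init__(self) -> None:
        unknown = [c for c in self.data.columns if c not in COVARIATE_NAMES]
        if unknown:
            raise ValueError(f"unknown covariate columns: {unknown}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_id: {dups}")

    @property
    def covariates(self) -> list[str]:
        return list(self.data.columns)

    def loc(self, sample_ids: np.ndarray) -> pd.DataFrame:
        return self.data.loc[list(sample_ids)]


_ANGLE_RE = re.compile(r"(\d+(?:\.\d+)?)\s*$")


def _angle_from_header(header: str) -> float | None:
    """Extract the trailing degree label from an angular column header."""
    m = _ANGLE_RE.search(header.strip().rstrip("°"))
    if m is None:
        return None
    return float(m.group(1))


def _angular_label(angle: float) -> str:
    """Export label for an internal grid angle: 0° is written as the 360° column."""
    deg = 360 if angle == 0 else angle
    return f"t_{int(deg):03d}" if float(deg).is_integer() else f"t_{deg:g}"


def read_profiles(path, grid: AngularGrid | None = None) -> ProfileSet:
    """Read a wide profiles CSV (sample_id, eye, age, one column per angle).

    Angular headers carry degrees (e.g. ``t_002 .. t_360``); the 360° column
    is stored at internal angle 0.  Row order is preserved.
    """
    if grid is None:
        grid = AngularGrid()
    df = pd.read_csv(path, float_precision="round_trip")
    meta_cols = {"sample_id", "eye", "age"}
    missing_meta = meta_cols - set(df.columns)
    if missing_meta:
        raise ProfileFormatError(f"missing metadata columns: {sorted(missing_meta)}")

    header_angle: dict[str, float] = {}
    for col in df.columns:
        if col in meta_cols:
            continue
        ang = _angle_from_header(col)
        if ang is not None:
            header_angle[col] = ang % 360.0

    want = {round(a, 9): i for i, a in enumerate(grid.angles)}
    got: dict[float, str] = {}
    extra: list[str] = []
    for col, ang in header_angle.items():
        key = round(ang, 9)
        if key in want and key not in got:
            got[key] = col
        else:
            extra.append(col)
    missing = [
        _angular_label(a) for a in grid.angles if round(a, 9) not in got
    ]
    if missing or extra:
        raise ProfileFormatError(
            f"angular columns do not match the {grid.n_points}-point grid; "
            f"missing={missing[:10]}{'...' if len(missing) > 10 else ''} "
            f"unexpected={extra[:10]}"
        )

    ordered = [got[round(a, 9)] for a in grid.angles]
    try:
        values = df[ordered].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for _, row in df.iterrows():
            try:
                row[ordered].astype(float)
            except (TypeError, ValueError):
                raise ProfileFormatError(
                    f"non-numeric thickness in sample {row['sample_id']!r}"
                ) from exc
        raise
    return ProfileSet(
        grid=grid,
        values=values,
        sample_id=df["sample_id"].astype(str).to_numpy(dtype=object),
        eye=df["eye"].astype(str).to_numpy(dtype=object),
        age=df["age"].to_numpy(dtype=float),
    )


def write_profiles(profiles: ProfileSet, path) -> None:
    """Write the wide CSV dialect read by :func:`read_profiles` (lossless)."""
    labels = [_angular_label(a) for a in profiles.grid.angles]
    # export in ascending label order 2..360, i.e. internal index 1..L-1, 0
    order = np.argsort([360.0 if a == 0 else a for a in profiles.grid.angles])
    meta = pd.DataFrame(
        {
            "sample_id": profiles.sample_id,
            "eye": profiles.eye,
            "age": profiles.age,
        }
    )
    angular = pd.DataFrame(
        profiles.values[:, order], columns=[labels[idx] for idx in order]
    )
    pd.concat([meta, angular], axis=1).to_csv(path, index=False)


def read_covariates(path) -> CovariateTable:
    """Read a covariates CSV; keeps the recognized clinical columns only."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "sample_id" not in cols:
        raise ProfileFormatError("covariates CSV must have a sample_id column")
    recognized = [name for name in COVARIATE_NAMES if name in cols]
    if not recognized:
        raise ProfileFormatError(
            f"no recognized covariate columns; expected some of {list(COVARIATE_NAMES)}"
        )
    unrecognized = [
        c for c in df.columns
        if c.strip().lower() not in set(recognized) | {"sample_id"}
    ]
    if unrecognized:
        logger.warning("ignoring unrecognized covariate columns: %s", unrecognized)
    absent = [name for name in COVARIATE_NAMES if name not in cols]
    if absent:
        logger.warning("covariates absent from file: %s", absent)
    out = df[[cols["sample_id"]] + [cols[name] for name in recognized]].copy()
    out.columns = ["sample_id"] + recognized
    out = out.set_index("sample_id")
    out.index = out.index.astype(str)
    out = out.astype(float)
    return CovariateTable(out)


def write_covariates(table: CovariateTable, path) -> None:
    table.data.rename_axis("sample_id").to_csv(path)


def stratum_of_age(age: float) -> int:
    for label, (lo, hi) in AGE_STRATA.items():
        if lo <= age < hi:
            return label
    raise ValueError(f"age {age} outside the studied range (>= 40 years)")


def stratify_by_age(profiles: ProfileSet) -> dict[int, ProfileSet]:
    """Partition samples into the three age strata [40,50), [50,60), [60,∞).

    Every sample lands in exactly one stratum; ages below 40 or missing raise.
    """
    bad = profiles.sample_id[~np.isfinite(profiles.age) | (profiles.age < 40)]
    if len(bad):
        raise ValueError(f"samples with missing or <40 age: {list(bad)}")
    labels = np.array([stratum_of_age(a) for a in profiles.age])
    return {s: profiles.subset(labels == s) for s in AGE_STRATA}


def read_supplementary_profiles(path, grid: AngularGrid | None = None):
    """Read a deposited normalized-curves table (one row per eye, 180 angular
    columns plus a cluster id column) as used for conformance checks.

    Returns ``(ProfileSet, cluster_ids)``.  Accepts either the package's own
    dialect plus a ``cluster`` column, or a bare matrix whose last column is
    the cluster id.
    """
    if grid is None:
        grid = AngularGrid()
    df = pd.read_csv(path)
    cluster_col = next(
        (c for c in df.columns if c.strip().lower() in {"cluster", "cluster_id"}),
        None,
    )
    if cluster_col is None:
        raise ProfileFormatError("no cluster id column found")
    clusters = df[cluster_col].to_numpy()
    angular = [c for c in df.columns if _angle_from_header(c) is not None]
    if len(angular) != grid.n_points:
        raise ProfileFormatError(
            f"expected {grid.n_points} angular columns, found {len(angular)}"
        )
    pairs = sorted(
        ((_angle_from_header(c) % 360.0, c) for c in angular), key=lambda t: t[0]
    )
    values = df[[c for _, c in pairs]].to_numpy(dtype=float)
    n = len(df)
    sid = (
        df["sample_id"].astype(str).to_numpy(dtype=object)
        if "sample_id" in df.columns
        else np.array([f"s{i}" for i in range(n)], dtype=object)
    )
    eye = (
        df["eye"].astype(str).to_numpy(dtype=object)
        if "eye" in df.columns
        else np.array(["OD"] * n, dtype=object)
    )
    age = df["age"].to_numpy(dtype=float) if "age" in df.columns else np.full(n, 45.0)
    ps = ProfileSet(grid=grid, values=values, sample_id=sid, eye=eye, age=age,
                    normalized=True)
    return ps, clusters
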