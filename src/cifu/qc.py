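"""Outlier-curve detection and unit-integral normalization.

A curve is an outlier if any of its grid values exceeds

    X_out = max_l mean(X(t_l)) + factor · max_l sd(X(t_l)),

with the maxima taken separately over angles and the default factor 3.5.
Detection is a single pass over the full input set (the threshold is not
recomputed after removals) and operates on the raw grid values, where a
spike artifact is sharpest.  Normalization divides each curve by its
circular integral so curves compare by shape, like circular densities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .basis import curve_stats
from .profiles import ProfileSet


@dataclass
class OutlierReport:
    """Outcome of the threshold rule applied to a curve set."""

    threshold: float
    factor: float
    flagged: np.ndarray        # (n,) bool
    max_value: np.ndarray      # (n,) per-sample max over angles
    sample_id: np.ndarray

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "flagged": self.flagged,
                "max_value": self.max_value,
                "threshold": self.threshold,
            }
        )


def outlier_threshold(profiles: ProfileSet, factor: float = 3.5) -> float:
    """Threshold X_out = max pointwise mean + factor · max pointwise sd."""
    stats = curve_stats(profiles)
    return float(stats.mean_curve.max() + factor * stats.sd_curve.max())


def flag_outliers(profiles: ProfileSet, factor: float = 3.5) -> OutlierReport:
    """Flag curves exceeding the threshold anywhere on the grid (single pass)."""
    thr = outlier_threshold(profiles, factor)
    max_value = profiles.values.max(axis=1)
    return OutlierReport(
        threshold=thr,
        factor=factor,
        flagged=max_value > thr,
        max_value=max_value,
        sample_id=profiles.sample_id.copy(),
    )


def remove_outliers(
    profiles: ProfileSet, factor: float = 3.5
) -> tuple[ProfileSet, OutlierReport]:
    report = flag_outliers(profiles, factor)
    return profiles.subset(~report.flagged), report


def normalize(profiles: ProfileSet) -> ProfileSet:
    """Divide each curve by its circular integral (rectangle rule, Δt = step).

    The result integrates to one around the circle, i.e. behaves like a
    circular probability density; normalizing twice is a no-op.
    """
    integrals = profiles.circular_integrals()
    bad = profiles.sample_id[integrals <= 0]
    if len(bad):
        raise ValueError(f"nonpositive circular integral for samples {list(bad)}")
    return replace(
        profiles, values=profiles.values / integrals[:, None], normalized=True
    )
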