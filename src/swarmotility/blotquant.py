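"""Western-blot band quantification.

Band intensities are normalized lane-by-lane to a loading control
(DnaK), compared across growth conditions as fold-changes with a
two-sample t-test, and chloramphenicol-chase time courses are fitted
for first-order degradation rates by ordinary least squares on the log
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecayCourse",
    "normalize_bands",
    "fold_change",
    "decay_rate",
    "compare_rates",
]


@dataclass
class DecayCourse:
    """Band intensity vs time for one chase replicate.

    ``t`` in minutes, strictly increasing; ``intensity`` strictly
    positive (arbitrary units).  ``loading`` optionally carries the
    same-lane loading-control intensities for normalization.
    """

    replicate_id: int
    t: np.ndarray
    intensity: np.ndarray
    loading: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t.shape != self.intensity.shape:
            raise ValueError("t and intensity must align")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be strictly positive")
        if self.loading is not None:
            self.loading = np.asarray(self.loading, dtype=float)
            if self.loading.shape != self.t.shape:
                raise ValueError("loading must align with t")
            if np.any(self.loading <= 0):
                raise ValueError("loading intensities must be strictly positive")

    def normalized(self) -> np.ndarray:
        """Loading-normalized intensity (identity if no loading lane)."""
        if self.loading is None:
            return self.intensity
        return self.intensity / self.loading


def normalize_bands(
    measurements: pd.DataFrame, reference_condition: str | None = None
) -> pd.DataFrame:
    """Loading-normalize band intensities and scale to a reference condition.

    ``measurements`` needs columns ``condition``, ``target`` and
    ``loading``.  Returns a copy with a ``level`` column
    (target/loading); if ``reference_condition`` is given, levels are
    rescaled so that its mean level is 1.
    """
    for col in ("condition", "target", "loading"):
        if col not in measurements.columns:
            raise ValueError(f"missing required column {col!r}")
    if np.any(measurements["loading"].to_numpy() == 0):
        raise ValueError("loading intensity of zero: cannot normalize")
    out = measurements.copy()
    out["level"] = out["target"] / out["loading"]
    if reference_condition is not None:
        ref = out.loc[out["condition"] == reference_condition, "level"]
        if ref.empty:
            raise ValueError(f"no rows for reference condition {reference_condition!r}")
        out["level"] = out["level"] / ref.mean()
    return out


def fold_change(numerator: np.ndarray, denominator: np.ndarray) -> dict:
    """Ratio of mean normalized levels between two conditions.

    Returns the fold change (mean of ``numerator`` over mean of
    ``denominator``) and the p-value of a two-sided two-sample t-test on
    the per-replicate levels.  Requires >= 2 replicates per condition.
    """
    a = np.asarray(numerator, dtype=float)
    b = np.asarray(denominator, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per condition")
    ratio = float(a.mean() / b.mean())
    t, p = stats.ttest_ind(a, b)
    return {"fold": ratio, "p_value": float(p), "t_statistic": float(t),
            "n": (int(a.size), int(b.size))}


def decay_rate(course: DecayCourse, t_max: float | None = None) -> dict:
    """First-order degradation rate from a chase time course.

    Fits ln(normalized intensity) vs t (minutes) by OLS; the rate is the
    negated slope, in min⁻¹.  ``t_max`` optionally truncates the fit
    window (default: all time points).
    """
    y = course.normalized()
    t = course.t
    if t_max is not None:
        keep = t <= t_max
        t, y = t[keep], y[keep]
    if t.size < 3:
        raise ValueError("need >= 3 time points to fit a rate")
    res = stats.linregress(t, np.log(y))
    return {
        "rate_per_min": -float(res.slope),
        "rate_stderr": float(res.stderr),
        "log_intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "n_points": int(t.size),
        "replicate_id": course.replicate_id,
    }


def compare_rates(rates_a: np.ndarray, rates_b: np.ndarray) -> dict:
    """Two-sample t-test on per-replicate degradation rates."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicate rates per condition")
    t, p = stats.ttest_ind(a, b)
    return {
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
        "t_statistic": float(t),
        "p_value": float(p),
    }
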