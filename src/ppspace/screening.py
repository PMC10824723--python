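"""Participant screening by linear RT-vs-distance fits.

Multisensory facilitation predicts that tactile RTs rise as the irrelevant
looming stimulus is farther away at vibration onset.  Each participant's
baseline data are summarized as per-distance mean RTs and fit with an
ordinary least-squares line; across the cohort, goodness of fit (R^2)
correlates positively with slope, and participants in the flat/noisy corner
(R^2 < 0.1 and slope < 0.005 s/m, strict conjunction) are excluded from all
conditions.  The thresholds are fixed cut-offs, not a clustering algorithm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data import TrialRecord
from .exceptions import UndefinedFitError
from .preprocess import pool_central

#: Exclusion thresholds: poor linear fit AND flat slope.
R2_MAX = 0.1
SLOPE_MAX = 0.005  # s/m


@dataclass(frozen=True)
class LinearFit:
    """OLS summary of one participant's RT-distance relation.

    ``slope`` is the coefficient multiplying distance (s/m), ``intercept`` the
    RT offset (s); ``r_squared`` is clipped into [0, 1] against tiny negative
    numerical values.
    """

    participant_id: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int = 0


@dataclass
class ScreeningResult:
    fits: list
    pearson_r: Optional[float]
    included_ids: list
    excluded_ids: list
    r2_max: float = R2_MAX
    slope_max: float = SLOPE_MAX
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "included_ids": list(self.included_ids),
            "excluded_ids": list(self.excluded_ids),
            "r2_max": self.r2_max,
            "slope_max": self.slope_max,
            "fits": [
                {
                    "participant_id": f.participant_id,
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "r_squared": f.r_squared,
                }
                for f in self.fits
            ],
            "warnings": list(self.warnings),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def distance_means(trials: Sequence[TrialRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Per-distance mean RT of the given (already filtered, pooled) trials."""
    by_distance: dict[float, list[float]] = {}
    for t in trials:
        by_distance.setdefault(t.distance_m, []).append(t.rt_s)
    dists = np.array(sorted(by_distance), dtype=float)
    means = np.array([np.mean(by_distance[d]) for d in dists])
    return dists, means


def fit_linear(
    participant_trials: Sequence[TrialRecord], trial_level: bool = False
) -> LinearFit:
    """OLS of RT against distance for one participant in one condition.

    By default the fit uses the per-distance mean RTs (five points for the
    standard design); ``trial_level=True`` regresses the individual trials
    instead.  Data with constant RT get slope 0 and R^2 defined as 0.
    """
    if not participant_trials:
        raise UndefinedFitError("no trials to fit")
    pid = participant_trials[0].participant_id
    if trial_level:
        x = np.array([t.distance_m for t in participant_trials], dtype=float)
        y = np.array([t.rt_s for t in participant_trials], dtype=float)
    else:
        x, y = distance_means(participant_trials)
    if len(np.unique(x)) < 2:
        raise UndefinedFitError(
            f"participant {pid}: need >= 2 distinct distances, got {len(np.unique(x))}"
        )
    if np.ptp(y) == 0.0:
        return LinearFit(pid, 0.0, float(y[0]), 0.0, n_points=len(x))
    res = stats.linregress(x, y)
    r2 = float(np.clip(res.rvalue**2, 0.0, 1.0))
    return LinearFit(pid, float(res.slope), float(res.intercept), r2, n_points=len(x))


def fit_cohort(
    trials: Sequence[TrialRecord],
    condition: str = "baseline",
    trial_level: bool = False,
) -> list[LinearFit]:
    """Per-participant screening fits on central-pooled trials of one
    condition (the baseline, in the standard workflow)."""
    by_pid: dict[str, list[TrialRecord]] = {}
    for t in pool_central(trials):
        if t.condition == condition:
            by_pid.setdefault(t.participant_id, []).append(t)
    return [fit_linear(ts, trial_level=trial_level) for ts in by_pid.values()]


def screen_cohort(
    fits: Sequence[LinearFit],
    r2_max: float = R2_MAX,
    slope_max: float = SLOPE_MAX,
) -> ScreeningResult:
    """Apply the exclusion rule and the cohort-level R^2-slope correlation.

    A participant is excluded iff ``r_squared < r2_max`` and
    ``slope < slope_max`` (both strict).  Pearson's r is computed over all
    screened participants, before exclusion; with fewer than 3 fits or zero
    variance in either variable it is undefined and reported as None, but the
    exclusion rule is still applied.
    """
    fits = list(fits)
    result = ScreeningResult(
        fits=fits,
        pearson_r=None,
        included_ids=[],
        excluded_ids=[],
        r2_max=r2_max,
        slope_max=slope_max,
    )
    r2 = np.array([f.r_squared for f in fits])
    slope = np.array([f.slope for f in fits])
    if len(fits) < 3 or np.ptp(r2) == 0.0 or np.ptp(slope) == 0.0:
        result.warnings.append(
            "pearson_r undefined (need >= 3 fits with variance in R^2 and slope)"
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result.pearson_r = float(stats.pearsonr(r2, slope).statistic)
    for f in fits:
        excluded = f.r_squared < r2_max and f.slope < slope_max
        (result.excluded_ids if excluded else result.included_ids).append(
            f.participant_id
        )
    return result
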