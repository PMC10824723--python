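"""Balanced bootstrap of the PPS boundary and condition comparisons.

Each bootstrap iteration resamples trials with replacement *within each
distance stratum*, drawing the same quota round(total / n_distances) from
every stratum so no resampled dataset is unbalanced across distances while
the total matches the original dataset size (up to rounding).  Each resampled
dataset is rebuilt into a profile, re-normalized, and re-fit with the
anchored sigmoid; the 12,000 x_c estimates form the condition's bootstrap
distribution.

Two conditions are compared by pairing iterations by index and computing the
two-sided sign-test estimate p = 2 * min(P(d <= 0), P(d >= 0)) on the paired
differences; a Studentized (bootstrap-t style) variant is available behind
``method="t"``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .data import TrialRecord
from .exceptions import PPSError
from .fitting import B_BOUNDS, XC_BOUNDS, RTProfile, fit_logistic_batch, fit_sigmoid

logger = logging.getLogger(__name__)

DEFAULT_ITERATIONS = 12_000

RngLike = Union[int, np.random.Generator, np.random.SeedSequence]


@dataclass
class BootstrapDistribution:
    """Bootstrap x_c estimates for one condition.

    ``xc_samples`` holds one boundary estimate per *usable* iteration:
    ``len(xc_samples) == n_iterations - n_failed_fits``.  Failed fits are
    recorded, never imputed.
    """

    condition: str
    xc_samples: np.ndarray
    n_iterations: int
    per_distance_resample_n: dict
    seed: Optional[int]
    n_failed_fits: int = 0
    warnings: list = field(default_factory=list)

    def summary(self) -> dict:
        s = np.asarray(self.xc_samples, dtype=float)
        if s.size == 0:
            return {"n": 0}
        lo, hi = np.percentile(s, [2.5, 97.5])
        return {
            "n": int(s.size),
            "mean_m": float(s.mean()),
            "sd_m": float(s.std(ddof=1)) if s.size > 1 else 0.0,
            "ci95_m": [float(lo), float(hi)],
            "n_failed_fits": int(self.n_failed_fits),
        }

    def to_csv(self, path) -> None:
        """Persist the sample vector as a single-column CSV."""
        np.savetxt(path, np.asarray(self.xc_samples), header="xc_m", comments="")


@dataclass(frozen=True)
class ComparisonResult:
    """Paired bootstrap comparison of two conditions' boundary estimates."""

    condition_a: str
    condition_b: str
    delta_mean_m: float
    p_value: float
    n_pairs: int
    method: str = "sign"

    @property
    def p_display(self) -> str:
        if self.p_value == 0.0 and self.n_pairs > 0:
            return f"p < {1.0 / self.n_pairs:.2g}"
        return f"p = {self.p_value:.3g}"

    def to_dict(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "delta_mean_m": self.delta_mean_m,
            "p_value": self.p_value,
            "p_display": self.p_display,
            "n_pairs": self.n_pairs,
            "method": self.method,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _strata(
    trials: Sequence[TrialRecord], distances: Optional[Sequence[float]] = None
) -> tuple[tuple[float, ...], list[np.ndarray], list[list[TrialRecord]]]:
    groups: dict[float, list[TrialRecord]] = {}
    for t in trials:
        groups.setdefault(t.distance_m, []).append(t)
    if distances is None:
        distances = sorted(groups)
    distances = tuple(float(d) for d in distances)
    for d in distances:
        if not groups.get(d):
            raise PPSError(f"empty distance stratum at {d} m: cannot resample")
    lists = [groups[d] for d in distances]
    rts = [np.array([t.rt_s for t in g], dtype=float) for g in lists]
    return distances, rts, lists


def stratum_quota(n_total: int, n_distances: int) -> int:
    """Per-distance resample count: round(total / n_distances)."""
    q = int(round(n_total / n_distances))
    if q < 1:
        raise PPSError("not enough trials for a balanced resample")
    return q


def balanced_resample(
    trials: Sequence[TrialRecord],
    seed: RngLike,
    distances: Optional[Sequence[float]] = None,
) -> list[TrialRecord]:
    """One balanced resample with replacement of a condition's trials.

    Every distance stratum contributes exactly the quota, drawn only within
    that stratum (a singleton stratum is repeated quota times); strata are
    visited in increasing distance order, so the draw is deterministic under
    ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dists, _, lists = _strata(trials, distances)
    quota = stratum_quota(len(trials), len(dists))
    out: list[TrialRecord] = []
    for group in lists:
        idx = rng.integers(0, len(group), size=quota)
        out.extend(group[i] for i in idx)
    return out


def bootstrap_xc(
    trials: Sequence[TrialRecord],
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    distances: Optional[Sequence[float]] = None,
    xc_bounds: tuple[float, float] = XC_BOUNDS,
    b_bounds: tuple[float, float] = B_BOUNDS,
    engine: str = "batch",
    condition: Optional[str] = None,
) -> BootstrapDistribution:
    """Bootstrap distribution of the PPS boundary for one condition.

    Per iteration: balanced resample -> per-distance means -> min-max
    normalization -> anchored sigmoid fit -> record x_c.  Iteration draws use
    per-iteration child seeds spawned from the master ``seed``; the fits are
    solved by the vectorized batch solver (``engine="scalar"`` loops
    :func:`ppspace.fitting.fit_sigmoid` over the same profiles instead).
    Degenerate resamples (all five means equal) and non-converged fits are
    counted in ``n_failed_fits`` and skipped.
    """
    if engine not in ("batch", "scalar"):
        raise PPSError(f"unknown engine {engine!r}")
    dists, rts, _ = _strata(trials, distances)
    quota = stratum_quota(len(trials), len(dists))
    cond = condition or trials[0].condition
    x = np.array(dists)

    children = np.random.SeedSequence(seed).spawn(n_iterations)
    profiles = np.empty((n_iterations, len(dists)))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        for j, cell in enumerate(rts):
            idx = rng.integers(0, cell.size, size=quota)
            profiles[i, j] = cell[idx].mean()

    span = profiles.max(axis=1) - profiles.min(axis=1)
    usable = span > 0.0
    Z = np.empty_like(profiles)
    Z[usable] = (
        profiles[usable] - profiles[usable].min(axis=1, keepdims=True)
    ) / span[usable, None]

    if engine == "batch":
        xc_all, _, _, conv = fit_logistic_batch(
            x, Z[usable], xc_bounds=xc_bounds, b_bounds=b_bounds
        )
    else:
        xc_list, conv_list = [], []
        for z in Z[usable]:
            prof = RTProfile(
                condition=cond,
                distances_m=tuple(x),
                mean_rt_s=tuple(z),  # already normalized; raw scale irrelevant
                n_per_distance=(quota,) * len(dists),
                normalized=tuple(z),
            )
            fit = fit_sigmoid(prof, xc_bounds=xc_bounds, b_bounds=b_bounds)
            xc_list.append(fit.xc_m)
            conv_list.append(fit.converged)
        xc_all = np.array(xc_list)
        conv = np.array(conv_list, dtype=bool)

    samples = xc_all[conv]
    n_failed = n_iterations - int(samples.size)
    dist = BootstrapDistribution(
        condition=cond,
        xc_samples=samples,
        n_iterations=n_iterations,
        per_distance_resample_n={float(d): quota for d in dists},
        seed=seed if isinstance(seed, int) else None,
        n_failed_fits=n_failed,
    )
    if n_failed > 0.10 * n_iterations:
        msg = (
            f"condition {cond!r}: {n_failed}/{n_iterations} bootstrap fits "
            "failed; distribution may be unreliable"
        )
        dist.warnings.append(msg)
        logger.warning(msg)
    return dist


def compare_conditions(
    dist_a: BootstrapDistribution,
    dist_b: BootstrapDistribution,
    method: str = "sign",
) -> ComparisonResult:
    """Two-sided comparison of paired bootstrap boundary estimates.

    Iterations are paired by index (conditions are resampled independently,
    so the pairing is a deterministic convention, not a dependence claim);
    unequal usable counts are truncated to the shorter with a warning.
    ``method="sign"`` (default) is the bootstrap sign test
    p = 2 * min(P(d <= 0), P(d >= 0)) clipped to [0, 1]; ``method="t"`` is a
    Studentized normal-approximation variant on the paired differences.
    """
    a = np.asarray(dist_a.xc_samples, dtype=float)
    b = np.asarray(dist_b.xc_samples, dtype=float)
    n = min(a.size, b.size)
    if n == 0:
        raise PPSError("cannot compare empty bootstrap distributions")
    if a.size != b.size:
        logger.warning(
            "unequal usable iteration counts (%d vs %d); truncating to %d",
            a.size,
            b.size,
            n,
        )
    d = b[:n] - a[:n]
    delta_mean = float(d.mean())
    if method == "sign":
        p = 2.0 * min(float(np.mean(d <= 0.0)), float(np.mean(d >= 0.0)))
    elif method == "t":
        sd = float(d.std(ddof=1))
        if sd == 0.0:
            p = 1.0 if delta_mean == 0.0 else 0.0
        else:
            from scipy import stats

            p = 2.0 * float(stats.norm.sf(abs(delta_mean) / sd))
    else:
        raise PPSError(f"unknown method {method!r}")
    return ComparisonResult(
        condition_a=dist_a.condition,
        condition_b=dist_b.condition,
        delta_mean_m=delta_mean,
        p_value=float(np.clip(p, 0.0, 1.0)),
        n_pairs=int(n),
        method=method,
    )
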