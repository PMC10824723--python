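"""Group-level RT profiles and the anchored sigmoid boundary fit.

The group profile is the mean RT per distance over the pooled central trials
of all included participants (trial-level pooling: participants with more
surviving trials weigh more).  Profiles are min-max normalized to [0, 1] and
fit with the logistic

    y(x) = (y_min + y_max * exp((x - x_c) / b)) / (1 + exp((x - x_c) / b)),

with the asymptotes anchored at y_min = 0, y_max = 1 so the only free
parameters are the inflection point ``x_c`` — the operational peripersonal
space boundary, constrained to the measured distance range [0.25, 2.25] m —
and the transition width ``b > 0``.  With the asymptotes anchored this is the
standard logistic 1 / (1 + exp(-(x - x_c)/b)), and the point of maximum slope
coincides with x_c.

Two solvers are provided: :func:`fit_sigmoid`, a bounded multi-start
``scipy.optimize.least_squares`` fit for single profiles, and
:func:`fit_logistic_batch`, a vectorized grid-search + projected Gauss-Newton
solver for the thousands of five-point fits a bootstrap run needs.  A test
pins the two to each other.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .data import TrialRecord
from .exceptions import DegenerateProfileError, EmptyCellError, PPSError

XC_BOUNDS = (0.25, 2.25)  # m; shortest and longest stimulus distance
B_BOUNDS = (0.01, 5.0)  # m; lower bound prevents collapse to a step
_B_START = 0.3  # m


@dataclass(frozen=True)
class RTProfile:
    """Per-condition RT-distance profile (raw means and normalized values)."""

    condition: str
    distances_m: tuple
    mean_rt_s: tuple
    n_per_distance: tuple
    normalized: Optional[tuple] = None


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted anchored logistic; ``xc_m`` is the PPS boundary in meters."""

    xc_m: float
    width_b_m: float
    y_min: float
    y_max: float
    rss: float
    converged: bool
    xc_bounds: tuple = XC_BOUNDS
    b_bounds: tuple = B_BOUNDS
    n_points: int = 5

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        s = expit((x - self.xc_m) / self.width_b_m)
        return self.y_min + (self.y_max - self.y_min) * s

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def logistic(x, xc: float, b: float) -> np.ndarray:
    """Anchored (0-1) logistic with inflection ``xc`` and width ``b``."""
    return expit((np.asarray(x, dtype=float) - xc) / b)


def build_profile(
    trials: Sequence[TrialRecord],
    condition: Optional[str] = None,
    distances: Optional[Sequence[float]] = None,
    participant_mean: bool = False,
) -> RTProfile:
    """Mean RT per distance over pooled trials.

    ``trials`` are expected to be filtered, central-pooled test trials of the
    included participants; ``condition`` optionally sub-selects.  The default
    pools at the trial level (unequal trial counts weigh participants
    unequally); ``participant_mean=True`` averages per-participant means
    instead.  An empty distance cell raises :class:`EmptyCellError` naming it.
    """
    subset = [t for t in trials if condition is None or t.condition == condition]
    if not subset:
        raise EmptyCellError(f"no trials for condition {condition!r}")
    cond = condition if condition is not None else subset[0].condition
    if distances is None:
        distances = sorted({t.distance_m for t in subset})
    distances = tuple(float(d) for d in distances)

    means, counts = [], []
    for d in distances:
        cell = [t for t in subset if t.distance_m == d]
        if not cell:
            raise EmptyCellError(f"condition {cond!r}: no trials at {d} m")
        counts.append(len(cell))
        if participant_mean:
            by_pid: dict[str, list[float]] = {}
            for t in cell:
                by_pid.setdefault(t.participant_id, []).append(t.rt_s)
            means.append(float(np.mean([np.mean(v) for v in by_pid.values()])))
        else:
            means.append(float(np.mean([t.rt_s for t in cell])))
    return RTProfile(
        condition=cond,
        distances_m=distances,
        mean_rt_s=tuple(means),
        n_per_distance=tuple(counts),
    )


def normalize_profile(profile: RTProfile) -> RTProfile:
    """Min-max normalize the profile's means to [0, 1].

    z_i = (m_i - min(m)) / (max(m) - min(m)); the raw means are retained
    alongside.  All-equal means leave the normalization undefined and raise
    :class:`DegenerateProfileError`.  Idempotent on already-normalized
    values.
    """
    m = np.asarray(profile.mean_rt_s, dtype=float)
    if len(m) < 2 or np.ptp(m) == 0.0:
        raise DegenerateProfileError(
            f"condition {profile.condition!r}: all means equal; cannot normalize"
        )
    z = (m - m.min()) / (m.max() - m.min())
    return dataclasses.replace(profile, normalized=tuple(float(v) for v in z))


def fit_sigmoid(
    profile: RTProfile,
    xc_bounds: tuple[float, float] = XC_BOUNDS,
    b_bounds: tuple[float, float] = B_BOUNDS,
    anchor: bool = True,
) -> SigmoidFit:
    """Bounded nonlinear least squares of the normalized profile.

    Multi-start over the design distances as initial x_c values (width start
    0.3 m); the best-RSS solution wins, ties broken by smallest x_c.  With
    ``anchor=False`` the asymptotes are additionally free in [0, 1].  If every
    start fails, a fit with ``converged=False`` is returned and the caller
    decides.
    """
    if profile.normalized is None:
        raise PPSError("profile must be normalized before fitting")
    x = np.asarray(profile.distances_m, dtype=float)
    z = np.asarray(profile.normalized, dtype=float)

    if anchor:

        def resid(p):
            return logistic(x, p[0], p[1]) - z

        lo = [xc_bounds[0], b_bounds[0]]
        hi = [xc_bounds[1], b_bounds[1]]
    else:

        def resid(p):
            return p[2] + (p[3] - p[2]) * logistic(x, p[0], p[1]) - z

        lo = [xc_bounds[0], b_bounds[0], 0.0, 0.0]
        hi = [xc_bounds[1], b_bounds[1], 1.0, 1.0]

    candidates = []
    for xc0 in np.clip(x, xc_bounds[0], xc_bounds[1]):
        p0 = [float(xc0), _B_START] + ([] if anchor else [0.0, 1.0])
        try:
            res = least_squares(resid, p0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # pragma: no cover - optimizer blow-up
            continue
        if res.status > 0:
            candidates.append(res)
    if not candidates:
        return SigmoidFit(
            xc_m=float(np.clip(np.median(x), *xc_bounds)),
            width_b_m=_B_START,
            y_min=0.0 if anchor else float("nan"),
            y_max=1.0 if anchor else float("nan"),
            rss=float("inf"),
            converged=False,
            xc_bounds=tuple(xc_bounds),
            b_bounds=tuple(b_bounds),
            n_points=len(x),
        )
    # Ties in RSS (to within numerical noise) break toward the smallest x_c.
    best = min(candidates, key=lambda r: (round(2 * r.cost, 12), r.x[0]))
    p = best.x
    return SigmoidFit(
        xc_m=float(p[0]),
        width_b_m=float(p[1]),
        y_min=0.0 if anchor else float(p[2]),
        y_max=1.0 if anchor else float(p[3]),
        rss=float(2 * best.cost),
        converged=True,
        xc_bounds=tuple(xc_bounds),
        b_bounds=tuple(b_bounds),
        n_points=len(x),
    )


# ---------------------------------------------------------------------------
# Vectorized batch solver for bootstrap-scale workloads
# ---------------------------------------------------------------------------

def _grid(xc_bounds, b_bounds, n_xc=61, n_b=25):
    xc = np.linspace(xc_bounds[0], xc_bounds[1], n_xc)
    b = np.geomspace(b_bounds[0], b_bounds[1], n_b)
    XC, B = np.meshgrid(xc, b, indexing="ij")
    return XC.ravel(), B.ravel()


def fit_logistic_batch(
    x: np.ndarray,
    Z: np.ndarray,
    xc_bounds: tuple[float, float] = XC_BOUNDS,
    b_bounds: tuple[float, float] = B_BOUNDS,
    n_steps: int = 60,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares anchored-logistic fits for many profiles at once.

    ``Z`` is (n_profiles, n_points); returns arrays (xc, b, rss, converged).
    A coarse (x_c, log b) grid seeds a damped, bound-projected Gauss-Newton
    refinement, all vectorized across profiles; if refinement ever worsens a
    profile's RSS the grid solution is kept.  Agreement with
    :func:`fit_sigmoid` on identical profiles is part of the test suite.
    """
    x = np.asarray(x, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n = Z.shape[0]

    xc_g, b_g = _grid(xc_bounds, b_bounds)
    M = expit((x[None, :] - xc_g[:, None]) / b_g[:, None])  # (G, k)
    rss_grid = (
        (Z**2).sum(axis=1)[:, None] - 2.0 * Z @ M.T + (M**2).sum(axis=1)[None, :]
    )
    best = np.argmin(rss_grid, axis=1)
    xc = xc_g[best].copy()
    b = b_g[best].copy()

    def rss_of(xc_v, b_v):
        s = expit((x[None, :] - xc_v[:, None]) / b_v[:, None])
        return ((s - Z) ** 2).sum(axis=1)

    rss = rss_of(xc, b)
    lam = np.full(n, 1e-6)
    for _ in range(n_steps):
        s = expit((x[None, :] - xc[:, None]) / b[:, None])
        r = s - Z
        w = s * (1.0 - s)
        J_xc = -w / b[:, None]
        J_b = -w * (x[None, :] - xc[:, None]) / (b**2)[:, None]
        # 2x2 normal equations with Levenberg damping, solved in closed form.
        a11 = (J_xc * J_xc).sum(axis=1) + lam
        a12 = (J_xc * J_b).sum(axis=1)
        a22 = (J_b * J_b).sum(axis=1) + lam
        g1 = (J_xc * r).sum(axis=1)
        g2 = (J_b * r).sum(axis=1)
        det = a11 * a22 - a12 * a12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        d_xc = -(a22 * g1 - a12 * g2) / det
        d_b = -(a11 * g2 - a12 * g1) / det
        new_xc = np.clip(xc + d_xc, xc_bounds[0], xc_bounds[1])
        new_b = np.clip(b + d_b, b_bounds[0], b_bounds[1])
        new_rss = rss_of(new_xc, new_b)
        improved = new_rss <= rss + 1e-15
        xc = np.where(improved, new_xc, xc)
        b = np.where(improved, new_b, b)
        rss = np.where(improved, new_rss, rss)
        lam = np.where(improved, np.maximum(lam * 0.5, 1e-9), lam * 4.0)

    # Convergence check: projected gradient approximately zero.
    s = expit((x[None, :] - xc[:, None]) / b[:, None])
    r = s - Z
    w = s * (1.0 - s)
    g1 = (-w / b[:, None] * r).sum(axis=1)
    g2 = (-w * (x[None, :] - xc[:, None]) / (b**2)[:, None] * r).sum(axis=1)
    at_lo_xc = xc <= xc_bounds[0] + 1e-12
    at_hi_xc = xc >= xc_bounds[1] - 1e-12
    at_lo_b = b <= b_bounds[0] + 1e-12
    at_hi_b = b >= b_bounds[1] - 1e-12
    pg1 = np.where(at_lo_xc & (g1 > 0) | at_hi_xc & (g1 < 0), 0.0, g1)
    pg2 = np.where(at_lo_b & (g2 > 0) | at_hi_b & (g2 < 0), 0.0, g2)
    converged = np.hypot(pg1, pg2) < 1e-6
    return xc, b, rss, converged
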