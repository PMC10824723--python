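"""Synthetic visuo-tactile RT experiments.

The generator emulates the statistical structure the downstream analysis
assumes: mean reaction time rises with stimulus distance following a logistic
curve between a near-space floor (~0.25 s) and a far-space ceiling (~0.31 s),
with the inflection point ``true_xc_m`` playing the role of the generative
peripersonal-space boundary.  A participant's trial RT is that mean plus
truncated-at-zero Gaussian noise.  "Non-responder" participants — the flat,
poorly fit cluster that the screening stage exists to exclude — have a
distance-independent mean.  Missed and premature responses occur at small
per-trial rates so the preprocessing filters have something to remove, and
catch trials (tactile-only / visual-only) are emitted with the design's
counts.

Everything is deterministic under a seed: the same seed yields bit-identical
trial collections.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.special import expit

from .data import CONDITIONS, ExperimentDesign, TrialRecord
from .exceptions import PPSError

RngLike = Union[int, np.random.Generator, np.random.SeedSequence]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative model of one participant.

    ``rt_floor_s``/``rt_ceiling_s`` are the asymptotic mean RTs in near and
    far space; ``true_xc_m`` and ``width_m`` are the location and width of the
    logistic transition between them.  When ``responder`` is False the mean RT
    is flat (floor == ceiling) and the transition parameters are ignored.
    """

    rt_floor_s: float = 0.25
    rt_ceiling_s: float = 0.31
    true_xc_m: float = 1.26
    width_m: float = 0.30
    noise_sd_s: float = 0.05
    lapse_rate: float = 0.002
    premature_rate: float = 0.002
    responder: bool = True

    def __post_init__(self) -> None:
        if self.responder and not self.rt_floor_s < self.rt_ceiling_s:
            raise PPSError("responder profile needs rt_floor_s < rt_ceiling_s")
        if not self.responder and self.rt_floor_s != self.rt_ceiling_s:
            raise PPSError("non-responder profile needs equal floor and ceiling")
        if self.rt_floor_s <= 0:
            raise PPSError("rt_floor_s must be positive")
        for name in ("lapse_rate", "premature_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise PPSError(f"{name} must lie in [0, 1)")
        if self.lapse_rate + self.premature_rate >= 1.0:
            raise PPSError("lapse_rate + premature_rate must be < 1")
        if self.noise_sd_s < 0:
            raise PPSError("noise_sd_s must be non-negative")
        if self.responder and self.width_m <= 0:
            raise PPSError("width_m must be positive")

    def mean_rt(self, distance_m) -> np.ndarray:
        """Generative mean RT (s) at the given distance(s)."""
        distance_m = np.asarray(distance_m, dtype=float)
        if not self.responder:
            return np.full_like(distance_m, self.rt_floor_s)
        span = self.rt_ceiling_s - self.rt_floor_s
        return self.rt_floor_s + span * expit(
            (distance_m - self.true_xc_m) / self.width_m
        )


@dataclass(frozen=True)
class CohortSpec:
    """Population-level distributions from which participant profiles are drawn.

    Responders receive a logistic RT-distance profile with participant-level
    variation in boundary location, width, floor and floor-to-ceiling range;
    non-responders are flat at ``nonresponder_rt_s`` with the same trial
    noise.  Draws are clipped to keep every profile valid (width and range
    strictly positive, boundary inside the distance range).
    """

    n_responders: int
    n_nonresponders: int = 0
    seed: int = 0
    xc_mean_m: float = 1.26
    xc_sd_m: float = 0.10
    width_mean_m: float = 0.30
    width_sd_m: float = 0.05
    rt_floor_mean_s: float = 0.25
    rt_floor_sd_s: float = 0.015
    rt_range_mean_s: float = 0.06
    rt_range_sd_s: float = 0.01
    noise_sd_s: float = 0.05
    lapse_rate: float = 0.002
    premature_rate: float = 0.002
    nonresponder_rt_s: float = 0.28

    def __post_init__(self) -> None:
        if self.n_responders < 0 or self.n_nonresponders < 0:
            raise PPSError("participant counts must be non-negative")
        if self.n_responders + self.n_nonresponders == 0:
            raise PPSError("cohort needs at least one participant")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "CohortSpec":
        return cls(**dict(mapping))

    def draw_profiles(
        self, design: ExperimentDesign
    ) -> list[tuple[str, ParticipantProfile]]:
        """Draw the cohort's (participant_id, profile) pairs; deterministic
        under ``seed``.  Responder ids are R01.., non-responders N01.."""
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0xC0]))
        lo, hi = design.distances_m[0], design.distances_m[-1]
        out: list[tuple[str, ParticipantProfile]] = []
        for i in range(self.n_responders):
            xc = float(np.clip(rng.normal(self.xc_mean_m, self.xc_sd_m), lo, hi))
            width = float(max(rng.normal(self.width_mean_m, self.width_sd_m), 0.05))
            floor = float(max(rng.normal(self.rt_floor_mean_s, self.rt_floor_sd_s), 0.05))
            span = float(max(rng.normal(self.rt_range_mean_s, self.rt_range_sd_s), 0.01))
            out.append(
                (
                    f"R{i + 1:02d}",
                    ParticipantProfile(
                        rt_floor_s=floor,
                        rt_ceiling_s=floor + span,
                        true_xc_m=xc,
                        width_m=width,
                        noise_sd_s=self.noise_sd_s,
                        lapse_rate=self.lapse_rate,
                        premature_rate=self.premature_rate,
                        responder=True,
                    ),
                )
            )
        for i in range(self.n_nonresponders):
            out.append(
                (
                    f"N{i + 1:02d}",
                    ParticipantProfile(
                        rt_floor_s=self.nonresponder_rt_s,
                        rt_ceiling_s=self.nonresponder_rt_s,
                        true_xc_m=0.5 * (lo + hi),
                        width_m=self.width_mean_m,
                        noise_sd_s=self.noise_sd_s,
                        lapse_rate=self.lapse_rate,
                        premature_rate=self.premature_rate,
                        responder=False,
                    ),
                )
            )
        return out


def launcher_allocation(design: ExperimentDesign) -> tuple[int, int, int]:
    """Deterministic per-distance launcher counts (center, left, right).

    ``round(central_fraction * reps)`` trials launch centrally; the remainder
    is split across the lateral avatars, left taking the odd one.
    """
    reps = design.reps_per_distance
    n_center = int(round(design.central_fraction * reps))
    rem = reps - n_center
    n_left = rem - rem // 2
    return n_center, n_left, rem // 2


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Gaussian draw truncated at zero (redraw; practically never triggers)."""
    if sd == 0.0:
        return mean
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise PPSError("could not draw a positive RT; check profile means/SDs")


def simulate_participant(
    profile: ParticipantProfile,
    design: ExperimentDesign,
    condition: str,
    seed: RngLike,
    participant_id: str = "P01",
    experiment: str = "exp1",
) -> list[TrialRecord]:
    """Simulate one participant's measurement block for one condition.

    Emits exactly ``reps_per_distance`` test trials per distance with the
    deterministic launcher allocation, plus ``n_catch_per_type`` trials of
    each catch type.  Lapses become ``missed`` records and anticipations
    ``premature`` records, both with RT absent, so preprocessing has explicit
    rows to remove.
    """
    if condition not in CONDITIONS:
        raise PPSError(f"unknown condition {condition!r}")
    rng = _rng(seed)
    n_center, n_left, n_right = launcher_allocation(design)
    trials: list[TrialRecord] = []

    def emit(trial_type: str, launcher, distance, mean: float) -> None:
        u = rng.random()
        if u < profile.premature_rate:
            status, rt = "premature", None
        elif u < profile.premature_rate + profile.lapse_rate:
            status, rt = "missed", None
        else:
            status, rt = "valid", _positive_normal(rng, mean, profile.noise_sd_s)
        trials.append(
            TrialRecord(
                participant_id=participant_id,
                experiment=experiment,
                condition=condition,
                trial_type=trial_type,
                launcher=launcher,
                distance_m=distance,
                rt_s=rt,
                response_status=status,
            )
        )

    for distance in design.distances_m:
        mean = float(profile.mean_rt(distance))
        for launcher, n in (("center", n_center), ("left", n_left), ("right", n_right)):
            for _ in range(n):
                emit("test", launcher, float(distance), mean)
    # Tactile-only: vibration with no looming stimulus, hence no visual
    # facilitation — mean RT sits at the far-space ceiling.
    for _ in range(design.n_catch_per_type):
        emit("tactile_only", None, None, profile.rt_ceiling_s)
    # Visual-only: no vibration; the correct behavior is no response.
    for _ in range(design.n_catch_per_type):
        u = rng.random()
        status = "premature" if u < profile.premature_rate else "valid"
        trials.append(
            TrialRecord(
                participant_id=participant_id,
                experiment=experiment,
                condition=condition,
                trial_type="visual_only",
                launcher="center",
                distance_m=None,
                rt_s=None,
                response_status=status,
            )
        )
    return trials


def simulate_cohort(
    spec: CohortSpec,
    design: ExperimentDesign,
    conditions: Sequence[str],
    effect_map: Optional[Mapping[str, float]] = None,
    experiment: str = "exp1",
) -> list[TrialRecord]:
    """Simulate every participant in every condition.

    ``effect_map`` shifts each responder's generative boundary by a
    condition-specific amount (meters); all other profile fields are shared
    across conditions, so a zero effect map makes conditions differ only by
    sampling noise.  Deterministic under ``spec.seed``.
    """
    if not conditions:
        raise PPSError("conditions must be non-empty")
    effect_map = dict(effect_map or {})
    for cond in conditions:
        if cond not in CONDITIONS:
            raise PPSError(f"unknown condition {cond!r}")
    lo, hi = design.distances_m[0], design.distances_m[-1]
    profiles = spec.draw_profiles(design)
    trials: list[TrialRecord] = []
    for p_idx, (pid, profile) in enumerate(profiles):
        for c_idx, cond in enumerate(conditions):
            shift = float(effect_map.get(cond, 0.0))
            prof = profile
            if shift != 0.0 and profile.responder:
                prof = dataclasses.replace(
                    profile,
                    true_xc_m=float(np.clip(profile.true_xc_m + shift, lo, hi)),
                )
            child = np.random.SeedSequence([int(spec.seed), 1, p_idx, c_idx])
            trials.extend(
                simulate_participant(
                    prof, design, cond, child, participant_id=pid, experiment=experiment
                )
            )
    return trials
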