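"""Trial-level data schema and CSV interchange.

One row of the interchange CSV is one detection trial: a participant responds
(or fails to respond) to a tactile vibration while a task-irrelevant visual
stimulus looms toward them.  On ``test`` trials the vibration is delivered when
the stimulus is at one of a small set of fixed distances; ``tactile_only`` and
``visual_only`` catch trials guard against stereotyped responding and carry no
distance / no vibration respectively.

Reaction times are stored in seconds, distances in meters.  Absent values
(e.g. the RT of a missed response, the distance of a catch trial) are encoded
as empty CSV fields, never as sentinel numbers.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .exceptions import DesignError, SchemaError, TrialValidationError

EXPERIMENTS = ("exp1", "exp2")
CONDITIONS = ("baseline", "push", "pull", "hammer", "gun")
TRIAL_TYPES = ("test", "tactile_only", "visual_only")
LAUNCHERS = ("center", "left", "right")
RESPONSE_STATUSES = ("valid", "missed", "premature")

#: Stable column order of the interchange CSV.
COLUMNS = (
    "participant_id",
    "experiment",
    "condition",
    "trial_type",
    "launcher",
    "distance_m",
    "rt_s",
    "response_status",
)

#: Distance tolerance when matching a trial against the design's distance set.
_DIST_ATOL = 1e-9


@dataclass(frozen=True)
class ExperimentDesign:
    """Parameters of one measurement block of the visuo-tactile task.

    Defaults follow the paradigm this package models: five looming-stimulus
    distances between 0.25 and 2.25 m, 20 repetitions per distance (15 in the
    shorter second experiment), 80% of launches from the central avatar, and
    15 catch trials of each of the two control types.  ``rt_window_s`` and
    ``sd_cutoff`` parameterize the trial-exclusion rules applied by
    :func:`ppspace.preprocess.filter_trials`.
    """

    distances_m: tuple[float, ...] = (0.25, 0.75, 1.25, 1.75, 2.25)
    reps_per_distance: int = 20
    central_fraction: float = 0.8
    n_catch_per_type: int = 15
    rt_window_s: tuple[float, float] = (0.100, 1.000)
    sd_cutoff: float = 3.0

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.distances_m)
        object.__setattr__(self, "distances_m", d)
        if len(d) < 2 or any(x <= 0 for x in d):
            raise DesignError("distances must be positive and at least two")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise DesignError("distances must be strictly increasing")
        if not 0.0 < self.central_fraction < 1.0:
            raise DesignError("central_fraction must lie in (0, 1)")
        if self.reps_per_distance <= 0 or self.n_catch_per_type <= 0:
            raise DesignError("counts must be positive integers")
        lo, hi = self.rt_window_s
        if not 0 <= lo < hi:
            raise DesignError("rt_window_s must satisfy 0 <= lower < upper")
        if self.sd_cutoff <= 0:
            raise DesignError("sd_cutoff must be positive")

    @classmethod
    def exp1(cls, **overrides) -> "ExperimentDesign":
        return cls(**{"reps_per_distance": 20, **overrides})

    @classmethod
    def exp2(cls, **overrides) -> "ExperimentDesign":
        return cls(**{"reps_per_distance": 15, **overrides})

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "ExperimentDesign":
        """Build a design from a config mapping.

        An optional ``experiment`` key selects the exp1/exp2 repetition
        default; all other keys override fields directly.
        """
        mapping = dict(mapping)
        experiment = mapping.pop("experiment", "exp1")
        if experiment not in EXPERIMENTS:
            raise DesignError(f"unknown experiment {experiment!r}")
        base = cls.exp1 if experiment == "exp1" else cls.exp2
        if "distances_m" in mapping:
            mapping["distances_m"] = tuple(mapping["distances_m"])
        if "rt_window_s" in mapping:
            mapping["rt_window_s"] = tuple(mapping["rt_window_s"])
        return base(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentDesign":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    def distance_index(self, distance: float) -> int:
        for i, d in enumerate(self.distances_m):
            if math.isclose(distance, d, rel_tol=0.0, abs_tol=_DIST_ATOL):
                return i
        raise ValueError(f"distance {distance} not in design {self.distances_m}")


@dataclass(frozen=True)
class TrialRecord:
    """A single detection trial.

    ``distance_m`` is the looming stimulus' distance at vibration onset and is
    present only on test trials; ``rt_s`` is the reaction time from vibration
    onset and is absent when the participant missed or anticipated.
    """

    participant_id: str
    experiment: str
    condition: str
    trial_type: str
    launcher: Optional[str]
    distance_m: Optional[float]
    rt_s: Optional[float]
    response_status: str = "valid"

    def validation_errors(self, design: Optional[ExperimentDesign] = None) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        errs: list[str] = []
        if not self.participant_id:
            errs.append("participant_id is empty")
        if self.experiment not in EXPERIMENTS:
            errs.append(f"unknown experiment {self.experiment!r}")
        if self.condition not in CONDITIONS:
            errs.append(f"unknown condition {self.condition!r}")
        if self.trial_type not in TRIAL_TYPES:
            errs.append(f"unknown trial_type {self.trial_type!r}")
        if self.response_status not in RESPONSE_STATUSES:
            errs.append(f"unknown response_status {self.response_status!r}")

        if self.trial_type == "tactile_only":
            if self.launcher is not None:
                errs.append("tactile_only trial must not carry a launcher")
        elif self.launcher is not None and self.launcher not in LAUNCHERS:
            errs.append(f"unknown launcher {self.launcher!r}")
        elif self.launcher is None and self.trial_type == "test":
            errs.append("test trial must carry a launcher")

        if self.trial_type == "test":
            if self.distance_m is None:
                errs.append("test trial must carry distance_m")
            elif design is not None:
                try:
                    design.distance_index(self.distance_m)
                except ValueError:
                    errs.append(
                        f"distance_m={self.distance_m} not in design "
                        f"distances {design.distances_m}"
                    )
        elif self.distance_m is not None:
            errs.append(f"{self.trial_type} trial must not carry distance_m")

        if self.rt_s is not None and not self.rt_s > 0:
            errs.append(f"rt_s must be > 0, got {self.rt_s}")
        if self.response_status in ("missed", "premature") and self.rt_s is not None:
            errs.append(f"{self.response_status} trial must not carry rt_s")
        if self.trial_type == "visual_only" and self.rt_s is not None and (
            self.response_status == "valid"
        ):
            errs.append("visual_only trial has no vibration; a response is premature")
        return errs


def validate_trials(
    trials: Iterable[TrialRecord], design: Optional[ExperimentDesign] = None
) -> None:
    """Validate a collection; raise :class:`TrialValidationError` listing every
    offending row (1-based, in iteration order).  Never mutates the input."""
    bad = []
    for i, t in enumerate(trials, start=1):
        for msg in t.validation_errors(design):
            bad.append((i, msg))
    if bad:
        raise TrialValidationError(bad)


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Represent trials as a DataFrame with the stable interchange columns."""
    return pd.DataFrame(
        [dataclasses.asdict(t) for t in trials], columns=list(COLUMNS)
    )


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    def _opt_str(v):
        return None if v is None or (isinstance(v, float) and math.isnan(v)) or v == "" else str(v)

    def _opt_float(v):
        if v is None or v == "":
            return None
        v = float(v)
        return None if math.isnan(v) else v

    out = []
    for row in df.itertuples(index=False):
        out.append(
            TrialRecord(
                participant_id=str(row.participant_id),
                experiment=str(row.experiment),
                condition=str(row.condition),
                trial_type=str(row.trial_type),
                launcher=_opt_str(row.launcher),
                distance_m=_opt_float(row.distance_m),
                rt_s=_opt_float(row.rt_s),
                response_status=str(row.response_status),
            )
        )
    return out


def write_trials(trials: Sequence[TrialRecord], path) -> None:
    """Write trials as UTF-8 CSV with the stable column order.

    Absent fields become empty strings.  RTs survive a round trip to well
    below 1 ns (`repr`-precision floats).
    """
    validate_trials(trials)
    df = trials_to_frame(trials)
    df.to_csv(path, index=False, float_format="%.12g", na_rep="")


def read_trials(path, design: Optional[ExperimentDesign] = None) -> list[TrialRecord]:
    """Read a trial CSV, validating every row.

    Raises :class:`SchemaError` when columns are missing and
    :class:`TrialValidationError` (with 1-based data-row numbers) when rows
    violate the record invariants — e.g. a test-trial distance outside
    ``design.distances_m``.  Invalid rows are reported, never silently
    dropped.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={
            "participant_id": str,
            "experiment": str,
            "condition": str,
            "trial_type": str,
            "launcher": str,
            "response_status": str,
        },
        keep_default_na=True,
    )
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    trials = frame_to_trials(df[list(COLUMNS)])
    validate_trials(trials, design)
    return trials
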