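"""Trial-exclusion rules and central-launcher pooling.

Removals are applied in a fixed order:

1. missed / premature responses (no usable RT);
2. RTs outside the plausible window — strictly faster than 100 ms or slower
   than 1000 ms (boundary values are kept);
3. RTs beyond ``sd_cutoff`` sample standard deviations (n-1 denominator) from
   the participant-by-distance mean, with mean and SD computed once on the
   trials surviving steps 1-2 (single pass, no iteration).

Removed trials are never replaced.  Catch trials are subject to rules 1-2 but
carry no distance, so rule 3 does not apply to them; survivors are routed to
the report's ``n_catch`` bucket and never enter the kept analysis set, which
contains test trials only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import ExperimentDesign, TrialRecord

logger = logging.getLogger(__name__)

_RULES = ("missed_premature", "fast", "slow", "sd_outlier", "catch")


@dataclass
class FilterReport:
    """Accounting of one filtering pass.

    Invariant (asserted by :meth:`reconciles`): every input trial lands in
    exactly one bucket, ``n_input = n_kept + n_missed_premature + n_fast +
    n_slow + n_sd_outlier + n_catch``.
    """

    n_input: int = 0
    n_missed_premature: int = 0
    n_fast: int = 0
    n_slow: int = 0
    n_sd_outlier: int = 0
    n_catch: int = 0
    n_kept: int = 0
    per_participant: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return self.n_missed_premature + self.n_fast + self.n_slow + self.n_sd_outlier

    @property
    def removal_fraction(self) -> float:
        """Removed trials over all input trials (catch trials included in the
        denominator)."""
        return self.n_removed / self.n_input if self.n_input else 0.0

    def reconciles(self) -> bool:
        ok = self.n_input == self.n_kept + self.n_removed + self.n_catch
        for counts in self.per_participant.values():
            ok = ok and counts["input"] == sum(
                counts[k] for k in (*_RULES, "kept")
            )
        return ok

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_missed_premature": self.n_missed_premature,
            "n_fast": self.n_fast,
            "n_slow": self.n_slow,
            "n_sd_outlier": self.n_sd_outlier,
            "n_catch": self.n_catch,
            "n_kept": self.n_kept,
            "n_removed": self.n_removed,
            "removal_fraction": self.removal_fraction,
            "per_participant": self.per_participant,
            "warnings": list(self.warnings),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _bump(report: FilterReport, pid: str, bucket: str) -> None:
    counts = report.per_participant.setdefault(
        pid, {k: 0 for k in ("input", *_RULES, "kept")}
    )
    counts[bucket] += 1


def filter_trials(
    trials: Sequence[TrialRecord], design: ExperimentDesign
) -> tuple[list[TrialRecord], FilterReport]:
    """Apply the exclusion rules; return (kept test trials, report).

    A participant-by-distance cell with fewer than two surviving trials has no
    defined SD; rule 3 is skipped there and a warning recorded.  A cell of
    identical RTs has SD 0 and removes nothing (deviations cannot exceed 0
    strictly).
    """
    report = FilterReport(n_input=len(trials))
    lo, hi = design.rt_window_s

    survivors: list[TrialRecord] = []
    for t in trials:
        _bump(report, t.participant_id, "input")
        if t.response_status in ("missed", "premature"):
            report.n_missed_premature += 1
            _bump(report, t.participant_id, "missed_premature")
        elif t.rt_s is not None and t.rt_s < lo:
            report.n_fast += 1
            _bump(report, t.participant_id, "fast")
        elif t.rt_s is not None and t.rt_s > hi:
            report.n_slow += 1
            _bump(report, t.participant_id, "slow")
        else:
            survivors.append(t)

    # Rule 3 operates on test trials only (catch trials carry no distance).
    cells: dict[tuple[str, float], list[int]] = {}
    for i, t in enumerate(survivors):
        if t.trial_type == "test":
            cells.setdefault((t.participant_id, t.distance_m), []).append(i)

    outlier_idx: set[int] = set()
    for (pid, dist), idx in cells.items():
        rts = np.array([survivors[i].rt_s for i in idx], dtype=float)
        if len(rts) < 2:
            msg = (
                f"participant {pid}, distance {dist} m: {len(rts)} surviving "
                "trial(s); SD undefined, outlier rule skipped"
            )
            report.warnings.append(msg)
            logger.warning(msg)
            continue
        mean = rts.mean()
        sd = rts.std(ddof=1)
        dev = np.abs(rts - mean)
        for i, d in zip(idx, dev):
            if d > design.sd_cutoff * sd:
                outlier_idx.add(i)

    kept: list[TrialRecord] = []
    for i, t in enumerate(survivors):
        if i in outlier_idx:
            report.n_sd_outlier += 1
            _bump(report, t.participant_id, "sd_outlier")
        elif t.trial_type == "test":
            kept.append(t)
            _bump(report, t.participant_id, "kept")
        else:
            report.n_catch += 1
            _bump(report, t.participant_id, "catch")
    report.n_kept = len(kept)
    assert report.reconciles(), "filter report does not reconcile"
    return kept, report


def pool_central(trials: Sequence[TrialRecord]) -> list[TrialRecord]:
    """Keep central-launcher test trials (order preserved).

    The analysis pools these because the central avatar launches on 80% of
    trials; lateral trials survive filtering but are set aside here.  An empty
    result is a warning, not an error.
    """
    pooled = [
        t for t in trials if t.trial_type == "test" and t.launcher == "center"
    ]
    if not pooled:
        logger.warning("pool_central produced an empty set")
    return pooled
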