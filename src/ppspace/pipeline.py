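"""End-to-end orchestration: simulate/load -> filter -> screen -> fit ->
bootstrap -> compare, plus diagnostic figures.

The configuration is one YAML (or JSON) document::

    design: {experiment: exp1}            # ExperimentDesign overrides
    cohort: {n_responders: 33, n_nonresponders: 8, seed: 7}
    # or: trials_csv: path/to/trials.csv
    conditions: [baseline, pull, push]    # baseline must be present
    effects: {pull: 0.32, push: 0.20}     # generative boundary shifts (m)
    bootstrap: {iterations: 12000, seed: 7}
    screening: {r2_max: 0.1, slope_max: 0.005}

Screening is performed on the baseline condition; an excluded participant is
removed from every condition.  Every exclusion (trial or participant) is
logged and accounted for in the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import yaml

from . import __version__
from .bootstrap import (
    BootstrapDistribution,
    ComparisonResult,
    bootstrap_xc,
    compare_conditions,
)
from .data import ExperimentDesign, read_trials
from .exceptions import ConfigError
from .fitting import RTProfile, SigmoidFit, build_profile, fit_sigmoid, normalize_profile
from .preprocess import FilterReport, filter_trials, pool_central
from .screening import ScreeningResult, fit_cohort, screen_cohort
from .simulate import CohortSpec, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class ConditionResult:
    condition: str
    profile: RTProfile
    fit: SigmoidFit
    distribution: Optional[BootstrapDistribution] = None

    def to_dict(self) -> dict:
        d = {
            "condition": self.condition,
            "xc_m": self.fit.xc_m,
            "width_b_m": self.fit.width_b_m,
            "converged": self.fit.converged,
            "mean_rt_s": list(self.profile.mean_rt_s),
            "normalized": list(self.profile.normalized or ()),
            "n_per_distance": list(self.profile.n_per_distance),
        }
        if self.distribution is not None:
            d["bootstrap"] = self.distribution.summary()
        return d


@dataclass
class AnalysisReport:
    design: ExperimentDesign
    filter_report: FilterReport
    screening: ScreeningResult
    conditions: dict  # condition -> ConditionResult
    comparisons: list  # ComparisonResult vs baseline
    seed: Optional[int]
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "design": {
                "distances_m": list(self.design.distances_m),
                "reps_per_distance": self.design.reps_per_distance,
                "central_fraction": self.design.central_fraction,
                "n_catch_per_type": self.design.n_catch_per_type,
                "rt_window_s": list(self.design.rt_window_s),
                "sd_cutoff": self.design.sd_cutoff,
            },
            "filter_report": self.filter_report.to_dict(),
            "screening": self.screening.to_dict(),
            "conditions": {c: r.to_dict() for c, r in self.conditions.items()},
            "comparisons": [c.to_dict() for c in self.comparisons],
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            f"ppspace {self.version} analysis (seed={self.seed})",
            f"trials: {self.filter_report.n_input} in, "
            f"{self.filter_report.n_removed} removed "
            f"({100 * self.filter_report.removal_fraction:.2f}%), "
            f"{self.filter_report.n_kept} kept for analysis",
            f"screening: {len(self.screening.included_ids)} included, "
            f"{len(self.screening.excluded_ids)} excluded "
            f"(Pearson r = {self.screening.pearson_r if self.screening.pearson_r is None else round(self.screening.pearson_r, 3)})",
            "",
            f"{'condition':<10} {'x_c (m)':>8} {'95% CI':>18} {'failed fits':>12}",
        ]
        for cond, res in self.conditions.items():
            s = res.distribution.summary() if res.distribution else {}
            ci = s.get("ci95_m")
            ci_txt = f"[{ci[0]:.3f}, {ci[1]:.3f}]" if ci else "-"
            lines.append(
                f"{cond:<10} {res.fit.xc_m:>8.3f} {ci_txt:>18} "
                f"{s.get('n_failed_fits', 0):>12}"
            )
        lines.append("")
        for cmp_ in self.comparisons:
            lines.append(
                f"{cmp_.condition_b} vs {cmp_.condition_a}: "
                f"delta = {cmp_.delta_mean_m:+.3f} m, {cmp_.p_display} "
                f"({cmp_.method} test, {cmp_.n_pairs} pairs)"
            )
        return "\n".join(lines)


def load_config(config: Union[str, Path, Mapping]) -> dict:
    if isinstance(config, Mapping):
        return dict(config)
    with open(config, "r", encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ConfigError(f"{config}: expected a mapping at top level")
    return loaded


def run_analysis(
    config: Union[str, Path, Mapping],
    seed: Optional[int] = None,
    n_iterations: Optional[int] = None,
) -> AnalysisReport:
    """Run the full pipeline described by ``config``.

    ``seed`` overrides both the cohort seed and the bootstrap master seed so a
    single integer reproduces the whole analysis.  ``n_iterations`` overrides
    the configured bootstrap size.
    """
    cfg = load_config(config)
    design = ExperimentDesign.from_mapping(cfg.get("design", {}))
    conditions = list(cfg.get("conditions", ["baseline"]))
    if "baseline" not in conditions:
        raise ConfigError("configuration must include the baseline condition")

    boot_cfg = dict(cfg.get("bootstrap", {}))
    if n_iterations is not None:
        boot_cfg["iterations"] = n_iterations
    iterations = int(boot_cfg.get("iterations", 0))
    master_seed = seed if seed is not None else int(boot_cfg.get("seed", 0))

    if "trials_csv" in cfg:
        trials = read_trials(cfg["trials_csv"], design)
        logger.info("loaded %d trials from %s", len(trials), cfg["trials_csv"])
    elif "cohort" in cfg:
        cohort_cfg = dict(cfg["cohort"])
        if seed is not None:
            cohort_cfg["seed"] = seed
        spec = CohortSpec.from_mapping(cohort_cfg)
        trials = simulate_cohort(
            spec,
            design,
            conditions,
            effect_map=cfg.get("effects", {}),
            experiment=cfg.get("design", {}).get("experiment", "exp1"),
        )
        logger.info("simulated %d trials", len(trials))
    else:
        raise ConfigError("configuration needs either 'trials_csv' or 'cohort'")

    kept, filter_report = filter_trials(trials, design)
    for w in filter_report.warnings:
        logger.warning("filter: %s", w)

    scr_cfg = cfg.get("screening", {})
    fits = fit_cohort(kept, condition="baseline")
    screening = screen_cohort(
        fits,
        r2_max=float(scr_cfg.get("r2_max", 0.1)),
        slope_max=float(scr_cfg.get("slope_max", 0.005)),
    )
    for pid in screening.excluded_ids:
        logger.info("screening: participant %s excluded (flat/noisy baseline fit)", pid)
    included = set(screening.included_ids)

    pooled = [t for t in pool_central(kept) if t.participant_id in included]

    results: dict[str, ConditionResult] = {}
    for k, cond in enumerate(conditions):
        profile = normalize_profile(
            build_profile(pooled, condition=cond, distances=design.distances_m)
        )
        fit = fit_sigmoid(profile)
        dist = None
        if iterations > 0:
            cond_trials = [t for t in pooled if t.condition == cond]
            dist = bootstrap_xc(
                cond_trials,
                n_iterations=iterations,
                seed=int(
                    np.random.SeedSequence([master_seed, 2, k]).generate_state(1)[0]
                    % (2**31)
                ),
                distances=design.distances_m,
                condition=cond,
            )
        results[cond] = ConditionResult(cond, profile, fit, dist)

    comparisons = []
    if iterations > 0:
        base = results["baseline"].distribution
        for cond in conditions:
            if cond == "baseline":
                continue
            comparisons.append(compare_conditions(base, results[cond].distribution))

    return AnalysisReport(
        design=design,
        filter_report=filter_report,
        screening=screening,
        conditions=results,
        comparisons=comparisons,
        seed=master_seed,
    )


def make_figures(report: AnalysisReport, out_dir) -> list[Path]:
    """Write the four diagnostic figures; returns the paths created.

    Panels mirror the analysis stages: the screening R^2-vs-slope scatter with
    the exclusion-threshold guides, raw RT-distance profiles, normalized
    profiles with sigmoid overlays and fitted boundaries, and the bootstrap
    boundary histograms (skipped with a warning when a distribution has no
    usable iterations).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    # 1. screening scatter
    fig, ax = plt.subplots(figsize=(5, 4))
    r2 = [f.r_squared for f in report.screening.fits]
    slope = [f.slope for f in report.screening.fits]
    excl = set(report.screening.excluded_ids)
    colors = ["crimson" if f.participant_id in excl else "steelblue" for f in report.screening.fits]
    ax.scatter(r2, slope, c=colors, s=25)
    ax.axvline(report.screening.r2_max, ls=":", c="k")
    ax.axhline(report.screening.slope_max, ls=":", c="k")
    ax.set_xlabel("$R^2$ of linear fit")
    ax.set_ylabel("slope (s/m)")
    ax.set_title(f"screening (Pearson r = {report.screening.pearson_r})")
    p = out_dir / "screening_scatter.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    # 2. raw RT profiles
    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, res in report.conditions.items():
        ax.plot(res.profile.distances_m, res.profile.mean_rt_s, "o-", label=cond)
    ax.set_xlabel("stimulus distance (m)")
    ax.set_ylabel("mean RT (s)")
    ax.legend()
    p = out_dir / "rt_profiles.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    # 3. sigmoid overlays
    fig, ax = plt.subplots(figsize=(5, 4))
    xs = np.linspace(
        report.design.distances_m[0], report.design.distances_m[-1], 200
    )
    for cond, res in report.conditions.items():
        (line,) = ax.plot(res.profile.distances_m, res.profile.normalized, "o")
        ax.plot(xs, res.fit.predict(xs), "-", color=line.get_color(), label=cond)
        ax.axvline(res.fit.xc_m, color=line.get_color(), ls="--", alpha=0.5)
    ax.set_xlabel("stimulus distance (m)")
    ax.set_ylabel("normalized RT")
    ax.legend()
    p = out_dir / "sigmoid_fits.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    # 4. bootstrap histograms
    fig, ax = plt.subplots(figsize=(5, 4))
    drew = False
    for cond, res in report.conditions.items():
        dist = res.distribution
        if dist is None or len(dist.xc_samples) == 0:
            logger.warning("no usable bootstrap samples for %r; histogram skipped", cond)
            continue
        ax.hist(dist.xc_samples, bins=40, alpha=0.5, label=cond)
        drew = True
    ax.set_xlabel("bootstrap $x_c$ (m)")
    ax.set_ylabel("count")
    if drew:
        ax.legend()
    p = out_dir / "bootstrap_hist.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths
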