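"""End-to-end study orchestration.

``run_study`` goes from a config to a full analysis: simulate (or load)
trials, aggregate with the tablet-shortest exclusion, fit conjoint
psychometric functions per participant x platform (shared slope unless
the likelihood-ratio test rejects at alpha = 0.01, in which case the
free-slope fit is reported for that participant/platform), bootstrap the
thresholds for CIs and condition-difference tests (size within platform,
platform within size), and compute the group statistics.  Everything is
deterministic given the config seed.

``group_report`` recomputes the group statistics from a fits table alone,
so the reporting stage can be re-run from the fits CSV without refitting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import (
    bootstrap_difference_test,
    deviance_bootstrap_p,
    parametric_bootstrap_thresholds,
    percentile_ci,
)
from .exceptions import ConfigError
from .fitting import (
    TestResult,
    aggregate_counts,
    fit_conjoint,
    likelihood_ratio_test,
    threshold_from_fit,
)
from .group import (
    geometric_mean_ci,
    paired_t_test,
    pearson_correlation,
    rm_anova_2x2,
    suppression_index,
)
from .simulate import (
    DesignSpec,
    ObserverSpec,
    build_trial_list,
    read_trials,
    sample_cohort,
    simulate_trials,
)

__all__ = ["StudyConfig", "StudySummary", "validate_config", "run_study", "group_report", "write_summary"]

logger = logging.getLogger(__name__)

from . import __version__  # noqa: E402  (package version for provenance)


@dataclass(frozen=True)
class StudyConfig:
    """Validated configuration of one study run."""

    design: DesignSpec = field(default_factory=DesignSpec)
    observer: ObserverSpec = field(default_factory=ObserverSpec)
    input_path: str | None = None
    cohort_sd_common: float = 0.12
    cohort_sd_size: float = 0.08
    cohort_slope_sd: float = 0.1
    bootstrap_B: int = 2000
    ci_level: float = 0.99
    lrt_alpha: float = 0.01
    exclude_tablet_shortest: bool = True
    seed: int = 0
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"]["refresh_rates"] = dict(d["design"]["refresh_rates"])
        d["observer"]["platform_factors"] = dict(d["observer"]["platform_factors"])
        return d


@dataclass
class StudySummary:
    """All outputs of one study run."""

    fits: pd.DataFrame  # one row per participant x platform x size
    participants: pd.DataFrame  # one row per participant x platform
    platform_tests: pd.DataFrame  # per participant x size platform comparison
    group: dict  # group-level TestResults and summaries
    provenance: dict
    trials: pd.DataFrame | None = None


_TOP_KEYS = {
    "design",
    "observer",
    "input_path",
    "cohort_sd_common",
    "cohort_sd_size",
    "cohort_slope_sd",
    "bootstrap_B",
    "ci_level",
    "lrt_alpha",
    "exclude_tablet_shortest",
    "seed",
    "output_dir",
}


def validate_config(raw: dict | None) -> StudyConfig:
    """Build a :class:`StudyConfig` from a parsed config mapping.

    Missing keys take the full default study design (13 participants,
    7 log-spaced durations 0.01–0.2 s, B = 2000, 99% CIs).  Every
    violation found is reported in a single :class:`ConfigError`.
    """
    raw = dict(raw or {})
    errors: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")

    def build(cls, section_raw, name):
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(section_raw) - known
        if bad:
            errors.append(f"unknown {name} keys: {sorted(bad)}")
            section_raw = {k: v for k, v in section_raw.items() if k in known}
        for key in ("durations", "platforms", "sizes", "directions", "phases"):
            if key in section_raw and isinstance(section_raw[key], list):
                section_raw[key] = tuple(section_raw[key])
        try:
            return cls(**section_raw)
        except (TypeError, ValueError) as exc:
            errors.append(f"invalid {name}: {exc}")
            return cls()

    design = build(DesignSpec, dict(raw.get("design") or {}), "design")
    observer = build(ObserverSpec, dict(raw.get("observer") or {}), "observer")

    B = raw.get("bootstrap_B", 2000)
    if not isinstance(B, (int, np.integer)) or B < 1:
        errors.append(f"bootstrap_B must be a positive integer, got {B!r}")
        B = 2000
    level = raw.get("ci_level", 0.99)
    if not 0.0 < level < 1.0:
        errors.append(f"ci_level must be in (0, 1), got {level!r}")
        level = 0.99
    lrt_alpha = raw.get("lrt_alpha", 0.01)
    if not 0.0 < lrt_alpha < 1.0:
        errors.append(f"lrt_alpha must be in (0, 1), got {lrt_alpha!r}")
        lrt_alpha = 0.01
    input_path = raw.get("input_path")
    if input_path is not None and "observer" in raw:
        errors.append(
            "config must activate exactly one of observer simulation or input_path"
        )
    if errors:
        raise ConfigError("; ".join(errors))
    return StudyConfig(
        design=design,
        observer=observer,
        input_path=input_path,
        cohort_sd_common=float(raw.get("cohort_sd_common", 0.12)),
        cohort_sd_size=float(raw.get("cohort_sd_size", 0.08)),
        cohort_slope_sd=float(raw.get("cohort_slope_sd", 0.1)),
        bootstrap_B=int(B),
        ci_level=float(level),
        lrt_alpha=float(lrt_alpha),
        exclude_tablet_shortest=bool(raw.get("exclude_tablet_shortest", True)),
        seed=int(raw.get("seed", 0)),
        output_dir=raw.get("output_dir"),
    )


def _config_hash(config: StudyConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _test_row(t: TestResult | None, name: str, **extra) -> dict:
    row = {"name": name}
    if t is not None:
        row.update(
            statistic=t.statistic,
            df=str(t.df),
            p_value=t.p_value,
            significant=t.significant,
        )
    row.update(extra)
    return row


def run_study(config: StudyConfig) -> StudySummary:
    """Execute the full analysis pipeline for one configuration."""
    ss = np.random.SeedSequence(config.seed)
    seed_plan, seed_cohort, seed_sim, seed_boot = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)
    )

    if config.input_path is not None:
        trials = read_trials(config.input_path)
        simulated = None
        logger.info("loaded %d trials from %s", len(trials), config.input_path)
    else:
        plan = build_trial_list(config.design, seed_plan)
        cohort = sample_cohort(
            config.observer,
            config.design.participants,
            seed_cohort,
            between_sd_common=config.cohort_sd_common,
            between_sd_size=config.cohort_sd_size,
            slope_sd=config.cohort_slope_sd,
        )
        trials = simulate_trials(cohort, plan, seed_sim)
        simulated = trials
        logger.info("simulated %d trials (seed %d)", len(trials), config.seed)

    counts = aggregate_counts(trials, config.exclude_tablet_shortest)
    logger.info(
        "aggregated to %d condition sets; %d trials retained of %d",
        len(counts),
        int(sum(c.n.sum() for c in counts.values())),
        len(trials),
    )

    units = sorted({(pid, plat) for (pid, plat, _size) in counts})
    boot_seeds = {
        unit: int(s.generate_state(1)[0] % 2**31)
        for unit, s in zip(units, np.random.SeedSequence(seed_boot).spawn(len(units)))
    }

    fit_rows, part_rows = [], []
    boot_dists: dict[tuple, dict] = {}
    for pid, plat in units:
        cs = counts[(pid, plat, "small")]
        cl = counts[(pid, plat, "large")]
        shared = fit_conjoint(cs, cl, share_slope=True)
        free = fit_conjoint(cs, cl, share_slope=False)
        lrt = likelihood_ratio_test(shared, free, alpha=config.lrt_alpha)
        reported = free if lrt.significant else shared
        thr = threshold_from_fit(reported)
        dists = parametric_bootstrap_thresholds(
            reported, cs, cl, B=config.bootstrap_B, seed=boot_seeds[(pid, plat)]
        )
        boot_dists[(pid, plat)] = dists
        cis = {s: percentile_ci(dists[s], config.ci_level) for s in ("small", "large")}
        size_diff = bootstrap_difference_test(
            dists["large"], dists["small"], level=config.ci_level
        )
        dev_p = deviance_bootstrap_p(
            reported, cs, cl, B=config.bootstrap_B, seed=boot_seeds[(pid, plat)] + 1
        )
        si = suppression_index(thr["small"], thr["large"])
        model_name = "free" if lrt.significant else "shared"
        for size, cc in (("small", cs), ("large", cl)):
            slope = (
                reported.model.slope_small
                if size == "small"
                else reported.model.slope_large
            )
            fit_rows.append(
                {
                    "participant": pid,
                    "platform": plat,
                    "size": size,
                    "threshold_s": thr[size],
                    "ci_low": 10.0 ** cis[size][0],
                    "ci_high": 10.0 ** cis[size][1],
                    "slope": slope,
                    "deviance": reported.deviance,
                    "deviance_p": dev_p,
                    "lrt_D": lrt.statistic,
                    "lrt_p": lrt.p_value,
                    "model": model_name,
                    "converged": reported.converged,
                    "failed_refits": dists[size].failed_refits,
                }
            )
        part_rows.append(
            {
                "participant": pid,
                "platform": plat,
                "threshold_small": thr["small"],
                "ci_small_low": 10.0 ** cis["small"][0],
                "ci_small_high": 10.0 ** cis["small"][1],
                "threshold_large": thr["large"],
                "ci_large_low": 10.0 ** cis["large"][0],
                "ci_large_high": 10.0 ** cis["large"][1],
                "suppression_index": si,
                "size_diff_significant": size_diff.significant,
                "lrt_D": lrt.statistic,
                "lrt_p": lrt.p_value,
                "deviance": reported.deviance,
                "deviance_p": dev_p,
                "model": model_name,
            }
        )

    fits = pd.DataFrame(fit_rows)
    participants = pd.DataFrame(part_rows)

    # platform comparison within each size, per participant
    plat_rows = []
    platforms = sorted({plat for (_pid, plat) in units})
    if len(platforms) == 2:
        p0, p1 = platforms
        for pid in sorted({pid for (pid, _plat) in units}):
            if (pid, p0) not in boot_dists or (pid, p1) not in boot_dists:
                continue
            for size in ("small", "large"):
                da = boot_dists[(pid, p0)][size]
                db = boot_dists[(pid, p1)][size]
                m = min(len(da.values), len(db.values))
                da = dataclasses.replace(
                    da, values=da.values[:m], B=m, failed_refits=0
                )
                db = dataclasses.replace(
                    db, values=db.values[:m], B=m, failed_refits=0
                )
                res = bootstrap_difference_test(da, db, level=config.ci_level)
                plat_rows.append(
                    {
                        "participant": pid,
                        "size": size,
                        "comparison": f"{p0}-{p1}",
                        "mean_log10_diff": res.statistic,
                        "ci_low": res.interval[0],
                        "ci_high": res.interval[1],
                        "significant": res.significant,
                    }
                )
    platform_tests = pd.DataFrame(plat_rows)

    group = group_report(fits, ci_level=config.ci_level)

    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "package_version": __version__,
        "n_trials": int(len(trials)),
        "n_fits": int(len(units)),
    }
    return StudySummary(
        fits=fits,
        participants=participants,
        platform_tests=platform_tests,
        group=group,
        provenance=provenance,
        trials=simulated,
    )


def group_report(fits: pd.DataFrame, ci_level: float = 0.99) -> dict:
    """Group statistics from a fits table (participant, platform, size rows).

    Computes, where the design allows: per-size cross-platform Pearson
    correlations of log10 thresholds, the 2x2 repeated-measures ANOVA,
    the paired t on the suppression index across platforms, the Pearson
    correlation of the suppression indices, per-platform mean suppression
    indices, and geometric-mean thresholds with t-based CIs.  Statistics
    whose preconditions fail (single platform, too few participants) are
    reported as None.
    """
    out: dict = {}
    df = fits.copy()
    df["log10_threshold"] = np.log10(df["threshold_s"])
    platforms = sorted(df["platform"].unique())
    sizes = sorted(df["size"].unique())

    wide = df.pivot_table(
        index="participant", columns=["platform", "size"], values="log10_threshold"
    )
    two_by_two = len(platforms) == 2 and len(sizes) == 2 and not wide.isna().any().any()

    for size in sizes:
        key = f"correlation_{size}"
        out[key] = None
        if len(platforms) == 2:
            try:
                out[key] = pearson_correlation(
                    wide[(platforms[0], size)], wide[(platforms[1], size)]
                )
            except (ValueError, KeyError):
                pass

    out["anova"] = None
    if two_by_two:
        long = df.rename(columns={"log10_threshold": "value"})[
            ["participant", "size", "platform", "value"]
        ]
        try:
            out["anova"] = rm_anova_2x2(long)
        except ValueError:
            pass

    out["si_paired_t"] = None
    out["si_correlation"] = None
    out["si_means"] = None
    if two_by_two and "large" in sizes and "small" in sizes:
        si = {
            plat: (wide[(plat, "large")] - wide[(plat, "small")]).to_numpy()
            for plat in platforms
        }
        out["si_means"] = {plat: float(np.mean(si[plat])) for plat in platforms}
        try:
            out["si_paired_t"] = paired_t_test(si[platforms[0]], si[platforms[1]])
            out["si_correlation"] = pearson_correlation(
                si[platforms[0]], si[platforms[1]]
            )
        except ValueError:
            pass

    gm = {}
    for plat in platforms:
        for size in sizes:
            vals = df.loc[
                (df["platform"] == plat) & (df["size"] == size), "threshold_s"
            ]
            if len(vals) >= 2:
                mean, ci = geometric_mean_ci(vals, level=ci_level)
                gm[(plat, size)] = {"gmean_s": mean, "ci_low": ci[0], "ci_high": ci[1]}
    out["geometric_means"] = gm
    return out


def group_table(group: dict) -> pd.DataFrame:
    """Flatten a ``group_report`` dict into a tidy DataFrame for CSV output."""
    rows = []
    for key, val in group.items():
        if val is None:
            continue
        if isinstance(val, TestResult):
            rows.append(_test_row(val, key))
        elif key == "anova":
            for effect, t in val.items():
                rows.append(_test_row(t, f"anova_{effect}"))
        elif key == "si_means":
            for plat, m in val.items():
                rows.append({"name": f"si_mean_{plat}", "statistic": m})
        elif key == "geometric_means":
            for (plat, size), d in val.items():
                rows.append(
                    {
                        "name": f"gmean_{plat}_{size}",
                        "statistic": d["gmean_s"],
                        "ci_low": d["ci_low"],
                        "ci_high": d["ci_high"],
                    }
                )
    return pd.DataFrame(rows)


def write_summary(summary: StudySummary, outdir: str | Path) -> dict[str, Path]:
    """Write every table of a study summary as CSV plus provenance JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if summary.trials is not None:
        paths["trials"] = outdir / "trials.csv"
        summary.trials.to_csv(paths["trials"], index=False)
    paths["fits"] = outdir / "fits.csv"
    summary.fits.to_csv(paths["fits"], index=False)
    paths["participants"] = outdir / "participants.csv"
    summary.participants.to_csv(paths["participants"], index=False)
    paths["platform_tests"] = outdir / "platform_tests.csv"
    summary.platform_tests.to_csv(paths["platform_tests"], index=False)
    paths["group"] = outdir / "group_stats.csv"
    group_table(summary.group).to_csv(paths["group"], index=False)
    paths["provenance"] = outdir / "provenance.json"
    paths["provenance"].write_text(json.dumps(summary.provenance, indent=2))
    return paths
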