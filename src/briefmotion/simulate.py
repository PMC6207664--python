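"""Study design enumeration and synthetic 2AFC observers.

The default :class:`DesignSpec` reproduces the validation study's layout:
13 participants each run 2 blocks on a 120 Hz CRT and 2 on a 60 Hz tablet
(alternating platforms, with the starting platform counterbalanced across
participants); each block has two parts of 140 trials — the full factorial
crossing of 7 log-spaced durations (0.01–0.2 s) x 2 grating sizes x 2
motion directions x 5 initial phases, randomly interleaved.

The synthetic observer answers a left/right motion-direction question from
a logistic psychometric function of log10 duration with guess rate 0.5 and
lapse rate 0 (the 2AFC chance floor and a perfect upper asymptote).  An
optional "reversal" term — an exponentially decaying dip anchored at the
shortest duration — can push accuracy below chance for very brief
stimuli, emulating the systematic direction reversals some human
observers show there; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import SchemaError
from .stimulus import make_duration_grid

__all__ = [
    "DesignSpec",
    "ObserverSpec",
    "TRIAL_COLUMNS",
    "build_trial_list",
    "observer_prob_correct",
    "simulate_trials",
    "sample_cohort",
    "read_trials",
    "write_trials",
]

#: Required columns of a trial CSV, in canonical order.
TRIAL_COLUMNS = (
    "participant",
    "platform",
    "block",
    "part",
    "size",
    "duration_s",
    "direction",
    "phase_deg",
    "response",
    "correct",
)

_DEFAULT_RATES = {"CRT": 120.0, "tablet": 60.0}


@dataclass(frozen=True)
class DesignSpec:
    """Factorial layout of the two-platform duration-threshold study."""

    participants: int = 13
    platforms: tuple[str, ...] = ("CRT", "tablet")
    refresh_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RATES)
    )
    blocks_per_platform: int = 2
    parts_per_block: int = 2
    durations: tuple[float, ...] = tuple(make_duration_grid(7, 0.01, 0.2))
    sizes: tuple[str, ...] = ("small", "large")
    directions: tuple[str, ...] = ("left", "right")
    phases: tuple[float, ...] = (0.0, 72.0, 144.0, 216.0, 288.0)

    def __post_init__(self) -> None:
        for name in ("participants", "blocks_per_platform", "parts_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not all(
            a < b for a, b in zip(self.durations, self.durations[1:])
        ):
            raise ValueError("durations must be strictly increasing")
        if not self.platforms or not self.sizes or not self.directions:
            raise ValueError("factor levels must be non-empty")

    @property
    def trials_per_part(self) -> int:
        """Size of one full factorial crossing (140 in the default design)."""
        return (
            len(self.durations)
            * len(self.sizes)
            * len(self.directions)
            * len(self.phases)
        )


@dataclass(frozen=True)
class ObserverSpec:
    """Parametric 2AFC observer for motion-direction discrimination.

    ``threshold_small``/``threshold_large`` are the 75%-correct durations
    (s) for the two grating sizes; ``slope`` is the logistic scale in
    log10-duration units.  ``platform_factors`` multiply the thresholds
    per platform (additive in log10).  The reversal term subtracts
    ``reversal_amplitude * exp(-(log10 d - log10 anchor)/reversal_decay)``
    from the probability of a correct answer, producing below-chance
    accuracy near ``reversal_anchor`` when the amplitude is positive.
    """

    threshold_small: float = 0.02  # s
    threshold_large: float = 0.05  # s
    slope: float = 0.15  # log10-duration units
    reversal_amplitude: float = 0.0  # probability, in [0, 0.5)
    reversal_decay: float = 0.3  # log10-duration units
    reversal_anchor: float = 0.01  # s; the grid minimum
    platform_factors: Mapping[str, float] = field(
        default_factory=lambda: {"CRT": 1.0, "tablet": 1.0}
    )

    def __post_init__(self) -> None:
        if self.threshold_small <= 0 or self.threshold_large <= 0:
            raise ValueError("thresholds must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0.0 <= self.reversal_amplitude < 0.5:
            raise ValueError("reversal_amplitude must be in [0, 0.5)")

    def threshold(self, size: str, platform: str | None = None) -> float:
        thr = {"small": self.threshold_small, "large": self.threshold_large}[size]
        if platform is not None:
            thr = thr * dict(self.platform_factors).get(platform, 1.0)
        return thr


def _participant_streams(seed: int, n: int) -> list[np.random.Generator]:
    """One independent, reproducible RNG stream per participant."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def build_trial_list(design: DesignSpec, seed: int) -> pd.DataFrame:
    """Enumerate and randomize the planned trials of a whole study.

    Per part, every cell of the duration x size x direction x phase
    crossing appears exactly once, in an order randomized by ``seed``.
    Platforms alternate across a participant's blocks and the starting
    platform alternates across participants, so half the cohort starts on
    each platform.  ``block`` is the 1-based block index within platform.
    """
    cells = pd.MultiIndex.from_product(
        [design.durations, design.sizes, design.directions, design.phases],
        names=["duration_s", "size", "direction", "phase_deg"],
    ).to_frame(index=False)
    streams = _participant_streams(seed, design.participants)
    n_platforms = len(design.platforms)
    rows = []
    for pid in range(1, design.participants + 1):
        rng = streams[pid - 1]
        start = (pid - 1) % n_platforms
        block_count = {p: 0 for p in design.platforms}
        n_global_blocks = design.blocks_per_platform * n_platforms
        for g in range(n_global_blocks):
            platform = design.platforms[(start + g) % n_platforms]
            block_count[platform] += 1
            for part in range(1, design.parts_per_block + 1):
                order = rng.permutation(len(cells))
                part_df = cells.iloc[order].reset_index(drop=True)
                part_df.insert(0, "participant", pid)
                part_df.insert(1, "platform", platform)
                part_df.insert(2, "block", block_count[platform])
                part_df.insert(3, "part", part)
                rows.append(part_df)
    plan = pd.concat(rows, ignore_index=True)
    return plan[
        [
            "participant",
            "platform",
            "block",
            "part",
            "size",
            "duration_s",
            "direction",
            "phase_deg",
        ]
    ]


def observer_prob_correct(
    obs: ObserverSpec,
    size: str,
    platform: str,
    duration,
):
    """Probability of a correct direction report, vectorized over duration.

    ``p = 0.5 + 0.5 * logistic((log10 d - log10 thr) / slope) - reversal``,
    clipped to [0, 1]; ``thr`` includes the platform factor.
    """
    d = np.asarray(duration, float)
    if np.any(d <= 0):
        raise ValueError("duration must be positive")
    x = np.log10(d)
    mu = np.log10(obs.threshold(size, platform))
    p = 0.5 + 0.5 * expit((x - mu) / obs.slope)
    if obs.reversal_amplitude > 0:
        dip = obs.reversal_amplitude * np.exp(
            -(x - np.log10(obs.reversal_anchor)) / obs.reversal_decay
        )
        p = p - dip
    p = np.clip(p, 0.0, 1.0)
    return p if p.shape else float(p)


def simulate_trials(
    obs: ObserverSpec | Mapping[int, ObserverSpec],
    plan: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Draw responses for a planned trial list.

    ``obs`` is a single observer used for everyone, or a mapping from
    participant id to observer.  Each trial's correctness is an
    independent Bernoulli draw at the observer's probability; the response
    is the planned direction when correct and the other direction
    otherwise.  Per-participant RNG streams derive deterministically from
    ``seed``, so any participant's data can be regenerated independently.
    """
    plan = plan.reset_index(drop=True)
    pids = sorted(plan["participant"].unique())
    streams = dict(zip(pids, _participant_streams(seed, len(pids))))
    out = plan.copy()
    correct = np.empty(len(plan), dtype=bool)
    directions = np.asarray(plan["direction"])
    for pid in pids:
        mask = np.asarray(plan["participant"] == pid)
        sub = plan.loc[mask]
        observer = obs[pid] if isinstance(obs, Mapping) else obs
        p = np.empty(mask.sum())
        for (size, platform), grp in sub.groupby(["size", "platform"], sort=True):
            idx = sub.index.get_indexer(grp.index)
            p[idx] = observer_prob_correct(
                observer, size, platform, grp["duration_s"].to_numpy()
            )
        correct[mask] = streams[pid].random(mask.sum()) < p
    flip = {"left": "right", "right": "left"}
    response = np.where(
        correct, directions, np.vectorize(flip.get)(directions)
    )
    out["response"] = response
    out["correct"] = correct
    return out[list(TRIAL_COLUMNS) + [c for c in out.columns if c not in TRIAL_COLUMNS]]


def sample_cohort(
    base: ObserverSpec,
    n_participants: int,
    seed: int,
    between_sd_common: float = 0.12,
    between_sd_size: float = 0.08,
    slope_sd: float = 0.1,
) -> dict[int, ObserverSpec]:
    """Draw a cohort of observers around a base observer.

    Individual thresholds vary by a participant-level log10 shift common
    to both sizes (SD ``between_sd_common``) plus independent
    size-specific shifts (SD ``between_sd_size``); slopes vary
    lognormally (SD ``slope_sd`` in natural log units).  The common shift
    makes the two sizes' thresholds correlate across participants, as
    human thresholds do.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    cohort: dict[int, ObserverSpec] = {}
    for pid in range(1, n_participants + 1):
        g = rng.normal(0.0, between_sd_common)
        e_small = rng.normal(0.0, between_sd_size)
        e_large = rng.normal(0.0, between_sd_size)
        slope = base.slope * np.exp(rng.normal(0.0, slope_sd))
        cohort[pid] = replace(
            base,
            threshold_small=base.threshold_small * 10 ** (g + e_small),
            threshold_large=base.threshold_large * 10 ** (g + e_large),
            slope=slope,
        )
    return cohort


def write_trials(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a trial table to CSV (header always present)."""
    missing = [c for c in TRIAL_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"trial table is missing columns: {', '.join(missing)}")
    path = Path(path)
    records.to_csv(path, index=False)
    return path


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial CSV, checking the required column set.

    Unknown columns are preserved.  ``correct`` is coerced to bool and the
    numeric columns to their natural dtypes.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial CSV is missing columns: {', '.join(missing)}")
    if len(df):
        if df["correct"].dtype != bool:
            df["correct"] = (
                df["correct"].astype(str).str.strip().str.lower().map(
                    {"true": True, "false": False, "1": True, "0": False}
                )
            )
            if df["correct"].isna().any():
                raise SchemaError("column 'correct' has non-boolean values")
        df["duration_s"] = df["duration_s"].astype(float)
        df["phase_deg"] = df["phase_deg"].astype(float)
        for c in ("participant", "block", "part"):
            df[c] = df[c].astype(int)
    return df
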