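"""Synthetic 24-h multi-hormone panels with known injected measurement errors.

The generator emulates the structure of frequent-sampling endocrine studies:
blood drawn every 10 min for 24 h starting at 0900 h, five hormones from one
serum tube.  Each hormone's clean profile is

    baseline × circadian modulation + Σ secretory pulses + meal responses,

with pulse onsets Poisson over the day (GH's concentrated in the sleep
window, circa 2300–0800 h), log-normal pulse amplitudes, exponential decay
at the hormone's clearance half-life, and gamma-shaped meal responses for
glucose/insulin at three fixed feeding times.  Multiplicative log-normal
assay noise is applied at each hormone's configured CV (defaults inside the
reported inter-assay CV ranges, e.g. glucose 0.90–7.44%).

Two error types are injected on top, with ground truth recorded:
isolated spikes/drops that multiply a single point, and tube-level
dilutions that multiply all five hormones at one time point by a shared
factor in (0, 1) — the signature of a saline-flush or clotted sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import DEFAULT_N_TIMEPOINTS, DEFAULT_STEP_MINUTES, HORMONES, log
from .panel import HormonePanel

__all__ = [
    "HormoneProfile",
    "ErrorSpec",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_clean_panel",
    "inject_errors",
    "simulate_panel",
]

#: Clock hour at which sampling starts.
START_HOUR = 9.0
#: Lights-off window mapped onto the clock (2300–0800 h).
SLEEP_START_HOUR, SLEEP_END_HOUR = 23.0, 8.0


@dataclass(frozen=True)
class HormoneProfile:
    """Generative parameters for one hormone's clean 24-h profile.

    Amplitudes are in the hormone's own concentration units; the circadian
    amplitude is a relative modulation in [0, 1).  ``sleep_weight`` is the
    fraction of pulses forced into the sleep window (GH's nocturnal burst
    cluster); 0 means homogeneous-Poisson onsets.
    """

    baseline: float
    circadian_amplitude: float = 0.0
    acrophase_hour: float = 0.0
    pulse_rate: float = 0.0          # expected pulses per 24 h
    pulse_amp_median: float = 0.0    # log-normal median, concentration units
    pulse_amp_sigma: float = 0.5     # log-normal shape
    half_life_min: float = 60.0
    meal_amplitude: float = 0.0      # peak added concentration per meal
    meal_tau_min: float = 30.0       # gamma-shape time constant
    sleep_weight: float = 0.0
    cv: float = 0.03                 # assay coefficient of variation

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if not 0 <= self.circadian_amplitude < 1:
            raise ValueError("circadian_amplitude must be in [0, 1)")
        if self.cv < 0 or self.pulse_rate < 0:
            raise ValueError("rates and CVs must be non-negative")


@dataclass(frozen=True)
class ErrorSpec:
    """Rates and magnitudes of injected measurement errors.

    ``spike_rate``/``drop_rate`` are per-point Bernoulli probabilities within
    each (participant, hormone) series; ``dilution_rate`` is a per-time-point
    (per-tube) probability.  Factors are drawn uniformly from the stated
    ranges; dilution takes precedence over a spike/drop at the same point.
    """

    spike_rate: float = 0.025
    drop_rate: float = 0.025
    dilution_rate: float = 0.02
    spike_factor: tuple[float, float] = (2.0, 5.0)
    drop_factor: tuple[float, float] = (0.1, 0.6)
    dilution_factor: tuple[float, float] = (0.1, 0.6)

    def __post_init__(self) -> None:
        for r in (self.spike_rate, self.drop_rate, self.dilution_rate):
            if r < 0:
                raise ValueError("error rates must be >= 0")
        lo, hi = self.dilution_factor
        if not (0 < lo <= hi < 1):
            raise ValueError("dilution factors must lie in (0, 1)")


#: Default profiles: orders of magnitude follow published 24-h serum values;
#: CVs sit inside the reported inter-assay ranges per hormone.
DEFAULT_PROFILES: dict[str, HormoneProfile] = {
    "glucose": HormoneProfile(
        baseline=5.0, circadian_amplitude=0.03, acrophase_hour=12.0,
        pulse_rate=0.0, half_life_min=40.0,
        meal_amplitude=2.5, meal_tau_min=35.0, cv=0.02,
    ),
    "insulin": HormoneProfile(
        baseline=6.0, circadian_amplitude=0.05, acrophase_hour=13.0,
        pulse_rate=8.0, pulse_amp_median=3.0, pulse_amp_sigma=0.5,
        half_life_min=25.0, meal_amplitude=45.0, meal_tau_min=30.0, cv=0.05,
    ),
    "TSH": HormoneProfile(
        baseline=1.4, circadian_amplitude=0.35, acrophase_hour=2.0,
        pulse_rate=10.0, pulse_amp_median=0.35, pulse_amp_sigma=0.4,
        half_life_min=50.0, cv=0.028,
    ),
    "cortisol": HormoneProfile(
        baseline=0.28, circadian_amplitude=0.55, acrophase_hour=8.0,
        pulse_rate=15.0, pulse_amp_median=0.12, pulse_amp_sigma=0.5,
        half_life_min=70.0, cv=0.035,
    ),
    "GH": HormoneProfile(
        baseline=0.4, circadian_amplitude=0.0,
        pulse_rate=6.0, pulse_amp_median=8.0, pulse_amp_sigma=0.7,
        half_life_min=20.0, sleep_weight=0.8, cv=0.06,
    ),
}

#: Three fixed feeding times (minutes after sampling start ≈ 0930, 1330, 1800).
DEFAULT_MEAL_TIMES_MIN = (30.0, 270.0, 540.0)


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 5
    n_timepoints: int = DEFAULT_N_TIMEPOINTS
    step_minutes: int = DEFAULT_STEP_MINUTES
    profiles: Mapping[str, HormoneProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    meal_times_min: tuple[float, ...] = DEFAULT_MEAL_TIMES_MIN
    errors: ErrorSpec = field(default_factory=ErrorSpec)

    @property
    def hormones(self) -> list[str]:
        return list(self.profiles)


@dataclass
class SimulationTruth:
    """Ground-truth error annotations paired with a simulated panel.

    ``error_mask`` is boolean over (participant, time) × hormone;
    ``error_type`` holds 'spike' | 'drop' | 'dilution' where flagged;
    ``dilution_factors`` maps (participant, time) → shared factor.
    """

    error_mask: pd.DataFrame
    error_type: pd.DataFrame
    dilution_factors: dict[tuple, float] = field(default_factory=dict)

    def n_errors(self) -> int:
        return int(self.error_mask.sum().sum())

    def keys_of_type(self, kind: str) -> set[tuple]:
        stacked = self.error_type.stack(future_stack=True)
        return set(stacked[stacked == kind].index)

    def to_frame(self, step_minutes: int = DEFAULT_STEP_MINUTES) -> pd.DataFrame:
        rows = []
        for (p, t, h) in sorted(
            self.error_mask.stack(future_stack=True)
            .pipe(lambda s: s[s.fillna(False)]).index,
            key=str,
        ):
            kind = self.error_type.loc[(p, t), h]
            factor = self.dilution_factors.get((p, t)) if kind == "dilution" else np.nan
            rows.append((p, t * step_minutes, h, kind, factor))
        return pd.DataFrame(
            rows, columns=["participant", "time_min", "hormone", "error_type", "factor"]
        )


def _clock_hours(t_min: np.ndarray) -> np.ndarray:
    return (START_HOUR + t_min / 60.0) % 24.0


def _in_sleep(clock: np.ndarray) -> np.ndarray:
    return (clock >= SLEEP_START_HOUR) | (clock < SLEEP_END_HOUR)


def _pulse_train(
    t_min: np.ndarray, profile: HormoneProfile, rng: np.random.Generator
) -> np.ndarray:
    """Sum of exponentially decaying pulses with Poisson onsets."""
    total_min = t_min[-1] + (t_min[1] - t_min[0]) if len(t_min) > 1 else 1440.0
    n = rng.poisson(profile.pulse_rate)
    out = np.zeros_like(t_min, dtype=float)
    if n == 0 or profile.pulse_amp_median <= 0:
        return out
    onsets = rng.uniform(0.0, total_min, size=n)
    if profile.sleep_weight > 0:
        # re-draw the sleep-bound fraction of onsets inside the sleep window
        sleep_mask = _in_sleep(_clock_hours(t_min))
        sleep_times = t_min[sleep_mask]
        if len(sleep_times):
            move = rng.random(n) < profile.sleep_weight
            jitter = rng.uniform(0, t_min[1] - t_min[0], size=move.sum())
            onsets[move] = rng.choice(sleep_times, size=move.sum()) + jitter
    amps = profile.pulse_amp_median * rng.lognormal(
        0.0, profile.pulse_amp_sigma, size=n
    )
    lam = np.log(2.0) / profile.half_life_min
    for u, a in zip(onsets, amps):
        dt = t_min - u
        out += np.where(dt >= 0, a * np.exp(-lam * np.maximum(dt, 0)), 0.0)
    return out


def _meal_response(
    t_min: np.ndarray, profile: HormoneProfile, meal_times: tuple[float, ...]
) -> np.ndarray:
    """Gamma-shaped rise-and-decay response peaking at tau after each meal."""
    out = np.zeros_like(t_min, dtype=float)
    if profile.meal_amplitude <= 0:
        return out
    tau = profile.meal_tau_min
    for m in meal_times:
        dt = t_min - m
        shape = np.where(dt > 0, (dt / tau) * np.exp(1.0 - dt / tau), 0.0)
        out += profile.meal_amplitude * shape
    return out


def simulate_clean_panel(
    config: SimulationConfig = SimulationConfig(), seed: int | None = None
) -> HormonePanel:
    """Generate an error-free panel; bit-reproducible from the seed."""
    rng = np.random.default_rng(seed)
    t_min = np.arange(config.n_timepoints) * float(config.step_minutes)
    clock = _clock_hours(t_min)
    frames = {}
    for pid in range(1, config.n_participants + 1):
        participant = f"P{pid:02d}"
        cols = {}
        for h, prof in config.profiles.items():
            circ = 1.0 + prof.circadian_amplitude * np.cos(
                2 * np.pi * (clock - prof.acrophase_hour) / 24.0
            )
            signal = (
                prof.baseline * circ
                + _pulse_train(t_min, prof, rng)
                + _meal_response(t_min, prof, config.meal_times_min)
            )
            if (signal <= 0).any():
                raise ValueError(
                    f"profile for {h} produced non-positive concentrations"
                )
            if prof.cv > 0:
                sigma = np.sqrt(np.log1p(prof.cv**2))
                noise = np.exp(
                    rng.normal(0.0, sigma, size=len(t_min)) - sigma**2 / 2.0
                )
                signal = signal * noise
            cols[h] = signal
        frames[participant] = pd.DataFrame(
            cols, index=np.arange(config.n_timepoints)
        )
    values = pd.concat(frames, names=["participant", "time"])
    return HormonePanel(values=values, step_minutes=config.step_minutes)


def inject_errors(
    panel: HormonePanel,
    spec: ErrorSpec = ErrorSpec(),
    seed: int | None = None,
) -> tuple[HormonePanel, SimulationTruth]:
    """Overlay spikes, drops and tube dilutions; return panel + ground truth.

    Dilution multiplies every hormone of the tube group at the chosen time
    point by one shared factor and takes precedence over spike/drop
    assignments at the same point.  A factor of exactly 1.0 would leave the
    value unchanged and is not recorded as an error.
    """
    rng = np.random.default_rng(seed)
    out = panel.copy()
    idx, cols = panel.values.index, panel.values.columns
    mask = pd.DataFrame(False, index=idx, columns=cols)
    etype = pd.DataFrame(None, index=idx, columns=cols, dtype=object)
    dilution_factors: dict[tuple, float] = {}

    # tube-level dilutions first (they take precedence)
    for p in panel.participants:
        times = panel.values.loc[p].index.to_numpy()
        hit = times[rng.random(len(times)) < spec.dilution_rate]
        for t in hit:
            factor = float(rng.uniform(*spec.dilution_factor))
            if factor == 1.0:
                continue
            observed = panel.values.loc[(p, t)].notna()
            tube_cols = [h for h in cols if observed[h]]
            if not tube_cols:
                continue
            out.values.loc[(p, t), tube_cols] = (
                panel.values.loc[(p, t), tube_cols] * factor
            )
            mask.loc[(p, t), tube_cols] = True
            etype.loc[(p, t), tube_cols] = "dilution"
            dilution_factors[(p, t)] = factor

    # isolated single-point spikes and drops
    flat_obs = panel.values.notna() & ~mask
    draws = rng.random(panel.values.shape)
    kinds = rng.random(panel.values.shape)
    p_total = spec.spike_rate + spec.drop_rate
    p_spike = spec.spike_rate / p_total if p_total > 0 else 0.0
    for j, h in enumerate(cols):
        sel = flat_obs[h].to_numpy() & (draws[:, j] < p_total)
        for i in np.flatnonzero(sel):
            key = idx[i]
            is_spike = kinds[i, j] < p_spike
            factor = float(
                rng.uniform(*(spec.spike_factor if is_spike else spec.drop_factor))
            )
            if factor == 1.0:
                continue
            out.values.loc[key, h] = panel.values.loc[key, h] * factor
            mask.loc[key, h] = True
            etype.loc[key, h] = "spike" if is_spike else "drop"

    truth = SimulationTruth(
        error_mask=mask, error_type=etype, dilution_factors=dilution_factors
    )
    log.info(
        "injected %d errors (%d dilution tubes) into %d points",
        truth.n_errors(), len(dilution_factors), panel.n_nonmissing(),
    )
    return out, truth


def simulate_panel(
    config: SimulationConfig = SimulationConfig(), seed: int | None = None
) -> tuple[HormonePanel, SimulationTruth]:
    """Clean simulation + error injection with seeds derived from one seed."""
    ss = np.random.SeedSequence(seed)
    s_clean, s_err = ss.spawn(2)
    panel = simulate_clean_panel(config, seed=s_clean)
    return inject_errors(panel, config.errors, seed=s_err)
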