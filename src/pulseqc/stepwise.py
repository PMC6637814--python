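"""Stepwise outlier detection combining statistical and physiological rules.

The procedure runs in two passes over each participant's panel:

1.  Fit the moving-average smooth and standardize residuals per
    (participant, hormone) series.
2.  Within-hormone rule: flag z < −3 or z > 4.  The asymmetric cutoffs
    reflect pulsatile secretion — rapid rises are biologically plausible,
    rapid falls are not.  Additionally any glucose reading below
    2.8 mmol/L is flagged: such hypoglycaemia does not occur in healthy
    adults without an accompanying stress response.
3.  Cross-hormone (dilution) rule: at each time point, sum the standardized
    residuals of all hormones sharing the serum tube; a sum below −8 means
    the five residuals average below the standard-normal 5th percentile
    (≈1.64 SD) — the signature of a diluted sample — and every point in
    that tube is flagged.
4.  Flagged points are set missing, the smooth is refitted, and the fit +
    cross-hormone rules (steps 1 and 3) run once more.  The final flag set
    is the union of both passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_CROSS_SUM,
    DEFAULT_GLUCOSE_FLOOR,
    DEFAULT_LOG_HORMONES,
    DEFAULT_LOWER_Z,
    DEFAULT_SMOOTHER,
    DEFAULT_UPPER_Z,
    DEFAULT_WINDOW,
    log,
)
from .panel import HormonePanel, OutlierResult
from .smoothing import compute_residuals

__all__ = [
    "StepwiseParams",
    "flag_within",
    "flag_glucose_floor",
    "flag_cross",
    "detect_stepwise",
]


@dataclass(frozen=True)
class StepwiseParams:
    lower_z: float = DEFAULT_LOWER_Z
    upper_z: float = DEFAULT_UPPER_Z
    glucose_floor: float = DEFAULT_GLUCOSE_FLOOR
    cross_sum_threshold: float = DEFAULT_CROSS_SUM
    iterate: bool = True
    iterate_within: bool = False  # reapply the within-hormone cutoffs in pass 2
    cross_hormone_set: tuple[str, ...] | None = None  # None = all panel hormones

    def __post_init__(self) -> None:
        if not (self.lower_z < 0 < self.upper_z):
            raise ValueError("need lower_z < 0 < upper_z")
        if not self.cross_sum_threshold < 0:
            raise ValueError("cross_sum_threshold must be negative")


def flag_within(zresiduals, lower_z: float = DEFAULT_LOWER_Z,
                upper_z: float = DEFAULT_UPPER_Z) -> np.ndarray:
    """Flag standardized residuals strictly below lower_z or above upper_z."""
    z = np.asarray(zresiduals, dtype=float)
    with np.errstate(invalid="ignore"):
        out = (z < lower_z) | (z > upper_z)
    out[~np.isfinite(z)] = False
    return out


def flag_glucose_floor(
    panel: HormonePanel, floor: float = DEFAULT_GLUCOSE_FLOOR
) -> pd.DataFrame:
    """Flag glucose readings strictly below the physiological floor.

    Only the glucose point itself is flagged; other hormones in the tube
    are untouched by this rule.  Panels without glucose yield an empty flag
    frame and a warning.
    """
    flags = pd.DataFrame(False, index=panel.values.index, columns=panel.hormones)
    if "glucose" not in panel.hormones:
        log.warning("panel has no glucose column; glucose-floor rule inert")
        return flags
    flags["glucose"] = (panel.values["glucose"] < floor).fillna(False)
    return flags


def flag_cross(
    zresiduals: pd.DataFrame,
    cross_hormone_set: Iterable[str] | None = None,
    cross_sum_threshold: float = DEFAULT_CROSS_SUM,
) -> pd.DataFrame:
    """Cross-hormone dilution rule on one participant's z-residual block.

    At each time point the z-residuals of the cross set are summed (missing
    hormones contribute 0, not rescaled — the threshold is calibrated to a
    full five-hormone tube); if the sum is strictly below the threshold,
    every non-missing point of the cross set at that time is flagged.
    """
    cols = list(cross_hormone_set) if cross_hormone_set else list(zresiduals.columns)
    if len(cols) < 2:
        raise ValueError("cross-hormone rule needs >= 2 hormones")
    block = zresiduals[cols]
    sums = block.sum(axis=1, skipna=True)  # missing contribute 0
    n_present = block.notna().sum(axis=1)
    incomplete = int(((n_present > 0) & (n_present < len(cols))).sum())
    if incomplete:
        log.warning("%d time points have an incomplete cross-hormone set", incomplete)
    hit = (sums < cross_sum_threshold) & (n_present > 0)
    flags = pd.DataFrame(False, index=zresiduals.index, columns=zresiduals.columns)
    flags.loc[hit, cols] = block.loc[hit].notna()
    return flags


def _pass_flags(
    panel: HormonePanel,
    params: StepwiseParams,
    window: int,
    smoother: str,
    log_hormones: Iterable[str],
    within: bool,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One detection pass; returns (within ∪ glucose flags, cross flags)."""
    resid = compute_residuals(panel, window=window, smoother=smoother,
                              log_hormones=log_hormones)
    point = pd.DataFrame(False, index=panel.values.index, columns=panel.hormones)
    if within:
        z = resid.zresidual
        with np.errstate(invalid="ignore"):
            point |= ((z < params.lower_z) | (z > params.upper_z)).fillna(False)
    cross = pd.DataFrame(False, index=panel.values.index, columns=panel.hormones)
    cols = list(params.cross_hormone_set) if params.cross_hormone_set else panel.hormones
    cols = [c for c in cols if c in panel.hormones]
    for p in panel.participants:
        block = resid.zresidual.loc[p]
        cflags = flag_cross(block, cols, params.cross_sum_threshold)
        cross.loc[(p, block.index), :] = cflags.to_numpy()
    return point, cross


def detect_stepwise(
    panel: HormonePanel,
    params: StepwiseParams = StepwiseParams(),
    window: int = DEFAULT_WINDOW,
    smoother: str = DEFAULT_SMOOTHER,
    log_hormones: Iterable[str] = DEFAULT_LOG_HORMONES,
) -> OutlierResult:
    """Run the full two-pass stepwise detector.

    Pass 1 applies the within-hormone cutoffs, the glucose floor and the
    cross-hormone rule.  Detected points are then treated as missing, the
    smooth is refitted on the reduced data (standardization recomputed),
    and the cross-hormone rule runs once more (the within-hormone cutoffs
    are reapplied only if ``params.iterate_within``).  Flags are the union
    of both passes; ``step_labels`` records which rule flagged each point
    first (within | glucose | cross | within_pass2 | cross_pass2).
    """
    within1, cross1 = _pass_flags(panel, params, window, smoother, log_hormones,
                                  within=True)
    glucose = flag_glucose_floor(panel, params.glucose_floor)

    labels = pd.DataFrame(None, index=panel.values.index, columns=panel.hormones,
                          dtype=object)
    labels = labels.mask(cross1, "cross")
    labels = labels.mask(glucose & labels.isna(), "glucose")
    labels = labels.mask(within1 & labels.isna(), "within")
    pass1 = within1 | glucose | cross1

    total = pass1.copy()
    if params.iterate:
        reduced = panel.copy()
        reduced.values = reduced.values.mask(pass1)
        within2, cross2 = _pass_flags(
            reduced, params, window, smoother, log_hormones,
            within=params.iterate_within,
        )
        labels = labels.mask(cross2 & labels.isna(), "cross_pass2")
        if params.iterate_within:
            labels = labels.mask(within2 & labels.isna(), "within_pass2")
        total = pass1 | within2 | cross2

    n1, n2 = int(pass1.sum().sum()), int(total.sum().sum())
    log.info("stepwise: %d flags in pass 1, %d after pass 2", n1, n2)
    return OutlierResult(
        method="stepwise",
        params={
            "lower_z": params.lower_z,
            "upper_z": params.upper_z,
            "glucose_floor": params.glucose_floor,
            "cross_sum_threshold": params.cross_sum_threshold,
            "iterate": params.iterate,
            "iterate_within": params.iterate_within,
            "window": window,
            "smoother": smoother,
            "log_hormones": list(log_hormones),
        },
        flags=total,
        step_labels=labels,
    )
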