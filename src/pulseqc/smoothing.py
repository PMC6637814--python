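"""Trend fitting and residual computation for per-person hormone series.

Each (participant, hormone) series is smoothed with a centered moving
average (or moving median) of odd window width; the residual of a point is
its vertical distance to the fitted curve on the analysis scale (natural
log for skewed hormones such as insulin and GH).  Residuals are then
standardized within the series to mean 0, SD 1 — the common currency of the
downstream detectors.

Boundary handling: windows shrink at the series ends (the first point's
window covers only itself and its right-hand neighbours), and missing
values inside a window are simply skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_LOG_HORMONES, DEFAULT_SMOOTHER, DEFAULT_WINDOW, log
from .panel import HormonePanel

__all__ = [
    "ResidualPanel",
    "log_transform_panel",
    "moving_average",
    "moving_median",
    "compute_residuals",
]


@dataclass
class ResidualPanel:
    """Fitted smooth, raw residuals and standardized residuals.

    All three frames share the source panel's (participant, time) ×
    hormone shape.  ``scale`` records, per hormone, whether the analysis
    scale is linear or log; ``constant_series`` lists (participant, hormone)
    pairs whose residuals were identically zero (their z-residuals are
    reported as 0 rather than NaN).
    """

    smooth: pd.DataFrame
    residual: pd.DataFrame
    zresidual: pd.DataFrame
    scale: dict[str, str]
    window: int
    smoother: str = DEFAULT_SMOOTHER
    constant_series: list[tuple] = field(default_factory=list)


def log_transform_panel(
    panel: HormonePanel, hormones: Iterable[str] = DEFAULT_LOG_HORMONES
) -> HormonePanel:
    """Natural-log transform the selected hormones' values.

    Raises on non-positive values in a selected hormone (after
    detection-limit substitution all concentrations are strictly positive).
    """
    out = panel.copy()
    for h in hormones:
        if h not in out.hormones:
            continue
        col = out.values[h]
        bad = col[col <= 0]
        if len(bad):
            raise ValueError(
                f"cannot log-transform {h}: non-positive value at "
                f"{bad.index[0]} ({bad.iloc[0]})"
            )
        out.values[h] = np.log(col)
    return out


def _check_window(window: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")


def _rolling(values: Sequence[float], window: int, kind: str) -> np.ndarray:
    s = pd.Series(np.asarray(values, dtype=float))
    roll = s.rolling(window, center=True, min_periods=1)
    out = roll.mean() if kind == "mean" else roll.median()
    return out.to_numpy()


def moving_average(values: Sequence[float], window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centered moving average with truncated windows and NaN skipping.

    The value at index i is the mean of the non-missing observations with
    indices in [i − (w−1)/2, i + (w−1)/2] ∩ [0, n−1]; it is NaN only when
    that whole window is missing.
    """
    _check_window(window)
    return _rolling(values, window, "mean")


def moving_median(values: Sequence[float], window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centered moving median; same window/missing semantics as the mean."""
    _check_window(window)
    return _rolling(values, window, "median")


def _standardize(resid: pd.Series) -> tuple[pd.Series, bool]:
    """Series-wise z-scores with sample SD (n−1); constant series → zeros."""
    obs = resid.dropna()
    sd = obs.std(ddof=1)
    if len(obs) < 2 or not np.isfinite(sd) or sd == 0:
        z = resid.where(resid.isna(), 0.0)
        return z, True
    return (resid - obs.mean()) / sd, False


def compute_residuals(
    panel: HormonePanel,
    window: int = DEFAULT_WINDOW,
    smoother: str = DEFAULT_SMOOTHER,
    log_hormones: Iterable[str] = DEFAULT_LOG_HORMONES,
) -> ResidualPanel:
    """Fit the smooth and compute (standardized) residuals per series.

    The smooth is fitted on the analysis scale — log for the hormones in
    ``log_hormones`` — and residuals are observed(analysis scale) − smooth.
    Standardization uses each (participant, hormone) series' own mean and
    sample SD over its full 24 h.  Series with fewer non-missing points than
    the window get all-missing residuals and a warning.
    """
    _check_window(window)
    if smoother not in ("mean", "median"):
        raise ValueError(f"smoother must be 'mean' or 'median', got {smoother!r}")
    log_hormones = [h for h in log_hormones if h in panel.hormones]
    analysis = log_transform_panel(panel, log_hormones)

    smooth = pd.DataFrame(np.nan, index=panel.values.index, columns=panel.hormones)
    residual = smooth.copy()
    zresidual = smooth.copy()
    constant: list[tuple] = []

    for p in panel.participants:
        block = analysis.values.loc[p]
        for h in panel.hormones:
            series = block[h]
            n_obs = int(series.notna().sum())
            if n_obs == 0:
                continue
            if n_obs < window:
                log.warning(
                    "series (%s, %s) has %d < window=%d observations; "
                    "residuals left missing",
                    p, h, n_obs, window,
                )
                continue
            fit = _rolling(series.to_numpy(), window, smoother)
            fit = pd.Series(fit, index=series.index).where(series.notna())
            res = series - fit
            z, is_const = _standardize(res)
            if is_const:
                constant.append((p, h))
            smooth.loc[(p, series.index), h] = fit.to_numpy()
            residual.loc[(p, series.index), h] = res.to_numpy()
            zresidual.loc[(p, series.index), h] = z.to_numpy()

    if constant:
        log.info("%d constant series (zresidual set to 0): %s", len(constant), constant[:5])
    scale = {h: ("log" if h in log_hormones else "linear") for h in panel.hormones}
    return ResidualPanel(
        smooth=smooth,
        residual=residual,
        zresidual=zresidual,
        scale=scale,
        window=window,
        smoother=smoother,
        constant_series=constant,
    )
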