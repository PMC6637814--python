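"""Tukey's-fences outlier detection on moving-average residuals.

For each (participant, hormone) series the raw residuals from the fitted
smooth are summarized by their quartiles; points falling outside the fences
— k interquartile ranges from the center — are flagged.  Two fence
conventions exist in practice and both are supported: centered on the
median (Q2 ± k·IQR) or anchored on the quartiles (Q1 − k·IQR, Q3 + k·IQR).
The default is k = 3 ("far out") around the median.  Fences are
scale-equivariant, so raw rather than standardized residuals are used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_LOG_HORMONES,
    DEFAULT_SMOOTHER,
    DEFAULT_TUKEY_CENTER,
    DEFAULT_TUKEY_K,
    DEFAULT_WINDOW,
    log,
)
from .panel import HormonePanel, OutlierResult
from .smoothing import compute_residuals

__all__ = ["TukeyParams", "tukey_flags", "detect_tukey"]


@dataclass(frozen=True)
class TukeyParams:
    """Fence width k, fence center convention, and quantile rule."""

    k: float = DEFAULT_TUKEY_K
    center: str = DEFAULT_TUKEY_CENTER  # "median" or "quartiles"
    quantile_method: str = "linear"  # numpy interpolation rule

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if self.center not in ("median", "quartiles"):
            raise ValueError(f"center must be 'median' or 'quartiles', got {self.center!r}")


def tukey_flags(residuals, params: TukeyParams = TukeyParams()) -> np.ndarray:
    """Flag residuals lying strictly outside the fences.

    center="median" flags r < Q2 − k·IQR or r > Q2 + k·IQR;
    center="quartiles" flags r < Q1 − k·IQR or r > Q3 + k·IQR.
    Missing residuals are never flagged.  If all residuals are identical
    (IQR = 0) the fences are degenerate and any r ≠ Q2 is flagged.
    """
    r = np.asarray(residuals, dtype=float)
    obs = r[np.isfinite(r)]
    if len(obs) < 4:
        raise ValueError(f"need >= 4 non-missing residuals, got {len(obs)}")
    q1, q2, q3 = np.quantile(obs, [0.25, 0.5, 0.75], method=params.quantile_method)
    iqr = q3 - q1
    if iqr == 0:
        log.warning("degenerate fences (IQR=0); flagging any residual != median")
    if params.center == "median":
        lo, hi = q2 - params.k * iqr, q2 + params.k * iqr
    else:
        lo, hi = q1 - params.k * iqr, q3 + params.k * iqr
    with np.errstate(invalid="ignore"):
        out = (r < lo) | (r > hi)
    out[~np.isfinite(r)] = False
    return out


def detect_tukey(
    panel: HormonePanel,
    params: TukeyParams = TukeyParams(),
    window: int = DEFAULT_WINDOW,
    smoother: str = DEFAULT_SMOOTHER,
    log_hormones: Iterable[str] = DEFAULT_LOG_HORMONES,
) -> OutlierResult:
    """Run Tukey's fences per (participant, hormone) on smoothing residuals."""
    resid = compute_residuals(panel, window=window, smoother=smoother,
                              log_hormones=log_hormones)
    flags = pd.DataFrame(False, index=panel.values.index, columns=panel.hormones)
    for p in panel.participants:
        block = resid.residual.loc[p]
        for h in panel.hormones:
            r = block[h]
            if r.notna().sum() < 4:
                continue
            flags.loc[(p, r.index), h] = tukey_flags(r.to_numpy(), params)
    return OutlierResult(
        method="tukey",
        params={
            "k": params.k,
            "center": params.center,
            "quantile_method": params.quantile_method,
            "window": window,
            "smoother": smoother,
            "log_hormones": list(log_hormones),
        },
        flags=flags,
    )
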