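"""Method-comparison statistics for outlier-detection results.

Covers the descriptive layer used to compare detectors: outlier counts per
time point and per data point (mean ± SD across participants), before/after
summary statistics of the hormone levels (with probability-weighted variants
for the EM detector, weight w = 1 − P(outlier)), lagged cross-correlation
between two hormones, Venn-region overlap counts between methods, and
sensitivity/specificity/precision against simulated ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .config import DEFAULT_MAX_LAG_MINUTES, log
from .panel import HormonePanel, OutlierResult
from .simulate import SimulationTruth

__all__ = [
    "MethodComparison",
    "CrossCorrelationResult",
    "count_outliers",
    "descriptives",
    "cross_correlation",
    "overlap_counts",
    "detection_performance",
]


@dataclass
class MethodComparison:
    """Flag-count summary for one method, averaged over participants."""

    method: str
    pct_timepoints_mean: float
    pct_timepoints_sd: float
    pct_datapoints_mean: float
    pct_datapoints_sd: float
    per_hormone_mean: dict[str, float]
    per_participant: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "pct_timepoints": self.pct_timepoints_mean,
            "pct_timepoints_sd": self.pct_timepoints_sd,
            "pct_datapoints": self.pct_datapoints_mean,
            "pct_datapoints_sd": self.pct_datapoints_sd,
            "per_hormone_mean": self.per_hormone_mean,
        }


@dataclass
class CrossCorrelationResult:
    """Lagged Pearson correlations between two series.

    Lag convention: lag L (minutes) pairs x(t) with y(t + L).  A negative
    ``lag_at_max`` therefore means the correlation peaks with y shifted
    earlier in time relative to x.
    """

    lags_min: np.ndarray
    correlations: np.ndarray
    lag0: float
    max_correlation: float
    lag_at_max: float


def count_outliers(panel: HormonePanel, result: OutlierResult) -> MethodComparison:
    """Percent time points with ≥1 flagged hormone and percent flagged data
    points, computed per participant and then averaged (mean, SD)."""
    rows = []
    for p in panel.participants:
        obs = panel.values.loc[p].notna()
        fl = result.flags.loc[p] & obs
        tp_with_data = int((obs.any(axis=1)).sum())
        tp_flagged = int((fl.any(axis=1)).sum())
        n_obs = int(obs.sum().sum())
        n_flag = int(fl.sum().sum())
        rows.append(
            {
                "participant": p,
                "pct_timepoints": 100.0 * tp_flagged / tp_with_data if tp_with_data else np.nan,
                "pct_datapoints": 100.0 * n_flag / n_obs if n_obs else np.nan,
                **{f"n_{h}": int(fl[h].sum()) for h in panel.hormones},
            }
        )
    per_part = pd.DataFrame(rows).set_index("participant")
    return MethodComparison(
        method=result.method,
        pct_timepoints_mean=float(per_part["pct_timepoints"].mean()),
        pct_timepoints_sd=float(per_part["pct_timepoints"].std(ddof=1)),
        pct_datapoints_mean=float(per_part["pct_datapoints"].mean()),
        pct_datapoints_sd=float(per_part["pct_datapoints"].std(ddof=1)),
        per_hormone_mean={h: float(per_part[f"n_{h}"].mean()) for h in panel.hormones},
        per_participant=per_part,
    )


def _weighted_stats(x: np.ndarray, w: np.ndarray) -> dict[str, float]:
    sw = w.sum()
    if sw <= 0:
        return {k: np.nan for k in ("mean", "median", "min", "max", "sd")}
    mean = float((w * x).sum() / sw)
    var = float((w * (x - mean) ** 2).sum() / sw)
    heavy = x[w > 0.5]  # order statistics need a point set, not weights
    return {
        "mean": mean,
        "sd": float(np.sqrt(var)),
        "median": float(np.median(heavy)) if len(heavy) else np.nan,
        "min": float(np.min(heavy)) if len(heavy) else np.nan,
        "max": float(np.max(heavy)) if len(heavy) else np.nan,
    }


def descriptives(
    panel: HormonePanel,
    result: OutlierResult | None = None,
    weighted: bool = False,
) -> pd.DataFrame:
    """Per-hormone mean/median/min/max (and SD), per participant then
    averaged across participants, on the original concentration scale.

    With a boolean-flag result, flagged points are removed first.  With
    ``weighted=True`` (EM), each point enters with weight 1 − P(outlier):
    the mean/SD are weight-weighted and the order statistics are computed
    over points with weight > 0.5.
    """
    if weighted and (result is None or result.probabilities is None):
        raise ValueError("weighted descriptives need a probabilistic result")
    rows = []
    for p in panel.participants:
        block = panel.values.loc[p]
        for h in panel.hormones:
            x = block[h].dropna()
            if result is not None and not weighted:
                fl = result.flags.loc[p, h].reindex(x.index).fillna(False)
                x = x[~fl.astype(bool)]
            if len(x) == 0:
                log.warning("participant %s hormone %s: no points left", p, h)
                continue
            if weighted:
                w = 1.0 - result.probabilities.loc[p, h].reindex(x.index).to_numpy()
                stats = _weighted_stats(x.to_numpy(), np.nan_to_num(w, nan=1.0))
            else:
                v = x.to_numpy()
                stats = {
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
                    "median": float(np.median(v)),
                    "min": float(v.min()),
                    "max": float(v.max()),
                }
            rows.append({"participant": p, "hormone": h, **stats})
    per_part = pd.DataFrame(rows)
    out = (
        per_part.groupby("hormone", sort=False)[["mean", "median", "min", "max", "sd"]]
        .agg(["mean", "std"])
    )
    out.columns = [f"{stat}_{agg}" for stat, agg in out.columns]
    return out


def _pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray | None) -> float:
    if w is None:
        w = np.ones_like(x)
    sw = w.sum()
    mx, my = (w * x).sum() / sw, (w * y).sum() / sw
    cov = (w * (x - mx) * (y - my)).sum() / sw
    vx = (w * (x - mx) ** 2).sum() / sw
    vy = (w * (y - my) ** 2).sum() / sw
    if vx <= 0 or vy <= 0:
        return np.nan
    return float(cov / np.sqrt(vx * vy))


def cross_correlation(
    x: pd.Series,
    y: pd.Series,
    max_lag_minutes: float = DEFAULT_MAX_LAG_MINUTES,
    step_minutes: int = 10,
    weights_x: pd.Series | None = None,
    weights_y: pd.Series | None = None,
    min_overlap: int = 10,
) -> CrossCorrelationResult:
    """Pearson correlation of x(t) with y(t + L) over a symmetric lag grid.

    Series are indexed by integer sample index; pairs are formed over
    pairwise-complete observations, and a lag with fewer than
    ``min_overlap`` pairs is reported missing.  The weighted variant uses
    per-pair weight w_x(t)·w_y(t+L) in weighted covariance/variances.
    """
    max_steps = int(round(max_lag_minutes / step_minutes))
    lags = np.arange(-max_steps, max_steps + 1)
    cors = np.full(len(lags), np.nan)
    xv = x.astype(float)
    yv = y.astype(float)
    for i, lag in enumerate(lags):
        # pair x(t) with y(t + lag): shift y's index back by lag steps
        y_shift = yv.copy()
        y_shift.index = y_shift.index - lag
        pair = pd.concat([xv, y_shift], axis=1, join="inner", keys=["x", "y"]).dropna()
        if len(pair) < min_overlap:
            continue
        w = None
        if weights_x is not None or weights_y is not None:
            wx = (weights_x if weights_x is not None else pd.Series(1.0, index=xv.index))
            wy = (weights_y if weights_y is not None else pd.Series(1.0, index=yv.index))
            wy = wy.copy()
            wy.index = wy.index - lag
            w = (
                wx.reindex(pair.index).fillna(1.0).to_numpy()
                * wy.reindex(pair.index).fillna(1.0).to_numpy()
            )
        cors[i] = _pearson(pair["x"].to_numpy(), pair["y"].to_numpy(), w)
    lags_min = lags * float(step_minutes)
    if np.all(np.isnan(cors)):
        raise ValueError("no lag had sufficient overlapping observations")
    imax = int(np.nanargmax(cors))
    lag0_idx = int(np.where(lags == 0)[0][0])
    return CrossCorrelationResult(
        lags_min=lags_min,
        correlations=cors,
        lag0=float(cors[lag0_idx]),
        max_correlation=float(cors[imax]),
        lag_at_max=float(lags_min[imax]),
    )


def overlap_counts(
    results: Mapping[str, OutlierResult], level: str = "datapoint"
) -> dict[str, int]:
    """Venn-region counts for 2 or 3 methods.

    level="datapoint" compares flagged (participant, time, hormone) keys;
    level="timepoint" compares (participant, time) pairs with ≥1 flagged
    hormone.  Region keys are '&'-joined method-name combinations, each
    counting keys flagged by exactly that set of methods.
    """
    names = list(results)
    if not 2 <= len(names) <= 3:
        raise ValueError("overlap_counts supports 2 or 3 methods")
    sets: dict[str, set] = {}
    for name, res in results.items():
        if level == "datapoint":
            sets[name] = res.flagged_keys()
        elif level == "timepoint":
            fl = res.flags.any(axis=1)
            sets[name] = set(fl[fl].index)
        else:
            raise ValueError(f"unknown level {level!r}")
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            regions["&".join(combo)] = len(inside - outside)
    return regions


def detection_performance(
    result: OutlierResult,
    truth: SimulationTruth,
    panel: HormonePanel,
) -> pd.DataFrame:
    """Confusion-matrix rates against simulated ground truth.

    Returns sensitivity, specificity and precision over all non-missing
    points ('overall' row) and sensitivity stratified by error type.
    """
    obs = panel.notna()
    fl = (result.flags & obs).to_numpy().ravel()
    tr = (truth.error_mask & obs).to_numpy().ravel()
    keep = obs.to_numpy().ravel()
    fl, tr = fl[keep], tr[keep]
    tp = int((fl & tr).sum())
    fp = int((fl & ~tr).sum())
    fn = int((~fl & tr).sum())
    tn = int((~fl & ~tr).sum())
    rows = [
        {
            "stratum": "overall",
            "n_true_errors": tp + fn,
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
            "precision": tp / (tp + fp) if tp + fp else np.nan,
        }
    ]
    flagged = result.flagged_keys()
    for kind in ("spike", "drop", "dilution"):
        keys = truth.keys_of_type(kind)
        keys = {k for k in keys if obs.loc[(k[0], k[1]), k[2]]}
        if not keys:
            continue
        caught = len(keys & flagged)
        rows.append(
            {
                "stratum": kind,
                "n_true_errors": len(keys),
                "sensitivity": caught / len(keys),
                "specificity": np.nan,
                "precision": np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("stratum")
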