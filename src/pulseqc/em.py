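"""Two-component Gaussian-mixture EM for probabilistic outlier scoring.

The model: standardized residuals of true measurements are approximately
normal with a small standard deviation, while residuals of erroneous
measurements are normal with a much larger one.  Fitting the two-component
univariate normal mixture by expectation-maximization yields, for every
data point, the posterior probability of belonging to the wide (error)
component.  Residuals are pooled per hormone across all participants —
a single 24-h series is too short for a stable mixture fit — and points
with posterior above 0.9 are classified as outliers; alternatively the
probabilities serve as analysis weights (w = 1 − P(outlier)) downstream.

The EM itself is written out explicitly (E-step responsibilities, M-step
weighted moment updates) rather than delegated, so the log-likelihood trace
and degeneracy handling are fully under our control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import (
    DEFAULT_EM_MAX_ITER,
    DEFAULT_EM_THRESHOLD,
    DEFAULT_EM_TOL,
    DEFAULT_LOG_HORMONES,
    DEFAULT_SMOOTHER,
    DEFAULT_WINDOW,
    log,
)
from .panel import HormonePanel, OutlierResult
from .smoothing import compute_residuals

__all__ = ["MixtureFit", "fit_two_component_em", "detect_em"]

_SD_FLOOR = 1e-6
_MAX_RESTARTS = 5


@dataclass
class MixtureFit:
    """Fitted two-component normal mixture.

    Component 0 is the narrow (true-measurement) component, component 1 the
    wide (outlier) one: ``sds[1] >= sds[0]`` after relabeling.
    ``mix_weight`` is the weight of the narrow component; ``posteriors``
    holds each point's probability of membership in the wide component.
    """

    mix_weight: float
    means: np.ndarray
    sds: np.ndarray
    posteriors: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def outlier_sd(self) -> float:
        return float(self.sds[1])

    @property
    def outlier_weight(self) -> float:
        return 1.0 - self.mix_weight

    def separation_ok(self, min_ratio: float = 1.5) -> bool:
        """Whether the two components are meaningfully distinguishable."""
        return self.sds[1] / max(self.sds[0], _SD_FLOOR) >= min_ratio


def _loglik(x: np.ndarray, w: float, mu: np.ndarray, sd: np.ndarray) -> float:
    dens = w * norm.pdf(x, mu[0], sd[0]) + (1 - w) * norm.pdf(x, mu[1], sd[1])
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def _init_params(
    x: np.ndarray, init: str, rng: np.random.Generator
) -> tuple[float, np.ndarray, np.ndarray]:
    m = float(np.mean(x))
    a = np.abs(x - m)
    if init == "quantile":
        # narrow component sized like the bulk, wide like the extreme tail
        s0 = max(float(np.quantile(a, 0.25)), _SD_FLOOR)
        s1 = max(float(np.quantile(a, 0.975)), s0 * 2)
        return 0.9, np.array([m, m]), np.array([s0, s1])
    if init == "random":
        w = rng.uniform(0.7, 0.98)
        scales = np.sort(rng.uniform(0.2, 3.0, size=2)) * max(np.std(x), _SD_FLOOR)
        mus = m + rng.normal(0, 0.1 * max(np.std(x), _SD_FLOOR), size=2)
        return float(w), mus, np.maximum(scales, _SD_FLOOR)
    raise ValueError(f"unknown init {init!r}")


def fit_two_component_em(
    residuals,
    init: str = "quantile",
    seed: int | None = None,
    tol: float = DEFAULT_EM_TOL,
    max_iter: int = DEFAULT_EM_MAX_ITER,
    fix_means_zero: bool = False,
) -> MixtureFit:
    """Fit the two-component univariate normal mixture by EM.

    Parameters
    ----------
    residuals
        Pooled (standardized) residuals; NaNs are dropped.  At least 10
        finite values with nonzero variance are required.
    init
        "quantile" (deterministic moment-based start) or "random".
    tol
        Relative log-likelihood change declaring convergence.
    fix_means_zero
        Pin both component means at 0 (both distributions centered on the
        fitted curve); otherwise means are free parameters.

    Degenerate fits (a component's SD collapsing onto a single point) are
    retried with fresh random starts, up to 5 restarts, then raise.
    """
    x = np.asarray(residuals, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise ValueError(f"need >= 10 finite residuals, got {len(x)}")
    if np.std(x) == 0:
        raise ValueError("residuals have zero variance")

    rng = np.random.default_rng(seed)
    attempt_init = init
    for attempt in range(_MAX_RESTARTS + 1):
        w, mu, sd = _init_params(x, attempt_init, rng)
        if fix_means_zero:
            mu = np.zeros(2)
        trace: list[float] = []
        converged = False
        collapsed = False
        it = 0
        for it in range(1, max_iter + 1):
            # E-step: responsibilities of the narrow component
            d0 = w * norm.pdf(x, mu[0], sd[0])
            d1 = (1 - w) * norm.pdf(x, mu[1], sd[1])
            tot = np.maximum(d0 + d1, 1e-300)
            g0 = d0 / tot
            g1 = 1.0 - g0
            # M-step: weighted moments
            n0, n1 = g0.sum(), g1.sum()
            if n0 < 1e-8 or n1 < 1e-8:
                collapsed = True
                break
            w = n0 / len(x)
            if not fix_means_zero:
                mu = np.array([(g0 * x).sum() / n0, (g1 * x).sum() / n1])
            sd = np.sqrt(
                np.array(
                    [(g0 * (x - mu[0]) ** 2).sum() / n0,
                     (g1 * (x - mu[1]) ** 2).sum() / n1]
                )
            )
            sd = np.maximum(sd, _SD_FLOOR)
            # variance collapse: a component glued to (numerically) one point
            if (sd <= _SD_FLOOR).any() and min(n0, n1) < 1.5:
                collapsed = True
                break
            ll = _loglik(x, w, mu, sd)
            trace.append(ll)
            if len(trace) > 1:
                prev = trace[-2]
                if abs(ll - prev) <= tol * (abs(prev) + 1e-12):
                    converged = True
                    break
        if not collapsed:
            break
        log.warning("EM component collapsed; restarting (%d/%d)", attempt + 1,
                    _MAX_RESTARTS)
        attempt_init = "random"
    else:
        raise RuntimeError("EM failed: component collapse after restarts")

    if not converged:
        log.warning("EM did not converge in %d iterations", max_iter)

    # relabel so the wide (outlier) component is index 1
    order = np.argsort(sd)
    mu, sd = mu[order], sd[order]
    w_narrow = w if order[0] == 0 else 1 - w
    d0 = w_narrow * norm.pdf(x, mu[0], sd[0])
    d1 = (1 - w_narrow) * norm.pdf(x, mu[1], sd[1])
    post = d1 / np.maximum(d0 + d1, 1e-300)

    fit = MixtureFit(
        mix_weight=float(w_narrow),
        means=mu,
        sds=sd,
        posteriors=post,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
    )
    if not fit.separation_ok():
        log.warning(
            "mixture components overlap (sd ratio %.2f < 1.5); "
            "the data may not contain a distinct outlier distribution",
            sd[1] / max(sd[0], _SD_FLOOR),
        )
    return fit


def detect_em(
    panel: HormonePanel,
    threshold: float = DEFAULT_EM_THRESHOLD,
    window: int = DEFAULT_WINDOW,
    smoother: str = DEFAULT_SMOOTHER,
    log_hormones: Iterable[str] = DEFAULT_LOG_HORMONES,
    init: str = "quantile",
    seed: int | None = None,
    tol: float = DEFAULT_EM_TOL,
    max_iter: int = DEFAULT_EM_MAX_ITER,
    fix_means_zero: bool = False,
) -> OutlierResult:
    """Per hormone, pool all participants' standardized residuals into one
    mixture fit and map the wide-component posteriors back to data points.

    Flags are ``P(outlier) > threshold`` (default 0.9).
    """
    resid = compute_residuals(panel, window=window, smoother=smoother,
                              log_hormones=log_hormones)
    probs = pd.DataFrame(np.nan, index=panel.values.index, columns=panel.hormones)
    fits: dict[str, MixtureFit] = {}
    for h in panel.hormones:
        z = resid.zresidual[h]
        obs = z.dropna()
        if len(obs) < 10 or obs.std() == 0:
            log.warning("hormone %s: too few residuals for a mixture fit", h)
            continue
        fit = fit_two_component_em(obs.to_numpy(), init=init, seed=seed,
                                   tol=tol, max_iter=max_iter,
                                   fix_means_zero=fix_means_zero)
        fits[h] = fit
        probs.loc[obs.index, h] = fit.posteriors
    flags = (probs > threshold).fillna(False)
    result = OutlierResult(
        method="em",
        params={
            "threshold": threshold,
            "window": window,
            "smoother": smoother,
            "log_hormones": list(log_hormones),
            "init": init,
            "seed": seed,
            "tol": tol,
            "max_iter": max_iter,
            "fix_means_zero": fix_means_zero,
        },
        flags=flags,
        probabilities=probs,
        threshold=threshold,
    )
    result.fits = fits  # per-hormone MixtureFit diagnostics
    return result
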