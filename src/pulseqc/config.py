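"""Default parameters and logging setup shared across the package.

Every number here mirrors the published analysis defaults: a 5-point
moving-average window, Tukey ``k = 3``, stepwise cutoffs −3/+4 SD, the
2.8 mmol/L physiological glucose floor, the −8 cross-hormone residual-sum
threshold, and the 0.9 posterior-probability cutoff for the EM classifier.
"""

from __future__ import annotations

import logging

log = logging.getLogger("pulseqc")

#: Canonical hormone order used throughout (all measured from one serum tube).
HORMONES = ["glucose", "insulin", "TSH", "cortisol", "GH"]

#: Hormones whose skewed distributions are log-transformed before smoothing.
DEFAULT_LOG_HORMONES = ("insulin", "GH")

DEFAULT_UNITS = {
    "glucose": "mmol/L",
    "insulin": "mU/L",
    "TSH": "mU/L",
    "cortisol": "umol/L",
    "GH": "mU/L",
}

#: All five hormones share the serum tube, so a dilution hits all of them.
DEFAULT_TUBE_GROUPS = {h: "serum" for h in HORMONES}

DEFAULT_STEP_MINUTES = 10
DEFAULT_N_TIMEPOINTS = 144  # 24 h at 10-min sampling

# Smoothing
DEFAULT_WINDOW = 5
DEFAULT_SMOOTHER = "mean"

# Tukey's fences
DEFAULT_TUKEY_K = 3.0
DEFAULT_TUKEY_CENTER = "median"

# Stepwise approach
DEFAULT_LOWER_Z = -3.0
DEFAULT_UPPER_Z = 4.0
DEFAULT_GLUCOSE_FLOOR = 2.8  # mmol/L
DEFAULT_CROSS_SUM = -8.0

# EM classifier
DEFAULT_EM_THRESHOLD = 0.9
DEFAULT_EM_TOL = 1e-8
DEFAULT_EM_MAX_ITER = 1000

# Evaluation
DEFAULT_MAX_LAG_MINUTES = 120


def setup_logging(level: int | str = logging.INFO) -> None:
    """Route package logs to stderr with a compact format."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)
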