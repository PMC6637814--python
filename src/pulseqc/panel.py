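"""Data model and delimited-text I/O for multi-hormone 24-h panels.

A :class:`HormonePanel` holds concentrations on a fixed 10-min sampling grid
for several participants and hormones, with an explicit missing mask (NaN).
Readers/writers round-trip long and wide CSV/TSV layouts losslessly, and
:func:`apply_detection_limits` implements the assay convention of replacing
sub-detection-limit readings by half the lower detection limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import DEFAULT_STEP_MINUTES, DEFAULT_TUBE_GROUPS, DEFAULT_UNITS, log

__all__ = [
    "HormonePanel",
    "DetectionLimits",
    "OutlierResult",
    "read_panel",
    "write_panel",
    "apply_detection_limits",
]


@dataclass
class HormonePanel:
    """Rectangular store of hormone concentrations.

    Parameters
    ----------
    values
        DataFrame indexed by a (participant, time) MultiIndex — ``time`` is
        the integer sample index on the fixed grid — with one float column
        per hormone.  NaN marks a missing measurement.
    step_minutes
        Spacing of the sampling grid in minutes.
    units
        Hormone → unit string.
    tube_groups
        Hormone → tube label.  Hormones sharing a tube are co-flagged by
        dilution rules.
    """

    values: pd.DataFrame
    step_minutes: int = DEFAULT_STEP_MINUTES
    units: dict[str, str] = field(default_factory=dict)
    tube_groups: dict[str, str] = field(default_factory=dict)
    below_limit: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values.index, pd.MultiIndex):
            raise ValueError("values must be indexed by (participant, time)")
        self.values.index = self.values.index.set_names(["participant", "time"])
        self.values = self.values.astype(float)
        self.validate()
        if not self.units:
            self.units = {h: DEFAULT_UNITS.get(h, "") for h in self.hormones}
        if not self.tube_groups:
            self.tube_groups = {
                h: DEFAULT_TUBE_GROUPS.get(h, "serum") for h in self.hormones
            }

    # -- basic views ----------------------------------------------------

    @property
    def participants(self) -> list:
        return list(self.values.index.get_level_values("participant").unique())

    @property
    def hormones(self) -> list[str]:
        return list(self.values.columns)

    @property
    def time_index(self) -> np.ndarray:
        return np.asarray(sorted(self.values.index.get_level_values("time").unique()))

    def series(self, participant, hormone: str) -> pd.Series:
        """One participant's series for one hormone, indexed by time."""
        return self.values.loc[participant][hormone]

    def n_nonmissing(self) -> int:
        return int(self.values.notna().sum().sum())

    def notna(self) -> pd.DataFrame:
        return self.values.notna()

    def validate(self) -> None:
        vals = self.values.to_numpy()
        finite = np.isfinite(vals) | np.isnan(vals)
        if not finite.all():
            raise ValueError("panel contains non-finite, non-missing values")
        if np.nanmin(vals, initial=0.0) < 0:
            bad = self.values[(self.values < 0).any(axis=1)]
            raise ValueError(f"negative concentrations at {bad.index[0]}")
        for p in self.values.index.get_level_values("participant").unique():
            t = self.values.loc[p].index.to_numpy()
            if len(t) > 1:
                d = np.diff(t)
                if (d <= 0).any() or len(set(d)) > 1:
                    raise ValueError(
                        f"time index for participant {p!r} is not strictly "
                        "increasing and equally spaced"
                    )

    def copy(self) -> "HormonePanel":
        return replace(
            self,
            values=self.values.copy(),
            units=dict(self.units),
            tube_groups=dict(self.tube_groups),
            below_limit=None if self.below_limit is None else self.below_limit.copy(),
        )

    def equals(self, other: "HormonePanel") -> bool:
        return (
            self.values.equals(other.values)
            and self.step_minutes == other.step_minutes
        )


@dataclass(frozen=True)
class DetectionLimits:
    """Lower detection limits per hormone, in panel units."""

    limits: Mapping[str, float]

    def __post_init__(self) -> None:
        for h, lim in self.limits.items():
            if not lim > 0:
                raise ValueError(f"detection limit for {h} must be > 0, got {lim}")

    def __getitem__(self, hormone: str) -> float:
        return self.limits[hormone]

    def __contains__(self, hormone: str) -> bool:
        return hormone in self.limits


@dataclass
class OutlierResult:
    """Per-point outlier calls from one detector.

    ``flags`` is boolean and aligned 1:1 with the source panel; it is True
    only at non-missing points.  Probabilistic detectors additionally carry
    per-point outlier ``probabilities`` and the ``threshold`` that produced
    the flags.  ``step_labels`` records, for multi-rule detectors, which
    rule first flagged each point.
    """

    method: str
    params: dict
    flags: pd.DataFrame
    probabilities: pd.DataFrame | None = None
    threshold: float | None = None
    step_labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.flags = self.flags.astype(bool)
        if self.probabilities is not None and self.threshold is not None:
            implied = (self.probabilities > self.threshold).fillna(False)
            if not implied.equals(self.flags):
                raise ValueError("flags inconsistent with probabilities/threshold")

    def n_flagged(self) -> int:
        return int(self.flags.sum().sum())

    def flagged_keys(self) -> set[tuple]:
        """Set of (participant, time, hormone) keys that are flagged."""
        stacked = self.flags.stack()
        return set(stacked[stacked].index)

    def to_frame(self, panel: HormonePanel) -> pd.DataFrame:
        """Long-format table over the panel's non-missing points:
        participant, time_min, hormone, flag [, p_outlier] [, step_label]."""
        out = self.flags.stack(future_stack=True).rename("flag").reset_index()
        out.columns = ["participant", "time", "hormone", "flag"]
        out["time_min"] = out["time"] * panel.step_minutes
        cols = ["participant", "time_min", "hormone", "flag"]
        if self.probabilities is not None:
            out["p_outlier"] = (
                self.probabilities.stack(future_stack=True).reset_index(drop=True)
            )
            cols.append("p_outlier")
        if self.step_labels is not None:
            out["step_label"] = (
                self.step_labels.stack(future_stack=True).reset_index(drop=True)
            )
            cols.append("step_label")
        observed = panel.notna().stack(future_stack=True).reset_index(drop=True)
        return out[cols][observed.to_numpy()].reset_index(drop=True)


# -- I/O ----------------------------------------------------------------

_LONG_COLS = ("participant", "time_min", "hormone", "value")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_panel(
    path: str | Path,
    layout: str = "long",
    schema: Mapping[str, str] | None = None,
    step_minutes: int = DEFAULT_STEP_MINUTES,
    units: Mapping[str, str] | None = None,
    tube_groups: Mapping[str, str] | None = None,
    hormones: Iterable[str] | None = None,
) -> HormonePanel:
    """Read a long- or wide-layout delimited panel file.

    Long layout needs columns participant, time_min, hormone, value (renamed
    through ``schema`` if the file uses other headers).  Wide layout needs
    participant, time_min plus one column per hormone.  Empty cells are
    missing.  Duplicate (participant, time, hormone) keys and non-numeric
    values are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={0: object})
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})

    if layout == "long":
        missing_cols = [c for c in _LONG_COLS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"long layout requires columns {missing_cols}")
        bad = df[pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value {bad['value'].iloc[0]!r} at row {bad.index[0] + 2}"
            )
        df["value"] = pd.to_numeric(df["value"])
        keys = df[["participant", "time_min", "hormone"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (participant, time, hormone) key: {dup}")
        wide = df.pivot(
            index=["participant", "time_min"], columns="hormone", values="value"
        )
        if hormones is not None:
            wide = wide.reindex(columns=list(hormones))
        wide.columns.name = None
    elif layout == "wide":
        for c in ("participant", "time_min"):
            if c not in df.columns:
                raise ValueError(f"wide layout requires column {c!r}")
        if df[["participant", "time_min"]].duplicated().any():
            dup = df[df[["participant", "time_min"]].duplicated()].iloc[0]
            raise ValueError(
                f"duplicate (participant, time) key: {dup['participant']}, {dup['time_min']}"
            )
        hcols = [c for c in df.columns if c not in ("participant", "time_min")]
        for c in hcols:
            coerced = pd.to_numeric(df[c], errors="coerce")
            bad = df[coerced.isna() & df[c].notna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric value {bad[c].iloc[0]!r} in column {c} "
                    f"at row {bad.index[0] + 2}"
                )
            df[c] = coerced
        wide = df.set_index(["participant", "time_min"])[hcols]
    else:
        raise ValueError(f"unknown layout {layout!r}")

    # convert clock-minutes to integer sample index on the step grid
    tmin = wide.index.get_level_values("time_min").astype(float)
    tidx = tmin / step_minutes
    if not np.allclose(tidx, np.round(tidx)):
        raise ValueError(f"time_min values are not multiples of step={step_minutes}")
    wide.index = pd.MultiIndex.from_arrays(
        [wide.index.get_level_values("participant"), np.round(tidx).astype(int)],
        names=["participant", "time"],
    )
    wide = wide.sort_index()
    return HormonePanel(
        values=wide,
        step_minutes=step_minutes,
        units=dict(units) if units else {},
        tube_groups=dict(tube_groups) if tube_groups else {},
    )


def write_panel(panel: HormonePanel, path: str | Path, layout: str = "long") -> Path:
    """Write a panel as CSV/TSV; missing values become empty cells.

    ``read_panel(write_panel(p))`` reproduces the panel exactly.
    """
    path = Path(path)
    sep = _sep_for(path)
    df = panel.values.copy()
    df.index = pd.MultiIndex.from_arrays(
        [
            df.index.get_level_values("participant"),
            df.index.get_level_values("time") * panel.step_minutes,
        ],
        names=["participant", "time_min"],
    )
    if layout == "long":
        long = df.stack(future_stack=True).rename("value").reset_index()
        long.columns = ["participant", "time_min", "hormone", "value"]
        long.to_csv(path, sep=sep, index=False)
    elif layout == "wide":
        df.reset_index().to_csv(path, sep=sep, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return path


def apply_detection_limits(
    panel: HormonePanel, limits: DetectionLimits, mode: str = "substitute"
) -> HormonePanel:
    """Handle readings below the assay's lower detection limit.

    mode="substitute" replaces values strictly below the limit with half the
    limit (the assay-lab convention); mode="flag" leaves values untouched and
    stores a boolean below-limit mask on the returned panel.  Values at or
    above the limit are never modified; the operation is idempotent.
    """
    if mode not in ("substitute", "flag"):
        raise ValueError(f"unknown mode {mode!r}")
    out = panel.copy()
    mask = pd.DataFrame(False, index=panel.values.index, columns=panel.values.columns)
    for h in panel.hormones:
        if h not in limits:
            continue
        lim = limits[h]
        below = panel.values[h] < lim  # strict; NaN compares False
        mask[h] = below.fillna(False)
        if mode == "substitute":
            out.values.loc[mask[h], h] = lim / 2.0
    if mode == "flag":
        out.below_limit = mask
    n = int(mask.sum().sum())
    if n:
        log.info("%d values below detection limit (%s mode)", n, mode)
    return out
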