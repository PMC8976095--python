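"""Plate-reader kinetics: MEFL calibration, OD normalization, endpoint
extraction, ON/OFF fold changes and cross-condition correlation.

Raw fluorescence (a.u.) is blank-subtracted and converted to Molecules of
Equivalent Fluorescein with a linear standard curve; for whole-cell runs the
signal is first normalized by OD600 (MEFL/particle).  The ON/OFF fold change
is the ratio of the replicate-mean endpoint values of the two arms, the
endpoint being the latest sample at or before the requested time (150 min by
default, matching a 2 h 30 min cell-free readout).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

OD_FLOOR = 0.01


class PlateError(ValueError):
    """Invalid plate-reader input or processing request."""


@dataclass(frozen=True)
class PlateSeries:
    """One well's kinetic trace with its condition labels."""

    well: str
    switch_id: str
    trigger_id: str          # "none" for the OFF arm
    system: str              # "in_vivo" or "cell_free"
    replicate: int
    time: np.ndarray         # minutes, strictly increasing
    fluorescence: np.ndarray
    od600: Optional[np.ndarray] = None
    units: str = "au"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)
        if t.ndim != 1 or len(t) == 0:
            raise PlateError(f"well {self.well}: empty time vector")
        if np.any(np.diff(t) <= 0):
            raise PlateError(f"well {self.well}: time must be strictly increasing")
        if len(f) != len(t):
            raise PlateError(f"well {self.well}: fluorescence/time length mismatch")
        if self.od600 is not None:
            od = np.asarray(self.od600, dtype=float)
            object.__setattr__(self, "od600", od)
            if len(od) != len(t):
                raise PlateError(f"well {self.well}: od600/time length mismatch")
        if self.replicate < 1:
            raise PlateError(f"well {self.well}: replicate must be >= 1")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear fluorescein standard curve: MEFL = slope * (reading - blank) + intercept."""

    standard_concentrations: np.ndarray
    readings: np.ndarray
    blank: float
    slope: float
    intercept: float
    fit_r2: float


@dataclass(frozen=True)
class FoldChangeResult:
    """ON/OFF ratio of replicate-mean endpoints with per-arm statistics."""

    switch_id: str
    trigger_id: str
    system: str
    mean_on: float
    mean_off: float
    fold_change: float
    sd_on: float
    sd_off: float
    n_on: int
    n_off: int
    t_end_used: float

    @property
    def n_replicates(self) -> int:
        return min(self.n_on, self.n_off)


def fit_calibration(
    standard_concentrations: Sequence[float],
    readings: Sequence[float],
    blank: float = 0.0,
) -> CalibrationCurve:
    """Ordinary least squares of concentration on blank-subtracted reading."""
    conc = np.asarray(standard_concentrations, dtype=float)
    reads = np.asarray(readings, dtype=float)
    if conc.shape != reads.shape or conc.ndim != 1:
        raise PlateError("standards and readings must be equal-length 1-D sequences")
    if len(conc) < 2:
        raise PlateError(f"need at least 2 standards, got {len(conc)}")
    if len(conc) < 3:
        warnings.warn("fewer than 3 calibration standards; fit is fragile", stacklevel=2)
    span = conc.max() / conc.min() if conc.min() > 0 else np.inf
    if span < 10:
        warnings.warn(
            "calibration standards span less than one order of magnitude", stacklevel=2
        )
    x = reads - blank
    if np.ptp(x) == 0:
        raise PlateError("constant readings: cannot fit a calibration slope")
    fit = stats.linregress(x, conc)
    if fit.slope <= 0:
        raise PlateError(
            f"non-positive calibration slope ({fit.slope:.3g}); inputs likely mislabeled"
        )
    return CalibrationCurve(
        standard_concentrations=conc,
        readings=reads,
        blank=float(blank),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        fit_r2=float(fit.rvalue**2),
    )


def convert_mefl(series: PlateSeries, curve: CalibrationCurve) -> PlateSeries:
    """Apply the standard curve element-wise; negatives clamp to 0 (count warned)."""
    values = curve.slope * (series.fluorescence - curve.blank) + curve.intercept
    n_neg = int(np.sum(values < 0))
    if n_neg:
        warnings.warn(
            f"well {series.well}: {n_neg} negative MEFL values clamped to 0",
            stacklevel=2,
        )
        values = np.clip(values, 0.0, None)
    units = "MEFL/particle" if series.units == "au/od" else "MEFL"
    return replace(series, fluorescence=values, units=units)


def normalize_by_od(series: PlateSeries, od_floor: float = OD_FLOOR) -> PlateSeries:
    """Per-particle signal: fluorescence / OD600, masking points below the OD floor."""
    if series.od600 is None:
        raise PlateError(
            f"well {series.well}: no OD600 channel; for cell-free data skip OD "
            "normalization entirely"
        )
    mask = series.od600 >= od_floor
    n_masked = int(np.sum(~mask))
    if n_masked:
        warnings.warn(
            f"well {series.well}: {n_masked} timepoints below OD floor {od_floor} masked",
            stacklevel=2,
        )
    values = np.where(mask, series.fluorescence / np.where(mask, series.od600, 1.0), np.nan)
    return replace(series, fluorescence=values, units=series.units + "/od")


def endpoint_value(series: PlateSeries, t_end: float) -> tuple[float, float]:
    """Value at the latest sample time <= t_end; returns (value, sample time used)."""
    if t_end < series.time[0]:
        raise PlateError(
            f"well {series.well}: t_end {t_end} precedes first sample {series.time[0]}"
        )
    idx = int(np.searchsorted(series.time, t_end, side="right")) - 1
    return float(series.fluorescence[idx]), float(series.time[idx])


def fold_change(
    on: Sequence[PlateSeries],
    off: Sequence[PlateSeries],
    t_end: float = 150.0,
) -> FoldChangeResult:
    """Ratio of replicate-mean endpoint values, ON over OFF.

    Both arms must have been processed identically beforehand (calibration,
    normalization).  SDs are per arm; fewer than 3 replicates triggers a
    warning rather than an error.
    """
    if not on or not off:
        raise PlateError("both arms need at least one replicate series")
    vals_on = np.array([endpoint_value(s, t_end)[0] for s in on])
    vals_off = np.array([endpoint_value(s, t_end)[0] for s in off])
    if np.any(np.isnan(vals_on)) or np.any(np.isnan(vals_off)):
        raise PlateError("endpoint falls on a masked (NaN) timepoint")
    if min(len(vals_on), len(vals_off)) < 3:
        warnings.warn("fewer than 3 replicates; reported SDs are unreliable", stacklevel=2)
    mean_off = float(vals_off.mean())
    if mean_off <= 0:
        raise PlateError(
            f"OFF-arm mean endpoint {mean_off:.4g} <= 0; cannot form a ratio "
            "(check blank subtraction)"
        )
    _, t_used = endpoint_value(on[0], t_end)
    return FoldChangeResult(
        switch_id=on[0].switch_id,
        trigger_id=on[0].trigger_id,
        system=on[0].system,
        mean_on=float(vals_on.mean()),
        mean_off=mean_off,
        fold_change=float(vals_on.mean() / mean_off),
        sd_on=float(vals_on.std(ddof=1)) if len(vals_on) > 1 else 0.0,
        sd_off=float(vals_off.std(ddof=1)) if len(vals_off) > 1 else 0.0,
        n_on=len(vals_on),
        n_off=len(vals_off),
        t_end_used=t_used,
    )


_EXACT_SPEARMAN_MAX_N = 8


def _exact_spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided permutation p-value for Spearman's rho, exhaustive over n! rankings."""
    base = np.arange(n, dtype=float)
    observed = abs(rho)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = stats.pearsonr(base, np.array(perm, dtype=float)).statistic
        if abs(r) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def condition_correlation(
    a: Sequence[FoldChangeResult],
    b: Sequence[FoldChangeResult],
) -> tuple[pd.DataFrame, float, float]:
    """Pair fold changes from two conditions by switch and rank-correlate them.

    Inner-joins on switch_id (>= 3 shared switches required) and returns the
    paired table, Spearman's rho, and a two-sided p-value (exact permutation
    null for n <= 8, large-sample approximation above).
    """
    ta = pd.DataFrame(
        {"switch_id": [r.switch_id for r in a], "fold_change_a": [r.fold_change for r in a]}
    )
    tb = pd.DataFrame(
        {"switch_id": [r.switch_id for r in b], "fold_change_b": [r.fold_change for r in b]}
    )
    paired = ta.merge(tb, on="switch_id")
    n = len(paired)
    if n < 3:
        raise PlateError(f"need >= 3 shared switch_ids, got {n}")
    res = stats.spearmanr(paired["fold_change_a"], paired["fold_change_b"])
    rho = float(res.statistic)
    if n <= _EXACT_SPEARMAN_MAX_N and not math.isnan(rho):
        pval = _exact_spearman_pvalue(rho, n)
    else:
        pval = float(res.pvalue)
    return paired, rho, pval


def series_to_frame(series: Sequence[PlateSeries]) -> pd.DataFrame:
    """Long-format export: one row per (well, timepoint)."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "well": s.well,
                    "time_min": s.time,
                    "fluorescence": s.fluorescence,
                    "od600": s.od600 if s.od600 is not None else np.nan,
                    "switch_id": s.switch_id,
                    "trigger_id": s.trigger_id,
                    "system": s.system,
                    "replicate": s.replicate,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_series(frame: pd.DataFrame) -> list[PlateSeries]:
    """Inverse of :func:`series_to_frame` (groups by well)."""
    required = {"well", "time_min", "fluorescence", "switch_id", "trigger_id", "system", "replicate"}
    if missing := required - set(frame.columns):
        raise PlateError(f"plate CSV missing columns {sorted(missing)}")
    out = []
    for well, grp in frame.groupby("well", sort=False):
        grp = grp.sort_values("time_min")
        od = None
        if "od600" in grp.columns and grp["od600"].notna().all():
            od = grp["od600"].to_numpy(dtype=float)
        out.append(
            PlateSeries(
                well=str(well),
                switch_id=str(grp["switch_id"].iloc[0]),
                trigger_id=str(grp["trigger_id"].iloc[0]),
                system=str(grp["system"].iloc[0]),
                replicate=int(grp["replicate"].iloc[0]),
                time=grp["time_min"].to_numpy(dtype=float),
                fluorescence=grp["fluorescence"].to_numpy(dtype=float),
                od600=od,
            )
        )
    return out
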