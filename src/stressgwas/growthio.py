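"""Growth-curve IO and extraction of the five per-curve growth parameters.

A growth curve is a time series of a population-density signal for one
(strain, condition, inhibitory level, replicate) well.  Five parameters are
extracted from each curve and feed the resistance scores downstream:

* ``lag_h``      lag time λ (h), Zwietering tangent construction
* ``mu_max``     maximum specific growth rate μmax (1/h), the maximal slope
                 of the natural log of the blank-subtracted signal
* ``amplitude``  maximal signal above blank A (signal units)
* ``t_half``     first time the signal reaches A/2 above blank (h)
* ``auc``        trapezoidal area under the blank-subtracted curve (signal·h)

Wells whose amplitude stays below a configurable threshold are flagged as
non-growing and receive defined worst-case sentinel values (λ = t_half = end
of observation, μmax = A = AUC = 0) so that downstream rankings are total.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "GrowthParams",
    "CurveParseError",
    "read_curves",
    "write_curves",
    "curves_from_frame",
    "smooth_curve",
    "extract_params",
    "aggregate_replicates",
    "extract_table",
    "PARAM_FIELDS",
]

#: the five growth parameters, in canonical order
PARAM_FIELDS = ("lag_h", "mu_max", "amplitude", "t_half", "auc")

CURVE_COLUMNS = ("strain", "condition", "level", "replicate", "time_h", "signal")


class CurveParseError(ValueError):
    """Raised when a curve table cannot be parsed; names the offending line."""


@dataclass
class GrowthCurve:
    strain_id: str
    condition_id: str
    level_index: int
    replicate: int
    times: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have equal length")
        if self.times.size < 5:
            raise ValueError("a growth curve needs at least 5 time points")
        if self.level_index < 0:
            raise ValueError("level_index must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(self.times)) or np.any(~np.isfinite(self.signal)):
            raise ValueError("times and signal must be finite")
        if np.any(self.signal < 0):
            raise ValueError("signal must be nonnegative")


@dataclass
class GrowthParams:
    """The five growth parameters of one curve (or replicate aggregate)."""

    lag_h: float
    mu_max: float
    amplitude: float
    t_half: float
    auc: float
    grew: bool
    strain_id: str | None = None
    condition_id: str | None = None
    level_index: int | None = None

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_FIELDS], dtype=float)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_curves(frame: pd.DataFrame, path) -> None:
    """Write a curve table (columns strain, condition, level, replicate,
    time_h, signal) as tab-separated text."""
    missing = [c for c in CURVE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"curve table missing columns: {missing}")
    frame.loc[:, CURVE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_curves(path) -> list[GrowthCurve]:
    """Read a delimited curve table into one :class:`GrowthCurve` per
    (strain, condition, level, replicate).

    Rows are validated: a missing/non-numeric signal or time raises
    :class:`CurveParseError` naming the line; time rows out of order are
    sorted with a warning; duplicated time points are an error.
    """
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CurveParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in CURVE_COLUMNS if c not in frame.columns]
    if missing:
        raise CurveParseError(f"{path}: missing columns {missing}")
    for col in ("time_h", "signal"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[vals.isna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise CurveParseError(
                f"{path}: line {bad[0] + 2}: missing or non-numeric {col!r}"
            )
        frame[col] = vals
    frame["level"] = frame["level"].astype(int)
    frame["replicate"] = frame["replicate"].astype(int)
    return curves_from_frame(frame)


def curves_from_frame(frame: pd.DataFrame) -> list[GrowthCurve]:
    """Group a long-format curve table into GrowthCurve objects."""
    curves = []
    for (strain, cond, level, rep), grp in frame.groupby(
        ["strain", "condition", "level", "replicate"], sort=True
    ):
        t = grp["time_h"].to_numpy(dtype=float)
        s = grp["signal"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            warnings.warn(
                f"curve {strain}/{cond}/L{level}/r{rep}: time rows out of order; sorting",
                stacklevel=2,
            )
            order = np.argsort(t, kind="stable")
            t, s = t[order], s[order]
        if np.any(np.diff(t) == 0):
            raise CurveParseError(
                f"curve {strain}/{cond}/L{level}/r{rep}: duplicated time point"
            )
        curves.append(
            GrowthCurve(
                strain_id=str(strain),
                condition_id=str(cond),
                level_index=int(level),
                replicate=int(rep),
                times=t,
                signal=s,
            )
        )
    return curves


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def smooth_curve(curve: GrowthCurve, window: int = 3) -> GrowthCurve:
    """Centered moving-median smoothing.

    Endpoints are handled by shrinking the window symmetrically so the
    median stays centered; ``window=1`` is the identity.  The window must be
    odd and no larger than the number of points.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window > curve.times.size:
        raise ValueError("smoothing window exceeds number of points")
    if window == 1:
        return curve
    half = window // 2
    s = curve.signal
    n = s.size
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = np.median(s[i - h : i + h + 1])
    return replace(curve, signal=out)


# ---------------------------------------------------------------------------
# parameter extraction
# ---------------------------------------------------------------------------

def _sentinel(curve: GrowthCurve) -> GrowthParams:
    end = float(curve.times[-1])
    return GrowthParams(
        lag_h=end, mu_max=0.0, amplitude=0.0, t_half=end, auc=0.0, grew=False,
        strain_id=curve.strain_id, condition_id=curve.condition_id,
        level_index=curve.level_index,
    )


def extract_params(
    curve: GrowthCurve,
    blank: float,
    min_amplitude: float = 0.1,
    fit_window: int = 5,
    smooth_window: int = 3,
) -> GrowthParams:
    """Extract the five growth parameters from one curve.

    μmax is the maximal slope of ln(signal − blank) over a sliding
    ``fit_window``-point least-squares regression; A is the maximal smoothed
    signal above blank; λ is where the tangent at the μmax window crosses the
    initial (baseline) level, the Zwietering construction; t_half is the
    first crossing of A/2 (linear interpolation); AUC is the trapezoidal
    area of the blank-subtracted signal.  Non-growing curves
    (A < ``min_amplitude``) get worst-case sentinels and never raise.
    """
    smoothed = smooth_curve(curve, smooth_window)
    t = smoothed.times
    adj = smoothed.signal - blank
    amplitude = float(np.max(adj))
    if not np.isfinite(amplitude) or amplitude < min_amplitude:
        return _sentinel(curve)

    auc = float(np.trapezoid(np.clip(adj, 0.0, None), t))

    # t_half: first upward crossing of A/2
    half_level = amplitude / 2.0
    above = np.nonzero(adj >= half_level)[0]
    i = int(above[0])
    if i == 0:
        t_half = float(t[0])
    else:
        t0, t1 = t[i - 1], t[i]
        y0, y1 = adj[i - 1], adj[i]
        t_half = float(t0 + (half_level - y0) * (t1 - t0) / (y1 - y0))

    # sliding log-linear regression for mu_max
    floor = max(amplitude * 1e-6, 1e-12)
    valid = adj > floor
    logy = np.where(valid, np.log(np.clip(adj, floor, None)), np.nan)
    n = t.size
    w = min(fit_window, n)
    best_slope, best_icpt = 0.0, math.nan
    for j in range(n - w + 1):
        if not valid[j : j + w].all():
            continue
        tw = t[j : j + w]
        yw = logy[j : j + w]
        tc = tw - tw.mean()
        denom = float(tc @ tc)
        if denom == 0.0:
            continue
        slope = float(tc @ (yw - yw.mean())) / denom
        if slope > best_slope:
            best_slope = slope
            best_icpt = float(yw.mean() - slope * tw.mean())
    mu_max = max(best_slope, 0.0)

    # lag: tangent at the mu_max window intersects the initial level
    k0 = max(3, min(5, n))
    base = float(np.median(adj[:k0]))
    base = max(base, floor)
    if mu_max > 0 and math.isfinite(best_icpt):
        lag = (math.log(base) - best_icpt) / mu_max
        lag = float(np.clip(lag, 0.0, t[-1]))
    else:
        lag = float(t[-1])

    return GrowthParams(
        lag_h=lag, mu_max=mu_max, amplitude=amplitude, t_half=t_half,
        auc=auc, grew=True, strain_id=curve.strain_id,
        condition_id=curve.condition_id, level_index=curve.level_index,
    )


def aggregate_replicates(
    params: Sequence[GrowthParams],
) -> tuple[GrowthParams, dict[str, float]]:
    """Aggregate replicate parameter sets by per-field median.

    grew is decided by majority vote (ties count as grown); dispersion is the
    median absolute deviation per field.  All replicates must share the same
    (strain, condition, level) key.
    """
    if not params:
        raise ValueError("need at least one replicate")
    keys = {(p.strain_id, p.condition_id, p.level_index) for p in params}
    if len(keys) > 1:
        raise ValueError(f"mixed replicate keys: {sorted(keys)}")
    mat = np.array([p.as_vector() for p in params])
    med = np.median(mat, axis=0)
    mad = np.median(np.abs(mat - med), axis=0)
    n_grew = sum(p.grew for p in params)
    grew = n_grew * 2 >= len(params)
    agg = GrowthParams(
        **dict(zip(PARAM_FIELDS, med.tolist())),
        grew=grew,
        strain_id=params[0].strain_id,
        condition_id=params[0].condition_id,
        level_index=params[0].level_index,
    )
    dispersion = dict(zip(PARAM_FIELDS, mad.tolist()))
    return agg, dispersion


def extract_table(
    curves: Iterable[GrowthCurve],
    blank: float,
    min_amplitude: float = 0.1,
    fit_window: int = 5,
    smooth_window: int = 3,
) -> pd.DataFrame:
    """Extract parameters for every curve and aggregate replicates.

    Returns one row per (strain, condition, level) with the five parameters,
    the grew flag and per-parameter replicate dispersions (``<param>_mad``).
    """
    by_key: dict[tuple, list[GrowthParams]] = {}
    for c in curves:
        p = extract_params(
            c, blank, min_amplitude=min_amplitude,
            fit_window=fit_window, smooth_window=smooth_window,
        )
        by_key.setdefault((c.strain_id, c.condition_id, c.level_index), []).append(p)
    rows = []
    for (strain, cond, level), plist in sorted(by_key.items()):
        agg, disp = aggregate_replicates(plist)
        row = {
            "strain": strain, "condition": cond, "level": level,
            **{k: getattr(agg, k) for k in PARAM_FIELDS},
            "grew": agg.grew, "n_replicates": len(plist),
            **{f"{k}_mad": v for k, v in disp.items()},
        }
        rows.append(row)
    return pd.DataFrame(rows)
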