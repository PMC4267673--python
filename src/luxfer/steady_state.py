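"""Per-cell output and steady-state detection for plate-reader time series.

A plate-reader run yields absorbance (OD660) and fluorescence for sample
wells and cell-free background wells over time.  The per-cell output is

    Theta = (f(S) - f(B)) / (OD(S) - OD(B))

which is proportional to the concentration of fluorescent protein per
cell.  Because cultures need time to produce and mature the reporter,
the transfer curve (Theta versus inducer) is only meaningful once the
signal has stopped changing.  Steady state is declared from the data:

* at each time, Theta across inducer conditions is normalized by its
  maximum;
* S(t, condition) is the coefficient of variation of the normalized
  signal over a trailing moving window (default 5 points = 50 min at a
  10-min cadence);
* alpha(t) is the standard deviation of S across conditions, collapsing
  the per-condition fluctuation level into one curve;
* the acquisition time is the earliest time after which alpha stays
  below a threshold through the end of the run.

All matrices are pandas DataFrames indexed by time (minutes) with one
column per inducer concentration (molar).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlateTimeSeries",
    "ThetaMatrix",
    "SteadyStateReport",
    "theta",
    "compute_theta",
    "normalize_per_time",
    "signal_variation",
    "alpha",
    "acquisition_time",
    "steady_state_report",
    "transfer_curve_at",
]

#: long-format columns every plate table must carry
PLATE_COLUMNS = ("time_min", "condition_M", "channel", "well_type", "value_kind", "value", "replicate")

_WELL_TYPES = frozenset({"sample", "background"})
_VALUE_KINDS = frozenset({"od", "fluor"})

#: alpha values at or below this are floating-point dust, not dispersion
_ALPHA_NUMERICAL_FLOOR = 1e-12


@dataclass
class PlateTimeSeries:
    """A tidy plate-reader table plus validated accessors.

    ``data`` columns: time_min, condition_M, channel (RFP/GFP for
    fluorescence rows, empty for od rows), well_type (sample or
    background), value_kind (od or fluor), value, replicate.
    Background wells share the sample time grid and are resolved per
    condition.
    """

    data: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"plate table is missing required columns: {missing}")
        bad_wt = set(self.data["well_type"].unique()) - _WELL_TYPES
        if bad_wt:
            raise ValueError(f"unknown well_type values: {sorted(bad_wt)}")
        bad_vk = set(self.data["value_kind"].unique()) - _VALUE_KINDS
        if bad_vk:
            raise ValueError(f"unknown value_kind values: {sorted(bad_vk)}")

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["time_min"].unique())

    @property
    def conditions(self) -> np.ndarray:
        return np.sort(self.data["condition_M"].unique())

    @property
    def replicates(self) -> np.ndarray:
        return np.sort(self.data["replicate"].unique())

    def signal(self, value_kind: str, well_type: str, channel: str | None = None,
               replicate=None) -> pd.DataFrame:
        """Pivot one measured quantity to a (time x condition) matrix.

        Replicates are averaged unless a single ``replicate`` id is given.
        """
        df = self.data[(self.data["value_kind"] == value_kind) & (self.data["well_type"] == well_type)]
        if value_kind == "fluor":
            if channel is None:
                raise ValueError("channel is required for fluorescence signals")
            df = df[df["channel"] == channel]
        if replicate is not None:
            df = df[df["replicate"] == replicate]
        if df.empty:
            raise ValueError(f"no rows for value_kind={value_kind!r}, well_type={well_type!r}, channel={channel!r}")
        return df.pivot_table(index="time_min", columns="condition_M", values="value", aggfunc="mean").sort_index()


@dataclass
class ThetaMatrix:
    """Per-cell output Theta on a (time x condition) grid for one channel."""

    theta: pd.DataFrame
    channel: str
    n_replicates: int = 1
    label: str = ""


@dataclass
class SteadyStateReport:
    """S and alpha curves with the inferred acquisition time."""

    s_curves: pd.DataFrame
    alpha_curve: pd.Series
    acquisition_time: float
    threshold: float
    window: int = 5
    label: str = ""


def theta(f_S, f_B, od_S, od_B, od_floor: float = 1e-3):
    """Background-corrected fluorescence per background-corrected OD.

    Theta = (f_S - f_B) / (od_S - od_B); proportional to fluorescent
    protein per cell.  Where the OD difference falls below ``od_floor``
    (cells indistinguishable from blank) the value is flagged missing
    (NaN) rather than allowed to blow up.  Accepts scalars or arrays.
    """
    f_S, f_B, od_S, od_B = (np.asarray(x, dtype=float) for x in (f_S, f_B, od_S, od_B))
    denom = od_S - od_B
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(denom) < od_floor, np.nan, (f_S - f_B) / denom)
    return float(out) if out.ndim == 0 else out


def compute_theta(plate: PlateTimeSeries, channel: str = "RFP", od_floor: float = 1e-3) -> ThetaMatrix:
    """Apply the Theta transform to replicate-averaged plate signals."""
    f_S = plate.signal("fluor", "sample", channel)
    f_B = plate.signal("fluor", "background", channel)
    od_S = plate.signal("od", "sample")
    od_B = plate.signal("od", "background")
    f_B, od_B = f_B.reindex_like(f_S), od_B.reindex_like(od_S)
    th = pd.DataFrame(
        theta(f_S.to_numpy(), f_B.to_numpy(), od_S.to_numpy(), od_B.to_numpy(), od_floor),
        index=f_S.index,
        columns=f_S.columns,
    )
    return ThetaMatrix(theta=th, channel=channel, n_replicates=len(plate.replicates), label=plate.label)


def normalize_per_time(tm: ThetaMatrix | pd.DataFrame, channel: str | None = None) -> pd.DataFrame:
    """Divide each time slice by its maximum across conditions.

    The result lies in [0, 1] with a maximum of exactly 1 at every time
    (ignoring missing entries, which propagate).  A time slice that is
    entirely missing or whose maximum is not positive cannot be
    normalized and raises, naming the offending time.
    """
    df = tm.theta if isinstance(tm, ThetaMatrix) else tm
    row_max = df.max(axis=1, skipna=True)
    bad = df.index[~(row_max > 0)]
    if len(bad):
        raise ValueError(f"cannot normalize time slice(s) with non-positive maximum at t={list(bad[:5])} min")
    return df.div(row_max, axis=0)


def signal_variation(norm: pd.DataFrame, window: int = 5, ddof: int = 1) -> pd.DataFrame:
    """Signal variation S: trailing-window coefficient of variation.

    For each condition, S(t) = sd/mean of the ``window`` consecutive
    normalized values ending at t (causal window, usable online during
    acquisition).  Undefined (NaN) for the first window-1 times and
    wherever the window mean is zero.  ``ddof=1`` selects the sample
    standard deviation.
    """
    if len(norm) < window:
        raise ValueError(f"series has {len(norm)} points, fewer than the window of {window}")
    roll = norm.rolling(window=window, min_periods=window)
    mean = roll.mean()
    sd = roll.std(ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = sd / mean.where(mean != 0)
    return s


def alpha(s_curves: pd.DataFrame, ddof: int = 1) -> pd.Series:
    """Across-condition standard deviation of S at each time.

    Collapses the per-condition fluctuation curves into a single
    steady-state indicator.  Missing where fewer than two conditions
    have a defined S.
    """
    out = s_curves.std(axis=1, ddof=ddof)
    out[s_curves.notna().sum(axis=1) < 2] = np.nan
    return out


def acquisition_time(alpha_curve: pd.Series, threshold: float) -> float:
    """Earliest time after which alpha stays below ``threshold`` to the end.

    Undefined (missing) alpha values do not count against the criterion.
    If alpha never rises to the threshold the first time of the series
    is returned; if it is still at or above the threshold at the last
    defined point, steady state was not reached and an error recommends
    a longer acquisition.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    defined = alpha_curve.dropna()
    above = defined.index[defined >= threshold]
    if len(above) == 0:
        return float(alpha_curve.index[0])
    last_above = above.max()
    later = alpha_curve.index[alpha_curve.index > last_above]
    if len(later) == 0:
        raise ValueError(
            f"alpha never settles below {threshold:g} (still {defined.iloc[-1]:.4g} at "
            f"t={last_above:g} min); acquire for longer before reading the transfer curve"
        )
    return float(later[0])


def steady_state_report(
    tm: ThetaMatrix,
    window: int = 5,
    threshold: float | None = None,
    ddof: int = 1,
    threshold_fraction: float = 0.1,
    on_unsettled: str = "raise",
) -> SteadyStateReport:
    """Run the S/alpha analysis end to end on a Theta matrix.

    Time slices that cannot be normalized (all-zero, e.g. before any
    reporter has been produced) are treated as undefined rather than
    fatal.  When no explicit ``threshold`` is given it defaults to
    ``threshold_fraction`` of the maximum observed alpha — a documented
    convention, since the choice of threshold is inherently arbitrary.

    If alpha never settles below the threshold, ``on_unsettled`` decides
    the outcome: ``"raise"`` propagates the error, while ``"endpoint"``
    follows the characterization protocol of reading the transfer curve
    at the final measured time (the threshold rule effectively
    disabled), with a warning.
    """
    if on_unsettled not in ("raise", "endpoint"):
        raise ValueError("on_unsettled must be 'raise' or 'endpoint'")
    df = tm.theta
    row_max = df.max(axis=1, skipna=True)
    ok = row_max > 0
    norm = df.where(ok).div(row_max.where(ok), axis=0)
    s = signal_variation(norm, window=window, ddof=ddof)
    a = alpha(s, ddof=ddof)
    # alpha at the floating-point roundoff level is indistinguishable from
    # zero dispersion (the noiseless limit); clamp it so the relative
    # threshold is not set by numerical dust
    a = a.mask(a.abs() <= _ALPHA_NUMERICAL_FLOOR, 0.0)
    if threshold is None:
        peak = a.max(skipna=True)
        if not np.isfinite(peak):
            raise ValueError("alpha curve is entirely undefined; supply an explicit threshold")
        threshold = threshold_fraction * float(peak) if peak > 0 else _ALPHA_NUMERICAL_FLOOR
    try:
        t_acq = acquisition_time(a, threshold)
    except ValueError:
        if on_unsettled == "raise":
            raise
        t_acq = float(df.index[-1])
        warnings.warn(
            f"alpha never settled below {threshold:g}; reading at the final time "
            f"{t_acq:g} min (threshold rule disabled)",
            RuntimeWarning,
        )
    return SteadyStateReport(
        s_curves=s, alpha_curve=a, acquisition_time=t_acq, threshold=threshold, window=window, label=tm.label
    )


def transfer_curve_at(tm: ThetaMatrix, time_min: float, construct: str = "", phi: float = float("nan")):
    """Read the transfer curve (inducer -> Theta) at one acquisition time."""
    from .fitting import TransferCurve  # local import: fitting also consumes this module's output

    if time_min not in tm.theta.index:
        raise ValueError(f"time {time_min} min is not on the measured grid")
    row = tm.theta.loc[time_min]
    row = row.dropna()
    return TransferCurve(
        ligand=row.index.to_numpy(dtype=float),
        theta=row.to_numpy(dtype=float),
        construct=construct or tm.label,
        phi=phi,
    )
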