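"""Comparison workflow between impedance growth channels and optical density.

Implements the cross-calibration of non-contact impedance channels against
discretely sampled optical density (OD) and optical reflection (OR):
baseline subtraction, min-max normalization (with inversion of decreasing
OR channels), per-channel sigmoid fits, channel delays relative to the OD
lag, time-slot averaging of the densely sampled impedance series onto the
OD sampling grid, and ordinary least-squares regression of impedance
against OD inside the photometrically valid OD window (default
0.16–1.3, a closed interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError, InvalidInputError
from .growth import GrowthCurve, SigmoidFit, fit_sigmoid

DEFAULT_OD_RANGE = (0.16, 1.3)


@dataclass
class GrowthExperiment:
    """Aligned multi-channel growth time series on one experiment clock.

    ``channels`` maps channel labels to :class:`GrowthCurve`;
    ``od_sample_interval`` is the OD sampling period (hours).
    """

    channels: dict[str, GrowthCurve]
    od_sample_interval: float = 0.75
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.channels:
            raise InvalidInputError("experiment needs at least one channel")
        if not (np.isfinite(self.od_sample_interval) and self.od_sample_interval > 0):
            raise InvalidInputError("od_sample_interval must be positive")
        for label, curve in self.channels.items():
            if curve.channel and curve.channel != label:
                raise InvalidInputError(
                    f"channel label mismatch: {label!r} vs curve {curve.channel!r}"
                )
            curve.channel = label


@dataclass(frozen=True)
class RegressionResult:
    """OLS of channel response against OD inside the valid OD window."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    n_excluded: int


@dataclass
class ComparisonResult:
    """Per-channel fits, delays and OD regressions for one experiment."""

    sigmoid: dict[str, SigmoidFit]
    tdelay: dict[str, float]
    regression: dict[str, RegressionResult]
    slots: dict[str, pd.DataFrame]
    od_range: tuple[float, float]
    reference: str


def subtract_baseline(obj, baseline_time: float):
    """Shift a curve (or per-frequency spectrum series) so it is zero at
    ``baseline_time``.

    For a :class:`GrowthCurve` the value at ``baseline_time`` (linearly
    interpolated between samples) is subtracted from every point.  For a
    DataFrame with columns ``time_h``, ``freq_hz``, ``value`` the
    subtraction is done independently per frequency.  Idempotent: applying
    twice with the same baseline time is a no-op.
    """
    if isinstance(obj, GrowthCurve):
        t = obj.times
        if not (t[0] <= baseline_time <= t[-1]):
            raise InvalidInputError(
                f"baseline_time {baseline_time} outside recorded window "
                f"[{t[0]}, {t[-1]}]"
            )
        base = float(np.interp(baseline_time, t, obj.values))
        return obj.replace_values(obj.values - base)
    if isinstance(obj, pd.DataFrame):
        required = {"time_h", "freq_hz", "value"}
        if not required.issubset(obj.columns):
            raise InvalidInputError(f"spectrum series needs columns {sorted(required)}")
        tmin, tmax = obj["time_h"].min(), obj["time_h"].max()
        if not (tmin <= baseline_time <= tmax):
            raise InvalidInputError("baseline_time outside recorded window")
        out = obj.copy()
        for f, grp in obj.groupby("freq_hz"):
            g = grp.sort_values("time_h")
            base = float(np.interp(baseline_time, g["time_h"], g["value"]))
            out.loc[grp.index, "value"] = grp["value"] - base
        return out
    raise InvalidInputError(f"cannot baseline-subtract object of type {type(obj)}")


def normalize(curve: GrowthCurve, invert: bool | None = None) -> GrowthCurve:
    """Min-max normalize a curve to [0, 1]; inverted channels get 1 - uN.

    ``invert=None`` takes the curve's own ``invert`` flag.  Raises
    :class:`DegenerateDataError` for a constant curve.
    """
    if invert is None:
        invert = curve.invert
    rng = np.ptp(curve.values)
    if rng == 0:
        raise DegenerateDataError(
            f"channel {curve.channel!r} is constant; cannot normalize"
        )
    un = (curve.values - curve.values.min()) / rng
    out = curve.replace_values(1.0 - un if invert else un)
    out.invert = False  # inversion already applied
    return out


def delay_vs_reference(t0_channel: float, t0_reference: float) -> float:
    """Channel delay relative to the reference lag (negative = earlier)."""
    if not (np.isfinite(t0_channel) and np.isfinite(t0_reference)):
        raise InvalidInputError("time lags must be finite")
    return t0_channel - t0_reference


def slot_average(ncis: GrowthCurve, od_times, tsample: float) -> pd.DataFrame:
    """Average a dense series in slots of width ``tsample`` around OD times.

    For each OD sampling time ``ti`` the statistics cover points with
    ``t`` in the closed interval ``[ti - tsample/2, ti + tsample/2]``.  A
    point on a boundary shared by two slots goes to the earlier slot.
    Empty slots are reported with ``n = 0`` and NaN statistics — they are
    data, not errors.
    """
    if not tsample > 0:
        raise InvalidInputError("tsample must be positive")
    od_times = np.asarray(od_times, dtype=float)
    order = np.argsort(od_times, kind="stable")
    taken = np.zeros(len(ncis), dtype=bool)
    rows = {}
    half = tsample / 2.0
    for i in order:
        ti = od_times[i]
        mask = (~taken) & (ncis.times >= ti - half) & (ncis.times <= ti + half)
        taken |= mask
        vals = ncis.values[mask]
        n = int(mask.sum())
        rows[i] = (ti, float(np.mean(vals)) if n else np.nan,
                   float(np.std(vals)) if n else np.nan, n)
    out = pd.DataFrame([rows[i] for i in range(len(od_times))],
                       columns=["od_time_h", "mean", "std", "n"])
    out["n"] = out["n"].astype(int)
    return out


def regress_vs_od(paired, od_range: tuple[float, float] = DEFAULT_OD_RANGE
                  ) -> RegressionResult:
    """OLS of channel response on OD for pairs inside the OD window.

    ``paired`` is a sequence of (od, response) pairs; pairs with OD outside
    the closed interval ``od_range`` are excluded and counted.  At least
    three in-range pairs are required.
    """
    arr = np.asarray(list(paired), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidInputError("paired must be a sequence of (od, value) pairs")
    od, y = arr[:, 0], arr[:, 1]
    keep = (od >= od_range[0]) & (od <= od_range[1]) & np.isfinite(y)
    n_in = int(keep.sum())
    if n_in < 3:
        raise InsufficientDataError(
            f"need >= 3 pairs with OD in [{od_range[0]}, {od_range[1]}], got {n_in}"
        )
    res = stats.linregress(od[keep], y[keep])
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), n_points=n_in,
        n_excluded=int(len(od) - n_in),
    )


def compare_experiment(exp: GrowthExperiment, reference_channel: str = "od_600",
                       od_range: tuple[float, float] = DEFAULT_OD_RANGE,
                       apply_delay: bool = True) -> ComparisonResult:
    """Run the full channel comparison against the reference (OD) channel.

    Every channel is min-max normalized (with inversion for flagged OR
    channels) and fit with the growth sigmoid; each non-reference
    channel's delay is its fitted lag minus the reference lag.  Each
    impedance channel is then slot-averaged onto the OD sampling times
    (shifted by its delay when ``apply_delay`` is set, aligning the
    channel's growth phase with the OD one) and regressed against OD
    inside ``od_range``.
    """
    if reference_channel not in exp.channels:
        raise InvalidInputError(
            f"reference channel {reference_channel!r} not in experiment "
            f"(have {sorted(exp.channels)})"
        )
    sigmoid: dict[str, SigmoidFit] = {}
    for label, curve in exp.channels.items():
        try:
            sigmoid[label] = fit_sigmoid(normalize(curve))
        except Exception as exc:
            raise type(exc)(f"channel {label!r}: {exc}") from exc

    t0_ref = sigmoid[reference_channel].params.t0
    tdelay = {
        label: delay_vs_reference(fit.params.t0, t0_ref)
        for label, fit in sigmoid.items() if label != reference_channel
    }

    ref_curve = exp.channels[reference_channel]
    regression: dict[str, RegressionResult] = {}
    slots: dict[str, pd.DataFrame] = {}
    for label, curve in exp.channels.items():
        if curve.kind != "ncis":
            continue
        shift = tdelay[label] if apply_delay else 0.0
        table = slot_average(curve, ref_curve.times + shift, exp.od_sample_interval)
        slots[label] = table
        pairs = [(od, m) for od, m, n in
                 zip(ref_curve.values, table["mean"], table["n"]) if n > 0]
        try:
            regression[label] = regress_vs_od(pairs, od_range)
        except InsufficientDataError:
            continue  # too little overlap in the OD window; no regression
    return ComparisonResult(sigmoid=sigmoid, tdelay=tdelay, regression=regression,
                            slots=slots, od_range=od_range,
                            reference=reference_channel)
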