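"""Bacterial growth-curve models: single sigmoid and the two-region model.

Two phenomenological descriptions of batch growth as seen by an impedance
(or optical) channel:

* a logistic sigmoid ``U(t) = Ua / (1 + exp(-(t - t0)/tau))`` with
  amplitude ``Ua`` (signed: a decreasing channel has Ua < 0), volume growth
  time constant ``tau`` and time lag ``t0``;

* a unified two-region model in which growth starts as a film on the
  container wall and later fills the bulk.  The sample is a coaxial pair of
  regions: an inner cylinder of radius ``r1(t)`` with resistivity index
  ``rho1(t)`` and a wall shell ``r1 < r < r2`` with constant index
  ``rho_a2``.  The wall film thickens with the cube root of exponential
  volume growth, ``r1(t) = r2 * exp(-(t - t0w)/(3*tau_u))`` for
  ``t >= t0w``, while the bulk index follows a sigmoid with lag ``t0b``.
  The two regions conduct in parallel, which yields the dimensionless
  growth signal

      Uu(t) = Un * [ exp(-2(t-t0w)/(3 tau_u)) / (1 + exp(-(t-t0b)/tau_u))
                     + (1 - exp(-2(t-t0w)/(3 tau_u))) * rho_a1/rho_a2 ]

  for ``t >= t0w`` and the plain bulk sigmoid before the wall lag.  Its
  late-time asymptote is ``Un * rho_a1/rho_a2``: a ratio above one makes
  the channel respond earlier and overshoot the bulk sigmoid (wall-
  sensitive, low-frequency behaviour), a ratio below one damps it
  (bulk-sensitive, high-frequency behaviour).

Fitting mirrors the measurement workflow: each channel is first fit
individually with the sigmoid; the wall lag is identified with the
low-frequency channel's lag and the bulk lag / time constant with the
high-frequency channel's, after which the resistivity-index ratio (and a
scale) is fit per channel.  Because a two-region curve's half-rise is not
at ``t0w``, those frozen stage-1 lags are biased for data that truly follow
the two-region model, so by default a joint multistart refinement of
(tau_u, t0w, t0b, per-curve ratio) follows; ``refine=False`` keeps the
frozen-lag procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .errors import (
    DegenerateDataError,
    FitFailureError,
    InsufficientDataError,
    InvalidGeometryError,
    InvalidInputError,
)


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the logistic growth sigmoid.

    ``ua`` is the signed amplitude in channel units, ``tau`` the growth
    time constant in hours, ``t0`` the time lag in hours.
    """

    ua: float
    tau: float
    t0: float

    def __post_init__(self):
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise InvalidInputError(f"tau must be positive, got {self.tau}")
        if not np.isfinite(self.ua) or self.ua == 0:
            raise InvalidInputError("ua must be finite and nonzero")
        if not np.isfinite(self.t0):
            raise InvalidInputError("t0 must be finite")


@dataclass(frozen=True)
class TwoRegionGeometry:
    """Coaxial two-region sample: bulk cylinder inside a wall shell."""

    r2: float          # inner container radius, m
    h: float           # electrode-to-electrode height, m
    rho_a1: float      # bulk resistivity index (arbitrary units)
    rho_a2: float      # wall-region resistivity index (same units)

    def __post_init__(self):
        for name in ("r2", "h", "rho_a1", "rho_a2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidInputError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class UnifiedGrowthParams:
    """Reduced parameters of the two-region growth signal."""

    un: float          # normalization constant, dimensionless
    tau_u: float       # volume growth time constant, h
    t0w: float         # wall-growth time lag, h
    t0b: float         # bulk-growth time lag, h
    rho_ratio: float   # rho_a1 / rho_a2

    def __post_init__(self):
        if not (np.isfinite(self.tau_u) and self.tau_u > 0):
            raise InvalidInputError(f"tau_u must be positive, got {self.tau_u}")
        if not (np.isfinite(self.un) and self.un > 0):
            raise InvalidInputError(f"un must be positive, got {self.un}")
        if not (np.isfinite(self.rho_ratio) and self.rho_ratio > 0):
            raise InvalidInputError(f"rho_ratio must be positive, got {self.rho_ratio}")
        if not (np.isfinite(self.t0w) and np.isfinite(self.t0b)):
            raise InvalidInputError("time lags must be finite")


@dataclass
class GrowthCurve:
    """A single-channel growth time series on a strictly increasing clock.

    ``kind`` tags how the pipeline treats the channel ("ncis", "od" or
    "or"); ``invert`` flags channels whose raw signal decreases during
    growth (optical reflection) so that normalization plots ``1 - uN``.
    """

    times: np.ndarray
    values: np.ndarray
    channel: str = ""
    kind: str = "ncis"
    invert: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise InvalidInputError("times and values must be equal-length 1-D arrays")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise InvalidInputError("times and values must be finite")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.kind not in ("ncis", "od", "or"):
            raise InvalidInputError(f"unknown channel kind {self.kind!r}")

    def __len__(self):
        return len(self.times)

    def replace_values(self, values: np.ndarray) -> "GrowthCurve":
        return GrowthCurve(self.times.copy(), np.asarray(values, dtype=float),
                           channel=self.channel, kind=self.kind, invert=self.invert)


def sigmoid_value(params: SigmoidParams, t) -> np.ndarray | float:
    """Evaluate the growth sigmoid Ua / (1 + exp(-(t - t0)/tau))."""
    t = np.asarray(t, dtype=float)
    out = params.ua * expit((t - params.t0) / params.tau)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SigmoidFit:
    params: SigmoidParams
    residual_rms: float
    covariance: np.ndarray | None
    n_points: int


def _sigmoid_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Start values: signed range, half-range crossing, quartile width."""
    ua0 = float(y[-1] - y[0])
    if ua0 == 0:
        ua0 = float(np.ptp(y)) or 1.0
    span = y[-1] - y[0] if y[-1] != y[0] else float(np.ptp(y))
    yn = (y - y[0]) / span
    t0_0 = float(t[np.argmin(np.abs(yn - 0.5))])
    t25 = float(t[np.argmin(np.abs(yn - 0.25))])
    t75 = float(t[np.argmin(np.abs(yn - 0.75))])
    tau0 = min(max(abs(t75 - t25) / 2.2, 1e-3), 100.0)
    return ua0, tau0, t0_0


def fit_sigmoid(curve: GrowthCurve) -> SigmoidFit:
    """Least-squares fit of the growth sigmoid to one channel.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 points.
    DegenerateDataError
        All values identical (no signal to fit).
    FitFailureError
        The optimizer failed.
    """
    t, y = curve.times, curve.values
    if len(t) < 4:
        raise InsufficientDataError("sigmoid fit needs >= 4 points")
    if np.ptp(y) == 0:
        raise DegenerateDataError("constant curve: nothing to fit")
    ua0, tau0, t0_0 = _sigmoid_init(t, y)

    model = lmfit.Model(
        lambda t, ua, tau, t0: ua * expit((t - t0) / tau),
        independent_vars=["t"],
    )
    pars = model.make_params(ua=ua0, tau=tau0, t0=t0_0)
    pars["tau"].set(min=1e-3, max=100.0)
    span = t[-1] - t[0]
    pars["t0"].set(min=t[0] - span, max=t[-1] + span)
    try:
        result = model.fit(y, pars, t=t)
    except Exception as exc:  # lmfit wraps scipy failures in various ways
        raise FitFailureError(f"sigmoid fit failed: {exc}") from exc
    if not result.success:
        raise FitFailureError(f"sigmoid fit did not converge: {result.message}")
    p = SigmoidParams(ua=float(result.params["ua"].value),
                      tau=float(result.params["tau"].value),
                      t0=float(result.params["t0"].value))
    rms = float(np.sqrt(np.mean(result.residual**2)))
    return SigmoidFit(params=p, residual_rms=rms,
                      covariance=result.covar, n_points=len(t))


def wall_radius(t, t0w: float, tau_u: float, r2: float) -> np.ndarray | float:
    """Inner radius of the wall film, shrinking with cube-root volume growth.

    ``r1 = r2`` before the wall lag ``t0w``; afterwards
    ``r1 = r2 * exp(-(t - t0w)/(3*tau_u))``.  Continuous, non-increasing.
    """
    if not (tau_u > 0 and r2 > 0):
        raise InvalidInputError("tau_u and r2 must be positive")
    t = np.asarray(t, dtype=float)
    out = r2 * np.exp(-np.clip(t - t0w, 0.0, None) / (3.0 * tau_u))
    return float(out) if out.ndim == 0 else out


def two_region_re_dz(geom: TwoRegionGeometry, rho1, rho2, r1) -> np.ndarray | float:
    """Resistance-like response of bulk cylinder and wall shell in parallel.

    ``h * rho1 * rho2 / (pi*r1^2*rho2 + pi*(r2^2 - r1^2)*rho1)`` — i.e. the
    reciprocal sum of the two cylinder conductances.
    """
    r1 = np.asarray(r1, dtype=float)
    if np.any(r1 <= 0) or np.any(r1 > geom.r2 * (1 + 1e-12)):
        raise InvalidGeometryError("need 0 < r1 <= r2")
    rho1 = np.asarray(rho1, dtype=float)
    rho2 = np.asarray(rho2, dtype=float)
    num = geom.h * rho1 * rho2
    den = np.pi * r1**2 * rho2 + np.pi * (geom.r2**2 - r1**2) * rho1
    out = num / den
    return float(out) if out.ndim == 0 else out


def unified_growth(params: UnifiedGrowthParams, t) -> np.ndarray | float:
    """Evaluate the two-region growth signal Uu(t).

    Before the wall lag this is the bulk sigmoid; afterwards the wall term
    pulls the signal toward the asymptote ``un * rho_ratio``.  The two
    branches meet continuously at ``t = t0w``.
    """
    t = np.asarray(t, dtype=float)
    sig = expit((t - params.t0b) / params.tau_u)
    decay = np.exp(-2.0 * np.clip(t - params.t0w, 0.0, None) / (3.0 * params.tau_u))
    out = params.un * np.where(
        t >= params.t0w,
        decay * sig + (1.0 - decay) * params.rho_ratio,
        sig,
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class UnifiedFit:
    """Result of the two-stage (plus optional refinement) unified fit."""

    params_low: UnifiedGrowthParams
    params_high: UnifiedGrowthParams
    stage1_low: SigmoidFit
    stage1_high: SigmoidFit
    residual_rms_low: float
    residual_rms_high: float
    offsets: tuple[float, float] = (0.0, 0.0)
    warnings: list = field(default_factory=list)
    refined: bool = True

    @property
    def shared(self) -> tuple[float, float, float]:
        """(tau_u, t0w, t0b) shared by the two channels."""
        p = self.params_low
        return p.tau_u, p.t0w, p.t0b


def _minmax(y: np.ndarray) -> np.ndarray:
    rng = np.ptp(y)
    if rng == 0:
        raise DegenerateDataError("constant curve cannot be normalized")
    return (y - y.min()) / rng


def _affine_profile(yn: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """Closed-form (scale, offset) minimizing ||yn - scale*g - offset||."""
    gm, ym = g.mean(), yn.mean()
    gc = g - gm
    denom = float(gc @ gc)
    scale = float(gc @ (yn - ym)) / denom if denom > 0 else 0.0
    return scale, float(ym - scale * gm)


def _rho_profile_fit(t, yn, tau_u, t0w, t0b,
                     log_rho_bounds=(-7.0, 7.0)) -> tuple[float, float, float, float]:
    """1-D least squares over rho_ratio with (scale, offset) profiled out."""
    from scipy.optimize import minimize_scalar

    def cost(lr):
        g = _unified_shape(t, tau_u, t0w, t0b, np.exp(lr))
        s, c = _affine_profile(yn, g)
        r = yn - s * g - c
        return float(r @ r)

    res = minimize_scalar(cost, bounds=log_rho_bounds, method="bounded",
                          options={"xatol": 1e-12})
    rho = float(np.exp(res.x))
    g = _unified_shape(t, tau_u, t0w, t0b, rho)
    s, c = _affine_profile(yn, g)
    rms = float(np.sqrt(np.mean((yn - s * g - c) ** 2)))
    return rho, s, c, rms


def _unified_shape(t, tau_u, t0w, t0b, rho):
    sig = expit((t - t0b) / tau_u)
    decay = np.exp(-2.0 * np.clip(t - t0w, 0.0, None) / (3.0 * tau_u))
    return np.where(t >= t0w, decay * sig + (1.0 - decay) * rho, sig)


def _rise_time(t: np.ndarray, yn: np.ndarray, frac: float) -> float:
    idx = np.argmax(yn >= frac)
    return float(t[idx])


def fit_unified(low_f_curve: GrowthCurve, high_f_curve: GrowthCurve,
                refine: bool = True) -> UnifiedFit:
    """Fit the two-region model to a low-/high-frequency channel pair.

    Stage 1 fits each channel individually with the sigmoid; the wall lag
    ``t0w`` is taken from the low-frequency fit and the bulk lag ``t0b``
    and time constant ``tau_u`` from the high-frequency fit.  Stage 2 then
    fits each channel's ``rho_ratio`` (with an affine scale profiled out)
    against the min-max-normalized data.

    With ``refine=True`` (default) a joint multistart least-squares
    refinement of (tau_u, t0w, t0b, rho_low, rho_high) over both
    normalized channels follows, initialized from the two-stage result;
    this removes the bias of the frozen stage-1 lags when the data truly
    follow the two-region model.  ``refine=False`` reproduces the
    frozen-lag literature procedure verbatim.

    A ``"lag_order"`` entry appears in ``warnings`` when the stage-1 lags
    come out inverted (t0w >= t0b), e.g. when the caller swapped the two
    channels; the curves are never silently reordered.
    """
    try:
        s1_low = fit_sigmoid(low_f_curve)
        s1_high = fit_sigmoid(high_f_curve)
    except (DegenerateDataError, InsufficientDataError, FitFailureError) as exc:
        raise FitFailureError(f"stage-1 sigmoid fit failed: {exc}") from exc

    warns = []
    t0w = s1_low.params.t0
    t0b = s1_high.params.t0
    tau_u = abs(s1_high.params.tau)
    if t0w >= t0b:
        warns.append("lag_order")
        warnings.warn(
            "stage-1 lags inverted (t0w >= t0b): low-/high-frequency curves "
            "may be swapped; not reordering",
            stacklevel=2,
        )

    t_lo, t_hi = low_f_curve.times, high_f_curve.times
    yn_lo = _minmax(low_f_curve.values)
    yn_hi = _minmax(high_f_curve.values)

    rho_lo, s_lo, c_lo, rms_lo = _rho_profile_fit(t_lo, yn_lo, tau_u, t0w, t0b)
    rho_hi, s_hi, c_hi, rms_hi = _rho_profile_fit(t_hi, yn_hi, tau_u, t0w, t0b)

    if refine:
        tau_u, t0w, t0b, rho_lo, rho_hi = _joint_refine(
            t_lo, yn_lo, t_hi, yn_hi, tau_u, t0w, t0b,
            stage1_t0w_candidates=(t0w,
                                   _rise_time(t_lo, yn_lo, 0.05),
                                   _rise_time(t_lo, yn_lo, 0.15),
                                   _rise_time(t_lo, yn_lo, 0.30)),
        )
        g = _unified_shape(t_lo, tau_u, t0w, t0b, rho_lo)
        s_lo, c_lo = _affine_profile(yn_lo, g)
        rms_lo = float(np.sqrt(np.mean((yn_lo - s_lo * g - c_lo) ** 2)))
        g = _unified_shape(t_hi, tau_u, t0w, t0b, rho_hi)
        s_hi, c_hi = _affine_profile(yn_hi, g)
        rms_hi = float(np.sqrt(np.mean((yn_hi - s_hi * g - c_hi) ** 2)))

    return UnifiedFit(
        params_low=UnifiedGrowthParams(un=max(s_lo, 1e-12), tau_u=tau_u,
                                       t0w=t0w, t0b=t0b, rho_ratio=rho_lo),
        params_high=UnifiedGrowthParams(un=max(s_hi, 1e-12), tau_u=tau_u,
                                        t0w=t0w, t0b=t0b, rho_ratio=rho_hi),
        stage1_low=s1_low, stage1_high=s1_high,
        residual_rms_low=rms_lo, residual_rms_high=rms_hi,
        offsets=(c_lo, c_hi), warnings=warns, refined=refine,
    )


def _joint_refine(t_lo, yn_lo, t_hi, yn_hi, tau0, t0w0, t0b0,
                  stage1_t0w_candidates=()):
    """Multistart joint least squares over (tau_u, t0w, t0b, log rho x2)."""
    t_min = float(min(t_lo[0], t_hi[0]))
    t_max = float(max(t_lo[-1], t_hi[-1]))
    lo = [1e-3, t_min, t_min, -7.0, -7.0]
    hi = [100.0, t_max, t_max, 7.0, 7.0]

    def residuals(p):
        tau, t0w, t0b, lr_lo, lr_hi = p
        out = []
        for t, yn, lr in ((t_lo, yn_lo, lr_lo), (t_hi, yn_hi, lr_hi)):
            g = _unified_shape(t, tau, t0w, t0b, np.exp(lr))
            s, c = _affine_profile(yn, g)
            out.append(yn - s * g - c)
        return np.concatenate(out)

    best = None
    cands = set(round(c, 6) for c in stage1_t0w_candidates) or {t0w0}
    for t0w_init in cands:
        for lr_init in (np.log(0.5), 0.0, np.log(3.0)):
            p0 = np.clip([tau0, t0w_init, t0b0, lr_init, lr_init], lo, hi)
            sol = least_squares(residuals, p0, bounds=(lo, hi),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not best.success and best.status <= 0:
        raise FitFailureError("joint unified refinement failed")
    tau, t0w, t0b, lr_lo, lr_hi = best.x
    return float(tau), float(t0w), float(t0b), float(np.exp(lr_lo)), float(np.exp(lr_hi))
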