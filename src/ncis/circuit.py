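"""Parallel-RC equivalent-circuit model for a non-contact conductivity cell.

A capacitively coupled (electrode-through-wall) conductivity cell reduces,
once the constant wall capacitance is removed by baseline subtraction, to a
single parallel RC circuit: the bulk solution resistance ``R = Kcell / kappa``
in parallel with a coupling capacitance ``C1``.  The measured quantities are
impedance *changes* relative to a low-conductivity baseline solution,

    Re dZ  =  (eps0*eps_r/C1) * [ k0/(k0^2 + (w*eps_r*eps0)^2)
                                  - kb/(kb^2 + (w*eps_r*eps0)^2) ]
    -Im dZ =  (w*(eps_r*eps0)^2/C1) * [ 1/(k0^2 + (w*eps_r*eps0)^2)
                                        - 1/(kb^2 + (w*eps_r*eps0)^2) ]

with ``w = 2*pi*f``.  The real part of a single-solution term peaks at the
diagnostic conductivity ``kappa_0d = w*eps_r*eps0``, with peak height
``1/(2*w*C1)``; the usable dynamic range spans roughly one decade either side
of the peak.  The only adjustable parameter of the whole sweep family is C1.

C1 and the cell constant are linked by ``C1 = eps_r*eps0 / Kcell`` (so that
C1 is a capacitance in farads and the RC time constant ``eps_r*eps0/kappa``
is geometry independent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitFailureError, InsufficientDataError, InvalidInputError

#: Vacuum permittivity in F/m.
EPSILON_0 = 8.8541878128e-12

#: Default relative permittivity (water at room temperature).
WATER_EPS_R = 78.0

SWEEP_COLUMNS = ("freq_hz", "kappa_s_per_m", "re_dz_ohm", "neg_im_dz_ohm")


@dataclass(frozen=True)
class CircuitParams:
    """Calibrated parameters of the parallel-RC cell model.

    Parameters
    ----------
    c1
        Coupling capacitance in farads.
    kappa_b
        Conductivity of the baseline solution in S/m.
    eps_r
        Relative permittivity of the solution (dimensionless).
    """

    c1: float
    kappa_b: float = 0.0
    eps_r: float = WATER_EPS_R

    def __post_init__(self):
        if not (np.isfinite(self.c1) and self.c1 > 0):
            raise InvalidInputError(f"c1 must be positive and finite, got {self.c1}")
        if not (np.isfinite(self.eps_r) and self.eps_r > 0):
            raise InvalidInputError(f"eps_r must be positive, got {self.eps_r}")
        if not (np.isfinite(self.kappa_b) and self.kappa_b >= 0):
            raise InvalidInputError(f"kappa_b must be >= 0, got {self.kappa_b}")

    @property
    def kcell(self) -> float:
        """Cell constant (1/m) implied by C1 via Kcell = eps_r*eps0/C1."""
        return cell_constant_from_c1(self.c1, self.eps_r)


@dataclass(frozen=True)
class CellGeometry:
    """Cell constant of a conductivity cell, R = Kcell / kappa."""

    kcell: float

    def __post_init__(self):
        if not (np.isfinite(self.kcell) and self.kcell > 0):
            raise InvalidInputError(f"kcell must be positive, got {self.kcell}")


@dataclass
class ImpedanceSweep:
    """A conductivity sweep: impedance changes vs (frequency, conductivity).

    ``data`` holds one record per (freq_hz, kappa_s_per_m) pair with the
    baseline-subtracted real part ``re_dz_ohm`` and the sign-flipped
    imaginary part ``neg_im_dz_ohm``.
    """

    data: pd.DataFrame
    baseline_label: str = "UPW"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in SWEEP_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidInputError(f"sweep missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)
        f = self.data["freq_hz"].to_numpy(float)
        k = self.data["kappa_s_per_m"].to_numpy(float)
        if len(self.data) == 0:
            raise InvalidInputError("sweep contains no records")
        if not np.all(np.isfinite(f) & (f > 0)):
            raise InvalidInputError("all frequencies must be finite and > 0")
        if not np.all(np.isfinite(k) & (k > 0)):
            raise InvalidInputError("all conductivities must be finite and > 0")
        if self.data.duplicated(["freq_hz", "kappa_s_per_m"]).any():
            raise InvalidInputError("duplicate (freq, kappa) pairs in sweep")

    def __len__(self):
        return len(self.data)

    @property
    def frequencies(self) -> np.ndarray:
        return np.sort(self.data["freq_hz"].unique())

    @property
    def conductivities(self) -> np.ndarray:
        return np.sort(self.data["kappa_s_per_m"].unique())


def _check_positive(**kwargs):
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr) & (arr > 0)):
            raise InvalidInputError(f"{name} must be finite and > 0, got {value}")


def resistance(geom: CellGeometry, kappa) -> np.ndarray | float:
    """Bulk solution resistance R = Kcell / kappa in ohms."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa == 0):
        raise ZeroDivisionError(
            "resistance undefined at kappa = 0 (R = Kcell/kappa diverges)"
        )
    _check_positive(kappa=kappa)
    out = geom.kcell / kappa
    return float(out) if out.ndim == 0 else out


def impedance_rc(params: CircuitParams, kappa, freq,
                 geom: CellGeometry | None = None) -> complex | np.ndarray:
    """Complex impedance of the parallel-RC cell, Z = R / (1 + i*w*R*C1).

    ``R = Kcell/kappa`` with the cell constant taken from ``geom`` when
    given, otherwise derived from C1 as ``eps_r*eps0/C1``.  The result has
    a positive real part and non-positive imaginary part.
    """
    _check_positive(kappa=kappa, freq=freq)
    kappa = np.asarray(kappa, dtype=float)
    freq = np.asarray(freq, dtype=float)
    kcell = geom.kcell if geom is not None else params.kcell
    r = kcell / kappa
    z = r / (1.0 + 1j * (2.0 * np.pi * freq) * r * params.c1)
    return complex(z) if z.ndim == 0 else z


def _single_term_real(params: CircuitParams, kappa, omega):
    a = omega * params.eps_r * EPSILON_0
    return kappa / (kappa**2 + a**2)


def delta_z_real(params: CircuitParams, kappa0, freq) -> np.ndarray | float:
    """Real part of the impedance change between kappa0 and the baseline."""
    _check_positive(kappa0=kappa0, freq=freq)
    kappa0 = np.asarray(kappa0, dtype=float)
    omega = 2.0 * np.pi * np.asarray(freq, dtype=float)
    pre = EPSILON_0 * params.eps_r / params.c1
    out = pre * (_single_term_real(params, kappa0, omega)
                 - _single_term_real(params, params.kappa_b, omega))
    return float(out) if np.ndim(out) == 0 else out


def delta_z_neg_imag(params: CircuitParams, kappa0, freq) -> np.ndarray | float:
    """Negative imaginary part of the impedance change (plotting convention)."""
    _check_positive(kappa0=kappa0, freq=freq)
    kappa0 = np.asarray(kappa0, dtype=float)
    omega = 2.0 * np.pi * np.asarray(freq, dtype=float)
    a = omega * params.eps_r * EPSILON_0
    pre = omega * (params.eps_r * EPSILON_0) ** 2 / params.c1
    out = pre * (1.0 / (kappa0**2 + a**2) - 1.0 / (params.kappa_b**2 + a**2))
    return float(out) if np.ndim(out) == 0 else out


def peak_conductivity(freq, eps_r: float = WATER_EPS_R) -> np.ndarray | float:
    """Conductivity of maximal real response, kappa_0d = 2*pi*f*eps_r*eps0."""
    _check_positive(freq=freq, eps_r=eps_r)
    out = 2.0 * np.pi * np.asarray(freq, dtype=float) * eps_r * EPSILON_0
    return float(out) if np.ndim(out) == 0 else out


def sensitivity_band(freq, eps_r: float = WATER_EPS_R) -> tuple:
    """Decade band of optimal sensitivity, (kappa_0d/10, 10*kappa_0d)."""
    k0d = peak_conductivity(freq, eps_r)
    return k0d / 10.0, 10.0 * k0d


def cell_constant_from_c1(c1: float, eps_r: float = WATER_EPS_R) -> float:
    """Cell constant implied by the coupling capacitance, Kcell = eps_r*eps0/C1."""
    _check_positive(c1=c1, eps_r=eps_r)
    return eps_r * EPSILON_0 / c1


def c1_from_cell_constant(kcell: float, eps_r: float = WATER_EPS_R) -> float:
    """Inverse of :func:`cell_constant_from_c1`."""
    _check_positive(kcell=kcell, eps_r=eps_r)
    return eps_r * EPSILON_0 / kcell


@dataclass(frozen=True)
class CircuitFit:
    """Result of a one-parameter (C1) sweep calibration."""

    params: CircuitParams
    residual_norm: float
    rel_rms_re: float
    rel_rms_im: float
    n_records: int

    @property
    def c1_pf(self) -> float:
        return self.params.c1 * 1e12

    @property
    def kcell(self) -> float:
        return self.params.kcell


_C1_BOUNDS = (1e-15, 1e-9)  # farads


def _c1_initial_guess(sweep: ImpedanceSweep, eps_r: float) -> float:
    """Closed-form start: at the peak, max Re dZ = 1/(2*w*C1).

    Uses the frequency whose sampled conductivities straddle its own
    kappa_0d (the sweep then actually sees the peak); falls back to 1 pF.
    """
    best = None
    for f, grp in sweep.data.groupby("freq_hz"):
        k = grp["kappa_s_per_m"].to_numpy(float)
        k0d = peak_conductivity(float(f), eps_r)
        if k.min() <= k0d <= k.max():
            re_max = grp["re_dz_ohm"].to_numpy(float).max()
            if re_max > 0:
                c1 = 1.0 / (2.0 * (2.0 * np.pi * float(f)) * re_max)
                if _C1_BOUNDS[0] <= c1 <= _C1_BOUNDS[1]:
                    best = c1
                    break
    return best if best is not None else 1e-12


def fit_circuit(sweep: ImpedanceSweep, eps_r: float = WATER_EPS_R,
                kappa_b: float | None = None) -> CircuitFit:
    """Calibrate C1 by joint weighted least squares over both channels.

    Both the real and the negative-imaginary impedance changes across all
    (frequency, conductivity) records are fit with the single free
    parameter C1.  Each channel's residuals are scaled by the channel's
    maximum absolute value so the (much smaller) imaginary channel is not
    drowned by the real one.

    Raises
    ------
    InsufficientDataError
        If the sweep holds fewer than two distinct conductivities, or the
        measured changes are identically zero.
    FitFailureError
        If the optimizer does not converge.
    """
    if kappa_b is None:
        kappa_b = float(sweep.metadata.get("kappa_b", sweep.conductivities.min()))
    if len(sweep.conductivities) < 2:
        raise InsufficientDataError(
            "need >= 2 distinct conductivities to calibrate C1"
        )
    freq = sweep.data["freq_hz"].to_numpy(float)
    kappa = sweep.data["kappa_s_per_m"].to_numpy(float)
    re_obs = sweep.data["re_dz_ohm"].to_numpy(float)
    im_obs = sweep.data["neg_im_dz_ohm"].to_numpy(float)
    scale_re = np.max(np.abs(re_obs))
    scale_im = np.max(np.abs(im_obs))
    if scale_re == 0 and scale_im == 0:
        raise InsufficientDataError("all impedance changes are zero; nothing to fit")
    scale_re = scale_re or 1.0
    scale_im = scale_im or 1.0

    def residuals(x):
        p = CircuitParams(c1=float(10.0 ** x[0]), kappa_b=kappa_b, eps_r=eps_r)
        return np.concatenate([
            (delta_z_real(p, kappa, freq) - re_obs) / scale_re,
            (delta_z_neg_imag(p, kappa, freq) - im_obs) / scale_im,
        ])

    x0 = [math.log10(_c1_initial_guess(sweep, eps_r))]
    sol = least_squares(
        residuals, x0,
        bounds=([math.log10(_C1_BOUNDS[0])], [math.log10(_C1_BOUNDS[1])]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if not sol.success:
        raise FitFailureError(f"C1 calibration did not converge: {sol.message}")
    params = CircuitParams(c1=float(10.0 ** sol.x[0]), kappa_b=kappa_b, eps_r=eps_r)
    re_fit = delta_z_real(params, kappa, freq)
    im_fit = delta_z_neg_imag(params, kappa, freq)
    rel_rms_re = float(np.sqrt(np.mean(((re_fit - re_obs) / scale_re) ** 2)))
    rel_rms_im = float(np.sqrt(np.mean(((im_fit - im_obs) / scale_im) ** 2)))
    return CircuitFit(
        params=params,
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        rel_rms_re=rel_rms_re,
        rel_rms_im=rel_rms_im,
        n_records=len(sweep),
    )
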