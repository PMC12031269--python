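"""Synthetic measurement generator for sweeps, growth runs and temperature.

Emulates the statistical structure of the instrument data the analysis
modules consume: conductivity sweeps with per-channel multiplicative
Gaussian noise at the instrument-reported relative standard deviations,
multi-channel growth experiments driven by sigmoid or two-region model
curves with discretely sampled OD, and temperature jitter that perturbs
conductivity through a linear temperature coefficient (default 2 %/degC).

Noise is multiplicative and mean-one relative to each point's model value,
so a fixed percentage applies across the many decades a conductivity sweep
spans.  Every generator is deterministic given its seed; nonzero noise
without a seed is refused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit import CircuitParams, ImpedanceSweep, delta_z_neg_imag, delta_z_real
from .errors import InvalidInputError
from .growth import GrowthCurve, SigmoidParams, UnifiedGrowthParams, sigmoid_value, unified_growth
from .pipeline import GrowthExperiment


@dataclass(frozen=True)
class NoiseSpec:
    """Relative (fractional) noise levels and the seed that realizes them.

    ``rel_sd_re`` applies to real-part / value channels, ``rel_sd_im`` to
    the imaginary channel of a sweep (defaults to ``rel_sd_re``).
    """

    rel_sd_re: float = 0.0
    rel_sd_im: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.rel_sd_re < 0 or (self.rel_sd_im is not None and self.rel_sd_im < 0):
            raise InvalidInputError("relative noise sd must be >= 0")
        if (self.rel_sd_re > 0 or (self.rel_sd_im or 0) > 0) and self.seed is None:
            raise InvalidInputError("a seed is required for nonzero noise")

    @property
    def sd_im(self) -> float:
        return self.rel_sd_re if self.rel_sd_im is None else self.rel_sd_im

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class TemperatureSpec:
    """Gaussian temperature jitter and its effect on conductivity.

    ``kappa_coeff`` is the fractional conductivity change per degC
    (broth and KCl solutions sit near 2 %/degC).
    """

    mean_c: float = 37.0
    sd_c: float = 0.0
    kappa_coeff: float = 0.02

    def __post_init__(self):
        if self.sd_c < 0:
            raise InvalidInputError("sd_c must be >= 0")


def gen_sweep(params: CircuitParams, freqs, kappas, noise: NoiseSpec,
              baseline_label: str = "UPW") -> ImpedanceSweep:
    """Generate a conductivity sweep from the RC forward model plus noise.

    All (frequency, conductivity) combinations are evaluated; each channel
    gets independent multiplicative Gaussian noise at its own relative sd.
    """
    freqs = np.asarray(freqs, dtype=float)
    kappas = np.asarray(kappas, dtype=float)
    if freqs.size == 0 or kappas.size == 0:
        raise InvalidInputError("freqs and kappas must be non-empty")
    ff, kk = (a.ravel() for a in np.meshgrid(freqs, kappas, indexing="ij"))
    re = np.asarray(delta_z_real(params, kk, ff), dtype=float)
    im = np.asarray(delta_z_neg_imag(params, kk, ff), dtype=float)
    if noise.rel_sd_re > 0 or noise.sd_im > 0:
        rng = noise.rng()
        re = re * (1.0 + noise.rel_sd_re * rng.standard_normal(re.shape))
        im = im * (1.0 + noise.sd_im * rng.standard_normal(im.shape))
    data = pd.DataFrame({
        "freq_hz": ff, "kappa_s_per_m": kk,
        "re_dz_ohm": re, "neg_im_dz_ohm": im,
    })
    meta = {"eps_r": params.eps_r, "kappa_b": params.kappa_b}
    return ImpedanceSweep(data=data, baseline_label=baseline_label, metadata=meta)


def _eval_model(model, t):
    if isinstance(model, SigmoidParams):
        return np.asarray(sigmoid_value(model, t), dtype=float)
    if isinstance(model, UnifiedGrowthParams):
        return np.asarray(unified_growth(model, t), dtype=float)
    raise InvalidInputError(f"unsupported channel model {type(model)}")


def _channel_kind(label: str) -> str:
    if label.startswith("od"):
        return "od"
    if label.startswith("or"):
        return "or"
    return "ncis"


def gen_growth_experiment(channel_models: dict, t_grid, od_interval: float = 0.75,
                          noise: NoiseSpec = NoiseSpec(),
                          od_jitter_frac: float = 0.1,
                          channel_kinds: dict | None = None,
                          metadata: dict | None = None) -> GrowthExperiment:
    """Generate a multi-channel growth experiment.

    ``channel_models`` maps channel labels to :class:`SigmoidParams` or
    :class:`UnifiedGrowthParams`.  Channels tagged ``od`` (by a
    ``channel_kinds`` entry or an ``od``/``or`` label prefix) are sampled
    at ``od_interval`` with uniform timing jitter of
    ``+-od_jitter_frac * od_interval``; all other channels sit on the
    dense ``t_grid``.  A channel whose model amplitude is negative
    (decreasing raw signal, e.g. optical reflection) is flagged for
    inversion in the pipeline.
    """
    if not channel_models:
        raise InvalidInputError("channel_models must not be empty")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or not np.all(np.diff(t_grid) > 0):
        raise InvalidInputError("t_grid must be strictly increasing, length >= 2")
    kinds = dict(channel_kinds or {})
    rng = noise.rng() if noise.seed is not None else np.random.default_rng(0)

    channels: dict[str, GrowthCurve] = {}
    for label, model in channel_models.items():
        kind = kinds.get(label, _channel_kind(label))
        if kind == "od":
            times = np.arange(t_grid[0], t_grid[-1] + od_interval / 2, od_interval)
            if od_jitter_frac > 0:
                jitter = rng.uniform(-od_jitter_frac, od_jitter_frac, times.shape)
                times = times + jitter * od_interval
                times[0] = max(times[0], t_grid[0])
                times = np.maximum.accumulate(times)  # keep monotone
                times = np.unique(times)
        else:
            times = t_grid
        values = _eval_model(model, times)
        if noise.rel_sd_re > 0:
            values = values * (1.0 + noise.rel_sd_re * rng.standard_normal(values.shape))
        decreasing = isinstance(model, SigmoidParams) and model.ua < 0
        channels[label] = GrowthCurve(times, values, channel=label, kind=kind,
                                      invert=decreasing or kind == "or")
    return GrowthExperiment(channels=channels, od_sample_interval=od_interval,
                            metadata=dict(metadata or {}))


def gen_temperature_trace(spec: TemperatureSpec, t_grid,
                          seed: int | None = None) -> pd.DataFrame:
    """Gaussian temperature trace and its conductivity factor.

    Returns columns ``time_h``, ``temp_c`` and ``kappa_factor`` where
    ``kappa_factor = 1 + kappa_coeff * (T - mean_c)``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if spec.sd_c > 0 and seed is None:
        raise InvalidInputError("a seed is required for nonzero temperature jitter")
    rng = np.random.default_rng(seed)
    temp = spec.mean_c + spec.sd_c * rng.standard_normal(t_grid.shape)
    factor = 1.0 + spec.kappa_coeff * (temp - spec.mean_c)
    return pd.DataFrame({"time_h": t_grid, "temp_c": temp, "kappa_factor": factor})


# ---------------------------------------------------------------------------
# Named scenarios with the study's printed parameters.

#: Individual sigmoid parameters per channel: (ua, tau_h, t0_h).
#: Amplitudes: impedance changes at representative channel scales
#: (low-frequency channels sit at hundreds of kiloohm impedance levels,
#: high-frequency at tens), OD rises to ~2, reflection drops by ~0.5.
_SPECIES_SIGMOIDS = {
    "s_epidermidis": {
        "re_dz_15khz": (1.0e5, 0.5, 5.6),
        "re_dz_300khz": (2.0e4, 1.0, 7.2),
        "od_600": (2.0, 0.5, 7.2),
        "or_800": (-0.5, 0.5, 5.1),
    },
    "e_coli": {
        "re_dz_15khz": (1.0e5, 0.5, 3.7),
        "re_dz_300khz": (2.0e4, 1.0, 5.4),
        "od_600": (2.0, 0.5, 6.4),
        "or_800": (-0.5, 0.5, 4.0),
    },
}

#: Unified two-region parameters (tau_u, t0w, t0b) and per-channel
#: resistivity-index ratios (low-frequency / high-frequency).
SPECIES_UNIFIED = {
    "s_epidermidis": {"tau_u": 1.0, "t0w": 5.6, "t0b": 7.2,
                      "rho_low": 3.5, "rho_high": 0.7},
    "e_coli": {"tau_u": 1.0, "t0w": 3.7, "t0b": 5.4,
               "rho_low": 3.5, "rho_high": 0.5},
}

#: Well-plate single-well growth at 160 MHz (ua, tau_h, t0_h).
_WELLPLATE_SIGMOIDS = {
    "re_dz_160mhz": (-10.0, 1.0, 17.2),
    "neg_im_dz_160mhz": (6.0, 1.0, 18.0),
}

SCENARIOS = (
    "kcl_sweep_bottle",
    "kcl_sweep_wellplate",
    "s_epidermidis_bottle",
    "e_coli_bottle",
    "s_epidermidis_wellplate",
)


def species_sigmoid_params(species: str) -> dict[str, SigmoidParams]:
    """Per-channel individual-fit sigmoid parameters for a species."""
    return {ch: SigmoidParams(*vals)
            for ch, vals in _SPECIES_SIGMOIDS[species].items()}


def build_scenario(name: str, seed: int | None = None, noisy: bool = True):
    """Build a named synthetic scenario.

    Returns ``("sweep", ImpedanceSweep)`` or
    ``("experiment", GrowthExperiment)``.  With ``noisy=False`` the output
    is the exact forward model and no seed is needed.
    """
    if name not in SCENARIOS:
        raise InvalidInputError(f"unknown scenario {name!r}; choose from {SCENARIOS}")

    def spec(re_sd, im_sd=None):
        if not noisy:
            return NoiseSpec()
        return NoiseSpec(rel_sd_re=re_sd, rel_sd_im=im_sd, seed=seed)

    if name == "kcl_sweep_bottle":
        params = CircuitParams(c1=6.0e-12, kappa_b=5.5e-6)
        sweep = gen_sweep(params,
                          freqs=[1e4, 5e4, 3e5, 1e6],
                          kappas=np.geomspace(5.5e-6, 1.7, 7),
                          noise=spec(0.007, 0.0004),
                          baseline_label="UPW")
        return "sweep", sweep
    if name == "kcl_sweep_wellplate":
        params = CircuitParams(c1=2.0e-12, kappa_b=1.0e-4)
        sweep = gen_sweep(params,
                          freqs=[5e6, 3e7, 1e8, 3e8],
                          kappas=np.geomspace(1.0e-2, 30.0, 7),
                          noise=spec(0.007, 0.0006),
                          baseline_label="pure water (CO2 saturated)")
        return "sweep", sweep
    if name in ("s_epidermidis_bottle", "e_coli_bottle"):
        species = name.rsplit("_", 1)[0]
        exp = gen_growth_experiment(
            species_sigmoid_params(species),
            t_grid=np.arange(0.0, 14.0 + 1e-9, 0.02),
            od_interval=0.75,
            noise=spec(0.01),
            od_jitter_frac=0.1 if noisy else 0.0,
            metadata={"species": species, "vessel": "lab_bottle"},
        )
        return "experiment", exp
    # s_epidermidis_wellplate: single well, no OD sampling line
    exp = gen_growth_experiment(
        {ch: SigmoidParams(*vals) for ch, vals in _WELLPLATE_SIGMOIDS.items()},
        t_grid=np.arange(12.0, 22.0 + 1e-9, 0.02),
        od_interval=0.75,
        noise=spec(0.01),
        metadata={"species": "s_epidermidis", "vessel": "well_plate"},
    )
    return "experiment", exp


def unified_pair(species: str, t_grid, un: float = 1.0,
                 noise: NoiseSpec = NoiseSpec()) -> tuple[GrowthCurve, GrowthCurve]:
    """Low-/high-frequency channel pair generated from the two-region model."""
    p = SPECIES_UNIFIED[species]
    low = UnifiedGrowthParams(un=un, tau_u=p["tau_u"], t0w=p["t0w"],
                              t0b=p["t0b"], rho_ratio=p["rho_low"])
    high = UnifiedGrowthParams(un=un, tau_u=p["tau_u"], t0w=p["t0w"],
                               t0b=p["t0b"], rho_ratio=p["rho_high"])
    t_grid = np.asarray(t_grid, dtype=float)
    y_lo = np.asarray(unified_growth(low, t_grid), dtype=float)
    y_hi = np.asarray(unified_growth(high, t_grid), dtype=float)
    if noise.rel_sd_re > 0:
        rng = noise.rng()
        y_lo = y_lo * (1.0 + noise.rel_sd_re * rng.standard_normal(y_lo.shape))
        y_hi = y_hi * (1.0 + noise.rel_sd_re * rng.standard_normal(y_hi.shape))
    return (GrowthCurve(t_grid, y_lo, channel="re_dz_15khz"),
            GrowthCurve(t_grid, y_hi, channel="re_dz_300khz"))
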