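"""Ground-truthed simulation of serially sampled venomous snakes.

The generator emulates the data structure the analysis assumes: an
individual sampled every second month over several years, whose venom is
a composition of HPLC peaks with per-peak latent trajectories (constant,
linear drift, or logistic switch in clr space), plus monotone body growth
with measurement error, testosterone rising with size and oscillating
seasonally, and prey records drawn per size quartile.  Every draw is
reproducible from the config seed, and the per-peak ground truth rides
along so downstream mode classification can be scored.

Noise is additive Gaussian in clr space — the geometry every downstream
statistic uses — and compositions are recovered by softmax, so simulated
rows are always valid simplex points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compositional import PeakTable
from .errors import ParameterError
from .hormone import HormoneSeries, prepare_hormone

__all__ = [
    "PeakSpec",
    "GrowthParams",
    "HormoneParams",
    "SimConfig",
    "SimulatedSnake",
    "simulate_snake",
    "simulate_diet",
    "default_peak_specs",
]


@dataclass
class PeakSpec:
    """Latent clr-space trajectory of one peak.

    ``base`` is the latent log-abundance at day 0.  ``slope`` applies in
    the linear mode (clr units/day); ``amplitude``, ``t0`` and ``scale``
    parameterize the logistic mode ``base + A/(1 + exp((t0 - t)/s))``.
    """

    mode: str = "constant"  # constant | linear | logistic
    base: float = 0.0
    slope: float = 0.0
    amplitude: float = 0.0
    t0: float = 0.0
    scale: float = 1.0

    def latent(self, t: np.ndarray) -> np.ndarray:
        if self.mode == "constant":
            return np.full_like(t, self.base, dtype=float)
        if self.mode == "linear":
            return self.base + self.slope * t
        if self.mode == "logistic":
            z = np.clip((self.t0 - t) / self.scale, -500, 500)
            return self.base + self.amplitude / (1.0 + np.exp(z))
        raise ParameterError(f"unknown peak mode {self.mode!r}")


@dataclass
class GrowthParams:
    """von Bertalanffy growth: L(t) = Linf - (Linf - L0) * exp(-k t)."""

    l_inf_cm: float = 110.0
    k_per_day: float = 0.0015
    l0_cm: float = 35.0
    measure_sd_cm: float = 1.0

    def true_svl(self, t: np.ndarray) -> np.ndarray:
        return self.l_inf_cm - (self.l_inf_cm - self.l0_cm) * np.exp(-self.k_per_day * t)


@dataclass
class HormoneParams:
    baseline_ng_ml: float = 0.5
    size_amplitude: float = 2.0  # ln-scale rise from neonate to asymptotic size
    seasonal_amplitude: float = 0.5  # ln-scale annual sinusoid
    noise_sd: float = 0.3  # lognormal (ln-scale) noise
    phase_days: float = 120.0


@dataclass
class SimConfig:
    n_peaks: int = 25
    peak_specs: list[PeakSpec] | None = None
    noise_sigma: float = 0.05  # clr-space sd
    interval_days: int = 61  # bimonthly sampling cadence
    total_days: int = 1220  # ~3.3 years in captivity
    growth: GrowthParams = field(default_factory=GrowthParams)
    hormone: HormoneParams = field(default_factory=HormoneParams)
    diet_quartile_probs: np.ndarray | None = None  # 4 x C
    diet_categories: list[str] | None = None
    svl_range_mm: tuple[float, float] = (512.0, 1595.0)
    snake_id: str = "SIM0001"
    species: str = "C. simulans"
    seed: int = 0


@dataclass
class SimulatedSnake:
    table: PeakTable
    hormone: HormoneSeries
    svl_true: np.ndarray
    true_modes: list[str]
    config: SimConfig


def default_peak_specs(
    n_peaks: int,
    n_logistic: int = 0,
    n_linear: int = 0,
    rng: np.random.Generator | None = None,
    amplitude: float = 2.0,
    t0: float = 500.0,
    scale: float = 40.0,
    slope: float = 1.5e-3,
) -> list[PeakSpec]:
    """Peak specs with the first ``n_logistic`` peaks switching, the next
    ``n_linear`` drifting, and the remainder constant; baselines are drawn
    so peaks differ in abundance as real chromatograms do."""
    if n_logistic + n_linear > n_peaks:
        raise ParameterError("more shifting peaks requested than peaks")
    rng = rng or np.random.default_rng(0)
    bases = rng.normal(0.0, 1.0, size=n_peaks)
    specs = []
    for i in range(n_peaks):
        if i < n_logistic:
            specs.append(
                PeakSpec("logistic", base=bases[i], amplitude=amplitude, t0=t0, scale=scale)
            )
        elif i < n_logistic + n_linear:
            sign = 1 if i % 2 == 0 else -1
            specs.append(PeakSpec("linear", base=bases[i], slope=sign * slope))
        else:
            specs.append(PeakSpec("constant", base=bases[i]))
    return specs


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def simulate_snake(config: SimConfig) -> SimulatedSnake:
    """Draw one individual's full longitudinal dataset from the config."""
    if config.n_peaks < 2:
        raise ParameterError("need at least 2 peaks")
    if config.total_days < config.interval_days:
        raise ParameterError("total_days shorter than one sampling interval")
    rng = np.random.default_rng(config.seed)
    specs = config.peak_specs
    if specs is None:
        specs = default_peak_specs(config.n_peaks, rng=rng)
    if len(specs) != config.n_peaks:
        raise ParameterError("one PeakSpec per peak required")
    if config.noise_sigma < 0:
        raise ParameterError("noise_sigma must be nonnegative")

    days = np.arange(0, config.total_days + 1, config.interval_days)
    t = days.astype(float)

    latent = np.column_stack([spec.latent(t) for spec in specs])
    latent = latent + rng.normal(0.0, config.noise_sigma, size=latent.shape)
    abundance = _softmax(latent)

    svl_true = config.growth.true_svl(t)
    svl_meas = svl_true + rng.normal(0.0, config.growth.measure_sd_cm, size=t.shape)

    # distinct retention times in [10, 125), sorted as peaks elute
    rts = np.sort(rng.uniform(10.0, 124.9, size=config.n_peaks))

    table = PeakTable(
        snake_id=config.snake_id,
        species=config.species,
        sample_days=days,
        svl=svl_meas,
        peak_ids=[f"peak_{i + 1}" for i in range(config.n_peaks)],
        retention_times=rts,
        abundance=abundance,
    )

    hp = config.hormone
    size_frac = (svl_true - config.growth.l0_cm) / max(
        config.growth.l_inf_cm - config.growth.l0_cm, 1e-9
    )
    ln_t = (
        np.log(hp.baseline_ng_ml)
        + hp.size_amplitude * size_frac
        + hp.seasonal_amplitude * np.sin(2 * np.pi * (t + hp.phase_days) / 365.0)
        + rng.normal(0.0, hp.noise_sd, size=t.shape)
    )
    hormone = prepare_hormone(days, [[v] for v in np.exp(ln_t)])

    return SimulatedSnake(
        table=table,
        hormone=hormone,
        svl_true=svl_true,
        true_modes=[s.mode for s in specs],
        config=config,
    )


def simulate_diet(
    config: SimConfig, n_records: int, seed: int | None = None
) -> tuple[np.ndarray, list[str]]:
    """Draw prey records: SVLs uniform over the configured range, prey
    category from the owning equal-width size quartile's multinomial."""
    if config.diet_quartile_probs is None or config.diet_categories is None:
        raise ParameterError("config lacks diet quartile probabilities/categories")
    probs = np.asarray(config.diet_quartile_probs, dtype=float)
    cats = list(config.diet_categories)
    if probs.shape != (4, len(cats)):
        raise ParameterError("diet probabilities must be 4 x n_categories")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
        raise ParameterError("each quartile's probabilities must sum to 1")
    if not cats:
        raise ParameterError("empty prey category set")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.svl_range_mm
    svl = rng.uniform(lo, hi, size=n_records)
    width = (hi - lo + 1) / 4
    quartile = np.minimum(((svl - lo) // width).astype(int), 3)
    prey = [cats[rng.choice(len(cats), p=probs[q])] for q in quartile]
    return svl, prey
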