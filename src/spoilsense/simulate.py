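"""Synthetic study generator: microbial growth plus linked sensor forward models.

The generator emulates the structure of the storage trial the pipeline was
designed for: *Alaria esculenta* from two aquaculture origins (MI, SAMS)
over 2-3 harvest years, stored isothermally at 0/5/10/15 degC, with four
replicate samples per sampling point and total viable counts (TVC) spanning
roughly 1.8-9.5 log CFU/g.  Three sensor modalities are simulated from the
same TVC trajectories:

* FT-IR absorbance spectra (4000-400 cm^-1, 1 cm^-1 grid) built from
  Gaussian bands at the wavenumbers where spoilage chemistry shows up
  (lipid esters 1745, amide II 1548, carbohydrates 1156/1074/1043 cm^-1, a
  broad uninformative water band at 1637 cm^-1), a gentle polynomial
  baseline, per-sample multiplicative scatter and additive noise.
* MSI feature tables (18 band means + 18 band SDs) dominated by an
  origin/year "color" nuisance in the visible bands, with only a weak TVC
  coupling — mirroring the fact that surface color tracks harvest, not
  microbial load.
* E-nose tables: 12 metal-oxide sensors reported as the relative
  resistance change (R - R0)/R0, with responses stronger for fresh than
  spoiled samples (for most sensors) and stronger for MI than SAMS.

Growth model: the study fits no kinetics, so trajectories here come from a
logistic curve in log10 counts with a lag phase, whose specific rate
follows the Ratkowsky square-root law mu(T) = (b (T - Tmin))^2.  Simulated
TVC is floored at 1.0 log CFU/g, the plate-count detection limit visible in
the study's tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import FeatureTable, SampleRecord, SpectralDataset
from .preprocess import MSI_WAVELENGTHS, enose_response

__all__ = [
    "GrowthParams",
    "PeakSpec",
    "SyntheticConfig",
    "default_config",
    "specific_growth_rate",
    "simulate_growth",
    "generate_study_design",
    "generate_ftir_dataset",
    "generate_msi_dataset",
    "generate_enose_dataset",
    "ENOSE_SENSORS",
    "DETECTION_FLOOR",
]

#: FOX 3000 metal-oxide sensor array.
ENOSE_SENSORS = (
    "LY2/LG", "LY2/G", "LY2/AA", "LY2/GH", "LY2/gCTL", "LY2/gCT",
    "T30/1", "P10/1", "P10/2", "P40/1", "T70/2", "PA/2",
)

#: Plate-count detection limit, log10 CFU/g.
DETECTION_FLOOR = 1.0

DEFAULT_SEED = 20220918


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the logistic-with-lag growth curve in log10 counts."""

    n0: float  # initial load, log10 CFU/g
    nmax: float  # carrying capacity, log10 CFU/g
    ratkowsky_b: float  # sqrt(rate) slope, 1/(degC sqrt(day))
    tmin: float  # notional minimum growth temperature, degC
    lag: float = 0.0  # lag time, days

    def __post_init__(self) -> None:
        if not self.n0 < self.nmax:
            raise ValueError("n0 must be < nmax")
        if self.ratkowsky_b <= 0:
            raise ValueError("ratkowsky_b must be > 0")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian FT-IR band and how its amplitude responds to the sample.

    ``tvc_coefficient`` is the absorbance change per log CFU/g: negative
    for substrates consumed by the microbiota, positive for metabolites
    produced, zero for bands carrying no spoilage information.
    """

    center: float  # cm^-1
    width: float  # Gaussian sigma, cm^-1
    base_amplitude: float
    tvc_coefficient: float = 0.0
    origin_offset: tuple[tuple[str, float], ...] = ()
    year_offset: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")

    def amplitude(self, tvc: float, origin: str, year: int) -> float:
        a = self.base_amplitude + self.tvc_coefficient * tvc
        a += dict(self.origin_offset).get(origin, 0.0)
        a += dict(self.year_offset).get(year, 0.0)
        return a


def _default_design() -> tuple:
    # (origin, year) -> storage temperatures, mirroring the study's plan
    return (
        (("MI", 2019), (5.0, 10.0)),
        (("MI", 2020), (0.0, 5.0, 10.0, 15.0)),
        (("MI", 2021), (5.0,)),
        (("SAMS", 2019), (5.0, 15.0)),
        (("SAMS", 2020), (0.0, 5.0, 10.0, 15.0)),
    )


def _default_growth() -> tuple:
    # n0 taken from the study's day-0 counts per origin/year; shared
    # Ratkowsky parameters chosen so 0 degC is nearly flat and 15 degC
    # saturates by day 3-4.
    b, tmin = 0.065, -5.0
    return (
        (("MI", 2019), GrowthParams(4.9, 9.7, b, tmin)),
        (("MI", 2020), GrowthParams(3.0, 9.6, b, tmin)),
        (("MI", 2021), GrowthParams(2.3, 9.0, b, tmin, lag=1.0)),
        (("SAMS", 2019), GrowthParams(5.1, 9.8, b, tmin)),
        (("SAMS", 2020), GrowthParams(1.8, 9.5, b, tmin, lag=0.5)),
    )


def _default_peaks() -> tuple[PeakSpec, ...]:
    return (
        # lipid ester C=O, consumed during spoilage
        PeakSpec(1745.0, 10.0, 0.16, -0.008),
        # broad water band: big, carries no TVC information
        PeakSpec(1637.0, 35.0, 0.90, 0.0, origin_offset=(("MI", 0.03),)),
        # amide II (protein), consumed
        PeakSpec(1548.0, 15.0, 0.35, -0.012),
        # sulphate S=O stretching
        PeakSpec(1410.0, 14.0, 0.20, 0.0, year_offset=((2019, 0.02), (2021, -0.02))),
        # phenolics, origin-linked
        PeakSpec(1260.0, 12.0, 0.15, 0.0, origin_offset=(("MI", 0.05),)),
        # sulphate esters (fucoidan), origin/year nuisance
        PeakSpec(1220.0, 12.0, 0.18, 0.0, year_offset=((2020, 0.02),)),
        # carbohydrates, consumed
        PeakSpec(1156.0, 10.0, 0.26, -0.010),
        PeakSpec(1074.0, 9.0, 0.30, -0.010, origin_offset=(("SAMS", 0.02),)),
        PeakSpec(1043.0, 9.0, 0.28, -0.009),
        # primary alcohols, produced by microbial metabolism
        PeakSpec(1020.0, 8.0, 0.12, 0.006),
        # weak monosaccharide C-H bands
        PeakSpec(880.0, 12.0, 0.10, 0.0, year_offset=((2019, 0.01),)),
    )


def _default_enose_directions() -> tuple:
    # +1: fresh-stronger (response decays with spoilage); -1: metabolite
    # sensors whose response grows. Ethanol/amine sensors respond to
    # fermentation products.
    fresh_stronger = {s: 1 for s in ENOSE_SENSORS}
    fresh_stronger["LY2/AA"] = -1
    fresh_stronger["PA/2"] = -1
    return tuple(fresh_stronger.items())


def _default_enose_amplitudes() -> tuple:
    amps = (0.25, 0.30, 0.40, 0.35, 0.20, 0.22, 1.6, 1.8, 1.5, 1.2, 1.4, 0.9)
    return tuple(zip(ENOSE_SENSORS, amps))


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything the generators need; fixed seed implies identical output."""

    design: tuple = field(default_factory=_default_design)
    days: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 7.0)
    replicates: int = 4
    growth: tuple = field(default_factory=_default_growth)
    replicate_sd: float = 0.4  # log CFU/g, typical of the study's +/-SD columns
    # FT-IR forward model
    grid_high: float = 4000.0
    grid_low: float = 400.0
    grid_step: float = 1.0
    peaks: tuple = field(default_factory=_default_peaks)
    baseline: tuple = (0.05, 0.02, 0.01)  # polynomial in nu/4000
    scatter_sd: float = 0.15  # log-normal multiplicative scatter
    noise_sd: float = 0.005  # additive absorbance noise
    # MSI forward model
    msi_nuisance_sd: float = 0.08  # per origin/year color shift, visible bands
    msi_tvc_coef: float = 0.004  # reflectance change per log CFU/g
    msi_noise_sd: float = 0.01
    # e-nose forward model
    enose_gain: tuple = (("MI", 1.2), ("SAMS", 0.8))
    enose_amplitude: tuple = field(default_factory=_default_enose_amplitudes)
    enose_direction: tuple = field(default_factory=_default_enose_directions)
    enose_midpoint: float = 6.0  # log CFU/g at half response
    enose_steepness: float = 1.2  # log CFU/g per logistic unit
    enose_noise_sd: float = 0.02
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if min(self.noise_sd, self.scatter_sd, self.replicate_sd,
               self.msi_noise_sd, self.enose_noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not self.design:
            raise ValueError("empty study design")


def default_config(**overrides) -> SyntheticConfig:
    """The study-like default configuration, with keyword overrides."""
    return SyntheticConfig(**overrides)


# ---------------------------------------------------------------------------
# Growth


def specific_growth_rate(params: GrowthParams, temp: float) -> float:
    """Ratkowsky square-root law: mu(T) = (b (T - Tmin))^2, zero at/below Tmin."""
    if temp <= params.tmin:
        return 0.0
    return (params.ratkowsky_b * (temp - params.tmin)) ** 2


def simulate_growth(params: GrowthParams, temp: float, t: float) -> float:
    """Deterministic mean TVC (log10 CFU/g) after t days at ``temp``.

    Logistic growth in log counts with carrying capacity ``nmax``,
    starting exactly at ``n0``, after a lag of ``params.lag`` days.
    Temperatures at or below ``tmin`` yield no growth.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    mu = specific_growth_rate(params, temp)
    t_eff = max(t - params.lag, 0.0)
    if mu == 0.0 or t_eff == 0.0:
        return params.n0
    ratio = (params.nmax - params.n0) / params.n0
    return params.nmax / (1.0 + ratio * math.exp(-mu * t_eff))


def _growth_lookup(config: SyntheticConfig) -> dict:
    return dict(config.growth)


def generate_study_design(config: SyntheticConfig) -> list[SampleRecord]:
    """One SampleRecord per origin x year x temperature x day x replicate.

    Replicate TVC = simulated mean + Normal(0, replicate_sd), floored at
    the plate-count detection limit.
    """
    growth = _growth_lookup(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    records: list[SampleRecord] = []
    for (origin, year), temps in config.design:
        params = growth[(origin, year)]
        for temp in temps:
            for day in config.days:
                mean_tvc = simulate_growth(params, temp, day)
                for rep in range(1, config.replicates + 1):
                    tvc = mean_tvc + rng.normal(0.0, config.replicate_sd)
                    tvc = max(tvc, DETECTION_FLOOR)
                    sid = f"{origin}-{year}-T{temp:g}-d{day:g}-r{rep}"
                    records.append(
                        SampleRecord(sid, origin, year, temp, day, round(tvc, 6))
                    )
    if not records:
        raise ValueError("empty study design")
    return records


# ---------------------------------------------------------------------------
# FT-IR


def _grid(config: SyntheticConfig) -> np.ndarray:
    # acquisition (descending) order
    return np.arange(config.grid_high, config.grid_low - 0.5 * config.grid_step,
                     -config.grid_step)


def generate_ftir_dataset(config: SyntheticConfig | None = None,
                          records: list[SampleRecord] | None = None) -> SpectralDataset:
    """Forward-model FT-IR spectra for every sample in the design.

    spectrum = scatter * (baseline + sum_p amplitude_p * gauss(nu)) + noise
    with amplitude_p = base + tvc_coefficient * tvc + origin/year offsets.
    """
    config = config or SyntheticConfig()
    if records is None:
        records = generate_study_design(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    nu = _grid(config)
    x = nu / 4000.0
    c0, c1, c2 = config.baseline
    baseline = c0 + c1 * x + c2 * x**2
    profiles = np.stack([np.exp(-0.5 * ((nu - p.center) / p.width) ** 2)
                         for p in config.peaks])
    spectra = np.empty((len(records), nu.size))
    for i, rec in enumerate(records):
        amps = np.array([p.amplitude(rec.tvc, rec.origin, rec.harvest_year)
                         for p in config.peaks])
        clean = baseline + amps @ profiles
        scatter = math.exp(rng.normal(0.0, config.scatter_sd)) if config.scatter_sd else 1.0
        noise = rng.normal(0.0, config.noise_sd, nu.size) if config.noise_sd else 0.0
        spectra[i] = scatter * clean + noise
    return SpectralDataset(nu, spectra, list(records))


# ---------------------------------------------------------------------------
# MSI


def _reflectance_profile() -> np.ndarray:
    # brown-seaweed-like base reflectance: dark in the visible, bright NIR
    lam = np.array(MSI_WAVELENGTHS, dtype=float)
    vis = 0.12 + 0.10 / (1.0 + np.exp(-(lam - 690.0) / 25.0))
    nir = 0.25 / (1.0 + np.exp(-(lam - 760.0) / 40.0))
    return vis + nir


def generate_msi_dataset(config: SyntheticConfig | None = None,
                         records: list[SampleRecord] | None = None) -> FeatureTable:
    """Per-sample 18 band means + 18 band SDs with a dominant color nuisance.

    The origin/year nuisance acts on the visible bands (<= 700 nm), the TVC
    coupling is weak and mostly in the NIR — so harvest identity, not
    microbial load, dominates the feature space, as in the real instrument.
    """
    config = config or SyntheticConfig()
    if records is None:
        records = generate_study_design(config)
    ss = np.random.SeedSequence([config.seed, 3])
    rng_nuisance, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    lam = np.array(MSI_WAVELENGTHS, dtype=float)
    visible = lam <= 700.0
    base = _reflectance_profile()
    # fixed per-(origin, year) color shift, drawn once per dataset
    cells = sorted({(r.origin, r.harvest_year) for r in records})
    shift = {}
    for cell in cells:
        s = rng_nuisance.normal(0.0, config.msi_nuisance_sd, lam.size)
        s[~visible] *= 0.2
        shift[cell] = s
    tvc_load = np.where(visible, 0.3, 1.0)  # TVC couples mostly in the NIR
    means = np.empty((len(records), lam.size))
    sds = np.empty_like(means)
    for i, rec in enumerate(records):
        mu = base + shift[(rec.origin, rec.harvest_year)] \
            - config.msi_tvc_coef * rec.tvc * tvc_load
        means[i] = mu + rng_noise.normal(0.0, config.msi_noise_sd, lam.size)
        sds[i] = np.abs(0.02 + 0.002 * rec.tvc
                        + rng_noise.normal(0.0, config.msi_noise_sd * 0.5, lam.size))
    names = [f"mean_{int(w)}" for w in lam] + [f"sd_{int(w)}" for w in lam]
    return FeatureTable(names, np.hstack([means, sds]), list(records))


# ---------------------------------------------------------------------------
# E-nose


def generate_enose_dataset(config: SyntheticConfig | None = None,
                           records: list[SampleRecord] | None = None) -> FeatureTable:
    """Maximum (R - R0)/R0 response of the 12-sensor array per sample.

    Each sensor follows a logistic response in TVC: fresh-stronger sensors
    decay from their full amplitude towards zero as the sample spoils;
    metabolite sensors do the opposite.  MI samples carry a higher gain
    than SAMS at equal microbial load.
    """
    config = config or SyntheticConfig()
    if records is None:
        records = generate_study_design(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    gain = dict(config.enose_gain)
    amp = dict(config.enose_amplitude)
    direction = dict(config.enose_direction)
    values = np.empty((len(records), len(ENOSE_SENSORS)))
    for i, rec in enumerate(records):
        g = gain[rec.origin]
        decay = 1.0 / (1.0 + math.exp((rec.tvc - config.enose_midpoint)
                                      / config.enose_steepness))
        for j, sensor in enumerate(ENOSE_SENSORS):
            f = decay if direction[sensor] > 0 else 1.0 - decay
            raw = g * amp[sensor] * f + rng.normal(0.0, config.enose_noise_sd)
            # report through the resistance-ratio definition
            r0 = 100.0
            values[i, j] = enose_response(r0 * (1.0 + raw), r0)
    return FeatureTable(list(ENOSE_SENSORS), values, list(records))
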