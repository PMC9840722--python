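"""Synthetic thermal-series and phantom-scene generator.

Emulates the statistical structure of the measured data so the whole
pipeline is testable without the deposited measurements:

* three base materials -- water, 50 mmol/L CaCl2 and 600 mmol/L CaCl2 --
  with near-linear LAC-vs-temperature trends over ~33-90 degC, a positive
  slope in the 33-45 keV bin and negative slopes elsewhere (the
  phenomenological signature of temperature-dependent Compton scatter);
* a quadratic dependence of thermal sensitivity on CaCl2 concentration, so
  the 300 mmol/L sensitivity is *not* the midpoint of the water and
  600 mmol/L values -- the non-linearity the regressor must capture and the
  linear mixture model misses;
* test materials: a "similar" 300 mmol/L-like series (baseline equal to the
  50/50 water / 600 mmol/L mixture, slope from the quadratic law) over
  35-60 degC, and a "dissimilar" organic surrogate (baseline LACs perturbed
  off the basis span, independently perturbed slopes) over 38-50 degC;
* phantom scenes: threshold-paired projection acquisitions of the square
  phantom consistent with the bin-subtraction inversion.

Default magnitudes are order-of-magnitude choices for water-like liquids
(LACs a few times 1e-2 mm^-1, sensitivities ~1e-5 mm^-1/degC), not claims
about the deposited measurements. All generators are pure functions of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ExtrapolationError
from .geometry import (
    EnergyBinning,
    PhantomGeometry,
    ProjectionFrame,
    bins_to_threshold_counts,
    simulate_projection_pair,
)
from .materials import BASELINE_TEMPERATURE_C, BaseMaterialSet, ThermalSeries

# -- frozen scenario defaults (mm^-1 and mm^-1 per degC) ---------------------

#: Baseline (33 degC) LAC of water per bin.
WATER_MU0_PER_BIN = np.array([0.0340, 0.0260, 0.0220, 0.0190])

#: Baseline LAC increase per mmol/L of CaCl2, per bin (strongest at low energy).
MU0_PER_MMOL = np.array([3.0e-5, 1.5e-5, 0.8e-5, 0.4e-5])

#: Fractional saturation of the concentration dependence at 600 mmol/L, per
#: bin. Strongest at low energy, so the spectral *shape* of the solute
#: contribution changes with concentration; without this the three base
#: spectra would be affinely dependent and volume fractions unidentifiable.
MU0_SATURATION_AT_600 = np.array([0.10, 0.06, 0.03, 0.015])


def baseline_lac_for_concentration(c_mmol: float) -> np.ndarray:
    """Baseline (33 degC) LAC of an aqueous CaCl2 solution, per bin."""
    sat = 1.0 - MU0_SATURATION_AT_600 * (c_mmol / 600.0)
    return WATER_MU0_PER_BIN + MU0_PER_MMOL * c_mmol * sat

#: Thermal sensitivity of water per bin; positive in the 33-45 keV bin,
#: negative elsewhere.
WATER_SLOPE_PER_BIN = np.array([-1.4e-5, +0.9e-5, -1.1e-5, -0.9e-5])

#: Base-material tabulation grid: every 5 degC from the 33 degC baseline.
DEFAULT_BASE_TEMPERATURES = np.arange(33.0, 94.0, 5.0)

DEFAULT_FLUX_PER_BIN = np.array([1.0e4, 1.0e4, 1.0e4, 1.0e4])

SIMILAR_CONCENTRATION_MMOL = 300.0
SIMILAR_TEMPERATURES = np.arange(35.0, 61.0, 5.0)
DISSIMILAR_TEMPERATURES = np.arange(38.0, 51.0, 3.0)

_SIGN_PATTERN = np.array([-1.0, +1.0, -1.0, -1.0])


@dataclass(frozen=True)
class SensitivityLaw:
    """Quadratic map from CaCl2 concentration to per-bin thermal slope.

    slope(c) = water_slope * (1 + beta*c + gamma*c^2). The defaults give a
    600 mmol/L sensitivity 2.9x water's and a 300 mmol/L sensitivity ~8%
    below the water/600 linear midpoint -- a genuinely non-linear
    concentration dependence.
    """

    water_slope_per_bin: tuple[float, ...] = tuple(WATER_SLOPE_PER_BIN)
    beta_per_mmol: float = 2.1667e-3
    gamma_per_mmol2: float = 1.6667e-6

    def __post_init__(self):
        object.__setattr__(self, "water_slope_per_bin",
                           tuple(float(s) for s in self.water_slope_per_bin))
        if self.gamma_per_mmol2 == 0:
            raise ValueError("the sensitivity law must be strictly quadratic")


@dataclass(frozen=True)
class MaterialSpec:
    """Generative parameters of one material's thermal series."""

    name: str
    mu0_per_bin: np.ndarray
    slope_per_bin: np.ndarray
    concentration_mmol: float | None = None
    enforce_sign_pattern: bool = True

    def __post_init__(self):
        object.__setattr__(self, "mu0_per_bin",
                           np.asarray(self.mu0_per_bin, dtype=float))
        object.__setattr__(self, "slope_per_bin",
                           np.asarray(self.slope_per_bin, dtype=float))
        if np.any(self.mu0_per_bin <= 0):
            raise ValueError("baseline LACs must be strictly positive")
        if self.enforce_sign_pattern and np.any(
                self.slope_per_bin * _SIGN_PATTERN < 0):
            raise ValueError(
                "slopes must be positive in the 33-45 keV bin and negative "
                "elsewhere (set enforce_sign_pattern=False to override)")
        if np.any(np.abs(self.slope_per_bin) * 60.0 >= self.mu0_per_bin):
            raise ValueError("slopes would drive the LAC non-positive in range")


def sensitivity_from_concentration(
    c_mmol: float, law: SensitivityLaw = SensitivityLaw()
) -> np.ndarray:
    """Per-bin thermal slope at a CaCl2 concentration (quadratic law)."""
    if c_mmol < 0:
        raise ValueError("concentration must be non-negative")
    g = 1.0 + law.beta_per_mmol * c_mmol + law.gamma_per_mmol2 * c_mmol**2
    return np.asarray(law.water_slope_per_bin) * g


def material_spec_for_concentration(
    c_mmol: float, law: SensitivityLaw = SensitivityLaw(), name: str | None = None
) -> MaterialSpec:
    """Material spec for an aqueous CaCl2 solution of the given strength."""
    if name is None:
        name = "water" if c_mmol == 0 else f"cacl2_{c_mmol:g}mmol"
    return MaterialSpec(
        name=name,
        mu0_per_bin=baseline_lac_for_concentration(c_mmol),
        slope_per_bin=sensitivity_from_concentration(c_mmol, law),
        concentration_mmol=c_mmol,
    )


def make_base_series(
    spec: MaterialSpec,
    temperatures: np.ndarray = DEFAULT_BASE_TEMPERATURES,
    noise_sd_rel: float = 0.0,
    seed: int | None = None,
    binning: EnergyBinning = EnergyBinning(),
) -> ThermalSeries:
    """Tabulate mu(T) = mu0 + slope * (T - 33) with optional Gaussian noise.

    Noise SD is ``noise_sd_rel`` x mu0 per bin, seeded. Temperatures must
    lie within [30, 95] degC and include the 33 degC baseline.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    if np.any((temperatures < 30.0) | (temperatures > 95.0)):
        raise ValueError("temperatures must lie within [30, 95] degC")
    if not np.any(np.isclose(temperatures, BASELINE_TEMPERATURE_C)):
        raise ValueError("the 33 degC baseline must be tabulated")
    dt = temperatures[:, None] - BASELINE_TEMPERATURE_C
    mu = spec.mu0_per_bin[None, :] + spec.slope_per_bin[None, :] * dt
    if noise_sd_rel > 0:
        rng = np.random.default_rng(seed)
        mu = mu + rng.normal(0.0, noise_sd_rel * spec.mu0_per_bin,
                             size=mu.shape)
    if np.any(mu <= 0):
        raise ValueError("material spec drives the LAC non-positive")
    return ThermalSeries(spec.name, temperatures, mu, binning=binning)


def default_base_set(
    law: SensitivityLaw = SensitivityLaw(),
    temperatures: np.ndarray = DEFAULT_BASE_TEMPERATURES,
    noise_sd_rel: float = 0.0,
    seed: int | None = None,
) -> BaseMaterialSet:
    """Water, 50 mmol/L and 600 mmol/L CaCl2 base-material series."""
    series = []
    for i, c in enumerate((0.0, 50.0, 600.0)):
        series.append(make_base_series(
            material_spec_for_concentration(c, law), temperatures,
            noise_sd_rel=noise_sd_rel,
            seed=None if seed is None else seed + i))
    return BaseMaterialSet(series)


def make_test_materials(
    law: SensitivityLaw = SensitivityLaw(),
    seed: int = 0,
) -> tuple[ThermalSeries, ThermalSeries]:
    """The two held-out evaluation series.

    ``similar``: a 300 mmol/L-like solution; its baseline LAC equals the
    equal-volume water / 600 mmol/L mixture (the composition identity) but
    its slope follows the quadratic law, so the linear mixture model is
    wrong on it by construction. Tabulated over 35-60 degC.

    ``dissimilar``: an organic surrogate outside the basis span -- water's
    baseline perturbed by up to +-5% per bin and independently perturbed
    slopes (+-10%) with the standard sign pattern. Tabulated over
    38-50 degC. This emulates dissimilarity in attenuation structure, not
    any specific foodstuff's composition.
    """
    rng = np.random.default_rng(seed)
    # equal-volume water / 600 mmol/L mixture: baseline is the elementwise
    # mean of the two base spectra; sensitivity follows the quadratic law
    # at 300 mmol/L, NOT the mixture-weighted slope.
    mu0_sim = 0.5 * (baseline_lac_for_concentration(0.0)
                     + baseline_lac_for_concentration(600.0))
    slope_sim = sensitivity_from_concentration(SIMILAR_CONCENTRATION_MMOL, law)
    similar = ThermalSeries(
        "similar_300mmol",
        SIMILAR_TEMPERATURES,
        mu0_sim[None, :] + slope_sim[None, :]
        * (SIMILAR_TEMPERATURES[:, None] - BASELINE_TEMPERATURE_C),
    )

    mu0_d = WATER_MU0_PER_BIN * (1.0 + rng.uniform(-0.05, 0.05, size=4))
    slope_d = WATER_SLOPE_PER_BIN * (1.0 + rng.uniform(-0.10, 0.10, size=4))
    dissimilar = ThermalSeries(
        "dissimilar_organic",
        DISSIMILAR_TEMPERATURES,
        mu0_d[None, :] + slope_d[None, :]
        * (DISSIMILAR_TEMPERATURES[:, None] - BASELINE_TEMPERATURE_C),
    )
    return similar, dissimilar


def make_phantom_scene(
    geometry: PhantomGeometry,
    series: ThermalSeries,
    temperature_C: float,
    flux_per_bin: np.ndarray = DEFAULT_FLUX_PER_BIN,
    noise: bool = False,
    seed: int | None = None,
    parallel: bool = False,
) -> dict[int, tuple[ProjectionFrame, ProjectionFrame]]:
    """Threshold acquisitions (empty, filled) of the phantom at one temperature.

    The material's per-bin LAC is interpolated from the series; per-bin
    expected counts are simulated along exact rays and summed into the four
    threshold frames (8/33/45/60 keV). Poisson noise, when enabled, is
    drawn independently per threshold acquisition, as separate readouts
    would be.
    """
    if not series.t_min <= temperature_C <= series.t_max:
        raise ExtrapolationError(
            f"{temperature_C} degC outside the series range "
            f"[{series.t_min}, {series.t_max}]")
    mu = series.lac_at(temperature_C).mu_per_bin
    empty_bins, filled_bins = simulate_projection_pair(
        geometry, mu, np.asarray(flux_per_bin, dtype=float),
        noise=False, parallel=parallel)
    thr_empty = bins_to_threshold_counts([f.counts for f in empty_bins])
    thr_filled = bins_to_threshold_counts([f.counts for f in filled_bins])

    rng = np.random.default_rng(seed)
    scene = {}
    for thr in (8, 33, 45, 60):
        e, f = thr_empty[thr], thr_filled[thr]
        if noise:
            e = rng.poisson(e).astype(float)
            f = rng.poisson(f).astype(float)
        scene[thr] = (ProjectionFrame(e, thr, "empty"),
                      ProjectionFrame(f, thr, "filled"))
    return scene
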