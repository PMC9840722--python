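"""Spectral material model: basis decomposition and thermal sensitivity.

The linear attenuation coefficient (LAC, mu) of a volumetric mixture is the
volume-fraction-weighted combination of the base materials' LACs in every
energy bin, with the fractions summing to one:

    mu(E_k) = sum_i V_i * mu_i(E_k),   sum_i V_i = 1.

With four energy bins and three bases this is an overdetermined linear
system; :func:`decompose` solves it as an equality-constrained least-squares
problem (the sum constraint enforced exactly).

Thermal behaviour: over roughly 30-90 degC each base's LAC is close to
linear in temperature, mu_i(T) ~ alpha_i (T - T0) + mu_i(T0), where the
slope alpha_i (the thermal sensitivity, dominated by thermal expansion) is
negative in all bins except 33-45 keV. The corresponding CT-number model is

    Delta CT(T) ~ -(1000 + CT(T0)) * alpha * Delta T

with alpha the volumetric thermal-expansion coefficient. The naive mixture
thermal model alpha' = sum V_i alpha_i, beta' = sum V_i mu_i(T0) is exact
only when sensitivity is linear in composition; measured sensitivities are
quadratic/higher-order in solute concentration, which is precisely why the
temperature regressor exists.

Units: mm^-1 throughout this module; :func:`mu_mm_to_cm` / :func:`mu_cm_to_mm`
convert at interface boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import stats

from .errors import ExtrapolationError, IllConditionedBasisError
from .geometry import EnergyBinning

#: Reference/baseline temperature (degC) for residuals and decompositions.
BASELINE_TEMPERATURE_C = 33.0

_COND_LIMIT = 1e10


def mu_mm_to_cm(mu_mm):
    """Convert a LAC from mm^-1 to cm^-1."""
    return np.asarray(mu_mm, dtype=float) * 10.0


def mu_cm_to_mm(mu_cm):
    """Convert a LAC from cm^-1 to mm^-1."""
    return np.asarray(mu_cm, dtype=float) / 10.0


@dataclass
class SpectralLAC:
    """A material's per-bin LAC (mm^-1) at one temperature."""

    material_id: str
    temperature_C: float
    mu_per_bin: np.ndarray

    def __post_init__(self):
        self.mu_per_bin = np.asarray(self.mu_per_bin, dtype=float)
        if np.any(self.mu_per_bin <= 0):
            raise ValueError("LACs must be strictly positive")
        if not 20.0 <= self.temperature_C <= 95.0:
            raise ValueError(
                f"temperature {self.temperature_C} degC outside the supported "
                "20-95 degC range")


@dataclass
class ThermalSeries:
    """Tabulated per-bin LAC (mm^-1) versus temperature for one material."""

    material_id: str
    temperatures_C: np.ndarray
    mu: np.ndarray  # shape (n_temperatures, n_bins)
    binning: EnergyBinning = field(default_factory=EnergyBinning)
    baseline_C: float = BASELINE_TEMPERATURE_C

    def __post_init__(self):
        self.temperatures_C = np.asarray(self.temperatures_C, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        order = np.argsort(self.temperatures_C)
        self.temperatures_C = self.temperatures_C[order]
        self.mu = self.mu[order]
        if self.mu.shape != (self.temperatures_C.size, self.binning.n_bins):
            raise ValueError("mu must be (n_temperatures, n_bins)")

    @property
    def t_min(self) -> float:
        return float(self.temperatures_C[0])

    @property
    def t_max(self) -> float:
        return float(self.temperatures_C[-1])

    def lac_at(self, temperature_C: float) -> SpectralLAC:
        """Linearly interpolated spectral LAC at ``temperature_C``."""
        if not self.t_min <= temperature_C <= self.t_max:
            raise ExtrapolationError(
                f"{temperature_C} degC outside [{self.t_min}, {self.t_max}] "
                f"for material '{self.material_id}'")
        mu = np.array([
            np.interp(temperature_C, self.temperatures_C, self.mu[:, b])
            for b in range(self.mu.shape[1])
        ])
        return SpectralLAC(self.material_id, temperature_C, mu)


@dataclass
class BaseMaterialSet:
    """Ordered base materials sharing binning and baseline temperature."""

    bases: list[ThermalSeries]

    def __post_init__(self):
        if len(self.bases) < 2:
            raise ValueError("need at least two base materials")
        b0 = self.bases[0]
        for b in self.bases[1:]:
            if b.binning != b0.binning:
                raise ValueError("base materials disagree in energy binning")
            if b.baseline_C != b0.baseline_C:
                raise ValueError("base materials disagree in baseline temperature")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def baseline_C(self) -> float:
        return self.bases[0].baseline_C

    def matrix_at(self, temperature_C: float) -> np.ndarray:
        """Basis LAC matrix, shape (n_bins, n_bases)."""
        return np.column_stack(
            [b.lac_at(temperature_C).mu_per_bin for b in self.bases])


@dataclass
class VolumeFractions:
    """Decomposition result: fractions (summing to 1) plus fit residual.

    Fractions may fall outside [0, 1] for targets dissimilar to the bases;
    they are flagged via :attr:`out_of_range`, never clipped, so the
    residual keeps its diagnostic value.
    """

    fractions: np.ndarray
    residual_norm: float

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if not np.isclose(self.fractions.sum(), 1.0, atol=1e-9):
            raise ValueError("volume fractions must sum to 1")

    @property
    def out_of_range(self) -> bool:
        return bool(np.any((self.fractions < 0) | (self.fractions > 1)))


@dataclass
class SensitivityFit:
    """Per-bin linear fit of LAC vs temperature."""

    material_id: str
    slope_per_bin: np.ndarray      # mm^-1 per degC
    intercept_per_bin: np.ndarray  # mm^-1 at the baseline temperature
    r2_per_bin: np.ndarray
    baseline_C: float = BASELINE_TEMPERATURE_C


def mix_spectral_lac(
    fractions: np.ndarray | VolumeFractions,
    bases: BaseMaterialSet,
    temperature_C: float,
    material_id: str = "mixture",
) -> SpectralLAC:
    """Volume-fraction-weighted spectral LAC of a mixture of the bases."""
    f = fractions.fractions if isinstance(fractions, VolumeFractions) else np.asarray(fractions, dtype=float)
    if f.shape != (len(bases),):
        raise ValueError("one fraction per base material is required")
    if not np.isclose(f.sum(), 1.0, atol=1e-9):
        raise ValueError("volume fractions must sum to 1")
    mu = bases.matrix_at(temperature_C) @ f
    return SpectralLAC(material_id, temperature_C, mu)


def decompose(
    target: SpectralLAC,
    bases: BaseMaterialSet,
    temperature_C: float | None = None,
) -> VolumeFractions:
    """Solve for the volume fractions of ``target`` in the base materials.

    All energy bins enter a least-squares fit while the sum-to-one
    constraint is enforced exactly (KKT system). The basis LACs are taken
    at ``temperature_C`` (default: the set's baseline, matching the
    baseline-scan design of the temperature regressor).
    """
    if temperature_C is None:
        temperature_C = bases.baseline_C
    B = bases.matrix_at(temperature_C)
    n_bins, n_bases = B.shape
    if n_bins < n_bases - 1:
        raise ValueError("too few energy bins for this number of bases")
    cond = np.linalg.cond(B)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise IllConditionedBasisError(cond)

    # KKT system for min ||B v - mu||^2  s.t.  1^T v = 1.
    kkt = np.zeros((n_bases + 1, n_bases + 1))
    kkt[:n_bases, :n_bases] = 2.0 * B.T @ B
    kkt[:n_bases, n_bases] = 1.0
    kkt[n_bases, :n_bases] = 1.0
    rhs = np.concatenate([2.0 * B.T @ target.mu_per_bin, [1.0]])
    sol = scipy.linalg.solve(kkt, rhs)
    v = sol[:n_bases]
    residual = float(np.linalg.norm(B @ v - target.mu_per_bin))
    return VolumeFractions(v, residual)


def lac_to_hu(mu: float | np.ndarray, mu_water: float | np.ndarray):
    """CT number in Hounsfield units: 1000 * (mu - mu_water) / mu_water."""
    mu_water = np.asarray(mu_water, dtype=float)
    if np.any(mu_water <= 0):
        raise ValueError("water LAC must be strictly positive")
    return 1000.0 * (np.asarray(mu, dtype=float) - mu_water) / mu_water


def predict_delta_ct(ct_at_t0: float, alpha: float, delta_t: float) -> float:
    """CT-number change from thermal expansion.

    Delta CT ~ -(1000 + CT(T0)) * alpha * Delta T, with ``alpha`` the
    volumetric thermal-expansion coefficient (per degC).
    """
    return -(1000.0 + ct_at_t0) * alpha * delta_t


def fit_thermal_sensitivity(series: ThermalSeries) -> SensitivityFit:
    """Per-bin ordinary least-squares line of LAC versus temperature.

    The slope is the thermal sensitivity in mm^-1 per degC; the intercept
    is evaluated at the series' baseline temperature.
    """
    if series.temperatures_C.size < 3:
        raise ValueError("need >= 3 temperature points for a sensitivity fit")
    t = series.temperatures_C
    slopes, intercepts, r2 = [], [], []
    for b in range(series.mu.shape[1]):
        res = stats.linregress(t, series.mu[:, b])
        slopes.append(res.slope)
        intercepts.append(res.intercept + res.slope * series.baseline_C)
        r2.append(0.0 if np.isnan(res.rvalue) else res.rvalue**2)
    return SensitivityFit(series.material_id, np.array(slopes),
                          np.array(intercepts), np.array(r2),
                          baseline_C=series.baseline_C)


def linear_mixture_thermal_model(
    fractions: np.ndarray | VolumeFractions,
    fits: list[SensitivityFit],
) -> tuple[np.ndarray, np.ndarray]:
    """Volume-weighted linear thermal model (the non-learned baseline).

    Returns ``(alpha_prime, beta_prime)`` per bin, with
    alpha' = sum_i V_i alpha_i and beta' = sum_i V_i mu_i(T0). Exact only
    when sensitivity is linear in composition; deliberately kept as the
    reference the regressor is measured against.
    """
    f = fractions.fractions if isinstance(fractions, VolumeFractions) else np.asarray(fractions, dtype=float)
    if f.shape != (len(fits),):
        raise ValueError("one fraction per sensitivity fit is required")
    slopes = np.stack([fit.slope_per_bin for fit in fits])
    intercepts = np.stack([fit.intercept_per_bin for fit in fits])
    return f @ slopes, f @ intercepts
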