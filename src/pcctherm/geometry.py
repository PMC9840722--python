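"""Diverging-beam projection model of a square liquid phantom.

A point X-ray source illuminates a square-cross-section phantom and a
photon-counting line/area detector. Within each detector row the beam is a
fan; obliquity across rows is ignored because the downstream analysis is
strictly one-dimensional (a single line of interest per projection). Photon
counts per energy bin follow Beer-Lambert attenuation along the exact ray
from the source through the square cross-section.

Threshold acquisitions (counts above 8/33/45/60 keV) are converted to the
four energy bins 8-33, 33-45, 45-60 and 60-100 keV by pairwise subtraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError

logger = logging.getLogger(__name__)

#: Lower thresholds (keV) of the two paired acquisitions.
THRESHOLDS_KEV = (8, 33, 45, 60)


@dataclass(frozen=True)
class PhantomGeometry:
    """Source/phantom/detector layout, lengths in mm.

    Defaults reproduce the reference instrument: a square phantom of external
    side ``L`` = 254 mm, source 278.5 mm from the phantom center and
    342.5 mm from the detector, 55 um detector pitch, 256 x 1280 pixels.

    Note these nominal values are not mutually consistent (a 254 mm
    phantom magnified 1.23x does not fit a 70.4 mm-wide detector), so
    simulations that need the shadow on the detector should use
    :meth:`self_consistent`, which keeps the distances (hence the 1.23
    magnification) but uses a 25.4 mm phantom.
    """

    side_length_mm: float = 254.0
    source_to_center_mm: float = 278.5
    source_to_detector_mm: float = 342.5
    pixel_pitch_mm: float = 0.055
    detector_shape: tuple[int, int] = (256, 1280)

    def __post_init__(self):
        if min(self.side_length_mm, self.source_to_center_mm,
               self.source_to_detector_mm, self.pixel_pitch_mm) <= 0:
            raise InvalidGeometryError("all lengths must be strictly positive")
        if self.source_to_detector_mm <= self.source_to_center_mm:
            raise InvalidGeometryError(
                "detector must lie beyond the phantom center")
        rows, cols = self.detector_shape
        if rows < 1 or cols < 1:
            raise InvalidGeometryError("detector must have >= 1 row and column")

    @classmethod
    def self_consistent(cls, **overrides) -> "PhantomGeometry":
        """Reference distances with a phantom that fits the detector."""
        overrides.setdefault("side_length_mm", 25.4)
        return cls(**overrides)

    @property
    def detector_xs_mm(self) -> np.ndarray:
        """Lateral pixel-center coordinates, symmetric about the beam axis."""
        _, cols = self.detector_shape
        return (np.arange(cols) - (cols - 1) / 2.0) * self.pixel_pitch_mm


@dataclass(frozen=True)
class EnergyBinning:
    """Energy-bin edges in keV; 5 edges define the 4 bins."""

    edges_kev: tuple[float, ...] = (8.0, 33.0, 45.0, 60.0, 100.0)

    def __post_init__(self):
        edges = np.asarray(self.edges_kev, dtype=float)
        if edges.size != 5:
            raise ValueError("exactly 5 edges (4 bins) are required")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges_kev) - 1

    @property
    def bounds(self) -> list[tuple[float, float]]:
        e = self.edges_kev
        return [(e[i], e[i + 1]) for i in range(self.n_bins)]


@dataclass
class ProjectionFrame:
    """One detector readout: photon counts plus acquisition metadata.

    ``counts`` is float64 so that noiseless simulations stay analytically
    exact; with Poisson noise enabled the values are integers.
    """

    counts: np.ndarray
    threshold_kev: float
    label: str  # "empty" | "filled"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.label not in ("empty", "filled"):
            raise ValueError("label must be 'empty' or 'filled'")


def magnification(geometry: PhantomGeometry) -> float:
    """Geometric magnification: source-detector over source-center distance.

    For the reference distances (278.5 mm, 342.5 mm) this is 1.23; object
    features at the phantom center appear this factor larger on the
    detector.
    """
    return geometry.source_to_detector_mm / geometry.source_to_center_mm


def chord_lengths(geometry: PhantomGeometry, parallel: bool = False) -> np.ndarray:
    """Intersection length (mm) of each detector column's ray with the square.

    Fan geometry: the ray runs from the point source through a pixel center.
    The axis-aligned square slab method gives the chord analytically. With
    ``parallel=True`` rays run parallel to the beam axis at the detector's
    lateral coordinates (magnification 1).
    """
    h = geometry.side_length_mm / 2.0
    xs = geometry.detector_xs_mm
    if parallel:
        return np.where(np.abs(xs) <= h, geometry.side_length_mm, 0.0)

    dc = geometry.source_to_center_mm
    dd = geometry.source_to_detector_mm
    # Ray: (x, y) = t * (xs, dd), t in [0, 1]; source at origin.
    ty0 = (dc - h) / dd
    ty1 = (dc + h) / dd
    with np.errstate(divide="ignore"):
        tx_a = -h / xs
        tx_b = h / xs
    tx0 = np.minimum(tx_a, tx_b)
    tx1 = np.maximum(tx_a, tx_b)
    on_axis = xs == 0.0
    tx0 = np.where(on_axis, -np.inf, tx0)
    tx1 = np.where(on_axis, np.inf, tx1)
    t0 = np.maximum(ty0, tx0)
    t1 = np.minimum(ty1, tx1)
    ray_len = np.sqrt(xs**2 + dd**2)
    return np.maximum(0.0, t1 - t0) * ray_len


def simulate_projection_pair(
    geometry: PhantomGeometry,
    mu_per_bin: np.ndarray,
    flux_per_bin: np.ndarray,
    noise: bool = False,
    seed: int | None = None,
    parallel: bool = False,
    enclosure_transmission: float | np.ndarray = 1.0,
    dead_columns: list[int] | None = None,
    binning: EnergyBinning = EnergyBinning(),
) -> tuple[list[ProjectionFrame], list[ProjectionFrame]]:
    """Simulate one empty and one filled frame per energy bin.

    Per pixel: filled = flux * exp(-mu * chord); empty = flux. Both are
    multiplied by ``enclosure_transmission`` (scalar or per-column), which
    models the phantom enclosure attenuating empty and filled acquisitions
    identically and therefore cancels in the profile difference.

    Returns ``(empty_frames, filled_frames)``, one frame per bin, with the
    bin's lower edge recorded as ``threshold_kev``.
    """
    mu_per_bin = np.asarray(mu_per_bin, dtype=float)
    flux_per_bin = np.asarray(flux_per_bin, dtype=float)
    if np.any(mu_per_bin < 0):
        raise ValueError("attenuation coefficients must be non-negative")
    if np.any(flux_per_bin <= 0):
        raise ValueError("incident flux must be strictly positive")
    if mu_per_bin.shape != (binning.n_bins,) or flux_per_bin.shape != (binning.n_bins,):
        raise ValueError("mu_per_bin and flux_per_bin must have one entry per bin")

    rows, cols = geometry.detector_shape
    chords = chord_lengths(geometry, parallel=parallel)
    trans = np.broadcast_to(np.asarray(enclosure_transmission, dtype=float), (cols,))
    rng = np.random.default_rng(seed)

    col_mask = np.ones(cols, dtype=bool)
    for c in dead_columns or []:
        col_mask[c] = False

    empty_frames, filled_frames = [], []
    for b in range(binning.n_bins):
        empty_cols = flux_per_bin[b] * trans
        filled_cols = empty_cols * np.exp(-mu_per_bin[b] * chords)
        empty = np.tile(empty_cols, (rows, 1))
        filled = np.tile(filled_cols, (rows, 1))
        if noise:
            empty = rng.poisson(empty).astype(float)
            filled = rng.poisson(filled).astype(float)
        empty[:, ~col_mask] = 0.0
        filled[:, ~col_mask] = 0.0
        lo = binning.edges_kev[b]
        empty_frames.append(ProjectionFrame(empty, lo, "empty"))
        filled_frames.append(ProjectionFrame(filled, lo, "filled"))
    return empty_frames, filled_frames


def counts_to_bins(
    acq_8_45: dict[float, ProjectionFrame],
    acq_33_60: dict[float, ProjectionFrame],
) -> tuple[list[np.ndarray], int]:
    """Convert the two paired threshold acquisitions to per-bin counts.

    ``acq_8_45`` maps thresholds {8, 45} to frames and ``acq_33_60`` maps
    {33, 60}, mirroring the acquisition protocol (two thresholds per
    readout). Bins are formed by subtracting counts at adjacent thresholds;
    with counting noise a difference can come out negative, in which case
    it is clipped to zero and counted.

    Returns ``(bin_count_arrays, n_clipped_pixels)``.
    """
    try:
        c8, c45 = acq_8_45[8].counts, acq_8_45[45].counts
        c33, c60 = acq_33_60[33].counts, acq_33_60[60].counts
    except KeyError as exc:
        raise ValueError(f"missing threshold frame: {exc}") from exc
    shapes = {a.shape for a in (c8, c33, c45, c60)}
    if len(shapes) != 1:
        raise ValueError(f"threshold frames disagree in shape: {shapes}")

    raw = [c8 - c33, c33 - c45, c45 - c60, c60.copy()]
    n_clipped = int(sum(np.count_nonzero(r < 0) for r in raw))
    if n_clipped:
        logger.warning("clipped %d negative bin-difference pixels to zero", n_clipped)
    return [np.maximum(r, 0.0) for r in raw], n_clipped


def bins_to_threshold_counts(bin_counts: list[np.ndarray]) -> dict[int, np.ndarray]:
    """Expected counts above each threshold: cumulative sums of the bins."""
    if len(bin_counts) != 4:
        raise ValueError("expected 4 bin count arrays")
    b1, b2, b3, b4 = bin_counts
    return {8: b1 + b2 + b3 + b4, 33: b2 + b3 + b4, 45: b3 + b4, 60: b4.copy()}
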