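"""File formats: 16-bit TIFF projection frames with JSON sidecars, CSV
tables for thermal series / LAC measurements / predictions, JSON models."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .extraction import LacMeasurement
from .geometry import EnergyBinning, PhantomGeometry, ProjectionFrame
from .materials import ThermalSeries


def frame_path(out_dir: Path, material: str, temperature_C: float,
               threshold_kev: float, label: str) -> Path:
    return Path(out_dir) / (
        f"{material}_T{temperature_C:g}_thr{threshold_kev:g}_{label}.tif")


def write_frame(path, frame: ProjectionFrame, geometry: PhantomGeometry,
                seed=None, flux=None, extra: dict | None = None) -> None:
    path = Path(path)
    counts = np.rint(frame.counts)
    if counts.max() > np.iinfo(np.uint16).max:
        raise ValueError("counts exceed the 16-bit TIFF range")
    tifffile.imwrite(path, counts.astype(np.uint16))
    sidecar = {
        "geometry": asdict(geometry),
        "threshold_kev": frame.threshold_kev,
        "label": frame.label,
        "seed": seed,
        "flux": None if flux is None else np.asarray(flux).tolist(),
    }
    sidecar.update(extra or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_frame(path) -> tuple[ProjectionFrame, dict]:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    counts = tifffile.imread(path).astype(float)
    frame = ProjectionFrame(counts, sidecar["threshold_kev"], sidecar["label"])
    return frame, sidecar


def geometry_from_sidecar(sidecar: dict) -> PhantomGeometry:
    g = dict(sidecar["geometry"])
    g["detector_shape"] = tuple(g["detector_shape"])
    return PhantomGeometry(**g)


def series_to_frame(series: ThermalSeries) -> pd.DataFrame:
    """Long-format rows: material, temperature_C, bin_lo/hi_kev, mu_mm."""
    rows = []
    for i, t in enumerate(series.temperatures_C):
        for b, (lo, hi) in enumerate(series.binning.bounds):
            rows.append({
                "material": series.material_id,
                "temperature_C": float(t),
                "bin_lo_kev": lo,
                "bin_hi_kev": hi,
                "mu_mm": series.mu[i, b],
            })
    return pd.DataFrame(rows)


def write_series_csv(path, series_list: list[ThermalSeries]) -> None:
    pd.concat([series_to_frame(s) for s in series_list],
              ignore_index=True).to_csv(path, index=False)


def read_series_csv(path) -> list[ThermalSeries]:
    df = pd.read_csv(path)
    out = []
    for material, grp in df.groupby("material", sort=False):
        pivot = grp.pivot_table(index="temperature_C", columns="bin_lo_kev",
                                values="mu_mm", sort=True)
        pivot = pivot[sorted(pivot.columns)]
        edges = sorted(grp["bin_lo_kev"].unique()) + [grp["bin_hi_kev"].max()]
        out.append(ThermalSeries(
            str(material),
            pivot.index.to_numpy(dtype=float),
            pivot.to_numpy(dtype=float),
            binning=EnergyBinning(tuple(float(e) for e in edges)),
        ))
    return out


def measurement_rows(material: str, temperature_C: float,
                     m: LacMeasurement,
                     binning: EnergyBinning = EnergyBinning()) -> pd.DataFrame:
    rows = []
    for b, (lo, hi) in enumerate(binning.bounds):
        rows.append({
            "material": material,
            "temperature_C": temperature_C,
            "bin_lo_kev": lo,
            "bin_hi_kev": hi,
            "mu_mm": m.mu_per_bin[b],
            "var": np.nan if m.var_per_bin is None else m.var_per_bin[b],
            "n_loi": m.n_loi,
        })
    return pd.DataFrame(rows)
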