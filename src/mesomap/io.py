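"""Reading and writing the package's plain-text data formats.

Conventions, fixed once here: scattering curves are 2- or 3-column
ASCII (q in 1/Angstrom, intensity, optional sigma) in the canSAS 1D
text style; Raman spectra are 2-column ASCII (wavenumber in 1/cm,
intensity); raster scans are a directory of curve files plus a CSV
manifest (pixel_x_mm, pixel_y_mm, filename) and a key=value ground-truth
sidecar; tabular results are CSV.  Distances are mm, lattice parameters
Angstrom.  Every file written carries provenance header comments
(package version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .containers import RamanSpectrum, RasterScan, ScatteringCurve

__all__ = [
    "read_curve", "write_curve", "read_spectrum", "write_spectrum",
    "write_raster", "read_raster", "provenance_header", "config_hash",
]

PathLike = Union[str, Path]


def config_hash(obj: Any) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed: Optional[int] = None, **extra: Any) -> str:
    parts = [f"mesomap {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    parts.extend(f"{k}={v}" for k, v in extra.items())
    return " ".join(parts)


def _read_columns(path: PathLike, n_min: int, axis_name: str,
                  value_name: str) -> tuple[np.ndarray, np.ndarray,
                                            Optional[np.ndarray]]:
    rows: list[tuple[float, ...]] = []
    bad: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            fields = text.replace(",", " ").split()
            try:
                vals = tuple(float(v) for v in fields)
            except ValueError:
                bad.append(lineno)
                continue
            if len(vals) < n_min:
                bad.append(lineno)
                continue
            rows.append(vals[:3])
    if bad:
        raise ValueError(
            f"{path}: malformed data on line(s) {bad[:10]}"
            + (" ..." if len(bad) > 10 else ""))
    if len(rows) < 2:
        raise ValueError(f"{path}: need at least 2 data rows")
    ncol = min(len(r) for r in rows)
    data = np.asarray([r[:ncol] for r in rows], dtype=float)
    axis, values = data[:, 0], data[:, 1]
    if np.any(np.diff(axis) <= 0):
        i = int(np.argmax(np.diff(axis) <= 0))
        raise ValueError(
            f"{path}: {axis_name} axis not strictly increasing near row "
            f"{i + 1} ({axis[i]:g} -> {axis[i + 1]:g})")
    sigma = data[:, 2] if ncol >= 3 else None
    return axis, values, sigma


def read_curve(path: PathLike) -> ScatteringCurve:
    """Parse a 2/3-column ASCII scattering curve (q, I[, sigma])."""
    q, intensity, sigma = _read_columns(path, 2, "q", "intensity")
    return ScatteringCurve(q, intensity, sigma=sigma,
                           metadata={"source": str(path)})


def write_curve(path: PathLike, curve: ScatteringCurve,
                seed: Optional[int] = None, **extra: Any) -> None:
    cols = [curve.q, curve.intensity]
    names = "q_invA intensity"
    if curve.sigma is not None:
        cols.append(curve.sigma)
        names += " sigma"
    header = (provenance_header(seed, **extra)
              + f"\npixel_x_mm={curve.pixel_x} pixel_y_mm={curve.pixel_y}"
              + f"\n{names}")
    np.savetxt(path, np.column_stack(cols), header=header)


def read_spectrum(path: PathLike) -> RamanSpectrum:
    """Parse a 2-column ASCII Raman spectrum (wavenumber, intensity)."""
    nu, intensity, _ = _read_columns(path, 2, "wavenumber", "intensity")
    return RamanSpectrum(nu, intensity, metadata={"source": str(path)})


def write_spectrum(path: PathLike, spectrum: RamanSpectrum,
                   seed: Optional[int] = None, **extra: Any) -> None:
    header = (provenance_header(seed, **extra)
              + f"\nposition_mm={spectrum.position_mm} "
              + f"age_days={spectrum.age_days}"
              + "\nwavenumber_invcm intensity")
    np.savetxt(path, np.column_stack([spectrum.wavenumber,
                                      spectrum.intensity]), header=header)


def write_raster(scan: RasterScan, outdir: PathLike,
                 seed: Optional[int] = None) -> Path:
    """Write a raster scan: curve files, CSV manifest, truth sidecar.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for i in range(scan.n_pixels):
        fname = f"pixel_{i:05d}.dat"
        np.savetxt(outdir / fname,
                   np.column_stack([scan.q, scan.intensities[i]]),
                   header=provenance_header(seed) + "\nq_invA intensity")
        records.append({"pixel_x_mm": scan.pixel_x[i],
                        "pixel_y_mm": scan.pixel_y[i],
                        "filename": fname})
    manifest = outdir / "manifest.csv"
    with open(manifest, "w") as fh:
        fh.write(f"# {provenance_header(seed)}\n")
        fh.write(f"# pixel_pitch_mm={scan.pixel_pitch}\n")
        pd.DataFrame(records).to_csv(fh, index=False)

    with open(outdir / "ground_truth.txt", "w") as fh:
        fh.write(f"# {provenance_header(seed)}\n")
        for key, value in scan.metadata.items():
            fh.write(f"{key}={value}\n")
        fh.write("pixel_index phase lattice_A weight radius_mm\n")
        for i in range(scan.n_pixels):
            fh.write(f"{i} {scan.truth['phase'][i]} "
                     f"{scan.truth['lattice_A'][i]:.4f} "
                     f"{scan.truth['weight'][i]:.4f} "
                     f"{scan.truth['radius_mm'][i]:.4f}\n")
    return manifest


def read_raster(manifest_path: PathLike) -> RasterScan:
    """Load a raster scan from its CSV manifest."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, comment="#")
    required = {"pixel_x_mm", "pixel_y_mm", "filename"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest missing columns {required - set(df.columns)}")
    base = manifest_path.parent
    pitch = None
    with open(manifest_path) as fh:
        for line in fh:
            if line.startswith("#") and "pixel_pitch_mm=" in line:
                pitch = float(line.split("pixel_pitch_mm=")[1])
    curves = [read_curve(base / fname) for fname in df["filename"]]
    q = curves[0].q
    for c in curves[1:]:
        if c.q.size != q.size or not np.allclose(c.q, q):
            raise ValueError("raster curves must share one q grid")
    if pitch is None:
        xs = np.unique(df["pixel_x_mm"].to_numpy())
        pitch = float(np.min(np.diff(xs))) if xs.size > 1 else 1.0
    return RasterScan(q, np.vstack([c.intensity for c in curves]),
                      df["pixel_x_mm"].to_numpy(),
                      df["pixel_y_mm"].to_numpy(), pitch,
                      metadata={"source": str(manifest_path)})
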