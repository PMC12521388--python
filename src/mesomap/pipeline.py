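"""End-to-end pipeline orchestration: simulate -> index -> map -> segment,
plus the Raman chain, with a machine-readable run log."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import config_hash, provenance_header, write_raster, write_spectrum
from .mapping import assemble_map, radial_profile, segment_layers
from .raman import estimate_composition, estimate_hydration, fit_bands, \
    intensity_ratios
from .synthetic import generate_raman, generate_raster, make_depot_scenario

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    ``ages_days`` selects the depot time points to simulate and map;
    Raman spectra are generated at ``raman_positions_mm`` from the
    scenario's composition/hydration profiles.
    """

    outdir: Path
    seed: int = 0
    ages_days: tuple[float, ...] = (1.0, 2.0, 7.0, 14.0, 21.0, 28.0)
    depot_radius_mm: float = 4.0
    spc_fraction: float = 0.5
    pixel_pitch_mm: float = 0.1
    fraction_threshold: float = 0.25
    raman_positions_mm: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)
    write_png: bool = False
    write_curves: bool = False
    verbosity: int = 1
    extra: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        for key in ("ages_days", "raman_positions_mm"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        if "outdir" not in kwargs:
            raise ValueError("config must define 'outdir'")
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["outdir"] = str(self.outdir)
        return d


def _write_matrix(path: Path, matrix: np.ndarray, header: str) -> None:
    np.savetxt(path, matrix, delimiter=",", header=header)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis chain; returns the run log dict.

    Stages per age: simulate raster, assemble phase maps, radial
    profile, layer segmentation; then the Raman chain (simulate,
    band-fit, ratios, composition/hydration estimates).  Any stage
    failure raises :class:`PipelineError` naming the stage.  All CSV
    outputs carry provenance headers; identical config and seed give
    byte-identical CSVs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # hash the analysis parameters, not the output location
    chash = config_hash({k: v for k, v in config.to_dict().items()
                         if k != "outdir"})
    log: dict[str, Any] = {
        "version": __version__, "seed": config.seed,
        "config_hash": chash, "config": config.to_dict(),
        "stages": {}, "outputs": [],
    }
    header = provenance_header(config.seed, config_hash=chash)

    def _stage(name: str):
        t0 = time.perf_counter()

        def done() -> None:
            log["stages"][name] = round(time.perf_counter() - t0, 3)
        return done

    layer_rows = []
    for age in config.ages_days:
        stage = f"map-age-{age:g}d"
        tick = _stage(stage)
        try:
            scenario = make_depot_scenario(
                age, depot_radius_mm=config.depot_radius_mm,
                spc_fraction=config.spc_fraction, noise_seed=config.seed)
            scan = generate_raster(scenario,
                                   pixel_pitch=config.pixel_pitch_mm)
            if config.write_curves:
                write_raster(scan, outdir / f"raster_{age:g}d",
                             seed=config.seed)
            pmap = assemble_map(scan)
            prof = radial_profile(pmap)
            layers = segment_layers(prof, config.fraction_threshold)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

        for name, arr in (("fraction", pmap.fraction),
                          ("lattice", pmap.lattice)):
            path = outdir / f"{name}_{age:g}d.csv"
            _write_matrix(path, arr, f"{header}\nage_days={age}")
            log["outputs"].append(str(path))
        for i, layer in enumerate(layers):
            layer_rows.append({"age_days": age, "layer": i,
                               "kind": layer.kind,
                               "r_inner_mm": round(layer.r_inner, 4),
                               "r_outer_mm": round(layer.r_outer, 4)})
        if config.write_png:
            _save_png(outdir / f"fraction_{age:g}d.png", pmap)
        tick()

    layer_path = outdir / "layers.csv"
    with open(layer_path, "w") as fh:
        fh.write(f"# {header}\n")
        pd.DataFrame(layer_rows).to_csv(fh, index=False)
    log["outputs"].append(str(layer_path))

    tick = _stage("raman")
    try:
        rng = np.random.default_rng(config.seed)
        rows = []
        for age in config.ages_days:
            scenario = make_depot_scenario(
                age, depot_radius_mm=config.depot_radius_mm,
                spc_fraction=config.spc_fraction, noise_seed=config.seed)
            for pos in config.raman_positions_mm:
                spec = generate_raman(
                    scenario.composition_profile(pos),
                    scenario.hydration_profile(pos),
                    noise_seed=int(rng.integers(2 ** 31)),
                    position_mm=pos, age_days=age)
                if config.write_curves:
                    d = outdir / "raman"
                    d.mkdir(exist_ok=True)
                    write_spectrum(d / f"raman_{age:g}d_{pos:g}mm.dat",
                                   spec, seed=config.seed)
                r715, r1264 = intensity_ratios(fit_bands(spec))
                x_spc, _ = estimate_composition(r1264)
                water, _ = estimate_hydration(r715, x_spc)
                rows.append({"age_days": age, "position_mm": pos,
                             "r715": round(r715, 4),
                             "r1264": round(r1264, 4),
                             "x_spc": round(x_spc, 4),
                             "water_frac": round(water, 4)})
        ratio_path = outdir / "raman_ratios.csv"
        with open(ratio_path, "w") as fh:
            fh.write(f"# {header}\n")
            pd.DataFrame(rows).to_csv(fh, index=False)
        log["outputs"].append(str(ratio_path))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'raman' failed: {exc}") from exc
    tick()

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return log


def _save_png(path: Path, pmap) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    extent = (pmap.x_mm[0], pmap.x_mm[-1], pmap.y_mm[0], pmap.y_mm[-1])
    shown = np.where(pmap.mask, pmap.fraction, np.nan)
    im = ax.imshow(shown, origin="lower", extent=extent, cmap="cividis",
                   vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, label="cubic phase fraction")
    ax.set_xlabel("x / mm")
    ax.set_ylabel("y / mm")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
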