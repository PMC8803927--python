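"""End-to-end QPI and invasion pipelines with reproducible outputs.

A run is driven by a single config (YAML on disk or a dict in memory);
all randomness flows from one seed, and a manifest (inputs, parameters,
package version, seed) is written next to the outputs so any result can
be reproduced bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

import qpicell
from qpicell import synth
from qpicell.background import run_background_pipeline
from qpicell.invasion import analyze_invasion_movie
from qpicell.metrics import fit_growth, summarize_movie, track_protrusion_records
from qpicell.phase import DryMassMap, opd_to_dry_mass, reconstruct_phase, unwrap_phase
from qpicell.segment import segment_frame, track_frames, tracks_to_dataframe

logger = logging.getLogger(__name__)

QPI_DEFAULTS = {
    "threshold_fraction": 0.01,
    "min_area_um2": 20.0,
    "smoothing_sigma_px": 1.0,
    "d_max_um": 30.0,
    "mass_tol": 0.35,
    "max_gap": 2,
    "alpha_um3_per_pg": 0.18,
    "f_min": 0.25,
    "blend_scale_px": 20.0,
}

INVASION_DEFAULTS = {
    "hole_factor": 0.5,
    "overlap_min": 0.3,
    "min_hole_area_um2": 50.0,
    "min_track_len": 3,
    "renormalize": False,
}


@dataclasses.dataclass
class QPIResults:
    """Bundle returned by :func:`run_qpi_pipeline`."""

    dry_mass: list[DryMassMap]
    frames: list
    tracks: list
    fits: list
    records: list
    summary: pd.DataFrame
    background: object


def _write_manifest(outdir: Path, mode: str, params: dict, seed: int | None,
                    inputs: dict) -> None:
    manifest = {
        "mode": mode,
        "qpicell_version": qpicell.__version__,
        "parameters": params,
        "rng_seed": seed,
        "inputs": inputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_qpi_pipeline(
    interferogram_sets: list,
    pixel_size_um: float,
    lapse_interval_min: float,
    params: dict | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> QPIResults:
    """Reconstruct, background-correct, segment, track and measure a movie.

    Stage order: phase reconstruction -> unwrapping -> frame-fluctuation
    removal -> temporal-mode background reconstruction + inpainting ->
    subtraction -> dry-mass calibration -> segmentation -> tracking ->
    growth/speed/protrusion metrics -> summary table.
    """
    if not interferogram_sets:
        raise ValueError("no interferograms to process")
    p = {**QPI_DEFAULTS, **(params or {})}
    wavelength = interferogram_sets[0].wavelength_nm
    opd_stack = []
    for ifs in interferogram_sets:
        opd = reconstruct_phase(ifs, pixel_size_um=pixel_size_um)
        opd = unwrap_phase(opd, wavelength)
        opd_stack.append(opd.values)
    opd_stack = np.stack(opd_stack)
    corrected, bg = run_background_pipeline(
        opd_stack, f_min=p["f_min"], blend_scale_px=p["blend_scale_px"]
    )
    dms = [
        opd_to_dry_mass(
            dataclasses.replace(
                reconstruct_phase(ifs, pixel_size_um=pixel_size_um),
                values=corrected[t],
                wrapped=False,
            ),
            p["alpha_um3_per_pg"],
        )
        for t, ifs in enumerate(interferogram_sets)
    ]
    frames = [
        segment_frame(
            dm,
            threshold_fraction=p["threshold_fraction"],
            min_area_um2=p["min_area_um2"],
            smoothing_sigma_px=p["smoothing_sigma_px"],
            frame_index=t,
        )
        for t, dm in enumerate(dms)
    ]
    tracks = track_frames(
        frames, d_max_um=p["d_max_um"], mass_tol=p["mass_tol"], max_gap=p["max_gap"]
    )
    fits = [f for f in (fit_growth(t) for t in tracks) if f is not None]
    records = []
    for track in tracks:
        records.extend(
            track_protrusion_records(track, frames, dms, lapse_interval_min)
        )
    summary = summarize_movie(tracks, records, fits, lapse_interval_min)
    results = QPIResults(dms, frames, tracks, fits, records, summary, bg)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tracks_to_dataframe(tracks).to_csv(outdir / "tracks.csv", index=False)
        summary.to_csv(outdir / "summary.csv", index=False)
        tifffile.imwrite(outdir / "background_surface.tif",
                         bg.surface.astype(np.float32))
        tifffile.imwrite(
            outdir / "labels.tif",
            np.stack([f.labels for f in frames]).astype(np.uint16),
        )
        pd.DataFrame({"frame": np.arange(len(bg.per_frame_offsets)),
                      "offset_um": bg.per_frame_offsets}).to_csv(
            outdir / "frame_offsets.csv", index=False)
        _write_manifest(outdir, "qpi", p, seed,
                        {"n_frames": len(interferogram_sets),
                         "pixel_size_um": pixel_size_um,
                         "lapse_interval_min": lapse_interval_min})
    return results


def run_qpi_pipeline_from_dir(indir: str | Path, outdir: str | Path | None = None,
                              params: dict | None = None) -> QPIResults:
    """Run the QPI pipeline on a scene directory written by the simulator."""
    indir = Path(indir)
    if not (indir / "scene.yaml").exists():
        raise FileNotFoundError(f"no scene.yaml in {indir}: not a scene directory")
    spec = synth.scene_spec_from_dict(yaml.safe_load((indir / "scene.yaml").read_text()))
    ifs = synth.read_interferogram_stacks(indir, spec)
    return run_qpi_pipeline(
        ifs, spec.pixel_size_um, spec.lapse_interval_min,
        params=params, outdir=outdir, seed=spec.rng_seed,
    )


def run_invasion_pipeline(
    red_stack: np.ndarray,
    green_stack: np.ndarray,
    pixel_size_um: float,
    lapse_interval_min: float,
    params: dict | None = None,
    outdir: str | Path | None = None,
    movie_id: str = "",
    treatment: str = "",
    seed: int | None = None,
):
    """Hole detection, green-cell tracking and invasion scoring for one movie."""
    p = {**INVASION_DEFAULTS, **(params or {})}
    result = analyze_invasion_movie(
        red_stack, green_stack, pixel_size_um, lapse_interval_min,
        hole_factor=p["hole_factor"], overlap_min=p["overlap_min"],
        min_hole_area_um2=p["min_hole_area_um2"],
        min_track_len=p["min_track_len"], renormalize=p["renormalize"],
        movie_id=movie_id, treatment=treatment,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {
                    "track_id": e.track_id,
                    "first_coincidence_frame": e.first_coincidence_frame,
                    "max_overlap_fraction": e.max_overlap_fraction,
                }
                for e in result.events
            ]
        ).to_csv(outdir / "invasion_events.csv", index=False)
        (outdir / "invasion_summary.json").write_text(
            json.dumps(
                {
                    "movie_id": result.movie_id,
                    "treatment": result.treatment,
                    "n_cells": result.n_cells,
                    "n_invading": result.n_invading,
                    "fraction": None if np.isnan(result.fraction) else result.fraction,
                }
            )
        )
        _write_manifest(outdir, "invasion", p, seed,
                        {"pixel_size_um": pixel_size_um,
                         "lapse_interval_min": lapse_interval_min})
    return result


def run_invasion_pipeline_from_dir(indir: str | Path,
                                   outdir: str | Path | None = None,
                                   params: dict | None = None,
                                   movie_id: str = "", treatment: str = ""):
    """Run the invasion pipeline on a scene directory written by the simulator."""
    indir = Path(indir)
    if not (indir / "scene.yaml").exists():
        raise FileNotFoundError(f"no scene.yaml in {indir}: not a scene directory")
    d = yaml.safe_load((indir / "scene.yaml").read_text())
    red = tifffile.imread(indir / "red.tif").astype(float)
    green = tifffile.imread(indir / "green.tif").astype(float)
    return run_invasion_pipeline(
        red, green, d["pixel_size_um"], d["lapse_interval_min"],
        params=params, outdir=outdir,
        movie_id=movie_id or indir.name, treatment=treatment,
        seed=d.get("rng_seed"),
    )
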