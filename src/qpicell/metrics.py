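"""Growth, speed, protrusion/retraction and dynamic-polarity metrics.

Dry-mass growth is fitted as an exponential: ordinary least squares on
log mass versus time gives the specific growth rate and the doubling
time Td = ln 2 / slope.  Speed converts per-step centroid displacements
to um/h (a 1 um displacement at 5-min lapse is 12 um/h).  Protrusion and
retraction are the set differences of consecutive cell masks: protrusion
is the newly allocated area, retraction the withdrawn area; their masses
and areas are normalized per minute of lapse.  Dynamic polarity is the
distance between the protrusion centroid and the retraction centroid —
the spatial asymmetry of shape change that drives translocation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from qpicell.phase import DryMassMap
from qpicell.segment import CellTrack

logger = logging.getLogger(__name__)


@dataclass
class GrowthFit:
    """Exponential growth fit of one track's dry-mass curve."""

    track_id: int
    slope_per_h: float
    slope_stderr: float
    doubling_time_h: float  # ln2/slope; +inf if slope == 0; negative = shrinking
    n_points: int
    r_squared: float

    @property
    def growing(self) -> bool:
        return self.slope_per_h > 0


@dataclass
class ProtrusionRecord:
    """Protrusion/retraction quantification for one frame pair."""

    track_id: int
    frame_pair: tuple[int, int]
    protrusion_mass_pg_per_min: float
    protrusion_area_um2_per_min: float
    retraction_mass_pg_per_min: float
    retraction_area_um2_per_min: float
    max_pixel_mass_fg: float  # heaviest pixel in the protrusion, femtograms
    dynamic_polarity_um: float | None  # None when P or R is empty
    suspect: bool = False  # masks disjoint: displacement too large


def fit_growth(track: CellTrack) -> GrowthFit | None:
    """OLS fit of ln(mass) vs time (h); Td = ln 2 / slope.

    Non-positive mass points are excluded (logged); fewer than 3 usable
    points yields no fit.  A negative slope gives a negative doubling time,
    reported as shrinkage with |Td|.
    """
    m = track.masses_pg
    t_h = track.times_min / 60.0
    ok = m > 0
    if (~ok).any():
        logger.info("fit_growth: excluded %d non-positive mass points", int((~ok).sum()))
    if ok.sum() < 3:
        return None
    res = stats.linregress(t_h[ok], np.log(m[ok]))
    slope = float(res.slope)
    td = np.log(2) / slope if slope != 0 else np.inf
    return GrowthFit(
        track_id=track.track_id,
        slope_per_h=slope,
        slope_stderr=float(res.stderr),
        doubling_time_h=float(td),
        n_points=int(ok.sum()),
        r_squared=float(res.rvalue ** 2),
    )


def compute_speed(track: CellTrack, lapse_interval_min: float) -> dict:
    """Per-step and mean centroid speed in um/h.

    Step speed = displacement (um) * 60 / lapse (min); displacements
    spanning a tracking gap (non-consecutive frames) are excluded from the
    step set.
    """
    pos = track.positions_um
    frames = np.array([p.frame_index for p in track.points])
    if len(pos) < 2:
        return {"step_speeds_um_per_h": np.array([]), "mean_um_per_h": np.nan,
                "sem_um_per_h": np.nan, "n_steps": 0}
    consecutive = np.diff(frames) == 1
    disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)[consecutive]
    speeds = disp * 60.0 / lapse_interval_min
    sem = float(speeds.std(ddof=1) / np.sqrt(len(speeds))) if len(speeds) > 1 else 0.0
    return {
        "step_speeds_um_per_h": speeds,
        "mean_um_per_h": float(speeds.mean()) if len(speeds) else np.nan,
        "sem_um_per_h": sem,
        "n_steps": int(len(speeds)),
    }


def _mask_centroid_um(mask: np.ndarray, pixel_size_um: float,
                      weights: np.ndarray | None = None) -> np.ndarray:
    """(x, y) centroid of a boolean mask in um; optionally weighted."""
    rr, cc = np.nonzero(mask)
    if weights is None:
        cy, cx = rr.mean(), cc.mean()
    else:
        w = np.clip(weights[rr, cc], 0, None)
        if w.sum() <= 0:
            cy, cx = rr.mean(), cc.mean()
        else:
            cy, cx = (rr * w).sum() / w.sum(), (cc * w).sum() / w.sum()
    return np.array([cx * pixel_size_um, cy * pixel_size_um])


def protrusion_retraction(
    mask_t: np.ndarray,
    mask_t1: np.ndarray,
    dm_t: DryMassMap,
    dm_t1: DryMassMap,
    lapse_interval_min: float,
    track_id: int = 0,
    frame_pair: tuple[int, int] = (0, 1),
    mass_weighted_centroids: bool = False,
) -> ProtrusionRecord:
    """Quantify protrusion and retraction between two masks of one cell.

    P = mask(t+1) \\ mask(t) (newly allocated), R = mask(t) \\ mask(t+1)
    (withdrawn).  Protrusion mass integrates the *new* frame's density over
    P, retraction mass the *old* frame's density over R; both are divided
    by the lapse in minutes.  ``max_pixel_mass_fg`` is the heaviest single
    pixel of the protrusion in femtograms.  Dynamic polarity is the
    distance between the P and R centroids (area centroids by default);
    it is None when either set is empty.  The pixel identity
    ``area(t) + P*dt - R*dt = area(t+1)`` holds exactly by construction.
    """
    p_set = mask_t1 & ~mask_t
    r_set = mask_t & ~mask_t1
    suspect = not (mask_t & mask_t1).any()
    if suspect:
        logger.warning("protrusion_retraction: disjoint masks for track %d %s",
                       track_id, frame_pair)
    px_area = dm_t1.pixel_area_um2
    dt = lapse_interval_min
    p_mass = float(dm_t1.values[p_set].sum() * px_area) / dt
    r_mass = float(dm_t.values[r_set].sum() * px_area) / dt
    p_area = float(p_set.sum() * px_area) / dt
    r_area = float(r_set.sum() * px_area) / dt
    max_px = float(dm_t1.values[p_set].max() * px_area * 1000.0) if p_set.any() else 0.0
    if p_set.any() and r_set.any():
        pw = dm_t1.values if mass_weighted_centroids else None
        rw = dm_t.values if mass_weighted_centroids else None
        cp = _mask_centroid_um(p_set, dm_t1.pixel_size_um, pw)
        cr = _mask_centroid_um(r_set, dm_t.pixel_size_um, rw)
        polarity = float(np.linalg.norm(cp - cr))
    else:
        polarity = None
    return ProtrusionRecord(
        track_id=track_id,
        frame_pair=frame_pair,
        protrusion_mass_pg_per_min=p_mass,
        protrusion_area_um2_per_min=p_area,
        retraction_mass_pg_per_min=r_mass,
        retraction_area_um2_per_min=r_area,
        max_pixel_mass_fg=max_px,
        dynamic_polarity_um=polarity,
        suspect=suspect,
    )


def track_protrusion_records(
    track: CellTrack,
    frames: list,
    dry_mass_maps: list[DryMassMap],
    lapse_interval_min: float,
    mass_weighted_centroids: bool = False,
) -> list[ProtrusionRecord]:
    """Protrusion records for every consecutive frame pair of a track."""
    records = []
    for p0, p1 in zip(track.points[:-1], track.points[1:]):
        if p1.frame_index - p0.frame_index != 1:
            continue
        f0, f1 = frames[p0.frame_index], frames[p1.frame_index]
        records.append(
            protrusion_retraction(
                f0.mask(p0.label),
                f1.mask(p1.label),
                dry_mass_maps[p0.frame_index],
                dry_mass_maps[p1.frame_index],
                lapse_interval_min,
                track_id=track.track_id,
                frame_pair=(p0.frame_index, p1.frame_index),
                mass_weighted_centroids=mass_weighted_centroids,
            )
        )
    return records


def _mean_sem(x: np.ndarray) -> tuple[float, float, int]:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n == 0:
        return np.nan, np.nan, 0
    sem = float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(x.mean()), sem, n


def summarize_movie(
    tracks: list[CellTrack],
    records: list[ProtrusionRecord],
    fits: list[GrowthFit],
    lapse_interval_min: float,
) -> pd.DataFrame:
    """Movie-level summary: mean +- SEM with the N each is computed over.

    N is cells for mass and doubling time, steps for speed, frame pairs for
    protrusion/retraction/polarity; a per-cell speed summary (SEM over
    cells) is reported alongside the pooled per-step one.
    """
    rows = []

    def add(quantity, unit, values):
        mean, sem, n = _mean_sem(np.asarray(values, dtype=float))
        rows.append({"quantity": quantity, "unit": unit, "mean": mean,
                     "sem": sem, "n": n})

    add("mass", "pg", [t.masses_pg.mean() for t in tracks])
    add("doubling_time", "h",
        [f.doubling_time_h for f in fits if f is not None and np.isfinite(f.doubling_time_h)])
    all_steps = np.concatenate(
        [compute_speed(t, lapse_interval_min)["step_speeds_um_per_h"] for t in tracks]
    ) if tracks else np.array([])
    add("speed_pooled_steps", "um/h", all_steps)
    add("speed_per_cell", "um/h",
        [compute_speed(t, lapse_interval_min)["mean_um_per_h"] for t in tracks
         if t.n_points >= 2])
    add("protrusion_mass", "pg/min", [r.protrusion_mass_pg_per_min for r in records])
    add("protrusion_area", "um2/min", [r.protrusion_area_um2_per_min for r in records])
    add("retraction_mass", "pg/min", [r.retraction_mass_pg_per_min for r in records])
    add("max_protrusion_pixel_mass", "fg", [r.max_pixel_mass_fg for r in records])
    add("dynamic_polarity", "um",
        [r.dynamic_polarity_um for r in records if r.dynamic_polarity_um is not None])
    return pd.DataFrame(rows)
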