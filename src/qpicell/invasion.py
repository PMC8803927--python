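"""Two-channel fluorescence invasion-assay quantification.

Cancer cells (green channel) migrating on a confluent labeled monolayer
(red channel) are scored as invading when they coincide with an opening
in the monolayer — a significant local reduction of the red signal
relative to the intact-monolayer baseline of the first frame.  The
invading fraction per movie is the experimental unit for comparing
treatments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu

from qpicell.phase import DryMassMap
from qpicell.segment import CellTrack, LabeledFrame, segment_frame, track_frames

logger = logging.getLogger(__name__)


@dataclass
class InvasionEvent:
    track_id: int
    first_coincidence_frame: int | None
    max_overlap_fraction: float


@dataclass
class InvasionResult:
    """Invasion quantification of one movie."""

    movie_id: str
    treatment: str
    n_cells: int
    n_invading: int
    events: list[InvasionEvent] = field(default_factory=list)

    @property
    def fraction(self) -> float:
        """Invading fraction; NaN when no cell was tracked."""
        if self.n_cells == 0:
            return np.nan
        return self.n_invading / self.n_cells


def detect_holes(
    red_stack: np.ndarray,
    pixel_size_um: float,
    hole_factor: float = 0.5,
    min_hole_area_um2: float = 50.0,
    smooth_sigma_px: float = 2.0,
    renormalize: bool = False,
    baseline_min_fraction: float = 0.1,
) -> list[np.ndarray]:
    """Per-frame hole masks: significant local reduction of the red signal.

    The baseline is the median-smoothed first frame (intact monolayer).
    A pixel is a hole at frame t iff its matched-smoothed value falls below
    ``hole_factor`` times the baseline; connected components smaller than
    ``min_hole_area_um2`` are discarded.  With ``renormalize`` each frame
    is first scaled so its median matches the baseline median, absorbing
    global photobleaching.  Pre-existing near-zero baseline regions (below
    ``baseline_min_fraction`` of the baseline median) cannot "open" and are
    masked out of scoring (logged).
    """
    stack = np.asarray(red_stack, dtype=float)
    baseline = ndimage.median_filter(stack[0], size=5)
    baseline = ndimage.gaussian_filter(baseline, smooth_sigma_px)
    base_med = np.median(baseline)
    dead = baseline < baseline_min_fraction * base_med
    if dead.any():
        logger.warning("detect_holes: %d pre-existing near-zero baseline px excluded",
                       int(dead.sum()))
    min_px = max(int(np.ceil(min_hole_area_um2 / pixel_size_um ** 2)), 1)
    masks = []
    for t in range(stack.shape[0]):
        frame = ndimage.gaussian_filter(stack[t], smooth_sigma_px)
        if renormalize:
            med = np.median(frame)
            if med > 0:
                frame = frame * (base_med / med)
        hole = (frame < hole_factor * baseline) & ~dead
        lab, n = ndimage.label(hole, structure=np.ones((3, 3), dtype=bool))
        if n:
            sizes = np.bincount(lab.ravel())
            small = np.nonzero(sizes < min_px)[0]
            hole &= ~np.isin(lab, small[small > 0])
        masks.append(hole)
    return masks


def segment_track_green(
    green_stack: np.ndarray,
    pixel_size_um: float,
    lapse_interval_min: float,
    min_area_um2: float = 100.0,
    d_max_um: float = 40.0,
    mass_tol: float = 0.5,
) -> tuple[list[CellTrack], list[LabeledFrame]]:
    """Segment and track green cells; intensity integral stands in for mass.

    A stack-global Otsu threshold separates cells from background; tracking
    reuses the mass-gated nearest-neighbour linker with the integrated
    fluorescence as the conserved quantity.
    """
    stack = np.asarray(green_stack, dtype=float)
    thr = threshold_otsu(stack.ravel()[:: max(stack.size // 200_000, 1)])
    frames = []
    for t in range(stack.shape[0]):
        shifted = np.where(stack[t] > thr, stack[t], 0.0)
        dm = DryMassMap(values=shifted, pixel_size_um=pixel_size_um,
                       timestamp_min=t * lapse_interval_min)
        frames.append(
            segment_frame(dm, threshold_fraction=0.0, min_area_um2=min_area_um2,
                          smoothing_sigma_px=0.0, frame_index=t)
        )
    if stack.shape[0] < 2:
        return [], frames
    tracks = track_frames(frames, d_max_um=d_max_um, mass_tol=mass_tol)
    return tracks, frames


def score_invasion(
    tracks: list[CellTrack],
    frames: list[LabeledFrame],
    hole_masks: list[np.ndarray],
    overlap_min: float = 0.3,
    min_track_len: int = 3,
    movie_id: str = "",
    treatment: str = "",
) -> InvasionResult:
    """Score each tracked cell for coincidence with a monolayer opening.

    A cell invades iff at any frame the overlap of its footprint with the
    hole mask reaches ``overlap_min`` of the footprint.  The fraction is
    over tracked cells with lifetime >= ``min_track_len`` frames; with no
    such cell the fraction is NaN (flagged), not 0.
    """
    events = []
    n_invading = 0
    eligible = [t for t in tracks if t.n_points >= min_track_len]
    if not eligible:
        logger.warning("score_invasion: no tracked cell of sufficient lifetime")
    for track in eligible:
        best = 0.0
        first = None
        for p in track.points:
            footprint = frames[p.frame_index].mask(p.label)
            n_fp = footprint.sum()
            if n_fp == 0:
                continue
            frac = float((footprint & hole_masks[p.frame_index]).sum() / n_fp)
            best = max(best, frac)
            if first is None and frac >= overlap_min:
                first = p.frame_index
        if first is not None:
            n_invading += 1
        events.append(InvasionEvent(track.track_id, first, best))
    return InvasionResult(
        movie_id=movie_id,
        treatment=treatment,
        n_cells=len(eligible),
        n_invading=n_invading,
        events=events,
    )


def compare_treatments(
    results: list[InvasionResult], reference: str
) -> pd.DataFrame:
    """Treatment summary mirroring a per-movie invasion table.

    The movie is the experimental unit: each treatment's mean and SEM are
    computed over movie fractions, and every non-reference treatment is
    compared to the reference with a one-way ANOVA over movie fractions.
    A treatment with fewer than 2 movies has no SEM and its comparison is
    refused.
    """
    by_treatment: dict[str, list[InvasionResult]] = {}
    for r in sorted(results, key=lambda r: r.movie_id):
        by_treatment.setdefault(r.treatment, []).append(r)
    if reference not in by_treatment:
        raise ValueError(f"reference treatment {reference!r} absent")
    ref_fracs = [r.fraction for r in by_treatment[reference]
                 if np.isfinite(r.fraction)]
    rows = []
    for treatment, rs in by_treatment.items():
        fracs = np.array([r.fraction for r in rs if np.isfinite(r.fraction)])
        n_movies = len(fracs)
        if n_movies < 2:
            raise ValueError(
                f"treatment {treatment!r} has {n_movies} movie(s); at least 2 "
                "are needed for an SEM and a comparison"
            )
        sem = float(fracs.std(ddof=1) / np.sqrt(n_movies))
        if treatment == reference:
            p = None
        else:
            p = float(stats.f_oneway(ref_fracs, fracs).pvalue)
        rows.append(
            {
                "treatment": treatment,
                "fraction_mean": float(fracs.mean()),
                "fraction_sem": sem,
                "n_movies": n_movies,
                "total_cells": int(sum(r.n_cells for r in rs)),
                "anova_p_vs_reference": p,
            }
        )
    return pd.DataFrame(rows)


def analyze_invasion_movie(
    red_stack: np.ndarray,
    green_stack: np.ndarray,
    pixel_size_um: float,
    lapse_interval_min: float,
    hole_factor: float = 0.5,
    overlap_min: float = 0.3,
    min_hole_area_um2: float = 50.0,
    min_track_len: int = 3,
    renormalize: bool = False,
    movie_id: str = "",
    treatment: str = "",
) -> InvasionResult:
    """Full single-movie analysis: holes, green tracks, coincidence scoring."""
    holes = detect_holes(
        red_stack,
        pixel_size_um,
        hole_factor=hole_factor,
        min_hole_area_um2=min_hole_area_um2,
        renormalize=renormalize,
    )
    tracks, frames = segment_track_green(
        green_stack, pixel_size_um, lapse_interval_min
    )
    return score_invasion(
        tracks, frames, holes,
        overlap_min=overlap_min,
        min_track_len=min_track_len,
        movie_id=movie_id,
        treatment=treatment,
    )
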