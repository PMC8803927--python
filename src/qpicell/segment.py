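"""Cell segmentation and mass-gated nearest-neighbour tracking.

Segmentation thresholds a lightly smoothed dry-mass map at a small
fraction (default 1%) of its maximum cell signal, which preserves the
thin cell periphery; per-object statistics are always computed on the
raw values inside the mask, so legitimately negative pixels in the
thinnest cell parts contribute with their sign to the object's mass.

Tracking follows the rule "nearest object with a similar mass in the
next frame": candidate links are taken greedily in ascending
centroid-distance order, admissible only below a distance gate and a
relative mass-difference gate.  Touching cells form clusters that are
tracked as single objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from qpicell.phase import DryMassMap

logger = logging.getLogger(__name__)

EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class LabeledObject:
    """One segmented object in one frame."""

    label: int
    area_um2: float
    mass_pg: float
    centroid_um: tuple[float, float]  # (x, y)
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1)


@dataclass
class LabeledFrame:
    """Segmentation of one frame: label image plus per-object statistics."""

    labels: np.ndarray  # (H, W) int, 0 = background
    objects: list[LabeledObject]
    pixel_size_um: float
    timestamp_min: float = 0.0
    frame_index: int = 0

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class TrackPoint:
    frame_index: int
    label: int
    centroid_um: tuple[float, float]
    mass_pg: float
    area_um2: float
    t_min: float


@dataclass
class CellTrack:
    """One cell (or cluster) followed over time."""

    track_id: int
    points: list[TrackPoint] = field(default_factory=list)

    @property
    def start_frame(self) -> int:
        return self.points[0].frame_index

    @property
    def end_frame(self) -> int:
        return self.points[-1].frame_index

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def positions_um(self) -> np.ndarray:
        return np.array([p.centroid_um for p in self.points])

    @property
    def masses_pg(self) -> np.ndarray:
        return np.array([p.mass_pg for p in self.points])

    @property
    def times_min(self) -> np.ndarray:
        return np.array([p.t_min for p in self.points])


def segment_frame(
    dm: DryMassMap,
    threshold_fraction: float = 0.01,
    min_area_um2: float = 20.0,
    smoothing_sigma_px: float = 1.0,
    frame_index: int = 0,
) -> LabeledFrame:
    """Segment a background-subtracted dry-mass map.

    The mask is ``smoothed > threshold_fraction * max(smoothed)``;
    8-connected components above ``min_area_um2`` are kept.  Statistics are
    computed on the RAW values inside the mask: the object mass is the
    signed sum, centroids are weighted by the positive part of the signal
    (signed weights could place a centroid outside the object).
    An empty frame yields an empty :class:`LabeledFrame`.
    """
    raw = dm.values
    smoothed = ndimage.gaussian_filter(raw, smoothing_sigma_px) if smoothing_sigma_px > 0 else raw
    peak = smoothed.max()
    px_area = dm.pixel_area_um2
    objects: list[LabeledObject] = []
    labels = np.zeros(raw.shape, dtype=np.int32)
    if peak > 0:
        mask = smoothed > threshold_fraction * peak
        lab, n = ndimage.label(mask, structure=EIGHT_CONN)
        min_px = max(int(np.ceil(min_area_um2 / px_area)), 1)
        keep_label = 0
        slices = ndimage.find_objects(lab)
        for k in range(1, n + 1):
            sl = slices[k - 1]
            obj_mask = lab[sl] == k
            n_px = int(obj_mask.sum())
            if n_px < min_px:
                continue
            keep_label += 1
            vals = raw[sl][obj_mask]
            mass = float(vals.sum() * px_area)
            weights = np.clip(raw[sl], 0, None) * obj_mask
            wsum = weights.sum()
            rr, cc = np.mgrid[sl[0].start:sl[0].stop, sl[1].start:sl[1].stop]
            if wsum > 0:
                cy = float((weights * rr).sum() / wsum)
                cx = float((weights * cc).sum() / wsum)
            else:
                cy = float(rr[obj_mask].mean())
                cx = float(cc[obj_mask].mean())
            labels[sl][obj_mask] = keep_label
            objects.append(
                LabeledObject(
                    label=keep_label,
                    area_um2=n_px * px_area,
                    mass_pg=mass,
                    centroid_um=(cx * dm.pixel_size_um, cy * dm.pixel_size_um),
                    bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
                )
            )
    return LabeledFrame(
        labels=labels,
        objects=objects,
        pixel_size_um=dm.pixel_size_um,
        timestamp_min=dm.timestamp_min,
        frame_index=frame_index,
    )


def track_frames(
    frames: list[LabeledFrame],
    d_max_um: float = 30.0,
    mass_tol: float = 0.35,
    max_gap: int = 2,
) -> list[CellTrack]:
    """Link segmented objects into tracks (greedy nearest, mass-gated).

    A candidate (track endpoint, object) pair is admissible iff the
    centroid distance is at most ``d_max_um`` per elapsed frame and the
    relative mass difference ``|m1 - m2| / max(m1, m2)`` is at most
    ``mass_tol``.  Pairs are linked greedily in ascending distance order.
    Unmatched objects start new tracks; a track unmatched for more than
    ``max_gap`` frames is closed.  When two tracks converge on one object
    (a merge), the heavier track keeps it and the lighter one is closed
    with a logged merge event.
    """
    if len(frames) < 2:
        raise ValueError("tracking needs at least 2 frames")
    tracks: list[CellTrack] = []
    active: list[CellTrack] = []
    next_id = 1

    def _add_point(track: CellTrack, frame: LabeledFrame, obj: LabeledObject):
        track.points.append(
            TrackPoint(
                frame_index=frame.frame_index,
                label=obj.label,
                centroid_um=obj.centroid_um,
                mass_pg=obj.mass_pg,
                area_um2=obj.area_um2,
                t_min=frame.timestamp_min,
            )
        )

    for frame in frames:
        f = frame.frame_index
        candidates = []
        for ti, track in enumerate(active):
            last = track.points[-1]
            elapsed = f - last.frame_index
            if elapsed < 1 or elapsed > max_gap + 1:
                continue
            for oi, obj in enumerate(frame.objects):
                d = float(np.hypot(
                    obj.centroid_um[0] - last.centroid_um[0],
                    obj.centroid_um[1] - last.centroid_um[1],
                ))
                if d > d_max_um * elapsed:
                    continue
                m1, m2 = last.mass_pg, obj.mass_pg
                if abs(m1 - m2) / max(abs(m1), abs(m2), 1e-12) > mass_tol:
                    continue
                candidates.append((d, ti, oi))
        candidates.sort(key=lambda c: c[0])
        taken_tracks: dict[int, int] = {}
        taken_objs: dict[int, int] = {}
        for d, ti, oi in candidates:
            if ti in taken_tracks or oi in taken_objs:
                continue
            taken_tracks[ti] = oi
            taken_objs[oi] = ti
        # merge detection: an unmatched track whose admissible objects were
        # all taken by heavier tracks is closed now
        merged: set[int] = set()
        for d, ti, oi in candidates:
            if ti in taken_tracks or ti in merged:
                continue
            other_ti = taken_objs.get(oi)
            if other_ti is None:
                continue
            if active[other_ti].points[-1].mass_pg >= active[ti].points[-1].mass_pg:
                logger.info(
                    "merge: track %d absorbed near track %d at frame %d",
                    active[ti].track_id, active[other_ti].track_id, f,
                )
                merged.add(ti)
        for ti, oi in taken_tracks.items():
            _add_point(active[ti], frame, frame.objects[oi])
        for oi, obj in enumerate(frame.objects):
            if oi not in taken_objs:
                track = CellTrack(track_id=next_id)
                next_id += 1
                _add_point(track, frame, obj)
                tracks.append(track)
                active.append(track)
        active = [
            t
            for ti, t in enumerate(active)
            if ti not in merged and f - t.points[-1].frame_index <= max_gap
        ]
    return tracks


def tracks_to_dataframe(tracks: list[CellTrack]) -> pd.DataFrame:
    """Tidy table: one row per (track, frame)."""
    rows = [
        {
            "track_id": t.track_id,
            "frame": p.frame_index,
            "t_min": p.t_min,
            "x_um": p.centroid_um[0],
            "y_um": p.centroid_um[1],
            "mass_pg": p.mass_pg,
            "area_um2": p.area_um2,
            "label": p.label,
        }
        for t in tracks
        for p in t.points
    ]
    return pd.DataFrame(rows)
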