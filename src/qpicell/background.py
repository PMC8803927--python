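"""Background fluctuation removal, temporal-mode reconstruction and subtraction.

Interference microscopy backgrounds drift between frames (a global OPD
offset from the reference-arm geometry) and carry a smooth static
aberration surface.  Cells occupy any given pixel only transiently, so the
most frequent OPD value in a pixel's time course estimates the cell-free
background there.  Pixels covered by cells during the whole time-lapse
have no dominant value; they are flagged and inpainted with a blend of a
harmonic (Laplace) extension of the local boundary values and a global
degree-2 polynomial fit, weighted toward the local solution near the gap
boundary and the global one deep inside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

logger = logging.getLogger(__name__)


@dataclass
class BackgroundEstimate:
    """Reconstructed cell-free background surface."""

    surface: np.ndarray  # (H, W) um OPD
    covered_always_mask: np.ndarray  # (H, W) bool: inpainted pixels
    per_frame_offsets: np.ndarray  # (T,) um OPD


def robust_noise_sd(stack: np.ndarray) -> float:
    """Per-pixel temporal noise SD, robust to moving cells.

    Median absolute deviation of frame-to-frame differences, scaled to the
    SD of a Gaussian; the difference of two frames carries twice the noise
    variance.
    """
    if stack.shape[0] < 2:
        return 0.0
    d = np.diff(stack, axis=0)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _mode_of_values(values: np.ndarray, bin_width: float) -> float:
    """Modal value of a 1D sample.

    Histogram bins are anchored at the sample median so the binning is
    aligned with the distribution (identical across frames that differ only
    by a shift); the estimate is the mean of the samples within one bin
    width of the fullest bin, which removes the half-bin quantization bias.
    """
    if bin_width <= 0 or np.ptp(values) < bin_width:
        return float(np.median(values))
    anchor = np.median(values)
    q = np.floor((values - anchor) / bin_width).astype(np.int64)
    bins, counts = np.unique(q, return_counts=True)
    modal = bins[np.argmax(counts)]
    sel = (q >= modal - 1) & (q <= modal + 1)
    return float(values[sel].mean())


def remove_frame_fluctuations(
    opd_stack: np.ndarray, bin_width: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract each frame's modal background level; return stack and offsets.

    The provisional background of a frame is its lowest 50% of pixel values
    (cells only add positive OPD); the modal value of those pixels is
    subtracted so the background mode sits at zero in every frame.
    A single-frame stack passes through with offset 0.
    """
    stack = np.asarray(opd_stack, dtype=float)
    n = stack.shape[0]
    if n < 2:
        return stack.copy(), np.zeros(n)
    if bin_width is None:
        noise = robust_noise_sd(stack)
        bin_width = 4.0 * noise
    offsets = np.empty(n)
    out = np.empty_like(stack)
    for t in range(n):
        frame = stack[t]
        lo = frame[frame <= np.median(frame)]
        offsets[t] = _mode_of_values(lo.ravel(), bin_width)
        out[t] = frame - offsets[t]
    return out, offsets


def temporal_mode_background(
    opd_stack: np.ndarray,
    bin_width: float | None = None,
    f_min: float = 0.25,
) -> BackgroundEstimate:
    """Per-pixel temporal mode of a fluctuation-corrected stack.

    A histogram bin of a pixel's time course is *dominant* when it holds at
    least ``f_min`` of the frames.  Cells only add OPD, so the lowest-valued
    dominant bin is the cell-free background; the estimate is refined to
    the mean of the samples in that bin.  Pixels with no dominant bin were
    covered by cells throughout and are flagged in ``covered_always_mask``
    for inpainting.

    Default bin width: 4x the robust per-pixel noise SD.
    """
    stack = np.asarray(opd_stack, dtype=float)
    n_frames = stack.shape[0]
    if bin_width is None:
        bin_width = 4.0 * robust_noise_sd(stack)
    if bin_width <= 0:
        bin_width = max(1e-12, 1e-6 * max(np.ptp(stack), 1.0))
    h, w = stack.shape[1:]
    q_flat = np.floor(stack / bin_width).astype(np.int64).reshape(n_frames, -1)
    # per-pixel modal bin: sort each pixel's time course, find the longest
    # run of equal quantized values
    qs = np.sort(q_flat, axis=0)
    first_of_run = np.zeros((n_frames, h * w), dtype=bool)
    first_of_run[0] = True
    first_of_run[1:] = np.diff(qs, axis=0) != 0
    run_id = np.cumsum(first_of_run, axis=0) - 1  # run index per sorted sample
    n_runs = int(run_id.max()) + 1
    flat_pix = np.broadcast_to(np.arange(h * w), (n_frames, h * w))
    run_flat = (run_id * (h * w) + flat_pix).ravel()
    counts = np.bincount(run_flat, minlength=n_runs * h * w).reshape(n_runs, h * w)
    # a bin is dominant if it holds at least f_min of the frames; cells only
    # add OPD, so among dominant bins the lowest-valued one is the background
    min_count = max(int(np.ceil(f_min * n_frames)), 1)
    qualifies = counts >= min_count
    best_run = qualifies.argmax(axis=0)  # runs are sorted ascending in value
    has_dominant = qualifies.any(axis=0)
    # bin value of the chosen run = sorted value at its first sample
    first_idx = (run_id == best_run[None]).argmax(axis=0)
    modal_bin = qs[first_idx, np.arange(h * w)]
    # average all samples within one bin width of the chosen bin: the window
    # spans the whole noise distribution wherever the bin edges fell,
    # removing the half-bin quantization bias of the raw bin centre
    in_modal = (q_flat >= modal_bin[None] - 1) & (q_flat <= modal_bin[None] + 1)
    surface = (
        np.where(in_modal, stack.reshape(n_frames, -1), 0.0).sum(axis=0)
        / np.maximum(in_modal.sum(axis=0), 1)
    ).reshape(h, w)
    covered = (~has_dominant).reshape(h, w)
    surface[covered] = np.nan
    return BackgroundEstimate(
        surface=surface,
        covered_always_mask=covered,
        per_frame_offsets=np.zeros(n_frames),
    )


def flag_surface_outliers(
    est: BackgroundEstimate, threshold: float, window_px: int = 7
) -> BackgroundEstimate:
    """Flag surface pixels that break local smoothness for inpainting.

    The aberration surface is smooth by assumption; a trusted-looking pixel
    deviating from its local median by more than ``threshold`` (um OPD) was
    contaminated — typically by a cell hovering over it with stable values —
    and is added to ``covered_always_mask``.
    """
    surface = est.surface.copy()
    work = surface.copy()
    gap = est.covered_always_mask
    if gap.any():
        # neutral fill so gaps do not drag the local median
        work[gap] = np.nanmedian(surface)
    med = ndimage.median_filter(work, size=window_px)
    outliers = (np.abs(work - med) > threshold) & ~gap
    if outliers.any():
        logger.info("flag_surface_outliers: %d contaminated px flagged",
                    int(outliers.sum()))
    surface[outliers] = np.nan
    return replace(
        est, surface=surface, covered_always_mask=gap | outliers
    )


def _harmonic_fill(surface: np.ndarray, gap: np.ndarray) -> np.ndarray:
    """Solve the Laplace equation on gap pixels with Dirichlet boundary values."""
    h, w = surface.shape
    gap_idx = np.flatnonzero(gap.ravel())
    n = gap_idx.size
    pos = -np.ones(h * w, dtype=np.int64)
    pos[gap_idx] = np.arange(n)
    rows, cols, data = [], [], []
    rhs = np.zeros(n)
    filled = np.nan_to_num(surface, nan=0.0)
    for k, p in enumerate(gap_idx):
        r, c = divmod(p, w)
        rows.append(k)
        cols.append(k)
        neigh = []
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < h and 0 <= cc < w:
                neigh.append(rr * w + cc)
        data.append(float(len(neigh)))
        for q in neigh:
            if pos[q] >= 0:
                rows.append(k)
                cols.append(pos[q])
                data.append(-1.0)
            else:
                rhs[k] += filled.ravel()[q]
    lap = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    sol = spsolve(lap.tocsc(), rhs)
    out = surface.copy()
    out.ravel()[gap_idx] = sol
    return out


def _poly2_fit(surface: np.ndarray, valid: np.ndarray, max_samples: int = 20000) -> np.ndarray:
    """Least-squares degree-2 polynomial fit to valid pixels, evaluated everywhere."""
    h, w = surface.shape
    vv, uu = np.mgrid[0:h, 0:w]
    u = uu / max(w - 1, 1)
    v = vv / max(h - 1, 1)
    design = np.column_stack(
        [np.ones(h * w), u.ravel(), v.ravel(), (u * u).ravel(), (u * v).ravel(), (v * v).ravel()]
    )
    vid = np.flatnonzero(valid.ravel())
    if vid.size > max_samples:
        step = vid.size // max_samples
        vid = vid[::step]
    coeffs, *_ = np.linalg.lstsq(design[vid], surface.ravel()[vid], rcond=None)
    return (design @ coeffs).reshape(h, w)


def inpaint_background(
    est: BackgroundEstimate, blend_scale_px: float = 20.0
) -> BackgroundEstimate:
    """Fill flagged gap pixels with a local-harmonic / global-polynomial blend.

    Gap pixels receive ``w*L + (1-w)*G`` where L is the harmonic (Laplace)
    interpolation from the gap boundary, G a global degree-2 polynomial
    fitted to the trusted pixels, and ``w = exp(-d / d0)`` decays with the
    distance d to the gap boundary (``d0 = blend_scale_px``).  A plane
    background is reproduced exactly by both components, hence by any
    blend.  If a gap touches all four image borders the harmonic component
    is unreliable and the polynomial alone is used (logged).
    """
    gap = est.covered_always_mask
    if not gap.any():
        return replace(est, surface=est.surface.copy())
    surface = est.surface
    valid = ~gap
    g_fit = _poly2_fit(surface, valid)
    h, w = surface.shape
    touches_all = (
        gap[0].any() and gap[-1].any() and gap[:, 0].any() and gap[:, -1].any()
    )
    if touches_all:
        logger.warning("inpaint_background: gap touches all borders; polynomial only")
        out = surface.copy()
        out[gap] = g_fit[gap]
        return replace(est, surface=out)
    l_fill = _harmonic_fill(surface, gap)
    dist = ndimage.distance_transform_edt(gap)
    weight = np.exp(-dist / blend_scale_px)
    out = surface.copy()
    out[gap] = weight[gap] * l_fill[gap] + (1 - weight[gap]) * g_fit[gap]
    return replace(est, surface=out)


def subtract_background(opd_stack: np.ndarray, est: BackgroundEstimate) -> np.ndarray:
    """Subtract the reconstructed background surface from every frame."""
    stack = np.asarray(opd_stack, dtype=float)
    if stack.shape[1:] != est.surface.shape:
        raise ValueError(
            f"stack shape {stack.shape[1:]} != surface shape {est.surface.shape}"
        )
    if np.isnan(est.surface).any():
        raise ValueError("background surface has unfilled gaps; inpaint first")
    return stack - est.surface[None]


def run_background_pipeline(
    opd_stack: np.ndarray,
    bin_width: float | None = None,
    f_min: float = 0.25,
    blend_scale_px: float = 20.0,
) -> tuple[np.ndarray, BackgroundEstimate]:
    """Fluctuation removal -> temporal mode -> outlier flagging -> inpainting -> subtraction."""
    corrected, offsets = remove_frame_fluctuations(opd_stack, bin_width=bin_width)
    if bin_width is None:
        bin_width = 4.0 * robust_noise_sd(corrected)
    est = temporal_mode_background(corrected, bin_width=bin_width, f_min=f_min)
    est = flag_surface_outliers(est, threshold=max(4.0 * bin_width, 1e-9))
    est = inpaint_background(est, blend_scale_px=blend_scale_px)
    est = replace(est, per_frame_offsets=offsets)
    return subtract_background(corrected, est), est
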