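"""Phase-shifting reconstruction and dry-mass calibration.

Recovers the optical path difference (OPD) introduced by cells from four
interferograms acquired with quarter-wave reference phase steps, unwraps
it where cells exceed half a wavelength of optical thickness, and converts
it to dry-mass surface density through the specific refractive increment.

The four-step algorithm: with intensities

    I_k = A + B cos(phi + delta_k),    delta_k = k * pi/2,

the object phase follows in closed form as

    phi = atan2(I_3 - I_1, I_0 - I_2),

exact per pixel for noise-free data.  OPD = phi * lambda / (2 pi), and the
dry-mass surface density is sigma = OPD / alpha with alpha the average
specific refractive increment of cellular dry matter
(default 0.18 um^3/pg).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase as _skimage_unwrap

logger = logging.getLogger(__name__)

#: Average specific refractive increment of cellular dry matter, um^3 per pg.
DEFAULT_ALPHA_UM3_PER_PG = 0.18

QUARTER_WAVE_STEPS = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])


class UnsupportedScheduleError(ValueError):
    """Raised for phase-step schedules the two-difference formula cannot invert.

    Only quarter-wave schedules (steps of pi/2, up to a common offset) are
    supported; arbitrary-step algorithms such as the Carre method are out
    of scope.
    """


@dataclass
class InterferogramSet:
    """Four co-registered phase-shifted intensity frames for one time point."""

    frames: np.ndarray  # (4, H, W)
    phase_steps_rad: np.ndarray  # (4,)
    wavelength_nm: float
    timestamp_min: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.phase_steps_rad = np.asarray(self.phase_steps_rad, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != 4:
            raise ValueError("expected exactly 4 frames of identical shape")
        if self.phase_steps_rad.shape != (4,):
            raise ValueError("expected exactly 4 phase steps")
        if np.any(np.diff(self.phase_steps_rad) <= 0):
            raise ValueError("phase steps must be strictly increasing")
        if not self.wavelength_nm > 0:
            raise ValueError("wavelength must be positive")


@dataclass
class OPDMap:
    """Optical path difference field in micrometres."""

    values: np.ndarray  # (H, W), um of optical path
    pixel_size_um: float
    timestamp_min: float = 0.0
    wrapped: bool = False
    invalid_mask: np.ndarray | None = None

    @property
    def shape(self):
        return self.values.shape


@dataclass
class DryMassMap:
    """Dry-mass surface density field in pg per um^2."""

    values: np.ndarray  # (H, W)
    pixel_size_um: float
    timestamp_min: float = 0.0
    alpha_um3_per_pg: float = DEFAULT_ALPHA_UM3_PER_PG

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2

    def total_mass_pg(self, mask: np.ndarray | None = None) -> float:
        """Integrated dry mass (pg) over the full field or a boolean mask."""
        v = self.values if mask is None else self.values[mask]
        return float(v.sum() * self.pixel_area_um2)

    @property
    def shape(self):
        return self.values.shape


def _check_quarter_wave(steps: np.ndarray) -> float:
    """Validate a quarter-wave schedule; return the common offset delta_0."""
    steps = np.asarray(steps, dtype=float)
    rel = steps - steps[0]
    if not np.allclose(rel, QUARTER_WAVE_STEPS, atol=1e-9):
        raise UnsupportedScheduleError(
            "phase steps must be (0, pi/2, pi, 3pi/2) up to a common offset; "
            f"got {steps!r}. Generalized schedules (e.g. the Carre algorithm) "
            "are not supported."
        )
    return float(steps[0])


def _fill_nearest(values: np.ndarray, invalid: np.ndarray) -> np.ndarray:
    """Replace invalid pixels by their nearest valid neighbour's value."""
    if not invalid.any():
        return values
    if invalid.all():
        return np.zeros_like(values)
    _, idx = ndimage.distance_transform_edt(invalid, return_indices=True)
    return values[tuple(idx)]


def reconstruct_phase(
    ifs: InterferogramSet,
    pixel_size_um: float = 1.0,
    modulation_floor: float = 1e-12,
) -> OPDMap:
    """Recover the wrapped OPD from four quarter-wave interferograms.

    phi = atan2(I3 - I1, I0 - I2) per pixel (four-quadrant arctangent of the
    ratio of two image differences), then OPD = phi * lambda / (2 pi) in um.

    Pixels with zero fringe modulation (both differences below
    ``modulation_floor``) carry no phase information; they are filled by
    nearest-neighbour interpolation, flagged in ``invalid_mask`` and their
    count logged.
    """
    delta0 = _check_quarter_wave(ifs.phase_steps_rad)
    i0, i1, i2, i3 = ifs.frames
    num = i3 - i1  # 2 B sin(phi + delta0)
    den = i0 - i2  # 2 B cos(phi + delta0)
    invalid = (np.abs(num) < modulation_floor) & (np.abs(den) < modulation_floor)
    phi = np.arctan2(num, den) - delta0
    # rewrap into [-pi, pi) after removing the schedule offset
    phi = np.mod(phi + np.pi, 2 * np.pi) - np.pi
    n_invalid = int(invalid.sum())
    if n_invalid:
        logger.info("reconstruct_phase: %d zero-modulation pixels filled", n_invalid)
        phi = _fill_nearest(phi, invalid)
    lam_um = ifs.wavelength_nm * 1e-3
    return OPDMap(
        values=phi * lam_um / (2 * np.pi),
        pixel_size_um=pixel_size_um,
        timestamp_min=ifs.timestamp_min,
        wrapped=True,
        invalid_mask=invalid if n_invalid else None,
    )


def unwrap_phase(opd: OPDMap, wavelength_nm: float) -> OPDMap:
    """Unwrap a wrapped OPD map (2D reliability-guided unwrapping).

    The result differs from the input by integer multiples of the wavelength
    per pixel; flat fields pass through unchanged.  Disconnected valid
    regions are unwrapped independently by the underlying algorithm.
    """
    if not opd.wrapped:
        return opd
    lam_um = wavelength_nm * 1e-3
    phi = opd.values * 2 * np.pi / lam_um
    if np.ptp(phi) < np.pi:
        unwrapped_phi = phi  # range too small to contain a wrap
    else:
        # Sensor noise flips pixels near the wrap contour across the branch
        # cut, which derails path-following unwrappers.  Unwrap a
        # complex-smoothed copy of the field to get a clean integer
        # wrap-count map, then apply those counts to the raw phase so pixel
        # values are preserved exactly (mod 2 pi).
        z = np.exp(1j * phi)
        zs = ndimage.gaussian_filter(z.real, 1.5) + 1j * ndimage.gaussian_filter(
            z.imag, 1.5
        )
        phi_smooth = np.asarray(_skimage_unwrap(np.angle(zs)))
        k = np.round((phi_smooth - phi) / (2 * np.pi))
        unwrapped_phi = phi + 2 * np.pi * k
    return replace(opd, values=unwrapped_phi * lam_um / (2 * np.pi), wrapped=False)


def opd_to_dry_mass(
    opd: OPDMap, alpha_um3_per_pg: float = DEFAULT_ALPHA_UM3_PER_PG
) -> DryMassMap:
    """Convert an (unwrapped, background-subtracted) OPD map to dry mass density.

    sigma = OPD / alpha, in pg um^-2.  The conversion is exactly linear.
    """
    if not alpha_um3_per_pg > 0:
        raise ValueError("alpha must be positive")
    return DryMassMap(
        values=opd.values / alpha_um3_per_pg,
        pixel_size_um=opd.pixel_size_um,
        timestamp_min=opd.timestamp_min,
        alpha_um3_per_pg=alpha_um3_per_pg,
    )


def reconstruct_phase_fourier(
    hologram: np.ndarray,
    carrier_cycles_per_px: tuple[float, float],
    wavelength_nm: float,
    pixel_size_um: float = 1.0,
    timestamp_min: float = 0.0,
) -> OPDMap:
    """Off-axis holographic reconstruction by Fourier sideband demodulation.

    The +1 diffraction order around the carrier frequency is isolated with a
    Gaussian filter of radius half the carrier magnitude, shifted to the
    origin, and inverse-transformed; the wrapped object phase is the argument
    of the resulting complex field.

    Parameters
    ----------
    hologram:
        Single fringe image ``A + B cos(2 pi (fx x + fy y) + phi)``.
    carrier_cycles_per_px:
        Carrier spatial frequency ``(fy, fx)`` in cycles per pixel along the
        (row, col) axes.
    """
    holo = np.asarray(hologram, dtype=float)
    h, w = holo.shape
    fy, fx = carrier_cycles_per_px
    fmag = float(np.hypot(fx, fy))
    # carrier must be resolvable: several cycles across the field, below Nyquist
    if fmag * min(h, w) < 4 or fmag > 0.5:
        raise ValueError(
            f"carrier magnitude {fmag:.4f} cycles/px not resolvable for a "
            f"{h}x{w} field"
        )
    # Hann apodization suppresses the spectral leakage of a non-periodic
    # carrier; it modulates the field amplitude, not its phase
    taper = np.hanning(h)[:, None] * np.hanning(w)[None, :]
    spec = np.fft.fft2(holo * taper)
    freq_y = np.fft.fftfreq(h)[:, None]
    freq_x = np.fft.fftfreq(w)[None, :]
    # Gaussian sideband window with effective radius about half the carrier
    # magnitude (the DC and conjugate orders are strongly suppressed)
    sigma = fmag / 4.5
    window = np.exp(-(((freq_y - fy) ** 2 + (freq_x - fx) ** 2)) / (2 * sigma ** 2))
    sideband = spec * window
    field = np.fft.ifft2(sideband)
    # demodulate the carrier
    yy, xx = np.mgrid[0:h, 0:w]
    field = field * np.exp(-2j * np.pi * (fy * yy + fx * xx))
    phi = np.angle(field)
    lam_um = wavelength_nm * 1e-3
    return OPDMap(
        values=phi * lam_um / (2 * np.pi),
        pixel_size_um=pixel_size_um,
        timestamp_min=timestamp_min,
        wrapped=True,
    )
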