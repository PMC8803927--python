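"""Seeded synthetic microscopy scenes with known ground truth.

Two forward models are provided:

* **QPI scenes** — cells rendered as smooth positive dry-mass blobs that
  move by a persistent random walk (optionally biased along a gradient) and
  grow exponentially; the dry-mass field is converted to optical path
  difference, a smooth quadratic background aberration plus per-frame
  offset fluctuations is added, and four quarter-wave phase-shifted
  interferograms are rendered per time point with Gaussian sensor noise.

* **Invasion scenes** — a confluent red monolayer under green cancer
  cells; scripted invaders open a hole (local red signal loss) beneath
  themselves from a given onset frame.

All randomness flows from one integer seed; identical spec + seed gives
bit-identical output.  Units: positions and sizes in micrometres, masses
in picograms, time in minutes, OPD in micrometres.

The persistent random walk: the heading angle receives a wrapped-normal
increment per step with variance ``2 * dt / persistence_time`` so the
directional autocorrelation decays as ``exp(-t / persistence_time)``;
each step has length ``speed * dt`` exactly.  Chemotactic drift replaces
a fraction of steps with steps straight along the gradient direction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from qpicell.phase import (
    DEFAULT_ALPHA_UM3_PER_PG,
    QUARTER_WAVE_STEPS,
    DryMassMap,
    InterferogramSet,
)

# defaults mirroring the imaging setup: 530 nm LED, 634 x 483 um field,
# 10-min lapse for QPI, 15-min lapse for the invasion assay
DEFAULT_WAVELENGTH_NM = 530.0
DEFAULT_PIXEL_SIZE_UM = 634.0 / 512.0  # 634 um across a 512-px field
DEFAULT_FRINGE_MEAN = 100.0  # interferogram DC level A (counts)
DEFAULT_FRINGE_AMPLITUDE = 50.0  # fringe modulation B (counts)


@dataclass
class CellSpec:
    """One simulated cell: an anisotropic Gaussian dry-mass blob."""

    initial_mass_pg: float = 300.0
    doubling_time_h: float = np.inf  # inf = non-growing
    initial_position_um: tuple[float, float] = (0.0, 0.0)  # (x, y)
    speed_um_per_h: float = 0.0
    persistence_time_min: float = 30.0
    drift_direction_rad: float | None = None
    drift_fraction: float = 0.0
    shape_sigma_um: tuple[float, float] = (8.0, 6.0)

    def __post_init__(self):
        if not self.initial_mass_pg > 0:
            raise ValueError("initial mass must be positive")
        if not self.doubling_time_h > 0:
            raise ValueError("doubling time must be positive (use inf for none)")
        if not 0.0 <= self.drift_fraction <= 1.0:
            raise ValueError("drift_fraction must be in [0, 1]")
        if self.drift_fraction > 0 and self.drift_direction_rad is None:
            raise ValueError("drift_fraction > 0 requires a drift direction")


@dataclass
class SceneSpec:
    """Full QPI scene: geometry, optics, cells, background, noise."""

    field_size_px: tuple[int, int] = (512, 390)  # (W, H) -> 634 x 483 um
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    lapse_interval_min: float = 10.0
    n_frames: int = 10
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    cells: list[CellSpec] = field(default_factory=list)
    #: coefficients of the background OPD polynomial (um) in normalized
    #: coordinates u, v in [0, 1]: [1, u, v, u^2, u*v, v^2]
    background_poly_coeffs: tuple[float, ...] = (0.0,)
    frame_offset_sd: float = 0.0  # um OPD
    intensity_noise_sd: float = 0.0  # counts
    fringe_mean: float = DEFAULT_FRINGE_MEAN
    fringe_amplitude: float = DEFAULT_FRINGE_AMPLITUDE
    phase_steps_rad: tuple[float, ...] = tuple(QUARTER_WAVE_STEPS)
    alpha_um3_per_pg: float = DEFAULT_ALPHA_UM3_PER_PG
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if not self.wavelength_nm > 0:
            raise ValueError("wavelength must be positive")
        w, h = self.field_size_px
        fw, fh = w * self.pixel_size_um, h * self.pixel_size_um
        for c in self.cells:
            x, y = c.initial_position_um
            if not (0 <= x < fw and 0 <= y < fh):
                raise ValueError(f"cell initially outside the field: {c}")

    @property
    def shape(self) -> tuple[int, int]:
        """Image array shape (rows, cols)."""
        return (self.field_size_px[1], self.field_size_px[0])


@dataclass
class SimulationTruth:
    """Ground truth of a simulated QPI scene."""

    dry_mass: list[DryMassMap]  # cell-only signal, no background
    cell_masks: list[np.ndarray]  # per frame: (n_cells, H, W) boolean
    trajectories: np.ndarray  # (n_cells, n_frames, 2) (x, y) um
    masses: np.ndarray  # (n_cells, n_frames) pg
    left_field: np.ndarray  # (n_cells, n_frames) bool: blob clipped by border
    background_surface: np.ndarray | None = None  # (H, W) um OPD
    frame_offsets_um: np.ndarray | None = None  # (n_frames,)

    @property
    def n_cells(self) -> int:
        return self.trajectories.shape[0]


def _background_surface(spec: SceneSpec) -> np.ndarray:
    """Evaluate the background OPD polynomial (um) over the field."""
    h, w = spec.shape
    v, u = np.mgrid[0:h, 0:w]
    u = u / max(w - 1, 1)
    v = v / max(h - 1, 1)
    terms = [np.ones_like(u), u, v, u * u, u * v, v * v]
    coeffs = list(spec.background_poly_coeffs) + [0.0] * 6
    out = np.zeros((h, w))
    for c, t in zip(coeffs[:6], terms):
        out += c * t
    return out


def _simulate_track(
    cell: CellSpec, n_frames: int, dt_min: float, rng: np.random.Generator
) -> np.ndarray:
    """Persistent-random-walk trajectory, (n_frames, 2) (x, y) um."""
    pos = np.empty((n_frames, 2))
    pos[0] = cell.initial_position_um
    step_len = cell.speed_um_per_h * dt_min / 60.0
    # heading increment SD: directional autocorrelation exp(-dt/P)
    sd = np.sqrt(2.0 * dt_min / cell.persistence_time_min)
    theta = (
        cell.drift_direction_rad
        if cell.drift_direction_rad is not None
        else rng.uniform(-np.pi, np.pi)
    )
    for t in range(1, n_frames):
        theta = theta + rng.normal(0.0, sd)
        if cell.drift_fraction > 0 and rng.random() < cell.drift_fraction:
            step_dir = cell.drift_direction_rad
        else:
            step_dir = theta
        pos[t] = pos[t - 1] + step_len * np.array(
            [np.cos(step_dir), np.sin(step_dir)]
        )
    return pos


def render_blob(
    shape: tuple[int, int],
    center_um: tuple[float, float],
    sigma_um: tuple[float, float],
    mass_pg: float,
    pixel_size_um: float,
    trunc_sigma: float = 2.5,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Render one truncated Gaussian blob as dry-mass density (pg/um^2).

    The blob is truncated at ``trunc_sigma`` (elliptical radius, default
    2.5 sigma) and renormalized so its integral equals ``mass_pg`` exactly,
    making mass-conservation checks exact.  The tight truncation mimics the
    compact edge of an adherent cell: the density at the rim is a few
    percent of the peak, so a low segmentation threshold captures the whole
    object.  Returns (density image, footprint mask, clipped flag).
    """
    h, w = shape
    cx, cy = center_um
    sx, sy = sigma_um
    cxp, cyp = cx / pixel_size_um, cy / pixel_size_um
    sxp, syp = sx / pixel_size_um, sy / pixel_size_um
    ts = trunc_sigma
    x0, x1 = int(np.floor(cxp - ts * sxp)), int(np.ceil(cxp + ts * sxp)) + 1
    y0, y1 = int(np.floor(cyp - ts * syp)), int(np.ceil(cyp + ts * syp)) + 1
    clipped = x0 < 0 or y0 < 0 or x1 > w or y1 > h
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    density = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    if x0c >= x1c or y0c >= y1c:
        return density, mask, True
    xs = np.arange(x0c, x1c)
    ys = np.arange(y0c, y1c)
    gx = (xs - cxp) / sxp
    gy = (ys - cyp) / syp
    r2 = gy[:, None] ** 2 + gx[None, :] ** 2
    g = np.exp(-0.5 * r2)
    g[r2 > ts * ts] = 0.0  # elliptical truncation
    total = g.sum()
    if total <= 0:
        return density, mask, True
    px_area = pixel_size_um ** 2
    density[y0c:y1c, x0c:x1c] = g * (mass_pg / (total * px_area))
    mask[y0c:y1c, x0c:x1c] = g > 0
    return density, mask, clipped


def simulate_ground_truth(spec: SceneSpec) -> SimulationTruth:
    """Simulate trajectories, masses and true dry-mass maps for a scene.

    Per-cell mass at frame t is ``m0 * 2**(t*dt/Td)``; with the renormalized
    blob rendering the integrated mass of an in-field cell matches this
    exactly.  A cell whose 4-sigma footprint is clipped by the field border
    is flagged in ``left_field`` (never an exception).
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_cells = len(spec.cells)
    shape = spec.shape
    dt = spec.lapse_interval_min
    trajectories = np.zeros((n_cells, spec.n_frames, 2))
    masses = np.zeros((n_cells, spec.n_frames))
    left = np.zeros((n_cells, spec.n_frames), dtype=bool)
    for i, cell in enumerate(spec.cells):
        trajectories[i] = _simulate_track(cell, spec.n_frames, dt, rng)
        t_h = np.arange(spec.n_frames) * dt / 60.0
        if np.isfinite(cell.doubling_time_h):
            masses[i] = cell.initial_mass_pg * 2.0 ** (t_h / cell.doubling_time_h)
        else:
            masses[i] = cell.initial_mass_pg
    dm_maps = []
    cell_masks = []
    for t in range(spec.n_frames):
        density = np.zeros(shape)
        masks = np.zeros((n_cells, *shape), dtype=bool)
        for i, cell in enumerate(spec.cells):
            d, m, clipped = render_blob(
                shape,
                tuple(trajectories[i, t]),
                cell.shape_sigma_um,
                masses[i, t],
                spec.pixel_size_um,
            )
            density += d
            masks[i] = m
            left[i, t] = clipped
        dm_maps.append(
            DryMassMap(
                values=density,
                pixel_size_um=spec.pixel_size_um,
                timestamp_min=t * dt,
                alpha_um3_per_pg=spec.alpha_um3_per_pg,
            )
        )
        cell_masks.append(masks)
    return SimulationTruth(
        dry_mass=dm_maps,
        cell_masks=cell_masks,
        trajectories=trajectories,
        masses=masses,
        left_field=left,
    )


def render_interferograms(
    truth: SimulationTruth, spec: SceneSpec
) -> tuple[list[InterferogramSet], SimulationTruth]:
    """Render 4 phase-shifted interferograms per frame from true dry mass.

    I_k = A + B cos(phi + delta_k) + eps, with
    phi = 2 pi OPD / lambda and OPD = alpha * sigma + background + offset_t.
    The fringe constants A, B and the step schedule are recorded in each
    set's metadata.  Returns the interferograms and the truth augmented with
    the background surface and the per-frame offsets actually drawn.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 1]))
    lam_um = spec.wavelength_nm * 1e-3
    background = _background_surface(spec)
    offsets = rng.normal(0.0, spec.frame_offset_sd, size=len(truth.dry_mass))
    if spec.frame_offset_sd == 0:
        offsets = np.zeros(len(truth.dry_mass))
    steps = np.asarray(spec.phase_steps_rad)
    out = []
    for t, dm in enumerate(truth.dry_mass):
        opd = spec.alpha_um3_per_pg * dm.values + background + offsets[t]
        phi = 2 * np.pi * opd / lam_um
        if np.ptp(phi) > 2 * np.pi:
            warnings.warn(
                f"frame {t}: phase range {np.ptp(phi):.2f} rad exceeds one "
                "wrap period; reconstruction will need unwrapping",
                stacklevel=2,
            )
        frames = np.stack(
            [
                spec.fringe_mean + spec.fringe_amplitude * np.cos(phi + d)
                for d in steps
            ]
        )
        if spec.intensity_noise_sd > 0:
            frames = frames + rng.normal(
                0.0, spec.intensity_noise_sd, size=frames.shape
            )
        out.append(
            InterferogramSet(
                frames=frames,
                phase_steps_rad=steps,
                wavelength_nm=spec.wavelength_nm,
                timestamp_min=dm.timestamp_min,
                meta={
                    "fringe_mean": spec.fringe_mean,
                    "fringe_amplitude": spec.fringe_amplitude,
                },
            )
        )
    truth.background_surface = background
    truth.frame_offsets_um = offsets
    return out, truth


def render_hologram(
    phase_rad: np.ndarray,
    carrier_cycles_per_px: tuple[float, float],
    fringe_mean: float = DEFAULT_FRINGE_MEAN,
    fringe_amplitude: float = DEFAULT_FRINGE_AMPLITUDE,
) -> np.ndarray:
    """Render a single off-axis hologram of a phase object.

    I = A + B cos(2 pi (fy y + fx x) + phi); the forward model for the
    Fourier-demodulation reconstruction mode.
    """
    h, w = phase_rad.shape
    fy, fx = carrier_cycles_per_px
    yy, xx = np.mgrid[0:h, 0:w]
    return fringe_mean + fringe_amplitude * np.cos(
        2 * np.pi * (fy * yy + fx * xx) + phase_rad
    )


# ---------------------------------------------------------------------------
# invasion assay scenes
# ---------------------------------------------------------------------------


@dataclass
class InvasionSceneSpec:
    """Two-channel invasion movie: red monolayer, green cancer cells."""

    field_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 1308.0 / 256.0  # 1308 um camera field
    lapse_interval_min: float = 15.0
    n_frames: int = 15  # 210 min at 15-min lapse
    n_green_cells: int = 10
    invading_indices: tuple[int, ...] = ()
    hole_onset_frame: int = 4
    hole_growth_rate_um_per_frame: float = 3.0
    hole_radius_um: float = 12.0  # initial hole radius at onset
    hole_decay_frames: int = 3  # frames over which red decays to residual
    red_baseline_level: float = 1000.0
    hole_residual_fraction: float = 0.1
    green_peak_level: float = 500.0
    cell_sigma_um: float = 10.0
    cell_speed_um_per_h: float = 10.0
    noise_sd: float = 10.0
    bleaching_per_frame: float = 0.0  # fractional global intensity loss/frame
    min_separation_um: float = 60.0  # enforced between initial cell positions
    rng_seed: int = 0

    def __post_init__(self):
        if not all(0 <= i < self.n_green_cells for i in self.invading_indices):
            raise ValueError("invading_indices must index the green cells")
        if not 0 <= self.hole_residual_fraction < 1:
            raise ValueError("hole_residual_fraction must be in [0, 1)")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.field_size_px[1], self.field_size_px[0])


@dataclass
class InvasionTruth:
    """Ground truth of a simulated invasion movie."""

    trajectories: np.ndarray  # (n_cells, n_frames, 2) um
    invading: np.ndarray  # (n_cells,) bool
    hole_centers_um: np.ndarray  # (n_invaders, 2)


def render_invasion_movie(
    spec: InvasionSceneSpec,
) -> tuple[np.ndarray, np.ndarray, InvasionTruth]:
    """Render red (monolayer) and green (cell) stacks plus ground truth.

    The red channel starts as a smooth confluent texture around the baseline
    level; for each scripted invader a disk pinned at the cell's position at
    hole onset decays linearly over ``hole_decay_frames`` to
    ``hole_residual_fraction * baseline`` and grows at the stated rate.
    The green channel is a Gaussian blob per cell.  Deterministic given
    the seed.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.shape
    n = spec.n_green_cells
    fw, fh = w * spec.pixel_size_um, h * spec.pixel_size_um
    margin = 4 * spec.cell_sigma_um
    # rejection-sample well-separated starting positions so every cell is
    # individually segmentable and trackable
    starts = np.empty((n, 2))
    placed = 0
    attempts = 0
    while placed < n:
        cand = np.array([
            rng.uniform(margin, fw - margin),
            rng.uniform(margin, fh - margin),
        ])
        attempts += 1
        if placed == 0 or np.linalg.norm(
            starts[:placed] - cand, axis=1
        ).min() >= spec.min_separation_um:
            starts[placed] = cand
            placed += 1
        if attempts > 10000 * n:
            raise ValueError("cannot place cells with the requested separation")
    cells = [
        CellSpec(
            initial_mass_pg=1.0,
            initial_position_um=tuple(starts[i]),
            speed_um_per_h=spec.cell_speed_um_per_h,
            persistence_time_min=60.0,
            shape_sigma_um=(spec.cell_sigma_um, spec.cell_sigma_um),
        )
        for i in range(n)
    ]
    traj = np.stack(
        [
            _simulate_track(c, spec.n_frames, spec.lapse_interval_min, rng)
            for c in cells
        ]
    )
    # smooth static monolayer texture (+-5% of baseline)
    v, u = np.mgrid[0:h, 0:w]
    texture = 1.0 + 0.05 * np.sin(2 * np.pi * u / w) * np.cos(2 * np.pi * v / h)
    invading = np.zeros(n, dtype=bool)
    invading[list(spec.invading_indices)] = True
    hole_centers = traj[invading, min(spec.hole_onset_frame, spec.n_frames - 1)]
    xx = (u + 0.0) * spec.pixel_size_um
    yy = (v + 0.0) * spec.pixel_size_um
    red = np.empty((spec.n_frames, h, w))
    green = np.empty((spec.n_frames, h, w))
    for t in range(spec.n_frames):
        scale = (1.0 - spec.bleaching_per_frame) ** t
        frame = spec.red_baseline_level * texture.copy()
        for (cx, cy) in hole_centers:
            dt_on = t - spec.hole_onset_frame
            if dt_on < 0:
                continue
            radius = spec.hole_radius_um + dt_on * spec.hole_growth_rate_um_per_frame
            depth = min(1.0, (dt_on + 1) / spec.hole_decay_frames)
            level = 1.0 - depth * (1.0 - spec.hole_residual_fraction)
            inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
            frame[inside] = spec.red_baseline_level * level
        red[t] = frame * scale
        g = np.zeros((h, w))
        sig_px = spec.cell_sigma_um / spec.pixel_size_um
        for i in range(n):
            cxp = traj[i, t, 0] / spec.pixel_size_um
            cyp = traj[i, t, 1] / spec.pixel_size_um
            x0 = max(int(cxp - 4 * sig_px), 0)
            x1 = min(int(cxp + 4 * sig_px) + 1, w)
            y0 = max(int(cyp - 4 * sig_px), 0)
            y1 = min(int(cyp + 4 * sig_px) + 1, h)
            if x0 >= x1 or y0 >= y1:
                continue
            gx = (np.arange(x0, x1) - cxp) / sig_px
            gy = (np.arange(y0, y1) - cyp) / sig_px
            g[y0:y1, x0:x1] += spec.green_peak_level * np.exp(
                -0.5 * (gy[:, None] ** 2 + gx[None, :] ** 2)
            )
        green[t] = g * scale
    if spec.noise_sd > 0:
        red += rng.normal(0.0, spec.noise_sd, size=red.shape)
        green += rng.normal(0.0, spec.noise_sd, size=green.shape)
    return red, green, InvasionTruth(traj, invading, hole_centers)


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------


def write_qpi_scene(
    outdir: str | Path, spec: SceneSpec, ifs: list[InterferogramSet], truth: SimulationTruth
) -> None:
    """Write a QPI scene: one multi-page TIFF per phase step, truth sidecar, spec YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = np.stack([s.frames for s in ifs])  # (T, 4, H, W)
    for k in range(4):
        tifffile.imwrite(
            outdir / f"interferograms_step{k}.tif",
            stack[:, k].astype(np.float32),
        )
    sidecar = {
        "trajectories_um": truth.trajectories.tolist(),
        "masses_pg": truth.masses.tolist(),
        "left_field": truth.left_field.tolist(),
        "frame_offsets_um": (
            truth.frame_offsets_um.tolist()
            if truth.frame_offsets_um is not None
            else None
        ),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar))
    (outdir / "scene.yaml").write_text(yaml.safe_dump(scene_spec_to_dict(spec)))


def write_invasion_scene(
    outdir: str | Path,
    spec: InvasionSceneSpec,
    red: np.ndarray,
    green: np.ndarray,
    truth: InvasionTruth,
) -> None:
    """Write an invasion movie: red/green multi-page TIFFs, truth sidecar, spec YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "red.tif", red.astype(np.float32))
    tifffile.imwrite(outdir / "green.tif", green.astype(np.float32))
    sidecar = {
        "trajectories_um": truth.trajectories.tolist(),
        "invading": truth.invading.tolist(),
        "hole_centers_um": truth.hole_centers_um.tolist(),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar))
    (outdir / "scene.yaml").write_text(yaml.safe_dump(_to_builtin(asdict(spec))))


def _to_builtin(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def scene_spec_to_dict(spec: SceneSpec) -> dict:
    d = _to_builtin(asdict(spec))
    for c in d["cells"]:
        if c["doubling_time_h"] == float("inf"):
            c["doubling_time_h"] = "inf"
    return d


def scene_spec_from_dict(d: dict) -> SceneSpec:
    d = dict(d)
    cells = []
    for c in d.pop("cells", []):
        c = dict(c)
        if c.get("doubling_time_h") in ("inf", None):
            c["doubling_time_h"] = np.inf
        for key in ("initial_position_um", "shape_sigma_um"):
            if key in c and c[key] is not None:
                c[key] = tuple(c[key])
        cells.append(CellSpec(**c))
    for key in ("field_size_px", "background_poly_coeffs", "phase_steps_rad"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SceneSpec(cells=cells, **d)


def read_interferogram_stacks(
    indir: str | Path, spec: SceneSpec | None = None
) -> list[InterferogramSet]:
    """Read interferograms written by :func:`write_qpi_scene`."""
    indir = Path(indir)
    if spec is None:
        spec = scene_spec_from_dict(
            yaml.safe_load((indir / "scene.yaml").read_text())
        )
    stacks = [
        tifffile.imread(indir / f"interferograms_step{k}.tif") for k in range(4)
    ]
    arr = np.stack(stacks, axis=1).astype(float)  # (T, 4, H, W)
    return [
        InterferogramSet(
            frames=arr[t],
            phase_steps_rad=np.asarray(spec.phase_steps_rad),
            wavelength_nm=spec.wavelength_nm,
            timestamp_min=t * spec.lapse_interval_min,
        )
        for t in range(arr.shape[0])
    ]


def default_qpi_scene(seed: int = 0, n_frames: int = 30) -> SceneSpec:
    """The reference synthetic QPI scene used by tests and examples.

    634 x 483 um field (512 x 390 px), 10-min lapse, three well-separated
    cells with masses spanning the few-hundred-pg range, 36-h doubling time,
    speeds around 20 um/h, a ~50-nm quadratic background aberration,
    5-nm per-frame offset jitter and 0.5-count sensor noise on 100-count
    fringes.
    """
    return SceneSpec(
        n_frames=n_frames,
        cells=[
            CellSpec(
                initial_mass_pg=300.0,
                doubling_time_h=36.0,
                initial_position_um=(150.0, 120.0),
                speed_um_per_h=20.0,
                persistence_time_min=60.0,
                shape_sigma_um=(9.0, 7.0),
            ),
            CellSpec(
                initial_mass_pg=600.0,
                doubling_time_h=36.0,
                initial_position_um=(450.0, 150.0),
                speed_um_per_h=15.0,
                persistence_time_min=60.0,
                shape_sigma_um=(10.0, 8.0),
            ),
            CellSpec(
                initial_mass_pg=900.0,
                doubling_time_h=36.0,
                initial_position_um=(300.0, 350.0),
                speed_um_per_h=25.0,
                persistence_time_min=60.0,
                shape_sigma_um=(11.0, 9.0),
            ),
        ],
        background_poly_coeffs=(0.02, 0.03, -0.02, 0.01, 0.015, -0.01),
        frame_offset_sd=0.005,
        intensity_noise_sd=0.5,
        rng_seed=seed,
    )
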