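"""Circular statistics for chemotaxis and incidence comparisons.

Trajectories are converted to circular data by the horizon rule: a cell's
direction is the bearing from its starting point to the point where its
path first reaches a fixed horizon distance (default 70 um).  Cells that
never reach the horizon are excluded — chemotaxis is undefined for
non-motile cells.

Uniformity of the resulting angles is assessed with the Rayleigh test
(mean resultant length R-bar, Z = n R-bar^2, series approximation for the
p-value), and a von-Mises-based 95% confidence interval is attached to
the mean direction.  Population differences in chemotactic displacement
use a two-level nested (hierarchical) ANOVA for unbalanced data —
populations over movies over cells — testing the population mean square
against the between-movie mean square.  A Pearson chi-square on a 2x2
table serves incidence comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from qpicell.segment import CellTrack


@dataclass
class DirectionalSample:
    """Horizon-crossing directions pooled from one or more movies."""

    angles_rad: np.ndarray
    horizon_um: float = 70.0
    n_total_cells: int = 0
    source_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.angles_rad = np.mod(np.asarray(self.angles_rad, dtype=float) + np.pi,
                                 2 * np.pi) - np.pi

    @property
    def n_reaching(self) -> int:
        return len(self.angles_rad)


@dataclass
class RayleighResult:
    n: int
    mean_resultant_length: float  # R-bar in [0, 1]
    mean_direction_rad: float
    z_statistic: float  # n * R-bar^2
    p_value: float
    ci95_halfwidth_rad: float


def horizon_directions(
    tracks: list[CellTrack] | list[np.ndarray],
    horizon_um: float = 70.0,
    source_ids: list | None = None,
) -> DirectionalSample:
    """Directions of cells on first reaching a horizon distance from start.

    For each trajectory, the first step whose endpoint lies at or beyond
    the horizon is interpolated linearly to the exact crossing of the
    horizon circle; the angle is the bearing of (crossing - start).
    Trajectories never reaching the horizon contribute no angle.
    Points after the first crossing are irrelevant.
    """
    angles = []
    kept_ids = []
    paths = [
        t.positions_um if isinstance(t, CellTrack) else np.asarray(t, dtype=float)
        for t in tracks
    ]
    for i, pos in enumerate(paths):
        if len(pos) < 2:
            continue
        rel = pos - pos[0]
        dist = np.linalg.norm(rel, axis=1)
        beyond = np.nonzero(dist >= horizon_um)[0]
        if beyond.size == 0:
            continue
        j = max(int(beyond[0]), 1)  # dist[0] = 0, so j >= 1 for any horizon > 0
        a, b = rel[j - 1], rel[j]
        # solve |a + s (b - a)| = horizon for s in (0, 1]
        d = b - a
        aa = d @ d
        bb = 2 * a @ d
        cc = a @ a - horizon_um ** 2
        if aa == 0:
            s = 1.0
        else:
            disc = max(bb * bb - 4 * aa * cc, 0.0)
            s = (-bb + np.sqrt(disc)) / (2 * aa)
        crossing = a + s * d
        angles.append(np.arctan2(crossing[1], crossing[0]))
        if source_ids is not None:
            kept_ids.append(source_ids[i])
    return DirectionalSample(
        angles_rad=np.asarray(angles),
        horizon_um=horizon_um,
        n_total_cells=len(paths),
        source_ids=kept_ids,
    )


def _vonmises_kappa(rbar: float) -> float:
    """ML von Mises concentration from R-bar (standard piecewise approximation)."""
    if rbar < 0.53:
        return 2 * rbar + rbar ** 3 + 5 * rbar ** 5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar ** 3 - 4 * rbar ** 2 + 3 * rbar)


def rayleigh_p_value(z: float | np.ndarray, n: int | np.ndarray) -> np.ndarray:
    """Series approximation of the Rayleigh test p-value, clipped to (0, 1]."""
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.exp(-z) * (
        1
        + (2 * z - z ** 2) / (4 * n)
        - (24 * z - 132 * z ** 2 + 76 * z ** 3 - 9 * z ** 4) / (288 * n ** 2)
    )
    return np.clip(p, np.finfo(float).tiny, 1.0)


def rayleigh_test(sample: DirectionalSample | np.ndarray) -> RayleighResult:
    """Rayleigh test of circular uniformity against unimodal clustering.

    R-bar = |sum exp(i theta)| / n, Z = n R-bar^2; the p-value uses the
    standard series approximation.  The 95% CI half-width of the mean
    direction comes from the circular standard error under a von Mises
    model, ``sigma = 1 / sqrt(n R-bar kappa)``.
    """
    angles = sample.angles_rad if isinstance(sample, DirectionalSample) else np.asarray(sample)
    n = len(angles)
    if n < 3:
        raise ValueError("Rayleigh test requires at least 3 angles")
    resultant = np.exp(1j * angles).sum()
    rbar = float(abs(resultant) / n)
    mean_dir = float(np.angle(resultant))
    z = n * rbar ** 2
    p = float(rayleigh_p_value(z, n))
    if rbar > 1e-12:
        kappa = _vonmises_kappa(min(rbar, 1 - 1e-12))
        sigma = 1.0 / np.sqrt(n * rbar * kappa)
        ci = float(np.arcsin(min(1.0, 1.959963984540054 * sigma)))
    else:
        ci = np.pi
    return RayleighResult(
        n=n,
        mean_resultant_length=rbar,
        mean_direction_rad=mean_dir,
        z_statistic=float(z),
        p_value=p,
        ci95_halfwidth_rad=ci,
    )


@dataclass
class NestedAnovaResult:
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    ms_population: float
    ms_movies: float


def nested_anova(values: list[list[np.ndarray]]) -> NestedAnovaResult:
    """Two-level nested ANOVA, unbalanced: populations / movies / cells.

    ``values[i][j]`` holds the per-cell responses of movie j in population
    i.  The population effect (fixed) is tested against the between-movie
    (random) stratum: F = MS_population / MS_movies(population), with
    unbalanced sums of squares

        SS_pop    = sum_i n_i (ybar_i - ybar)^2
        SS_movies = sum_ij n_ij (ybar_ij - ybar_i)^2

    Every population must contribute at least 2 movies, else the
    between-movie error stratum is undefined.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 populations")
    for i, movies in enumerate(values):
        if len(movies) < 2:
            raise ValueError(
                f"population {i} has a single movie: the between-movie "
                "(within-population) error stratum cannot be estimated"
            )
    all_vals = np.concatenate([np.concatenate(m) for m in values])
    grand = all_vals.mean()
    ss_pop = 0.0
    ss_mov = 0.0
    df_mov = 0
    for movies in values:
        pooled = np.concatenate(movies)
        n_i = len(pooled)
        ybar_i = pooled.mean()
        ss_pop += n_i * (ybar_i - grand) ** 2
        for mv in movies:
            mv = np.asarray(mv, dtype=float)
            ss_mov += len(mv) * (mv.mean() - ybar_i) ** 2
        df_mov += len(movies) - 1
    df_pop = len(values) - 1
    ms_pop = ss_pop / df_pop
    ms_mov = ss_mov / df_mov
    if ms_mov == 0:
        f = 0.0 if ms_pop == 0 else np.inf
    else:
        f = ms_pop / ms_mov
    p = float(stats.f.sf(f, df_pop, df_mov)) if np.isfinite(f) else 0.0
    return NestedAnovaResult(
        f_statistic=float(f),
        p_value=p,
        df_num=df_pop,
        df_den=df_mov,
        ms_population=float(ms_pop),
        ms_movies=float(ms_mov),
    )


def gradient_displacement_components(
    tracks: list[CellTrack] | list[np.ndarray],
    gradient_direction_rad: float,
) -> np.ndarray:
    """Per-cell mean step displacement component along the gradient (um).

    The sampling unit is the cell: each track contributes the mean of its
    step displacements projected on the gradient unit vector.
    """
    u = np.array([np.cos(gradient_direction_rad), np.sin(gradient_direction_rad)])
    out = []
    for t in tracks:
        pos = t.positions_um if isinstance(t, CellTrack) else np.asarray(t, dtype=float)
        if len(pos) < 2:
            continue
        steps = np.diff(pos, axis=0)
        out.append(float((steps @ u).mean()))
    return np.asarray(out)


def gradient_component_anova(
    grouped_tracks: dict[str, list[list]],
    gradient_direction_rad: float,
    reference: str | None = None,
) -> dict:
    """Nested ANOVA on gradient displacement components per population.

    ``grouped_tracks[population]`` is a list of movies, each a list of
    tracks (or raw (n, 2) position arrays).  Returns the omnibus test over
    all populations and, when a ``reference`` population is named, a
    pairwise contrast of every other population against it.
    """
    responses = {
        pop: [
            gradient_displacement_components(movie, gradient_direction_rad)
            for movie in movies
        ]
        for pop, movies in grouped_tracks.items()
    }
    result = {"omnibus": nested_anova(list(responses.values()))}
    if reference is not None:
        contrasts = {}
        for pop in responses:
            if pop == reference:
                continue
            contrasts[pop] = nested_anova([responses[reference], responses[pop]])
        result["contrasts"] = contrasts
    return result


def incidence_chi_square(
    a: int, b: int, c: int, d: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test on a 2x2 incidence table, df = 1.

    Table rows are groups, columns outcomes: ``[[a, b], [c, d]]``.
    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); optional Yates
    continuity correction.  All four margins must be positive.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined: zero margin in the 2x2 table")
    det = a * d - b * c
    if yates:
        det = max(abs(det) - n / 2.0, 0.0)
    chi2 = n * det ** 2 / np.prod([float(m) for m in margins])
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
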