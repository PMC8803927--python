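"""Growth fitting, speed conventions, protrusion/retraction and
dynamic polarity."""

import numpy as np
import pytest

from qpicell.metrics import (
    compute_speed,
    fit_growth,
    protrusion_retraction,
    summarize_movie,
)
from qpicell.phase import DryMassMap
from qpicell.segment import CellTrack, TrackPoint


def _track(masses, times_min, positions=None, track_id=1):
    positions = positions or [(0.0, 0.0)] * len(masses)
    return CellTrack(
        track_id=track_id,
        points=[
            TrackPoint(frame_index=i, label=1, centroid_um=tuple(p),
                       mass_pg=m, area_um2=100.0, t_min=t)
            for i, (m, t, p) in enumerate(zip(masses, times_min, positions))
        ],
    )


class TestFitGrowth:
    def test_exact_doubling_gives_exact_td(self):
        t_h = np.arange(25.0)
        masses = 500.0 * 2.0 ** (t_h / 24.0)
        fit = fit_growth(_track(masses, t_h * 60.0))
        assert fit.doubling_time_h == pytest.approx(24.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_mass_reported_non_growing(self):
        fit = fit_growth(_track([500.0] * 10, np.arange(10.0) * 60))
        assert fit.slope_per_h == pytest.approx(0.0, abs=1e-12)
        assert not fit.growing
        assert np.isinf(fit.doubling_time_h)

    def test_noisy_td_recovered_within_ten_percent(self):
        rng = np.random.default_rng(42)
        t_h = np.arange(60) * 10.0 / 60.0
        masses = 600.0 * 2.0 ** (t_h / 36.0) * np.exp(rng.normal(0, 0.02, 60))
        fit = fit_growth(_track(masses, t_h * 60.0))
        assert fit.doubling_time_h == pytest.approx(36.0, rel=0.10)

    def test_non_positive_points_excluded(self):
        masses = [100.0, -5.0, 110.0, 120.0]
        fit = fit_growth(_track(masses, np.arange(4.0) * 60))
        assert fit is not None and fit.n_points == 3

    def test_too_few_points_gives_no_fit(self):
        assert fit_growth(_track([100.0, 110.0], [0.0, 60.0])) is None


class TestComputeSpeed:
    def test_five_minute_rule_multiplied_by_twelve(self):
        track = _track([100.0] * 2, [0.0, 5.0], positions=[(0, 0), (1.0, 0)])
        out = compute_speed(track, lapse_interval_min=5.0)
        assert out["mean_um_per_h"] == pytest.approx(12.0, abs=1e-12)

    def test_static_object_zero_speed(self):
        track = _track([100.0] * 5, np.arange(5.0) * 5)
        assert compute_speed(track, 5.0)["mean_um_per_h"] == 0.0

    def test_gap_steps_excluded(self):
        track = CellTrack(track_id=1, points=[
            TrackPoint(0, 1, (0.0, 0.0), 100.0, 50.0, 0.0),
            TrackPoint(1, 1, (1.0, 0.0), 100.0, 50.0, 10.0),
            TrackPoint(3, 1, (9.0, 0.0), 100.0, 50.0, 30.0),  # gap
        ])
        out = compute_speed(track, 10.0)
        assert out["n_steps"] == 1
        assert out["mean_um_per_h"] == pytest.approx(6.0)


def _disk(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def brute_force_polarity(mask_t, mask_t1):
    """Protrusion/retraction centroid distance by explicit pixel enumeration."""
    p_pix = [(r, c) for r in range(mask_t.shape[0]) for c in range(mask_t.shape[1])
             if mask_t1[r, c] and not mask_t[r, c]]
    r_pix = [(r, c) for r in range(mask_t.shape[0]) for c in range(mask_t.shape[1])
             if mask_t[r, c] and not mask_t1[r, c]]
    if not p_pix or not r_pix:
        return None
    pc = np.mean(p_pix, axis=0)
    rc = np.mean(r_pix, axis=0)
    return float(np.hypot(*(pc - rc)))


class TestProtrusionRetraction:
    SHAPE = (80, 80)

    def _dm(self, value=1.0):
        return DryMassMap(np.full(self.SHAPE, value), pixel_size_um=1.0)

    def test_identical_masks_all_zero(self):
        mask = _disk(self.SHAPE, (40, 40), 15)
        rec = protrusion_retraction(mask, mask, self._dm(), self._dm(), 10.0)
        assert rec.protrusion_area_um2_per_min == 0.0
        assert rec.retraction_area_um2_per_min == 0.0
        assert rec.dynamic_polarity_um is None

    def test_uniform_expansion_has_no_retraction(self):
        m0 = _disk(self.SHAPE, (40, 40), 12)
        m1 = _disk(self.SHAPE, (40, 40), 16)
        rec = protrusion_retraction(m0, m1, self._dm(), self._dm(), 10.0)
        assert rec.retraction_area_um2_per_min == 0.0
        assert rec.protrusion_area_um2_per_min > 0

    def test_area_accounting_identity_exact(self):
        m0 = _disk(self.SHAPE, (40, 38), 14)
        m1 = _disk(self.SHAPE, (42, 44), 15)
        dt = 10.0
        rec = protrusion_retraction(m0, m1, self._dm(), self._dm(), dt)
        lhs = m0.sum() + rec.protrusion_area_um2_per_min * dt \
            - rec.retraction_area_um2_per_min * dt
        assert lhs == m1.sum()

    def test_translated_disk_polarity_matches_pixel_oracle(self):
        m0 = _disk(self.SHAPE, (40, 38), 20)
        m1 = _disk(self.SHAPE, (40, 42), 20)  # 4 px translation
        rec = protrusion_retraction(m0, m1, self._dm(), self._dm(), 10.0)
        oracle = brute_force_polarity(m0, m1)
        assert rec.dynamic_polarity_um == pytest.approx(oracle, rel=1e-9)

    def test_polarity_rotation_equivariant(self):
        m0 = _disk(self.SHAPE, (40, 36), 14) | _disk(self.SHAPE, (30, 40), 6)
        m1 = _disk(self.SHAPE, (40, 42), 15)
        rec = protrusion_retraction(m0, m1, self._dm(), self._dm(), 10.0)
        rec90 = protrusion_retraction(
            np.rot90(m0).copy(), np.rot90(m1).copy(), self._dm(), self._dm(), 10.0
        )
        assert rec90.dynamic_polarity_um == pytest.approx(
            rec.dynamic_polarity_um, abs=1e-9)

    def test_disjoint_masks_flagged_suspect(self):
        m0 = _disk(self.SHAPE, (20, 20), 8)
        m1 = _disk(self.SHAPE, (60, 60), 8)
        rec = protrusion_retraction(m0, m1, self._dm(), self._dm(), 10.0)
        assert rec.suspect

    def test_protrusion_mass_uses_new_frame_density(self):
        m0 = _disk(self.SHAPE, (40, 38), 10)
        m1 = _disk(self.SHAPE, (40, 44), 10)
        dm_t1 = self._dm(2.0)
        rec = protrusion_retraction(m0, m1, self._dm(1.0), dm_t1, 10.0)
        p_px = (m1 & ~m0).sum()
        assert rec.protrusion_mass_pg_per_min == pytest.approx(2.0 * p_px / 10.0)
        assert rec.max_pixel_mass_fg == pytest.approx(2000.0)


class TestSummaries:
    def test_single_cell_sem_zero(self):
        track = _track([500.0] * 5, np.arange(5.0) * 10)
        df = summarize_movie([track], [], [], 10.0)
        row = df[df.quantity == "mass"].iloc[0]
        assert row["mean"] == 500.0 and row["sem"] == 0.0 and row["n"] == 1

    def test_two_cell_sem_is_half_range(self):
        tracks = [
            _track([400.0] * 4, np.arange(4.0) * 10, track_id=1),
            _track([600.0] * 4, np.arange(4.0) * 10, track_id=2),
        ]
        df = summarize_movie(tracks, [], [], 10.0)
        row = df[df.quantity == "mass"].iloc[0]
        assert row["mean"] == 500.0 and row["sem"] == pytest.approx(100.0)

    def test_pooled_vs_per_cell_speed_weighting_differs(self):
        # one slow cell with many steps, one fast cell with few steps
        slow = _track([100.0] * 11, np.arange(11.0) * 10,
                      positions=[(i * 0.5, 0) for i in range(11)], track_id=1)
        fast = _track([100.0] * 3, np.arange(3.0) * 10,
                      positions=[(0, 0), (0, 5.0), (0, 10.0)], track_id=2)
        df = summarize_movie([slow, fast], [], [], 10.0).set_index("quantity")
        pooled = df.loc["speed_pooled_steps", "mean"]
        per_cell = df.loc["speed_per_cell", "mean"]
        # pooled: (10*3 + 2*30)/12 = 7.5; per cell: (3 + 30)/2 = 16.5
        assert pooled == pytest.approx(7.5)
        assert per_cell == pytest.approx(16.5)
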