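import numpy as np
import pytest

from rimpet import (
    Contour2D,
    area_fraction,
    call_brl,
    cell_density,
    cortical_lesion_rate,
    demyelination_score,
    interedge_rim_width,
    remyelination_score,
)
from rimpet.errors import (
    ContourError,
    GeometryError,
    NumericDomainError,
    SamplingError,
)
from rimpet.histology import RimWidthProfile, resample_arc_length


def circle(radius, center=(0.0, 0.0), n=360):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour2D(
        np.column_stack([center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)])
    )


def square(half_side, center=(0.0, 0.0)):
    h = half_side
    return Contour2D(
        np.array(
            [
                [center[0] - h, center[1] - h],
                [center[0] + h, center[1] - h],
                [center[0] + h, center[1] + h],
                [center[0] - h, center[1] + h],
            ]
        )
    )


def brute_force_min_distance(point, polygon_points):
    """Exhaustive point-to-segment oracle over every polygon edge."""
    p = np.asarray(point, float)
    pts = np.asarray(polygon_points, float)
    best = np.inf
    for a, b in zip(pts, np.roll(pts, -1, axis=0)):
        ab = b - a
        t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        best = min(best, float(np.linalg.norm(p - (a + t * ab))))
    return best


class TestInteredgeWidth:
    def test_concentric_circles_recover_annulus_width(self):
        """Radii 3000/1500 um: every sampled distance is 1500 um within the
        sub-percent polygonal resampling tolerance."""
        prof = interedge_rim_width(circle(3000), circle(1500), step=100)
        assert np.all(np.abs(prof.distances - 1500) <= 15)  # <= 1%
        assert prof.mean_width == pytest.approx(1500, rel=0.01)

    def test_identical_contours_give_zero_width(self):
        c = circle(2000, n=90)
        prof = interedge_rim_width(c, Contour2D(c.points.copy()), step=100)
        assert prof.mean_width == pytest.approx(0.0, abs=1e-9)
        assert np.all(prof.distances <= 1e-9)

    def test_concentric_squares_corner_geometry(self):
        """Half-side difference 500 um: edge samples measure 500, corner
        samples up to 500*sqrt(2); the mean lies between."""
        prof = interedge_rim_width(square(2000), square(1500), step=100)
        assert 500.0 <= prof.mean_width <= 500.0 * np.sqrt(2)
        assert prof.distances.min() == pytest.approx(500.0, abs=1e-9)

    def test_sampled_distances_match_brute_force_oracle(self):
        """Point-to-segment distances agree with the exhaustive oracle to
        1e-6 um on small polygons."""
        rng = np.random.default_rng(4)
        outer = square(2000)
        th = np.sort(rng.uniform(0, 2 * np.pi, size=12))
        r = rng.uniform(400, 900, size=12)
        inner = Contour2D(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        prof = interedge_rim_width(outer, inner, step=250)
        for pt, d in zip(prof.sample_points, prof.distances):
            assert d == pytest.approx(brute_force_min_distance(pt, inner.points), abs=1e-6)

    def test_rotation_invariance_of_mean_width(self):
        base = interedge_rim_width(circle(3000), circle(1800), step=100).mean_width
        for angle in (0.3, 1.1, 2.6):
            rot = np.array(
                [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
            )
            prof = interedge_rim_width(
                Contour2D(circle(3000).points @ rot.T),
                Contour2D(circle(1800).points @ rot.T),
                step=100,
            )
            assert prof.mean_width == pytest.approx(base, rel=0.01)

    def test_inner_outside_outer_rejected(self):
        with pytest.raises(GeometryError):
            interedge_rim_width(circle(1000), circle(1500), step=100)

    def test_degenerate_contour_rejected(self):
        with pytest.raises(ContourError):
            Contour2D(np.array([[0, 0], [1, 1]]))

    def test_invalid_samples_dropped_from_mean(self):
        outer, inner = circle(3000, n=36), circle(1500, n=36)
        prof_all = interedge_rim_width(outer, inner, step=1000)
        mask = np.ones(prof_all.n_samples, bool)
        mask[:3] = False
        prof = interedge_rim_width(outer, inner, step=1000, valid_mask=mask)
        assert prof.n_samples == prof_all.n_samples
        assert prof.mean_width == pytest.approx(prof_all.distances[mask].mean())

    def test_resampling_interval_is_uniform(self):
        pts = resample_arc_length(circle(3000), 100.0)
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert np.all(np.abs(gaps - 100.0) < 1.0)  # chord vs arc on 1-deg polygon


class TestBrlCall:
    def _profile(self, width):
        d = np.full(40, float(width))
        return RimWidthProfile(np.zeros((40, 2)), d, float(width), 40)

    def test_reported_brl_width_is_called_positive(self):
        assert call_brl(self._profile(1761), "mixed", 1000) is True

    def test_reported_mixed_lesion_width_is_negative(self):
        assert call_brl(self._profile(344), "mixed", 1000) is False

    def test_non_mixed_lesion_never_brl(self):
        assert call_brl(self._profile(2000), "active", 1000) is False
        assert call_brl(self._profile(2000), "inactive", 1000) is False

    def test_switch_exactly_at_min_width(self):
        assert call_brl(self._profile(999.99), "mixed", 1000) is False
        assert call_brl(self._profile(1000.0), "mixed", 1000) is True

    def test_alternative_summaries(self):
        d = np.concatenate([np.full(30, 1500.0), np.full(10, 200.0)])
        prof = RimWidthProfile(np.zeros((40, 2)), d, float(d.mean()), 40)
        assert call_brl(prof, "mixed", 1000, summary="median") is True
        assert call_brl(prof, "mixed", 1000, summary="fraction_above") is True


class TestScores:
    def _masks(self, frac, n=100):
        lesion = np.ones((n, n), bool)
        remy = np.zeros((n, n), bool)
        remy.reshape(-1)[: int(round(frac * n * n))] = True
        return lesion, remy

    @pytest.mark.parametrize(
        "frac,score",
        [(0.0, 0), (0.10, 0), (0.1001, 1), (0.50, 1), (0.60, 2), (0.985, 2), (0.99, 3), (1.0, 3)],
    )
    def test_remyelination_bins(self, frac, score):
        assert remyelination_score(*self._masks(frac)) == score

    def test_remyelination_empty_lesion_rejected(self):
        with pytest.raises(NumericDomainError):
            remyelination_score(np.zeros((4, 4), bool), np.zeros((4, 4), bool))

    @pytest.mark.parametrize(
        "frac,score",
        [(0.0, 0), (0.1, 1), (0.20, 1), (0.201, 2), (0.40, 2), (0.50, 3), (0.60, 3), (0.80, 4), (1.0, 5)],
    )
    def test_demyelination_bins(self, frac, score):
        assert demyelination_score(frac) == score

    def test_demyelination_out_of_range_rejected(self):
        with pytest.raises(NumericDomainError):
            demyelination_score(1.2)

    def test_scores_are_monotone_step_functions(self):
        fr = np.arange(0.0, 1.0005, 0.001)
        demy = [demyelination_score(f) for f in np.clip(fr, 0, 1)]
        assert np.all(np.diff(demy) >= 0)
        remy = [remyelination_score(*self._masks(f, n=200)) for f in fr[::10]]
        assert np.all(np.diff(remy) >= 0)


class TestCellDensity:
    def test_poisson_field_recovers_density(self):
        """Homogeneous Poisson points at 500 /mm^2: estimate within 3 s.e."""
        rng = np.random.default_rng(11)
        lam = 500.0
        side_um = 5000.0
        n = rng.poisson(lam * (side_um / 1000.0) ** 2)
        pts = rng.uniform(0, side_um, size=(n, 2))
        mask = np.ones((250, 250), bool)  # 20 um pixels
        res = cell_density(pts, mask, 20.0, n_fields=10, field_size=500.0, seed=3)
        n_expected_per_field = lam * 0.25
        se = np.sqrt(n_expected_per_field / 10) / 0.25
        assert abs(res.density - lam) <= 3 * se

    def test_zero_points_give_zero_density(self):
        res = cell_density(np.empty((0, 2)), np.ones((100, 100), bool), 20.0, seed=0)
        assert res.density == 0.0

    def test_region_smaller_than_field_rejected(self):
        with pytest.raises(SamplingError):
            cell_density(np.empty((0, 2)), np.ones((10, 10), bool), 20.0,
                         field_size=500.0, seed=0)

    def test_field_placement_is_seeded(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 2000, size=(400, 2))
        mask = np.ones((100, 100), bool)
        a = cell_density(pts, mask, 20.0, seed=9)
        b = cell_density(pts, mask, 20.0, seed=9)
        assert a.density == b.density


class TestRatesAndFractions:
    @pytest.mark.parametrize("counts,blocks,rate", [([2, 2, 2], 3, 2.0), ([], 5, 0.0), ([3, 4], 2, 3.5)])
    def test_cortical_lesion_rate(self, counts, blocks, rate):
        assert cortical_lesion_rate(counts, blocks) == rate

    def test_zero_blocks_rejected(self):
        with pytest.raises(NumericDomainError):
            cortical_lesion_rate([1], 0)

    def test_area_fraction_cases(self):
        total = np.ones((10, 10), bool)
        assert area_fraction(total, total) == 1.0
        quarter = np.zeros((10, 10), bool)
        quarter[:5, :5] = True
        assert area_fraction(quarter, total) == 0.25
        assert area_fraction(np.zeros((10, 10), bool), total) == 0.0

    def test_empty_total_rejected(self):
        with pytest.raises(NumericDomainError):
            area_fraction(np.zeros((4, 4), bool), np.zeros((4, 4), bool))
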