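"""Random demographic map generation: boundaries, segments, priors, transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from mapnn import maps
from mapnn.maps import (MapPrior, ViabilityFit, apply_dihedral_transform,
                        apply_habitat_mask, assign_segments, calibrate_viability,
                        dihedral_transform_array, draw_channel, draw_map,
                        draw_segment_values, fit_boundary_polynomial, load_map,
                        save_map, viability_correct)

from conftest import make_flat_map

SIGMA_PRIOR = MapPrior(0.73, 3.08, "dispersal")
K_PRIOR = MapPrior(4.0, 40.0, "density")


class TestBoundaryPolynomial:
    @pytest.mark.parametrize("points,expected", [
        ([(0, 0), (1, 1)], [1.0, 0.0]),                 # the line y = x
        ([(0, 0), (0.5, 1), (1, 0)], [-4.0, 4.0, 0.0]),  # hand-solved quadratic
    ])
    def test_interpolates_exactly(self, points, expected):
        coeffs = fit_boundary_polynomial(points)
        assert np.allclose(coeffs, expected)
        for x, y in points:
            assert np.polyval(coeffs, x) == pytest.approx(y, abs=1e-12)

    def test_duplicate_x_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            fit_boundary_polynomial([(0.3, 0), (0.3, 1)])


class TestAssignSegments:
    def test_horizontal_line_splits_in_half(self):
        labels = assign_segments(50, np.array([25.0]))
        counts = np.bincount(labels.ravel())
        assert sorted(counts) == [1250, 1250]

    def test_curve_outside_habitat_gives_one_segment(self):
        labels = assign_segments(20, np.array([-5.0]))
        assert len(np.unique(labels)) == 1

    def test_components_match_flood_fill_oracle(self, rng):
        def flood_fill_components(binary):
            seen = np.zeros_like(binary, dtype=bool)
            n = 0
            h, w = binary.shape
            for sy in range(h):
                for sx in range(w):
                    if seen[sy, sx]:
                        continue
                    n += 1
                    stack = [(sy, sx)]
                    seen[sy, sx] = True
                    while stack:
                        y, x = stack.pop()
                        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                            yy, xx = y + dy, x + dx
                            if (0 <= yy < h and 0 <= xx < w and not seen[yy, xx]
                                    and binary[yy, xx] == binary[y, x]):
                                seen[yy, xx] = True
                                stack.append((yy, xx))
            return n

        w = 20
        for _ in range(20):
            deg = rng.integers(1, 4)
            pts = rng.uniform(0, w, size=(deg + 1, 2))
            try:
                coeffs = fit_boundary_polynomial(pts)
            except ValueError:
                continue
            labels = assign_segments(w, coeffs, max_segments=100)
            xc = np.arange(w) + 0.5
            below = (np.arange(w) + 0.5)[:, None] < np.polyval(coeffs, xc)[None, :]
            assert len(np.unique(labels)) == flood_fill_components(below)

    def test_segment_cap_respected(self, rng):
        for _ in range(50):
            ch = draw_channel(SIGMA_PRIOR, 3, rng, width=20)
            assert ch.n_segments <= 3
            assert len(np.unique(ch.values)) <= 3


class TestSegmentValues:
    def test_flat_single_log_uniform(self, rng):
        vals = [draw_segment_values(K_PRIOR, 1, rng)[0] for _ in range(2000)]
        assert all(4.0 <= v <= 40.0 for v in vals)
        # log of flat values uniform on (log pmin, log pmax)
        u = (np.log(vals) - np.log(4.0)) / (np.log(40.0) - np.log(4.0))
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_two_segments_span_r(self, rng):
        for _ in range(200):
            lo, hi = sorted(draw_segment_values(K_PRIOR, 2, rng))
            r = hi - lo
            assert K_PRIOR.p_min <= lo and hi <= K_PRIOR.p_max
            assert K_PRIOR.p_min <= r <= K_PRIOR.p_max - K_PRIOR.p_min

    def test_third_value_strictly_between(self, rng):
        for _ in range(200):
            v = draw_segment_values(K_PRIOR, 3, rng)
            lo, hi = min(v[:2]), max(v[:2])
            assert lo < v[2] < hi


class TestDrawChannel:
    def test_flat_fraction_matches_degree_distribution(self):
        rng = np.random.default_rng(7)
        flat = sum(draw_channel(SIGMA_PRIOR, 3, rng, width=16).degree == 0
                   for _ in range(10_000))
        assert flat / 10_000 == pytest.approx(0.25, abs=0.01)

    def test_values_always_within_prior(self, rng):
        for _ in range(1000):
            ch = draw_channel(K_PRIOR, 3, rng, width=10)
            assert ch.values.min() >= K_PRIOR.p_min
            assert ch.values.max() <= K_PRIOR.p_max

    def test_forced_flat_when_single_segment(self, rng):
        ch = draw_channel(K_PRIOR, 1, rng, width=12)
        assert ch.degree == 0
        assert len(np.unique(ch.values)) == 1

    def test_log_uniform_flat_values_ks(self):
        rng = np.random.default_rng(13)
        vals = []
        while len(vals) < 10_000:
            ch = draw_channel(K_PRIOR, 3, rng, width=4)
            if ch.degree == 0:
                vals.append(ch.values[0, 0])
        u = (np.log(vals) - np.log(4.0)) / (np.log(40.0) - np.log(4.0))
        assert stats.kstest(u, "uniform").pvalue > 0.01


class TestDihedral:
    def test_identity_leaves_map_unchanged(self, rng):
        m = draw_map(SIGMA_PRIOR, K_PRIOR, rng, width=10, transform=False)
        out = apply_dihedral_transform(m, rng, element=0)
        assert np.array_equal(out.dispersal.values, m.dispersal.values)
        assert np.array_equal(out.density.values, m.density.values)

    def test_two_quarter_turns_equal_half_turn(self, rng):
        a = rng.normal(size=(6, 6))
        once = dihedral_transform_array(dihedral_transform_array(a, 1), 1)
        assert np.array_equal(once, dihedral_transform_array(a, 2))

    def test_value_multiset_and_mean_preserved(self, rng):
        m = draw_map(SIGMA_PRIOR, K_PRIOR, rng, width=9, transform=False)
        for k in range(8):
            out = apply_dihedral_transform(m, rng, element=k)
            for ch_in, ch_out in ((m.dispersal, out.dispersal), (m.density, out.density)):
                assert np.array_equal(np.sort(ch_in.values.ravel()),
                                      np.sort(ch_out.values.ravel()))
                assert ch_out.values.mean() == pytest.approx(ch_in.values.mean())

    @settings(max_examples=30, derandomize=True)
    @given(arr=hnp.arrays(np.float64, (5, 5),
                          elements=st.floats(0.1, 100, allow_nan=False)),
           a=st.integers(0, 7), b=st.integers(0, 7))
    def test_group_closure_preserves_multiset(self, arr, a, b):
        once = dihedral_transform_array(dihedral_transform_array(arr, a), b)
        assert sorted(once.ravel()) == sorted(arr.ravel())
        # composing two elements stays inside the 8-element group
        matches = sum(np.array_equal(once, dihedral_transform_array(arr, k))
                      for k in range(8))
        assert matches >= 1

    def test_channels_and_mask_move_together(self, rng):
        mask = np.zeros((8, 8), dtype=bool)
        mask[:, :5] = True
        m = apply_habitat_mask(draw_map(SIGMA_PRIOR, K_PRIOR, rng, width=8,
                                        transform=False), mask)
        out = apply_dihedral_transform(m, rng, element=3)
        # masked cells stay zero-valued after the transform
        assert np.all(out.dispersal.values[~out.habitat_mask] == 0)
        assert out.habitat_mask.sum() == mask.sum()


class TestViability:
    def test_threshold_and_boost(self, rng):
        fit = ViabilityFit(slope=0.5, intercept=np.log(0.1), boost=1.25)
        m = make_flat_map(6, sigma=0.2, K=16.0)  # sigma_min = 0.1*sqrt(16) = 0.4 > 0.2
        rng_sigma = np.random.default_rng(0)     # first channel draw -> sigma boost
        out = viability_correct(m, fit, rng_sigma)
        boosted = out.dispersal.values if out.dispersal.values[0, 0] != 0.2 else out.density.values
        if out.dispersal.values[0, 0] != 0.2:
            assert out.dispersal.values[0, 0] == pytest.approx(0.4 * 1.25)
            assert np.all(out.density.values == 16.0)
        else:
            # K-boost branch: K raised so that sigma_min(K') = sigma, then *1.25
            expected = np.exp((np.log(0.2) - np.log(0.1)) / 0.5) * 1.25
            assert out.density.values[0, 0] == pytest.approx(expected)
        assert np.all(boosted >= 0.2)

    def test_cell_above_threshold_unchanged(self, rng):
        fit = ViabilityFit(slope=0.5, intercept=np.log(0.1))
        m = make_flat_map(5, sigma=2.0, K=9.0)   # threshold 0.3 < 2.0
        out = viability_correct(m, fit, rng)
        assert np.array_equal(out.dispersal.values, m.dispersal.values)
        assert np.array_equal(out.density.values, m.density.values)

    def test_correction_is_monotone(self, rng):
        fit = ViabilityFit(slope=1.0, intercept=0.0)
        m = draw_map(SIGMA_PRIOR, K_PRIOR, rng, width=8)
        out = viability_correct(m, fit, rng)
        assert (np.all(out.dispersal.values >= m.dispersal.values - 1e-12)
                or np.all(out.density.values >= m.density.values - 1e-12))

    def test_calibration_recovers_power_law(self):
        # ground truth: sigma_min = 0.3 * K^0.5
        stable = lambda K, s: s >= 0.3 * np.sqrt(K)
        fit = calibrate_viability([1, 4, 9, 16, 25], stable, (1e-3, 10.0), tol=1e-4)
        assert fit.slope == pytest.approx(0.5, abs=0.01)
        assert np.exp(fit.intercept) == pytest.approx(0.3, rel=0.02)


class TestHabitatMask:
    def test_all_true_mask_keeps_values(self, rng):
        m = draw_map(SIGMA_PRIOR, K_PRIOR, rng, width=6, transform=False)
        out = apply_habitat_mask(m, np.ones((6, 6), dtype=bool))
        assert np.array_equal(out.dispersal.values, m.dispersal.values)

    def test_fraction_of_cells_survive(self, rng):
        w = 20
        mask = rng.random((w, w)) < 0.2193
        m = draw_map(SIGMA_PRIOR, K_PRIOR, rng, width=w, transform=False)
        out = apply_habitat_mask(m, mask)
        assert (out.density.values > 0).sum() == mask.sum()
        assert np.all(out.dispersal.values[~mask] == 0)

    def test_empty_mask_rejected(self, rng):
        m = draw_map(SIGMA_PRIOR, K_PRIOR, rng, width=4, transform=False)
        with pytest.raises(ValueError, match="no habitat"):
            apply_habitat_mask(m, np.zeros((4, 4), dtype=bool))


class TestSerialization:
    def test_csv_round_trip(self, rng, tmp_path):
        mask = np.ones((7, 7), dtype=bool)
        mask[0, :3] = False
        m = apply_habitat_mask(draw_map(SIGMA_PRIOR, K_PRIOR, rng, width=7), mask)
        save_map(m, tmp_path, prefix="t", png=True)
        back = load_map(tmp_path, prefix="t")
        assert np.allclose(back.dispersal.values, m.dispersal.values)
        assert np.allclose(back.density.values, m.density.values)
        assert np.array_equal(back.habitat_mask, m.habitat_mask)
        assert (tmp_path / "t.png").exists()

    def test_mask_round_trip_png_and_csv(self, rng, tmp_path):
        from PIL import Image

        from mapnn.maps import read_mask
        mask = rng.random((9, 9)) < 0.4
        mask[0, 0] = True   # guard against the degenerate all-false draw
        maps.write_grid_csv(mask.astype(int), tmp_path / "m.csv")
        assert np.array_equal(read_mask(tmp_path / "m.csv"), mask)
        Image.fromarray((mask[::-1] * 255).astype(np.uint8)).save(tmp_path / "m.png")
        assert np.array_equal(read_mask(tmp_path / "m.png"), mask)

    def test_csv_rows_written_north_first(self, tmp_path):
        vals = np.arange(9, dtype=float).reshape(3, 3)  # row 2 is the northern row
        maps.write_grid_csv(vals, tmp_path / "g.csv")
        first_line = (tmp_path / "g.csv").read_text().splitlines()[0]
        assert [float(v) for v in first_line.split(",")] == [6.0, 7.0, 8.0]
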