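"""Sampling grid construction, segment clipping, and density fields."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurodensity import (
    AABB,
    DensityField,
    GridSpec,
    blur,
    clip_length,
    combine,
    load_field,
    make_grid,
    neuron_density,
    raw_length_grid,
    save_field,
    threshold_mask,
    total_length,
)
from neurodensity import fixtures as fx
from neurodensity.density import gaussian_kernel
from tests.conftest import random_morphologies


def mc_clip_estimate(p1, p2, box, n=100_000, seed=0):
    """Monte-Carlo oracle: fraction of uniform samples inside × length."""
    rng = np.random.default_rng(seed)
    t = rng.random(n)
    pts = np.asarray(p1) + t[:, None] * (np.asarray(p2) - np.asarray(p1))
    inside = np.all((pts >= box.lower) & (pts <= box.upper), axis=1)
    return inside.mean() * np.linalg.norm(np.asarray(p2) - np.asarray(p1))


def interval_clip_oracle(p1, p2, box):
    """Independent re-derivation: clip endpoints, then measure the chord."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = p2 - p1
    lo, hi = 0.0, 1.0
    for j in range(3):
        if d[j] == 0.0:
            if not (box.lower[j] <= p1[j] <= box.upper[j]):
                return 0.0
        else:
            ts = sorted(((box.lower[j] - p1[j]) / d[j], (box.upper[j] - p1[j]) / d[j]))
            lo, hi = max(lo, ts[0]), min(hi, ts[1])
    if hi <= lo:
        return 0.0
    return float(np.linalg.norm((p1 + hi * d) - (p1 + lo * d)))


class TestMakeGrid:
    def test_ceiling_formula(self):
        g = make_grid(AABB([0, 0, 0], [120, 100, 50]), [50, 50, 50])
        assert g.counts == (3, 2, 1)

    def test_default_cuboid_50(self):
        g = make_grid(AABB([0, 0, 0], [100, 100, 100]), 50.0)
        assert g.counts == (2, 2, 2)

    def test_point_cell_degenerates_to_single_voxel(self):
        g = make_grid(AABB([5, 5, 5], [5, 5, 5]), [50, 50, 50])
        assert g.counts == (1, 1, 1)

    def test_random_extents_match_ceiling(self, rng):
        for _ in range(100):
            lower = rng.normal(scale=100, size=3)
            extent = rng.uniform(0, 500, size=3)
            l = rng.uniform(1, 100, size=3)
            g = make_grid(AABB(lower, lower + extent), l)
            expected = tuple(max(1, math.ceil(e / s)) for e, s in zip(extent, l))
            assert g.counts == expected

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            make_grid(AABB([0, 0, 0], [1, 1, 1]), [0, 1, 1])


class TestClipLength:
    box = AABB([0, 0, 0], [10, 10, 10])

    def test_fully_inside(self):
        assert clip_length([0, 0, 0], [10, 0, 0], self.box) == pytest.approx(10.0)

    def test_symmetric_overhang(self):
        assert clip_length([-5, 5, 5], [15, 5, 5], self.box) == pytest.approx(10.0)

    def test_fully_outside(self):
        assert clip_length([20, 20, 20], [30, 30, 30], self.box) == 0.0

    def test_zero_length_segment(self):
        assert clip_length([5, 5, 5], [5, 5, 5], self.box) == 0.0

    def test_against_monte_carlo_and_interval_oracles(self, rng):
        for i in range(50):
            p1 = rng.uniform(-20, 30, 3)
            p2 = rng.uniform(-20, 30, 3)
            lo = rng.uniform(-10, 10, 3)
            box = AABB(lo, lo + rng.uniform(1, 30, 3))
            analytic = clip_length(p1, p2, box)
            assert analytic == pytest.approx(
                interval_clip_oracle(p1, p2, box), abs=1e-12, rel=1e-12
            )
            mc = mc_clip_estimate(p1, p2, box, n=100_000, seed=i)
            assert analytic == pytest.approx(
                mc, abs=max(1e-2 * np.linalg.norm(p2 - p1), 1e-9)
            )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=6, max_size=6),
           st.lists(st.floats(-20, 20), min_size=3, max_size=3),
           st.lists(st.floats(1, 40), min_size=3, max_size=3))
    def test_symmetry_and_box_monotonicity(self, seg, lo, ext):
        p1, p2 = np.array(seg[:3]), np.array(seg[3:])
        small = AABB(np.array(lo), np.array(lo) + np.array(ext))
        big = AABB(small.lower - 5.0, small.upper + 5.0)
        assert clip_length(p1, p2, small) == pytest.approx(
            clip_length(p2, p1, small), rel=1e-12, abs=1e-12
        )
        assert clip_length(p1, p2, small) <= clip_length(p1, p2, big) + 1e-12


class TestNeuronDensity:
    def test_cable_in_single_voxel_total_length_mode(self):
        cable = fx.make_cable(100, 11)
        grid = GridSpec([-50, -10, -50], [200, 200, 200], (1, 1, 1))
        f = neuron_density(cable, grid)
        assert f.values[0, 0, 0] == pytest.approx(1.0, abs=1e-12)
        assert f.stage == "per_neuron"

    def test_voxel_volume_mode(self):
        cable = fx.make_cable(100, 11)
        grid = GridSpec([-25, -10, -25], [50, 120, 50], (1, 1, 1))
        f = neuron_density(cable, grid, norm_mode="voxel_volume")
        assert f.values[0, 0, 0] == pytest.approx(100 / (50 * 120 * 50), rel=1e-12)

    def test_conservation_against_clipped_total_length(self, rng):
        for m in random_morphologies(5, rng):
            from neurodensity import bounding_box

            box = bounding_box(m)
            # grid deliberately smaller than the cell: clipping matters
            shrink = AABB(box.lower + 0.25 * box.extent, box.upper - 0.25 * box.extent)
            grid = make_grid(shrink, rng.uniform(5, 40, 3))
            raw = raw_length_grid(m, grid)
            child, parent, _ = m.edge_arrays()
            in_grid = sum(
                clip_length(p, c, grid.outer_box) for p, c in zip(parent, child)
            )
            assert raw.sum() == pytest.approx(in_grid, rel=1e-9)

    def test_fully_contained_cell_sums_to_one(self, rng):
        for m in random_morphologies(3, rng):
            from neurodensity import bounding_box

            box = bounding_box(m)
            pad = AABB(box.lower - 1, box.upper + 1)
            f = neuron_density(m, make_grid(pad, 25.0))
            assert f.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_grid_refinement_consistency(self):
        m = fx.make_random_tree(21, depth=3)
        from neurodensity import bounding_box

        box = bounding_box(m)
        l = np.array([20.0, 20.0, 20.0])
        coarse = make_grid(box, l)
        fine = GridSpec(coarse.lower, l / 2, tuple(2 * n for n in coarse.counts))
        raw_c = raw_length_grid(m, coarse)
        raw_f = raw_length_grid(m, fine)
        pooled = raw_f.reshape(
            coarse.counts[0], 2, coarse.counts[1], 2, coarse.counts[2], 2
        ).sum(axis=(1, 3, 5))
        np.testing.assert_allclose(pooled, raw_c, rtol=1e-9, atol=1e-9)

    def test_boundary_plane_segment_goes_to_higher_voxel(self):
        # cable exactly in the internal x-plane of a 2x1x1 grid
        grid = GridSpec([-10, 0, -5], [10, 100, 10], (2, 1, 1))
        cable = fx.make_cable(50, 6)  # along +y at x=0, the internal plane
        raw = raw_length_grid(cable, grid)
        assert raw[0, 0, 0] == 0.0
        assert raw[1, 0, 0] == pytest.approx(50.0)


class TestCombine:
    def _field(self, values):
        grid = GridSpec([0, 0, 0], [1, 1, 1], values.shape)
        return DensityField(grid, values, stage="per_neuron")

    def test_single_field_rescaled_to_max_one(self, rng):
        vals = rng.random((3, 4, 2))
        out = combine([self._field(vals)])
        assert out.values.max() == 1.0
        np.testing.assert_allclose(out.values, vals / vals.max())

    def test_scale_invariance_of_duplicates(self, rng):
        vals = rng.random((3, 3, 3))
        one = combine([self._field(vals)])
        two = combine([self._field(vals), self._field(vals.copy())])
        np.testing.assert_array_equal(one.values, two.values)

    def test_argmax_preserved_and_stage_normalized(self, rng):
        fields = [self._field(rng.random((4, 4, 4))) for _ in range(3)]
        total = sum(f.values for f in fields)
        out = combine(fields)
        assert np.argmax(out.values) == np.argmax(total)
        assert out.values.max() == 1.0
        assert out.stage == "normalized"
        assert np.all((out.values >= 0) & (out.values <= 1))

    def test_mismatched_grids_rejected(self, rng):
        a = self._field(rng.random((2, 2, 2)))
        b = DensityField(
            GridSpec([0, 0, 0], [2, 2, 2], (2, 2, 2)), rng.random((2, 2, 2))
        )
        with pytest.raises(ValueError):
            combine([a, b])

    def test_all_zero_fields_stay_zero(self):
        out = combine([self._field(np.zeros((2, 2, 2)))])
        assert np.all(out.values == 0)


class TestThresholdAndBlur:
    def _normalized(self, values):
        grid = GridSpec([0, 0, 0], [1, 1, 1], values.shape)
        return DensityField(grid, values, stage="normalized")

    def test_zero_pct_keeps_positive_voxels(self):
        f = self._normalized(np.array([[[0.0, 0.2], [1.0, 0.0]]]))
        np.testing.assert_array_equal(threshold_mask(f, 0.0), f.values > 0)

    def test_hundred_pct_keeps_nothing(self):
        f = self._normalized(np.array([[[0.5, 1.0]]]))
        assert not threshold_mask(f, 100.0).any()

    def test_fifty_pct_on_two_voxel_field(self):
        f = self._normalized(np.array([[[1.0, 0.25]]]))
        assert threshold_mask(f, 50.0).sum() == 1

    def test_delta_kernel_is_identity(self, rng):
        f = self._normalized(rng.random((4, 5, 6)))
        delta = np.zeros((3, 3, 3)); delta[1, 1, 1] = 1.0
        np.testing.assert_allclose(blur(f, delta).values, f.values, atol=1e-15)

    def test_mass_conserved_for_interior_support(self, rng):
        vals = np.zeros((9, 9, 9))
        vals[3:6, 3:6, 3:6] = rng.random((3, 3, 3))
        f = self._normalized(vals / vals.max())
        out = blur(f)  # default 5^3 Gaussian, sum 1
        assert out.values.sum() == pytest.approx(f.values.sum(), rel=1e-9)

    def test_uniform_field_is_fixed_point(self):
        f = self._normalized(np.full((4, 4, 4), 1.0))
        np.testing.assert_allclose(blur(f).values, f.values, rtol=1e-12)

    def test_even_kernel_rejected(self):
        f = self._normalized(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            blur(f, np.ones((2, 3, 3)))

    def test_default_kernel_normalized(self):
        k = gaussian_kernel()
        assert k.shape == (5, 5, 5)
        assert k.sum() == pytest.approx(1.0, abs=1e-12)


class TestFieldIO:
    def test_round_trip(self, tmp_path, rng):
        grid = GridSpec([1.5, -2.0, 0.0], [10, 20, 30], (3, 2, 4))
        f = DensityField(grid, rng.random((3, 2, 4)), stage="normalized",
                         norm_mode="voxel_volume")
        save_field(f, tmp_path / "field")
        g = load_field(tmp_path / "field")
        np.testing.assert_array_equal(g.values, f.values)
        np.testing.assert_array_equal(g.grid.lower, grid.lower)
        assert g.grid.counts == grid.counts
        assert g.stage == "normalized" and g.norm_mode == "voxel_volume"
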