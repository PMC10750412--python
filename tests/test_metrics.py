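"""Overlap, distance and asymmetry metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from craniofill.metrics import (
    cvai_diagonals,
    cvai_indices,
    directed_hausdorff,
    hd_unit_range,
    overlap_counts,
    sdi,
    select_measurement_plane,
    symmetric_hausdorff,
)
from craniofill.volume import BinaryVolume

from conftest import random_binary_volume


def _vol(points, shape=(6, 6, 6)):
    v = np.zeros(shape, dtype=np.uint8)
    for p in points:
        v[p] = 1
    return BinaryVolume(v)


class TestOverlapAndSdi:
    def test_identical_sets(self, rng):
        vol = random_binary_volume(rng)
        c = overlap_counts(vol, vol)
        assert (c.n_tp, c.n_fp, c.n_fn) == (vol.ones_count(), 0, 0)
        assert sdi(vol, vol) == 100.0

    def test_disjoint_sets(self):
        P = _vol([(0, 0, 0), (1, 0, 0)])
        G = _vol([(3, 3, 3), (4, 4, 4), (5, 5, 5)])
        c = overlap_counts(P, G)
        assert (c.n_tp, c.n_fp, c.n_fn) == (0, 2, 3)
        assert sdi(P, G) == 0.0

    def test_half_overlap(self):
        P = _vol([(0, 0, 0), (1, 1, 1)])
        G = _vol([(1, 1, 1), (2, 2, 2)])
        c = overlap_counts(P, G)
        assert (c.n_tp, c.n_fp, c.n_fn) == (1, 1, 1)
        assert sdi(P, G) == pytest.approx(50.0)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(10):
            P = random_binary_volume(rng, p=0.4)
            G = random_binary_volume(rng, p=0.4)
            if P.ones_count() + G.ones_count() == 0:
                continue
            assert sdi(P, G) == pytest.approx(sdi(G, P))
            assert 0.0 <= sdi(P, G) <= 100.0

    def test_both_empty_is_error(self):
        empty = _vol([])
        with pytest.raises(ValueError, match="undefined"):
            sdi(empty, empty)

    def test_dim_mismatch(self, rng):
        with pytest.raises(ValueError):
            overlap_counts(random_binary_volume(rng, (4, 4, 4)),
                           random_binary_volume(rng, (5, 5, 5)))


def _brute_directed_hd(G, P, spacing=None):
    g = np.argwhere(G.values).astype(float)
    p = np.argwhere(P.values).astype(float)
    if spacing is not None:
        g = g * spacing
        p = p * spacing
    return max(min(np.linalg.norm(gv - pv) for pv in p) for gv in g)


class TestDirectedHausdorff:
    def test_identical_sets_zero(self, rng):
        vol = random_binary_volume(rng)
        assert directed_hausdorff(vol, vol) == 0.0

    def test_two_point_lattice(self):
        G = _vol([(0, 0, 0)])
        P = _vol([(2, 0, 0)])
        assert directed_hausdorff(G, P) == pytest.approx(2.0)

    def test_sqrt3_case(self):
        G = _vol([(0, 0, 0), (1, 1, 1)])
        P = _vol([(0, 0, 0)])
        assert directed_hausdorff(G, P) == pytest.approx(np.sqrt(3.0))

    def test_zero_iff_subset(self, rng):
        G = random_binary_volume(rng, p=0.2)
        P = BinaryVolume(G.values | random_binary_volume(rng, p=0.2).values)
        assert directed_hausdorff(G, P) == 0.0  # G subset of P
        if P.ones_count() > G.ones_count():
            assert directed_hausdorff(P, G) > 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_equals_brute_force_oracle(self, seed):
        """KD-tree distances equal the exhaustive all-pairs scan exactly."""
        r = np.random.default_rng(seed)
        G = random_binary_volume(r, (6, 6, 6), p=0.15)
        P = random_binary_volume(r, (6, 6, 6), p=0.15)
        if G.ones_count() == 0 or P.ones_count() == 0:
            return
        assert directed_hausdorff(G, P) == pytest.approx(
            _brute_directed_hd(G, P), abs=1e-12
        )

    def test_mm_mode_scales_by_spacing(self):
        G = BinaryVolume(_vol([(0, 0, 0)]).values, spacing=(0.45, 0.45, 0.8))
        P = BinaryVolume(_vol([(0, 0, 2)]).values, spacing=(0.45, 0.45, 0.8))
        assert directed_hausdorff(G, P, in_mm=True) == pytest.approx(1.6)
        assert directed_hausdorff(G, P, in_mm=False) == pytest.approx(2.0)

    def test_symmetric_variant_is_max_of_directed(self, rng):
        G = random_binary_volume(rng, p=0.3)
        P = random_binary_volume(rng, p=0.3)
        assert symmetric_hausdorff(G, P) == max(
            directed_hausdorff(G, P), directed_hausdorff(P, G)
        )

    def test_empty_set_rejected(self, rng):
        with pytest.raises(ValueError):
            directed_hausdorff(_vol([]), random_binary_volume(rng))


class TestHdUnitRange:
    @pytest.mark.parametrize(
        "spacing,expected",
        [
            ((0.45, 0.45, 0.8), (0.45, 1.0223)),
            ((1.0, 1.0, 1.0), (1.0, 1.7321)),
            ((2.0, 2.0, 2.0), (2.0, 3.4641)),
        ],
    )
    def test_values(self, spacing, expected):
        lo, hi = hd_unit_range(spacing)
        assert round(lo, 4) == expected[0]
        assert round(hi, 4) == expected[1]

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            hd_unit_range((0.0, 1.0, 1.0))


class TestMeasurementPlane:
    def test_single_slice_implant(self):
        v = np.zeros((6, 6, 6), dtype=np.uint8)
        v[2:4, 2:4, 3] = 1
        assert select_measurement_plane(BinaryVolume(v)) == 3

    def test_tie_takes_inferior_most(self):
        v = np.zeros((6, 6, 8), dtype=np.uint8)
        v[0, 0, 1] = v[0, 1, 1] = v[1, 1, 1] = 1      # count 3
        v[0:4, 0, 3] = 1; v[0:3, 1, 3] = 1            # count 7
        v[0:4, 0, 4] = 1; v[0:3, 1, 4] = 1            # count 7 (tie)
        v[0, 0, 6] = 1                                 # count 1
        assert select_measurement_plane(BinaryVolume(v)) == 3

    def test_selected_plane_is_maximal(self, coarse_phantom):
        from craniofill.defects import make_defect_pairs

        pair = make_defect_pairs(coarse_phantom, n_variants=1, rng=4)[0]
        plane = select_measurement_plane(pair.implant_truth)
        counts = np.count_nonzero(pair.implant_truth.values, axis=(0, 1))
        assert counts[plane] == counts.max()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_measurement_plane(_vol([]))


def _annulus_volume(r_outer=20.0, r_inner=17.0, a=None, b=None, n=96):
    """One-slice elliptical annulus centred mid-grid, unit mm spacing."""
    a_out = a or r_outer
    b_out = b or r_outer
    x, y = np.meshgrid(np.arange(n) - (n - 1) / 2.0,
                       np.arange(n) - (n - 1) / 2.0, indexing="ij")
    scale = r_inner / r_outer
    outer = (x / a_out) ** 2 + (y / b_out) ** 2 <= 1
    inner = (x / (a_out * scale)) ** 2 + (y / (b_out * scale)) ** 2 <= 1
    ring = (outer & ~inner).astype(np.uint8)
    return BinaryVolume(np.repeat(ring[:, :, None], 3, axis=2))


class TestCvai:
    def test_circular_annulus_equal_radii(self):
        vol = _annulus_volume(20.0, 17.0)
        m = cvai_diagonals(vol, 1)
        for L in (m.AO, m.BO, m.CO, m.DO):
            assert L == pytest.approx(20.0, abs=0.6)
        assert m.acvai == pytest.approx(0.0, abs=1.0)
        assert m.pcvai == pytest.approx(0.0, abs=1.0)

    def test_ellipse_matches_polar_radius(self):
        a, b = 28.0, 20.0  # lateral, anterior semi-axes
        vol = _annulus_volume(1.0, 0.85, a=a, b=b)
        m = cvai_diagonals(vol, 1)
        th = np.deg2rad(60.0)
        # polar radius of the ellipse along a ray 60 deg from the Y-axis
        expect = a * b / np.sqrt((b * np.sin(th)) ** 2 + (a * np.cos(th)) ** 2)
        for L in (m.AO, m.BO, m.CO, m.DO):
            assert L == pytest.approx(expect, abs=0.6)

    def test_mirror_swap(self):
        """Flipping the slice left-right swaps AO<->BO and CO<->DO."""
        r = np.random.default_rng(3)
        vol = _annulus_volume(20.0, 16.0)
        v = vol.values.copy()
        v[:, 10:20, :] = 0  # asymmetric bite
        vol = BinaryVolume(v)
        m = cvai_diagonals(vol, 1, O=(47.5, 47.5))
        flipped = BinaryVolume(v[::-1, :, :])
        mf = cvai_diagonals(flipped, 1, O=(47.5, 47.5))
        assert m.AO == pytest.approx(mf.BO, abs=0.3)
        assert m.BO == pytest.approx(mf.AO, abs=0.3)
        assert m.CO == pytest.approx(mf.DO, abs=0.3)
        assert m.DO == pytest.approx(mf.CO, abs=0.3)


class TestCvaiIndices:
    def test_symmetric_zero(self):
        assert cvai_indices(80.0, 80.0, 90.0, 90.0) == (0.0, 0.0)

    def test_reference_lengths(self):
        """The published worked example: the deep-learning row's four
        diagonal lengths give 2.22 % / 2.14 % at 2-decimal rounding."""
        acvai, pcvai = cvai_indices(71.05, 72.63, 83.70, 85.53)
        assert round(acvai, 2) == 2.22
        assert round(pcvai, 2) == 2.14

    def test_direct_evaluation(self):
        acvai, _ = cvai_indices(100.0, 98.0, 90.0, 90.0)
        assert acvai == pytest.approx(2.0)

    def test_signed_values_preserved(self):
        a_s, p_s, a, p = cvai_indices(71.05, 72.63, 83.70, 85.53, signed=True)
        assert a_s < 0 and p_s < 0  # second diagonal longer in both pairs
        assert a == abs(a_s) and p == abs(p_s)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            cvai_indices(0.0, 1.0, 1.0, 1.0)
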