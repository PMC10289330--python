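import math

import numpy as np
import pytest
from skimage.measure import label as cc_label

from fuzzyflow.flow import FlowParams, PressureField, pressure_field
from fuzzyflow.grid import Direction
from fuzzyflow.separation import (
    InstanceLabelMap,
    PressurePoint,
    PressureZone,
    SeparationCandidate,
    accept_pair,
    candidate_pairs,
    count_instances,
    disconnectivity,
    draw_separation,
    find_pressure_zones,
    pressure_point,
    separate_instances,
    thickness,
)
from fuzzyflow.synthetic import SceneSpec, generate_scene, generate_two_disc


def field_from_psi(psi: np.ndarray, alpha=Direction.E) -> PressureField:
    wet = psi > 0
    return PressureField(
        alpha=alpha,
        wet=wet,
        psi=psi,
        constriction=np.zeros_like(psi),
        dmax=np.full(psi.shape, 999.0),
        tau=10.0,
    )


class TestPressureZones:
    def test_uniform_baseline_has_no_zones(self):
        psi = np.full((6, 6), 0.5)
        assert find_pressure_zones(field_from_psi(psi)) == []

    def test_single_supra_baseline_pixel(self):
        psi = np.full((5, 5), 0.5)
        psi[2, 3] = 0.7
        zones = find_pressure_zones(field_from_psi(psi))
        assert len(zones) == 1 and len(zones[0].pixels) == 1
        assert tuple(zones[0].pixels[0]) == (2, 3)

    def test_two_blobs_match_flood_fill_oracle(self):
        rng = np.random.default_rng(5)
        psi = np.full((20, 20), 0.5)
        psi[2:5, 2:5] = 0.6 + 0.1 * rng.random((3, 3))
        psi[10:14, 12:15] = 0.7 + 0.1 * rng.random((4, 3))
        zones = find_pressure_zones(field_from_psi(psi))
        oracle = cc_label(psi > 0.5 + 1e-9, connectivity=2)
        assert len(zones) == oracle.max() == 2
        for z in zones:
            labels_hit = {oracle[r, c] for r, c in z.pixels}
            assert len(labels_hit) == 1


class TestPressurePoint:
    def test_argmax(self):
        z = PressureZone(
            Direction.E,
            pixels=np.array([[2, 2], [2, 3]]),
            psi_values=np.array([0.6, 0.8]),
        )
        p = pressure_point(z)
        assert p.location == (2, 3) and p.psi == pytest.approx(0.8)

    def test_tie_breaks_lexicographically(self):
        z = PressureZone(
            Direction.N,
            pixels=np.array([[1, 2], [1, 1]]),
            psi_values=np.array([0.7, 0.7]),
        )
        assert pressure_point(z).location == (1, 1)

    def test_returned_psi_dominates_zone(self):
        rng = np.random.default_rng(9)
        pix = np.argwhere(np.ones((4, 4), dtype=bool))
        vals = 0.5 + 0.5 * rng.random(len(pix))
        z = PressureZone(Direction.S, pixels=pix, psi_values=vals)
        assert pressure_point(z).psi >= vals.max()

    def test_empty_zone_rejected(self):
        z = PressureZone(Direction.E, pixels=np.empty((0, 2)), psi_values=np.array([]))
        with pytest.raises(ValueError):
            pressure_point(z)


class TestThickness:
    def test_one_pixel_bar(self):
        m = np.zeros((7, 7), dtype=bool)
        m[1:6, 3] = True
        assert thickness(m, (3, 2)) == 1.0

    def test_square_edge_midpoint(self):
        m = np.zeros((11, 11), dtype=bool)
        m[2:9, 2:9] = True  # 7x7 square
        assert thickness(m, (1, 5)) == 7.0

    def test_dumbbell_waist_matches_analytic_neck(self, dumbbell):
        m = dumbbell.merged_mask
        neck = dumbbell.pairs[0].neck_width
        # probe from the notch tip just above the waist
        col = int(round(np.mean(np.nonzero(m.any(axis=0))[0])))  # central column
        rows = np.nonzero(m[:, col])[0]
        tip = (rows[0] - 1, col)
        assert thickness(m, tip) == pytest.approx(neck, abs=2.0)

    def test_rejects_invalid_probe_points(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        with pytest.raises(ValueError):
            thickness(m, (2, 2))  # object pixel
        with pytest.raises(ValueError):
            thickness(m, (0, 0))  # no adjacent object


class TestDisconnectivity:
    @pytest.mark.parametrize("t,tau,expected", [(10, 5, 1.0), (5, 5, 0.5), (25, 5, 1.0)])
    def test_cap_and_scaling(self, t, tau, expected):
        assert disconnectivity(t, tau) == expected

    def test_rejects_bad_tau(self):
        with pytest.raises(ValueError):
            disconnectivity(3, 0)


def _points_for(mask, tau=10.0):
    from fuzzyflow.flow import compute_all_fields

    return [
        pressure_point(z)
        for f in compute_all_fields(mask, tau=tau).values()
        for z in find_pressure_zones(f)
    ]


class TestCandidatePairs:
    def test_perpendicular_directions_never_pair(self):
        m = np.zeros((20, 20), dtype=bool)
        m[8:12, 8:12] = True
        pts = [
            PressurePoint((7, 10), Direction.S, 0.9),
            PressurePoint((10, 7), Direction.E, 0.9),
        ]
        assert candidate_pairs(pts, m, tau=10) == []

    def test_dumbbell_pairs_straddle_the_waist(self, dumbbell):
        m = dumbbell.merged_mask
        pts = _points_for(m)
        cands = candidate_pairs(pts, m, tau=10)
        assert len(cands) >= 1
        h_mid = m.shape[0] // 2
        for c in cands:
            rows = sorted((c.point1.location[0], c.point2.location[0]))
            assert rows[0] < h_mid < rows[1]
        # pairs oppose within at most one compass notch, each point used once
        from fuzzyflow.grid import angular_difference

        used = [
            (c.point1.location, c.point1.alpha) for c in cands
        ] + [(c.point2.location, c.point2.alpha) for c in cands]
        assert len(used) == len(set(used))
        for c in cands:
            assert angular_difference(c.point1.alpha.value, c.point2.alpha.value) >= 135

    def test_separated_discs_yield_no_pair(self):
        from fuzzyflow.synthetic import _paint_labels

        lab = _paint_labels((60, 90), [(30.0, 22.0, 10.0), (30.0, 58.0, 10.0)])
        m = lab > 0
        pts = _points_for(m)
        assert candidate_pairs(pts, m, tau=10) == []

    def test_exhaustive_enumeration_agrees(self, dumbbell):
        """Greedy matching picks a subset of the brute-force feasible pairs."""
        m = dumbbell.merged_mask
        pts = _points_for(m)
        chosen = candidate_pairs(pts, m, tau=10)
        brute = candidate_pairs(pts, m, tau=10, min_opposition=135.0)
        chosen_keys = {
            (c.point1.location, c.point2.location) for c in chosen
        }
        brute_keys = {(c.point1.location, c.point2.location) for c in brute}
        assert chosen_keys <= brute_keys


class TestAcceptPair:
    def _cand(self, m, p1, p2, psi1, psi2, a1=Direction.S, a2=Direction.N):
        return SeparationCandidate(
            point1=PressurePoint(p1, a1, psi1),
            point2=PressurePoint(p2, a2, psi2),
            distance=math.dist(p1, p2),
        )

    def test_strong_pressure_beats_thin_waist(self, dumbbell):
        m = dumbbell.merged_mask
        cands = candidate_pairs(_points_for(m), m, tau=10)
        assert accept_pair(cands[0], m, tau=10)

    def test_pressure_must_exceed_normalized_thickness(self):
        # horizontal slab 12 px thick; with tau = 10 every reading gives
        # D = 12/20 = 0.6, so psi 0.55 is rejected and 0.65 accepted
        m = np.zeros((32, 60), dtype=bool)
        m[10:22, :] = True
        weak = self._cand(m, (9, 30), (22, 30), 0.55, 0.55)
        strong = self._cand(m, (9, 30), (22, 30), 0.65, 0.65)
        assert not accept_pair(weak, m, tau=10)
        assert accept_pair(strong, m, tau=10)

    def test_thick_waist_capped_at_one_rejects_moderate_pressure(self):
        # a huge square: every crossing is >= 2*tau so D = 1 everywhere
        m = np.zeros((60, 60), dtype=bool)
        m[10:50, 10:50] = True
        cand = self._cand(m, (9, 30), (50, 30), 0.93, 0.93)
        assert not accept_pair(cand, m, tau=5)


class TestDrawSeparation:
    def test_horizontal_rasterization(self):
        m = np.zeros((6, 10), dtype=bool)
        m[2, 3:8] = True
        cand = SeparationCandidate(
            point1=PressurePoint((2, 3), Direction.E, 0.9),
            point2=PressurePoint((2, 7), Direction.W, 0.9),
            distance=4.0,
        )
        out = draw_separation(m, cand)
        assert not out.any()
        assert cand.line_pixels[:5] == [(2, 3), (2, 4), (2, 5), (2, 6), (2, 7)]

    def test_idempotent(self, dumbbell):
        m = dumbbell.merged_mask
        cand = candidate_pairs(_points_for(m), m, tau=10)[0]
        once = draw_separation(m, cand)
        twice = draw_separation(once, cand)
        assert np.array_equal(once, twice)

    def test_dumbbell_cut_disconnects_lobes(self, dumbbell):
        m = dumbbell.merged_mask
        assert cc_label(m, connectivity=2).max() == 1
        cand = candidate_pairs(_points_for(m), m, tau=10)[0]
        cut = draw_separation(m, cand)
        assert cc_label(cut, connectivity=2).max() == 2

    def test_never_adds_object_pixels(self, dumbbell):
        m = dumbbell.merged_mask
        cand = candidate_pairs(_points_for(m), m, tau=10)[0]
        cut = draw_separation(m, cand)
        assert not (cut & ~m).any()


class TestSeparateInstances:
    def test_single_disc_untouched(self):
        from fuzzyflow.synthetic import _paint_labels

        m = _paint_labels((50, 50), [(25.0, 25.0, 10.0)]) > 0
        res = separate_instances(m, tau=10)
        assert res.count == 1
        assert np.array_equal(res.labels > 0, m)

    def test_dumbbell_splits_in_two(self, dumbbell):
        res = separate_instances(dumbbell.merged_mask, tau=10)
        assert res.count == 2

    def test_non_touching_discs_keep_their_labels(self):
        spec = SceneSpec(
            height=200, width=200, n_nuclei=5, n_overlapping_pairs=0, seed=3
        )
        scene = generate_scene(spec)
        res = separate_instances(scene.merged_mask, tau=10)
        assert res.count == 5
        assert np.array_equal(res.labels > 0, scene.merged_mask)

    def test_empty_mask(self):
        res = separate_instances(np.zeros((10, 10), dtype=bool))
        assert res.count == 0 and res.centroids == []

    def test_conservation_and_monotonicity(self, dumbbell):
        m = dumbbell.merged_mask
        res, accepted, _ = separate_instances(m, tau=10, return_details=True)
        out = res.labels > 0
        assert not (out & ~m).any()  # nothing added
        removed = m & ~out
        line_px = {p for c in accepted for p in c.line_pixels}
        assert set(map(tuple, np.argwhere(removed))) <= line_px
        assert res.count >= cc_label(m, connectivity=2).max()

    def test_line_stays_local_to_its_pair(self, dumbbell):
        from fuzzyflow.separation import _ENDPOINT_EXTENSION

        m = dumbbell.merged_mask
        _, accepted, _ = separate_instances(m, tau=10, return_details=True)
        pad = 1 + _ENDPOINT_EXTENSION
        for c in accepted:
            r1, c1 = c.point1.location
            r2, c2 = c.point2.location
            rlo, rhi = min(r1, r2) - pad, max(r1, r2) + pad
            clo, chi = min(c1, c2) - pad, max(c1, c2) + pad
            assert all(rlo <= r <= rhi and clo <= cc_ <= chi for r, cc_ in c.line_pixels)

    def test_reassign_line_pixels_preserves_area(self, dumbbell):
        m = dumbbell.merged_mask
        res = separate_instances(m, tau=10, reassign_line_pixels=True)
        assert res.count == 2
        assert np.array_equal(res.labels > 0, m)


class TestCountInstances:
    def test_empty(self):
        lm = InstanceLabelMap.from_labels(np.zeros((5, 5), dtype=int))
        assert count_instances(lm) == (0, [])

    def test_square_centroid(self):
        lab = np.zeros((8, 8), dtype=int)
        lab[2:5, 2:5] = 1
        count, cents = count_instances(InstanceLabelMap.from_labels(lab))
        assert count == 1
        assert cents[0] == pytest.approx((3.0, 3.0))

    def test_count_equals_distinct_labels(self):
        rng = np.random.default_rng(17)
        lab = rng.integers(0, 9, size=(30, 30))
        count, cents = count_instances(InstanceLabelMap.from_labels(lab))
        expected = len(np.unique(lab)) - (1 if (lab == 0).any() else 0)
        assert count == expected == len(cents)
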