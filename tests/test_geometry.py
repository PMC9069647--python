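"""Distance profiles, straightness, pair enumeration and its oracle."""

import math
import random

import numpy as np
import pytest

from crossbeta import (
    GeometryParams,
    apply_coverage_filter,
    distance_profile,
    enumerate_parallel_pairs,
    straightness,
)
from crossbeta.geometry import ParallelSegmentPair
from crossbeta.synthetic import SheetSpec, generate_parallel_sheet

from _helpers import (
    brute_force_pairs,
    make_chain,
    make_structure,
    pair_keys,
    random_structure,
)


class TestDistanceProfile:
    def test_rigid_translation_gives_constant_profile(self):
        a = np.stack([3.4 * np.arange(8), np.zeros(8), np.zeros(8)], axis=1)
        b = a + np.array([4.8, 0.0, 0.0])
        d = distance_profile(a, b)
        assert np.allclose(d, 4.8)
        assert np.std(d) < 1e-12

    def test_matches_brute_force_on_twisted_pair(self):
        spec = SheetSpec(chain_sequence="GSTAQKLVFDEKNS", segment_start=4,
                         segment_length=7, twist_per_residue=3.0)
        st = generate_parallel_sheet(spec)
        a = np.array([r.ca_position for r in st.models[0][0].residues])
        b = np.array([r.ca_position for r in st.models[0][1].residues])
        d = distance_profile(a, b)
        expected = [math.dist(a[k], b[k]) for k in range(len(a))]
        assert np.allclose(d, expected)

    def test_single_residue_at_same_point(self):
        assert distance_profile([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]]) == \
            pytest.approx([0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            distance_profile(np.zeros((3, 3)), np.zeros((4, 3)))


class TestStraightness:
    def test_collinear_points(self):
        pts = np.stack([3.4 * np.arange(6), np.zeros(6), np.zeros(6)], axis=1)
        assert straightness(pts) == pytest.approx(1.0)

    def test_semicircle_closed_form(self):
        # ratio of the polyline: chord / (n-1 equal sub-chords)
        n = 10
        theta = np.linspace(0.0, np.pi, n)
        pts = np.stack([np.cos(theta), np.sin(theta), np.zeros(n)], axis=1)
        expected = 1.0 / ((n - 1) * math.sin(math.pi / (2 * (n - 1))))
        assert straightness(pts) == pytest.approx(expected, abs=1e-12)
        # densely sampled, the ratio approaches diameter / half-circumference
        n = 2001
        theta = np.linspace(0.0, np.pi, n)
        pts = np.stack([np.cos(theta), np.sin(theta), np.zeros(n)], axis=1)
        assert straightness(pts) == pytest.approx(2.0 / math.pi, abs=1e-6)

    def test_ideal_alpha_helix_below_threshold(self, params):
        i = np.arange(12)
        theta = np.radians(100.0) * i
        pts = np.stack([1.5 * i, 2.3 * np.cos(theta), 2.3 * np.sin(theta)],
                       axis=1)
        assert straightness(pts) < params.straightness_min

    def test_short_run_rejected(self):
        with pytest.raises(ValueError):
            straightness(np.zeros((1, 3)))


def _straight_pair_structure(n=14, start=4, seg=7, separation=4.8):
    spec = SheetSpec(chain_sequence="GSTAQKLVFDEKNS"[:n], segment_start=start,
                     segment_length=seg, inter_strand_spacing=separation)
    return generate_parallel_sheet(spec)


class TestEnumerate:
    def test_planted_pair_found_exactly_once(self, params):
        st = _straight_pair_structure()
        pairs = enumerate_parallel_pairs(st, params)
        assert pair_keys(pairs) == [("A", 4, "B", 4, 7)]
        p = pairs[0]
        assert p.mean_distance == pytest.approx(4.8)
        assert p.distance_sd == pytest.approx(0.0)
        assert p.resnum_range_a == (5, 11)

    def test_same_chain_arms_ignored(self, params):
        # hairpin-like: one chain runs out and back with arms 5 A apart
        arm = [(3.4 * i, 0.0, 0.0) for i in range(7)]
        back = [(3.4 * (6 - i), 5.0, 0.0) for i in range(7)]
        mid = [(22.0, 2.5, 0.0)]
        coords = np.array(arm + mid + back)
        chain = make_chain("A", "A" * len(coords), coords,
                           numbers=range(1, len(coords) + 1))
        st = make_structure([chain])
        assert enumerate_parallel_pairs(st, params) == []

    def test_far_strands_rejected(self, params):
        st = _straight_pair_structure()
        # move chain B 20 A away
        for r in st.models[0][1].residues:
            r.ca_position = r.ca_position + np.array([0.0, 15.2, 0.0])
        assert enumerate_parallel_pairs(st, params) == []
        assert brute_force_pairs(st, params) == []

    def test_antiparallel_rejected(self, params):
        n = 8
        a = make_chain("A", "A" * n, np.stack(
            [3.4 * np.arange(n), np.zeros(n), np.zeros(n)], axis=1))
        b = make_chain("B", "A" * n, np.stack(
            [3.4 * np.arange(n - 1, -1, -1), np.full(n, 4.8), np.zeros(n)],
            axis=1))
        st = make_structure([a, b])
        assert enumerate_parallel_pairs(st, params) == []

    def test_oracle_equivalence_on_random_structures(self, params, rng):
        for _ in range(60):
            st = random_structure(rng)
            assert pair_keys(enumerate_parallel_pairs(st, params)) == \
                brute_force_pairs(st, params)

    def test_oracle_equivalence_with_offset_scan(self, rng):
        params = GeometryParams(offset_scan=2)
        for _ in range(30):
            st = random_structure(rng)
            assert pair_keys(enumerate_parallel_pairs(st, params)) == \
                brute_force_pairs(st, params)

    def test_rigid_motion_invariance(self, params):
        spec = SheetSpec(chain_sequence="GSTAQKLVFDEKNSAW", segment_start=4,
                         segment_length=8, noise_sd=0.2, seed=3)
        st = generate_parallel_sheet(spec)
        before = enumerate_parallel_pairs(st, params)
        angle = 0.8
        rot = np.array([
            [math.cos(angle), -math.sin(angle), 0.0],
            [math.sin(angle), math.cos(angle), 0.0],
            [0.0, 0.0, 1.0],
        ])
        shift = np.array([11.0, -7.0, 23.0])
        for chain in st.models[0]:
            for r in chain.residues:
                r.ca_position = rot @ r.ca_position + shift
        after = enumerate_parallel_pairs(st, params)
        assert pair_keys(before) == pair_keys(after)
        for p, q in zip(before, after):
            np.testing.assert_allclose(p.distances, q.distances, atol=1e-6)

    def test_each_physical_pair_reported_once(self, params):
        st = _straight_pair_structure()
        pairs = enumerate_parallel_pairs(st, params)
        assert len(pairs) == 1
        assert pairs[0].chain_a < pairs[0].chain_b

    def test_relaxed_band_keeps_detections_as_containments(self, rng):
        strict = GeometryParams()
        relaxed = GeometryParams(d_min=1.0, d_max=20.0, sigma_max=3.0)
        for _ in range(30):
            st = random_structure(rng)
            strict_pairs = enumerate_parallel_pairs(st, strict)
            relaxed_pairs = enumerate_parallel_pairs(st, relaxed)
            for p in strict_pairs:
                assert any(
                    q.chain_a == p.chain_a and q.chain_b == p.chain_b
                    and q.start_b - q.start_a == p.start_b - p.start_a
                    and q.start_a <= p.start_a
                    and q.start_a + q.length >= p.start_a + p.length
                    for q in relaxed_pairs
                ), "strict detection lost after relaxing the band"


class TestCoverage:
    @staticmethod
    def _pair(length, cov_a, cov_b):
        return ParallelSegmentPair(
            entry_id="T", model_index=0, chain_a="A", start_a=0,
            chain_b="B", start_b=0, length=length,
            distances=np.full(length, 4.8), mean_distance=4.8,
            distance_sd=0.0, straightness_a=1.0, straightness_b=1.0,
            coverage_a=cov_a, coverage_b=cov_b, direction_dot=1.0,
            resnum_range_a=(1, length), resnum_range_b=(1, length))

    def test_exactly_one_seventh_is_accepted(self, params):
        pair = self._pair(3, 2 / 14, 2 / 14)
        assert apply_coverage_filter(pair, params)

    def test_below_one_seventh_rejected(self, params):
        assert not apply_coverage_filter(self._pair(3, 1 / 14, 1 / 14), params)
        assert not apply_coverage_filter(self._pair(10, 10 / 80, 10 / 80),
                                         params)

    def test_either_chain_suffices_unless_both_required(self):
        pair = self._pair(4, 0.5, 0.05)
        assert apply_coverage_filter(pair, GeometryParams())
        assert not apply_coverage_filter(
            pair, GeometryParams(coverage_both=True))


def test_params_validation():
    with pytest.raises(ValueError):
        GeometryParams(d_min=0.0)
    with pytest.raises(ValueError):
        GeometryParams(d_min=16.0, d_max=15.0)
    with pytest.raises(ValueError):
        GeometryParams(min_segment_length=2)


def test_params_from_config(tmp_path):
    cfg = tmp_path / "geom.cfg"
    cfg.write_text(
        "d_min = 2.5\nd_max = 12\ncoverage_min = 1/7\n"
        "min_segment_length = 4\ncoverage_both = true\n# comment\n")
    p = GeometryParams.from_config(cfg)
    assert p.d_min == 2.5
    assert p.d_max == 12.0
    assert p.coverage_min == pytest.approx(1 / 7)
    assert p.min_segment_length == 4
    assert p.coverage_both is True
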