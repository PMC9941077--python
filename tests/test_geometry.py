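"""Stitch-geometry criteria and their invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from suturemetrics.geometry import (
    Stitch,
    StitchSet,
    calibrate,
    inter_stitch_angle,
    inter_stitch_distance,
    length_ratios,
    quality_deviation,
    stitch_length,
    summarize_geometry,
)


def random_stitch_set(rng, n=3):
    stitches = []
    for k in range(1, n + 1):
        entry = rng.uniform(-5, 5, 2)
        exit_ = entry + rng.uniform(0.2, 3.0) * _unit(rng.uniform(0, 2 * np.pi))
        stitches.append(Stitch(index=k, entry=tuple(entry), exit=tuple(exit_)))
    return StitchSet(stitches=tuple(stitches), units="mm")


def _unit(theta):
    return np.array([np.cos(theta), np.sin(theta)])


def transform_set(sset, rotation_deg=0.0, translation=(0.0, 0.0), scale=1.0):
    a = np.radians(rotation_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    t = np.asarray(translation)

    def tf(p):
        return tuple(scale * (rot @ np.asarray(p)) + t)

    return StitchSet(
        stitches=tuple(
            Stitch(index=s.index, entry=tf(s.entry), exit=tf(s.exit),
                   completed=s.completed)
            for s in sset.stitches
        ),
        units=sset.units,
    )


class TestLengthAndCalibration:
    def test_vertical_and_pythagorean_lengths(self):
        assert stitch_length(Stitch(1, (0, 0), (0, 2))) == pytest.approx(2.0)
        assert stitch_length(Stitch(1, (0, 0), (3, 4))) == pytest.approx(5.0)

    def test_ideal_2mm_stitch_scores_zero_deviation(self):
        sset = StitchSet((Stitch(1, (0, 0), (0, 2)),), units="mm")
        dev = quality_deviation(sset)
        assert dev["mean_length_deviation_mm"] == pytest.approx(0.0)

    def test_uncompleted_stitch_excluded(self):
        with pytest.raises(ValueError):
            stitch_length(Stitch(1, (0, 0), (0, 2), completed=False))

    def test_pixel_calibration(self):
        sset = StitchSet((Stitch(1, (0, 0), (0, 100)),), units="px",
                         mm_per_px=0.01)
        assert stitch_length(calibrate(sset).stitches[0]) == pytest.approx(1.0)

    def test_calibrate_identity_on_mm(self, ideal_template):
        assert calibrate(ideal_template) is ideal_template

    def test_calibration_round_trip(self):
        sset = StitchSet((Stitch(1, (0.123, -4.5), (2.0, 1.0)),), units="mm")
        px = StitchSet(
            tuple(
                Stitch(s.index, tuple(np.array(s.entry) / 0.0125),
                       tuple(np.array(s.exit) / 0.0125))
                for s in sset.stitches
            ),
            units="px",
            mm_per_px=0.0125,
        )
        back = calibrate(px).stitches[0]
        np.testing.assert_allclose(back.entry, sset.stitches[0].entry, atol=1e-12)

    def test_px_without_scale_rejected(self):
        sset = StitchSet((Stitch(1, (0, 0), (0, 1)),), units="px")
        with pytest.raises(ValueError):
            calibrate(sset)


class TestRatiosDistancesAngles:
    @pytest.mark.parametrize(
        "lengths, expected",
        [((1.0, 1.0, 1.0), (1.0, 1.0)), ((1.0, 1.16, 1.16), (1.16, 1.16)),
         ((2.0, 1.0), (0.5,))],
    )
    def test_length_ratios(self, lengths, expected):
        stitches = tuple(
            Stitch(index=k, entry=(float(k), 0.0), exit=(float(k), length))
            for k, length in enumerate(lengths, start=1)
        )
        ratios = length_ratios(StitchSet(stitches, units="mm"))
        assert tuple(ratios[k] for k in sorted(ratios)) == pytest.approx(expected)

    def test_ratio_undefined_without_first_stitch(self):
        sset = StitchSet(
            (Stitch(1, (0, 0), (0, 1), completed=False),
             Stitch(2, (1, 0), (1, 1))),
            units="mm",
        )
        with pytest.raises(ValueError):
            length_ratios(sset)
        assert summarize_geometry(sset).ratio_defined is False

    def test_midpoint_distance_parallel_unit_stitches(self):
        a = Stitch(1, (0, 0), (0, 1))
        b = Stitch(2, (1, 0), (1, 1))
        assert inter_stitch_distance(a, b) == pytest.approx(1.0)
        assert inter_stitch_distance(b, a) == pytest.approx(1.0)

    def test_identical_stitches_distance_zero(self):
        a = Stitch(1, (0, 0), (0, 1))
        b = Stitch(2, (0, 0), (0, 1))
        assert inter_stitch_distance(a, b) == pytest.approx(0.0)

    def test_distance_matches_midpoint_arithmetic(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            sset = random_stitch_set(rng, n=2)
            a, b = sset.stitches
            ma = (np.array(a.entry) + np.array(a.exit)) / 2
            mb = (np.array(b.entry) + np.array(b.exit)) / 2
            assert inter_stitch_distance(a, b) == pytest.approx(
                float(np.hypot(*(ma - mb)))
            )

    def test_nonconsecutive_pair_rejected(self):
        a = Stitch(1, (0, 0), (0, 1))
        c = Stitch(3, (2, 0), (2, 1))
        with pytest.raises(ValueError):
            inter_stitch_distance(a, c)

    @pytest.mark.parametrize(
        "da, db, expected",
        [(((0, 0), (0, 1)), ((1, 0), (1, 1)), 0.0),
         (((0, 0), (0, 1)), ((1, 0), (2, 1)), 45.0),
         (((0, 0), (0, 1)), ((1, 0), (2, 0)), 90.0)],
    )
    def test_angles(self, da, db, expected):
        a = Stitch(1, *da)
        b = Stitch(2, *db)
        assert inter_stitch_angle(a, b) == pytest.approx(expected)

    def test_angle_invariant_to_endpoint_swap_and_order(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            sset = random_stitch_set(rng, n=2)
            a, b = sset.stitches
            base = inter_stitch_angle(a, b)
            assert inter_stitch_angle(b, a) == pytest.approx(base)
            flipped = Stitch(a.index, a.exit, a.entry)
            assert inter_stitch_angle(flipped, b) == pytest.approx(base)
            assert 0.0 <= base <= 90.0


class TestSummary:
    def test_ideal_template(self, ideal_template):
        g = summarize_geometry(ideal_template)
        assert list(g.lengths_mm.values()) == pytest.approx([2.0, 2.0, 2.0])
        assert list(g.length_ratios.values()) == pytest.approx([1.0, 1.0])
        assert list(g.distances_mm.values()) == pytest.approx([1.0, 1.0])
        assert list(g.angles_deg.values()) == pytest.approx([0.0, 0.0])

    def test_only_first_stitch_completed(self):
        sset = StitchSet(
            (Stitch(1, (0, 0), (0, 2)),
             Stitch(2, (1, 0), (1, 2), completed=False),
             Stitch(3, (2, 0), (2, 2), completed=False)),
            units="mm",
        )
        g = summarize_geometry(sset)
        assert set(g.lengths_mm) == {1}
        assert g.length_ratios == {} and g.distances_mm == {} and g.angles_deg == {}

    def test_no_completed_stitches_gives_empty_flagged_summary(self):
        sset = StitchSet(
            (Stitch(1, (0, 0), (0, 2), completed=False),), units="mm"
        )
        g = summarize_geometry(sset)
        assert g.n_completed == 0 and not g.lengths_mm and not g.ratio_defined

    def test_random_set_matches_per_operation_recomputation(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            sset = random_stitch_set(rng)
            g = summarize_geometry(sset)
            by_index = {s.index: s for s in sset.stitches}
            for k, v in g.lengths_mm.items():
                assert v == pytest.approx(stitch_length(by_index[k]))
            for k, v in g.length_ratios.items():
                assert v == pytest.approx(
                    stitch_length(by_index[k]) / stitch_length(by_index[1])
                )
            for (a, b), v in g.distances_mm.items():
                assert v == pytest.approx(
                    inter_stitch_distance(by_index[a], by_index[b])
                )

    def test_quality_deviation_arithmetic(self):
        sset = StitchSet(
            (Stitch(1, (0, 0), (0, 1.0)), Stitch(2, (1.5, 0), (1.5, 2.5))),
            units="mm",
        )
        dev = quality_deviation(sset)
        assert dev["length_deviation_mm"][1] == pytest.approx(1.0)
        assert dev["length_deviation_mm"][2] == pytest.approx(0.5)
        assert dev["mean_length_deviation_mm"] == pytest.approx(0.75)
        # midpoints (0, 0.5) and (1.5, 1.25): distance sqrt(1.5^2 + 0.75^2)
        d = np.hypot(1.5, 0.75)
        assert dev["spacing_deviation_mm"][(1, 2)] == pytest.approx(abs(d - 1.0))


class TestInvariances:
    @given(
        seed=st.integers(0, 10_000),
        angle=st.floats(-180, 180),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    @settings(max_examples=60, deadline=None)
    def test_rigid_motion_invariance(self, seed, angle, tx, ty):
        rng = np.random.default_rng(seed)
        sset = random_stitch_set(rng)
        moved = transform_set(sset, rotation_deg=angle, translation=(tx, ty))
        g0, g1 = summarize_geometry(sset), summarize_geometry(moved)
        for k in g0.lengths_mm:
            assert abs(g0.lengths_mm[k] - g1.lengths_mm[k]) < 1e-9
        for k in g0.length_ratios:
            assert abs(g0.length_ratios[k] - g1.length_ratios[k]) < 1e-9
        for k in g0.distances_mm:
            assert abs(g0.distances_mm[k] - g1.distances_mm[k]) < 1e-9
        for k in g0.angles_deg:
            assert abs(g0.angles_deg[k] - g1.angles_deg[k]) < 1e-6

    @given(seed=st.integers(0, 10_000), scale=st.floats(1e-2, 1e2))
    @settings(max_examples=60, deadline=None)
    def test_scale_covariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        sset = random_stitch_set(rng)
        scaled = transform_set(sset, scale=scale)
        g0, g1 = summarize_geometry(sset), summarize_geometry(scaled)
        for k in g0.lengths_mm:
            assert g1.lengths_mm[k] == pytest.approx(scale * g0.lengths_mm[k])
        for k in g0.distances_mm:
            assert g1.distances_mm[k] == pytest.approx(scale * g0.distances_mm[k])
        for k in g0.length_ratios:
            assert g1.length_ratios[k] == pytest.approx(g0.length_ratios[k])
        for k in g0.angles_deg:
            assert abs(g1.angles_deg[k] - g0.angles_deg[k]) < 1e-6
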