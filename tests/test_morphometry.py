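"""Morphometry: measurement constructions, classification, voxel pipeline."""
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from coarckit import morphometry as mm
from coarckit.arch_synth import (ArchParams, Centerline, LEVELS, build_arch,
                                 voxelize)

FAMILY_RANGES = {
    "gothic": (0.58, 0.92),
    "crenel": (0.42, 0.60),
    "romanesque": (0.46, 0.75),
}


def random_feasible_params(rng):
    arch_type = rng.choice(list(FAMILY_RANGES))
    lo, hi = FAMILY_RANGES[arch_type]
    aoa = rng.uniform(10.0, 14.0)
    ratios = {"D1": rng.uniform(0.55, 0.75), "D2": rng.uniform(0.45, 0.65),
              "D3": rng.uniform(0.2, 0.45), "D4": rng.uniform(0.6, 0.9),
              "D5": rng.uniform(0.55, 0.85)}
    return ArchParams(
        arch_type=arch_type,
        width_T=rng.uniform(30.0, 42.0),
        height_A=rng.uniform(lo, hi) * 36.0,
        aao_dao_angle=rng.uniform(18.0, 42.0),
        tao_dao_angle=rng.uniform(100.0, 122.0),
        level_diameters={"AOA": aoa, **{k: v * aoa for k, v in ratios.items()}})


class TestGeneratorRoundTrip:
    def test_hundred_random_arches_measure_back_exactly(self, rng):
        """Full morphometry on 100 random feasible phantoms recovers every
        generated quantity to 1e-6 relative (the module's core oracle)."""
        built = 0
        while built < 100:
            p = random_feasible_params(rng)
            try:
                arch = build_arch(p)
            except Exception:
                continue
            built += 1
            m = mm.measure_case(arch)
            assert m.width_T == pytest.approx(p.width_T, rel=1e-6)
            assert m.height_A == pytest.approx(p.height_A, rel=1e-6)
            assert m.at_ratio == pytest.approx(p.at_ratio, rel=1e-6)
            assert m.aao_dao_angle == pytest.approx(p.aao_dao_angle, rel=1e-6)
            assert m.tao_dao_angle == pytest.approx(p.tao_dao_angle, rel=1e-6)
            for k in LEVELS:
                assert m.diameters[k] == pytest.approx(p.level_diameters[k], rel=1e-6)

    def test_monotone_in_height(self):
        ats = []
        for A in np.linspace(22.0, 28.0, 5):
            arch = build_arch(ArchParams(arch_type="gothic", height_A=A, width_T=36.0))
            ats.append(mm.compute_arch_geometry(arch)["at_ratio"])
        assert np.all(np.diff(ats) > 0)


def _rotate(points, deg):
    a = np.radians(deg)
    R = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    return points @ R.T


class TestInvariance:
    @pytest.mark.parametrize("k", [0.37, 2.8])
    def test_scale_invariance(self, gothic_mean_arch, k):
        a = gothic_mean_arch
        m0 = mm.measure_case(a)
        cl = Centerline(s=a.s * k, points=a.points * k, radii=a.radii * k)
        lms = {n: v.point * k for n, v in a.landmarks.items()}
        m1 = mm.measure_case(cl, lms, window=mm.LEVEL_WINDOW * k)
        assert m1.at_ratio == pytest.approx(m0.at_ratio, abs=1e-9)
        assert m1.aao_dao_angle == pytest.approx(m0.aao_dao_angle, abs=1e-9)
        assert m1.tao_dao_angle == pytest.approx(m0.tao_dao_angle, abs=1e-9)
        assert m1.arch_class == m0.arch_class
        assert m1.haa_flags == m0.haa_flags and m1.coa_flag == m0.coa_flag
        for key in m0.ratios:
            assert m1.ratios[key] == pytest.approx(m0.ratios[key], abs=1e-9)

    @pytest.mark.parametrize("deg", [33.0, -118.0])
    def test_rigid_rotation_invariance(self, gothic_mean_arch, deg):
        a = gothic_mean_arch
        m0 = mm.measure_case(a)
        shift = np.array([13.0, -4.0, 0.0])
        cl = Centerline(s=a.s, points=_rotate(a.points, deg) + shift, radii=a.radii)
        lms = {n: _rotate(v.point[None], deg)[0] + shift for n, v in a.landmarks.items()}
        m1 = mm.measure_case(cl, lms)
        assert m1.height_A == pytest.approx(m0.height_A, abs=1e-9)
        assert m1.width_T == pytest.approx(m0.width_T, abs=1e-9)
        assert m1.aao_dao_angle == pytest.approx(m0.aao_dao_angle, abs=1e-9)
        assert m1.tao_dao_angle == pytest.approx(m0.tao_dao_angle, abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize("at,expected", [
        (0.85, "gothic"),          # above the gothic threshold
        (0.49028, "crenel"),       # the crenel group mean
        (0.70148, "romanesque"),   # the gothic group mean sits below 0.8
        (0.8, "romanesque"), (0.6, "romanesque"),   # boundary convention
        (0.80001, "gothic"), (0.59999, "crenel"),
    ])
    def test_breakpoints(self, at, expected):
        assert mm.classify_arch(at) == expected

    @pytest.mark.parametrize("bad", [0.0, -0.3, float("nan")])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            mm.classify_arch(bad)

    @given(st.floats(min_value=1e-6, max_value=5.0, allow_nan=False))
    def test_total_piecewise_constant(self, at):
        cls = mm.classify_arch(at)
        assert cls == ("gothic" if at > 0.8 else "crenel" if at < 0.6
                       else "romanesque")


class TestCriteria:
    def _meas(self, ratios, diameters=None):
        diam = diameters or {"AOA": 12.0, "D1": ratios["D1_AOA"] * 12,
                             "D2": ratios["D2_AOA"] * 12, "D3": ratios["D3_AOA"] * 12,
                             "D4": 8.5, "D5": 7.7}
        return mm.ArchMeasurements(diameters=diam, ratios=ratios, height_A=25,
                                   width_T=36, at_ratio=25 / 36,
                                   aao_dao_angle=27, tao_dao_angle=110)

    def test_isthmus_hypoplasia_at_gothic_mean(self):
        m = self._meas({"D1_AOA": 0.63, "D2_AOA": 0.53, "D3_AOA": 0.2896,
                        "D4_AOA": 0.71, "D5_AOA": 0.64})
        haa, coa = mm.evaluate_criteria(m)
        assert haa == {"proximal": False, "distal": False, "isthmus": True}
        assert coa  # 0.2896*12 = 3.48 mm <= half of D4

    def test_thresholds_are_strict(self):
        m = self._meas({"D1_AOA": 0.60, "D2_AOA": 0.50, "D3_AOA": 0.40,
                        "D4_AOA": 0.71, "D5_AOA": 0.64})
        haa, _ = mm.evaluate_criteria(m)
        assert haa == {"proximal": False, "distal": False, "isthmus": False}

    def test_unstenosed_tube_raises_no_flags(self):
        ratios = {f"D{i}_AOA": 1.0 for i in range(1, 6)}
        diam = {k: 12.0 for k in LEVELS}
        m = self._meas(ratios, diam)
        haa, coa = mm.evaluate_criteria(m)
        assert not any(haa.values()) and not coa

    def test_explicit_reference_diameter(self):
        m = self._meas({"D1_AOA": 1.0, "D2_AOA": 1.0, "D3_AOA": 0.5,
                        "D4_AOA": 1.0, "D5_AOA": 1.0})
        _, coa = mm.evaluate_criteria(m, reference_diameter=12.0)
        assert coa  # 6 mm <= 50% of 12 mm


class TestVoxelPipeline:
    def test_extracted_centerline_close_to_truth(self, gothic_mean_arch,
                                                 gothic_voxel_case):
        from scipy.spatial import cKDTree

        _, cl = gothic_voxel_case
        d, _ = cKDTree(gothic_mean_arch.points).query(cl.points)
        assert d.mean() <= 0.5

    def test_voxel_at_ratio_within_two_percent(self, gothic_voxel_case):
        mask, cl = gothic_voxel_case
        geo = mm.compute_arch_geometry(cl, mask.landmarks)
        assert geo["at_ratio"] == pytest.approx(0.70148, rel=0.02)

    def test_voxel_diameters_within_a_voxel(self, gothic_mean_arch,
                                            gothic_voxel_case):
        mask, cl = gothic_voxel_case
        diam = mm.measure_diameters(cl, mask.landmarks)
        for k in LEVELS:
            truth = gothic_mean_arch.params.level_diameters[k]
            assert abs(diam[k] - truth) <= 0.5, k

    def test_straight_tube_centerline_collinear(self):
        from coarckit.arch_synth import AnalyticArch

        s = np.linspace(0, 40, 161)
        pts = np.column_stack([s, np.zeros_like(s), np.zeros_like(s)])
        tube = AnalyticArch(
            centerline=Centerline(s=s, points=pts, radii=np.full_like(s, 5.0)),
            landmarks={}, branch_stubs=[], params=ArchParams())
        cl = mm.extract_centerline(voxelize(tube, 0.5, include_branches=False))
        assert np.abs(cl.points[:, 1:]).max() <= 0.5

    def test_disjoint_components_rejected(self):
        from coarckit.arch_synth import VoxelMask

        grid = np.zeros((16, 6, 6), np.uint8)
        grid[:4, :4, :4] = 1
        grid[10:14, :4, :4] = 1
        mask = VoxelMask(grid=grid, spacing=np.ones(3), origin=np.zeros(3))
        with pytest.raises(ValueError, match="component"):
            mm.extract_centerline(mask)

    def test_clipped_window_warns(self, gothic_mean_arch):
        a = gothic_mean_arch
        lms = {n: v for n, v in a.landmarks.items()}
        from coarckit.arch_synth import Landmark

        lms["D5"] = Landmark(float(a.s[-1]), a.points[-1])   # station at the very end
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            mm.measure_diameters(a.centerline, lms)
        assert any("clipped" in str(w.message) for w in rec)


def test_flat_arch_measures_zero_height():
    # degenerate synthetic centerline lying on the T-line
    s = np.linspace(0, 50, 201)
    pts = np.column_stack([s, np.zeros_like(s), np.zeros_like(s)])
    cl = Centerline(s=s, points=pts, radii=np.full_like(s, 4.0))
    lms = {"ascending_end": np.array([5.0, 0, 0]),
           "descending_mid": np.array([45.0, 0, 0]),
           "brachiocephalic_anterior": np.array([15.0, 0, 0]),
           "lscA_posterior": np.array([35.0, 0, 0])}
    geo = mm.compute_arch_geometry(cl, lms)
    assert geo["height_A"] == 0.0 and geo["at_ratio"] == 0.0
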