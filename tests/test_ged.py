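"""Geometry-based expected dose: closed forms, sub-targets, partitions."""

from __future__ import annotations

import numpy as np
import pytest


from protonkbp.cases import Structure
from protonkbp.ged import (
    GEDParams,
    GEDResult,
    combine_and_smooth,
    compute_ged,
    field_level_ged,
    ged_profile_1d,
    partition_oar,
    trace_ray_intervals,
)
from protonkbp.model import compute_partitions

PARAMS = GEDParams()


class TestRayIntervals:
    def test_convex_run_gives_one_interval(self):
        pos = np.arange(10, dtype=float) * 4.0
        prof = np.zeros(10, dtype=bool)
        prof[3:7] = True
        ivs = trace_ray_intervals(prof, pos)
        assert ivs == [(3 * 4.0 - 2.0, 6 * 4.0 + 2.0)]

    def test_horseshoe_profile_gives_two_intervals(self):
        pos = np.arange(12, dtype=float)
        prof = np.zeros(12, dtype=bool)
        prof[2:4] = True
        prof[8:11] = True
        ivs = trace_ray_intervals(prof, pos)
        assert len(ivs) == 2
        assert ivs[0][1] < ivs[1][0]

    def test_missing_ray_is_empty(self):
        assert trace_ray_intervals(np.zeros(5, dtype=bool), np.arange(5.0)) == []


class TestProfileFormula:
    def test_entry_dose_grows_with_target_length(self):
        d = np.array([-20.0])
        short = ged_profile_1d(d, [(0.0, 20.0)], 70.0, PARAMS)
        long = ged_profile_1d(d, [(0.0, 80.0)], 70.0, PARAMS)
        assert short < long < 70.0

    def test_distal_falloff_is_strictly_decreasing(self):
        t = np.linspace(21.0, 60.0, 40)
        vals = ged_profile_1d(t, [(0.0, 20.0)], 70.0, PARAMS)
        assert np.all(np.diff(vals) < 0)

    def test_distal_value_closed_form(self):
        s = PARAMS.falloff_steepness_mm
        val = ged_profile_1d(np.array([20.0 + 3 * s]), [(0.0, 20.0)], 70.0, PARAMS)
        assert val[0] == pytest.approx(70.0 * np.exp(-3.0), rel=1e-12)

    def test_entry_taper_reaches_zero(self):
        far = -(PARAMS.entry_decay_mm + 10.0)
        assert ged_profile_1d(np.array([far]), [(0.0, 30.0)], 70.0, PARAMS)[0] == 0.0


class TestFieldLevelGED:
    def test_slab_matches_scalar_oracle(self, slab_case):
        """Per-voxel agreement with an independent 1-D implementation."""
        case = slab_case
        raw = field_level_ged(case, case.fields[0], case.targets[0], PARAMS)
        mask = case.targets[0].structure.mask
        ys = case.grid.axis_coords(1)
        h = case.grid.spacing_mm[1]
        rx = case.targets[0].prescription_Gy
        p = PARAMS
        expected = np.zeros(case.grid.dims)
        for i in range(case.grid.dims[0]):
            for k in range(case.grid.dims[2]):
                cols = np.flatnonzero(mask[i, :, k])
                if cols.size == 0:
                    continue
                a, b = ys[cols[0]] - h / 2, ys[cols[-1]] + h / 2
                L = b - a
                r = p.entry_a0 + p.entry_a1 * L / (L + p.entry_L0_mm)
                for j, y in enumerate(ys):
                    if y < a:
                        expected[i, j, k] = rx * r * max(0.0, 1 - (a - y) / p.entry_decay_mm)
                    elif y <= b:
                        expected[i, j, k] = rx
                    else:
                        expected[i, j, k] = rx * np.exp(-(y - b) / p.falloff_steepness_mm)
        assert np.abs(raw - expected).max() < 1e-9

    def test_target_voxels_receive_prescription_exactly(self, phantom_case):
        case = phantom_case
        for lvl in case.targets:
            raw = field_level_ged(case, case.fields[0], lvl, PARAMS)
            assert np.all(raw[lvl.structure.mask] == lvl.prescription_Gy)
            assert raw.max() <= lvl.prescription_Gy + 1e-12

    def test_empty_target_rejected(self, slab_case):
        from protonkbp.cases import TargetLevel

        empty = Structure("ptv_x", np.zeros(slab_case.grid.dims, dtype=bool), role="target")
        lvl = TargetLevel.__new__(TargetLevel)
        lvl.structure = empty
        lvl.prescription_Gy = 70.0
        with pytest.raises(ValueError, match="empty target"):
            field_level_ged(slab_case, slab_case.fields[0], lvl, PARAMS)


class TestSubTargets:
    def test_splitting_never_increases_ged(self, horseshoe_case):
        case = horseshoe_case
        split = field_level_ged(case, case.fields[0], case.targets[0], PARAMS, True)
        merged = field_level_ged(case, case.fields[0], case.targets[0], PARAMS, False)
        assert np.all(split <= merged + 1e-12)

    def test_gap_dose_is_reduced_below_prescription(self, horseshoe_case):
        case = horseshoe_case
        split = field_level_ged(case, case.fields[0], case.targets[0], PARAMS, True)
        merged = field_level_ged(case, case.fields[0], case.targets[0], PARAMS, False)
        mask = case.targets[0].structure.mask
        # gap voxels: central hole of the horseshoe, crossed by the lateral beam
        gap = np.zeros(case.grid.dims, dtype=bool)
        X, Y = np.meshgrid(case.grid.axis_coords(0), case.grid.axis_coords(1), indexing="ij")
        gap[..., 3] = ((np.sqrt(X**2 + Y**2) < 14.0) & (np.abs(Y) < 6.0))[..., None][..., 0]
        gap &= ~mask
        assert gap.any()
        assert np.all(split[gap] < 70.0)
        assert np.all(merged[gap] == pytest.approx(70.0))
        assert split[gap].max() < merged[gap].min() - 1.0


class TestCombineAndSmooth:
    def test_zero_smoothing_is_identity(self, slab_case):
        raw = field_level_ged(slab_case, slab_case.fields[0], slab_case.targets[0], PARAMS)
        params0 = GEDParams(dilation_mm=0.0, gaussian_sigma_mm=0.0)
        res = combine_and_smooth({(0, "ptv_b"): raw}, params0, slab_case.grid)
        assert np.array_equal(res.total_smoothed, res.total_raw)
        assert np.array_equal(res.total_raw, raw)

    def test_duplicate_fields_average_to_single_field(self, slab_case):
        raw = field_level_ged(slab_case, slab_case.fields[0], slab_case.targets[0], PARAMS)
        res = combine_and_smooth({(0, "ptv_b"): raw, (1, "ptv_b"): raw.copy()},
                                 PARAMS, slab_case.grid)
        assert np.allclose(res.total_raw, raw)

    def test_point_source_blur_matches_convolution_oracle(self, slab_case):
        grid = slab_case.grid
        raw = np.zeros(grid.dims)
        raw[10, 12, 4] = 70.0
        params = GEDParams(dilation_mm=0.0, gaussian_sigma_mm=4.0)
        res = combine_and_smooth({(0, "ptv_b"): raw}, params, grid)
        # separable truncated-Gaussian convolution, written out directly
        sig = 4.0 / 4.0
        half = int(4.0 * sig + 0.5)
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sig) ** 2)
        k /= k.sum()
        expected = raw.copy()
        for ax in range(3):
            expected = np.apply_along_axis(
                lambda m: np.convolve(np.pad(m, half, mode="symmetric"), k, "same")[half:-half],
                ax, expected)
        assert np.abs(res.total_smoothed - expected).max() < 1e-9

    def test_smoothing_keeps_max_within_five_percent(self, phantom_case):
        ged = compute_ged(phantom_case, PARAMS)
        assert ged.total_smoothed.max() >= 0.95 * ged.total_raw.max()
        assert ged.total_smoothed.min() >= 0.0

    def test_mismatched_grids_rejected(self, slab_case):
        with pytest.raises(ValueError, match="mismatch"):
            combine_and_smooth({(0, "ptv_b"): np.zeros((2, 2, 2))}, PARAMS, slab_case.grid)


class TestPartition:
    def test_regions_partition_every_phantom_oar(self, phantom_case):
        ged = compute_ged(phantom_case, PARAMS)
        parts = compute_partitions(phantom_case, ged, PARAMS)
        for oar in phantom_case.oars:
            p = parts[oar.name]
            total = (p.overlap_mask.astype(int) + p.in_field_mask.astype(int)
                     + p.out_of_field_mask.astype(int))
            assert np.array_equal(total > 0, oar.mask)
            assert total.max() <= 1
            assert sum(p.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_oar_inside_target_is_pure_overlap(self, phantom_case):
        ged = compute_ged(phantom_case, PARAMS)
        inner = phantom_case.targets[0].structure.mask.copy()
        oar = Structure("embedded", inner)
        part = partition_oar(oar, ged, phantom_case.ptv_comp_mask(), 2.7, 2.7)
        assert part.fractions["overlap"] == pytest.approx(1.0)

    def test_distant_oar_is_out_of_field(self, slab_case):
        ged = compute_ged(slab_case, PARAMS)
        far = np.zeros(slab_case.grid.dims, dtype=bool)
        far[0:2, 0:2, :] = True
        part = partition_oar(Structure("far", far), ged,
                             slab_case.ptv_comp_mask(), 2.7, 2.7)
        assert part.fractions["out_of_field"] == pytest.approx(1.0)

    def test_bad_thresholds_rejected(self, slab_case):
        ged = compute_ged(slab_case, PARAMS)
        m = np.zeros(slab_case.grid.dims, dtype=bool)
        m[0, 0, 0] = True
        with pytest.raises(ValueError):
            partition_oar(Structure("x", m), ged, slab_case.ptv_comp_mask(), 2.0, 3.0)


def test_params_validation():
    with pytest.raises(ValueError):
        GEDParams(falloff_steepness_mm=0.0)
    with pytest.raises(ValueError):
        GEDParams(entry_a0=0.8, entry_a1=0.4)
    with pytest.raises(ValueError):
        GEDParams(tau_in_Gy=1.0, tau_out_Gy=2.0)
    p = GEDParams()
    assert GEDParams.from_dict(p.to_dict()) == p
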