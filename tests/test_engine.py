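"""Toy dose engine: kernels, linearity, optimizer behavior, normalization."""

from __future__ import annotations

import numpy as np
import pytest

from protonkbp.dvh import homogeneity_index, compute_dvh, mean_dose
from protonkbp.engine import (
    EngineParams,
    ManualPlanConfig,
    Planner,
    continue_optimization,
    make_manual_plan,
    manual_objectives,
    manual_oar_priorities,
    normalize_to_mean,
    sobp_depth_profile,
)
from protonkbp.objectives import Objective, ObjectiveSet, standard_target_objectives


@pytest.fixture(scope="module")
def slab_planner(slab_case):
    return Planner(slab_case)


@pytest.fixture(scope="module")
def phantom_planner(phantom_case):
    return Planner(phantom_case)


class TestDoseModel:
    def test_depth_profile_closed_form(self):
        p = EngineParams()
        t = np.array([-40.0, 97.6, 99.0, 100.0, 104.0, 200.0])
        prof = sobp_depth_profile(t, 100.0, p)
        assert prof[0] == p.entry_fraction
        assert prof[1] == 1.0 and prof[2] == 1.0 and prof[3] == 1.0
        assert prof[4] == pytest.approx(np.exp(-4.0 / p.falloff_mm), rel=1e-12)
        assert prof[5] == 0.0  # beyond the distal cutoff

    def test_spacing_rule_follows_fwhm(self):
        p = EngineParams()
        assert p.spot_spacing_mm == pytest.approx(0.425 * 2.355 * 3.9)

    def test_single_spot_depth_dose_matches_1d_profile(self, slab_planner):
        """Along the beam, a single spot's dose is the 1-D SOBP profile times
        a constant lateral factor (divided out here)."""
        planner = slab_planner
        sg = planner.spot_grids[0]
        frame = planner.frames[0]
        zc = planner.case.grid.axis_coords(2)
        j = len(sg) // 2
        w = np.zeros(planner.n_spots)
        w[j] = 1.0
        dose = planner.full_dose(w).ravel()[planner.point_flat]
        ix, iy, iz = planner.point_ixyz.T
        s_p = frame.vox_s[ix, iy]
        t_p = frame.vox_t[ix, iy]
        z_p = zc[iz]
        # the point column nearest the spot axis: constant lateral factor
        lat2 = (s_p - sg.s_mm[j]) ** 2 + (z_p - sg.z_mm[j]) ** 2
        col = (np.abs(s_p - s_p[lat2.argmin()]) < 1e-9) & (np.abs(z_p - z_p[lat2.argmin()]) < 1e-9)
        assert col.sum() >= 3
        lateral = np.exp(-lat2[col] / (2.0 * sg.sigma_mm[j] ** 2))
        expected = sobp_depth_profile(t_p[col], sg.layer_depth_mm[j], planner.params)
        assert np.abs(dose[col] - lateral * expected).max() < 1e-6

    def test_lateral_profile_is_gaussian_with_configured_sigma(self, slab_planner):
        planner = slab_planner
        sg = planner.spot_grids[0]
        frame = planner.frames[0]
        zc = planner.case.grid.axis_coords(2)
        j = len(sg) // 2
        w = np.zeros(planner.n_spots)
        w[j] = 1.0
        dose = planner.full_dose(w).ravel()[planner.point_flat]
        ix, iy, iz = planner.point_ixyz.T
        s_p = frame.vox_s[ix, iy]
        t_p = frame.vox_t[ix, iy]
        z_p = zc[iz]
        # fixed depth inside the flat top; log dose is linear in the squared
        # lateral distance with slope -1/(2 sigma^2)
        R = sg.layer_depth_mm[j]
        sel = (t_p > R - planner.params.layer_spacing_mm) & (t_p <= R) & (dose > 1e-10)
        assert sel.sum() >= 10
        r2 = (s_p[sel] - sg.s_mm[j]) ** 2 + (z_p[sel] - sg.z_mm[j]) ** 2
        A = np.column_stack([np.ones(r2.size), r2])
        coef, *_ = np.linalg.lstsq(A, np.log(dose[sel]), rcond=None)
        sigma_fit = np.sqrt(-1.0 / (2.0 * coef[1]))
        assert sigma_fit == pytest.approx(sg.sigma_mm[j], rel=1e-6)
        assert np.abs(A @ coef - np.log(dose[sel])).max() < 1e-6

    def test_dose_is_linear_in_weights(self, slab_planner):
        rng = np.random.default_rng(0)
        w1 = rng.uniform(0, 1, slab_planner.n_spots)
        w2 = rng.uniform(0, 1, slab_planner.n_spots)
        d12 = slab_planner.full_dose(w1 + w2)
        d1, d2 = slab_planner.full_dose(w1), slab_planner.full_dose(w2)
        assert np.allclose(d12, d1 + d2, rtol=1e-9, atol=1e-9)
        s12 = slab_planner.sampled_dose(w1 + w2)
        assert np.allclose(s12, slab_planner.sampled_dose(w1) + slab_planner.sampled_dose(w2),
                           rtol=1e-4, atol=1e-4)

    def test_doubling_one_weight_doubles_its_contribution(self, slab_planner):
        w = np.zeros(slab_planner.n_spots)
        w[7] = 1.0
        assert np.allclose(slab_planner.full_dose(2 * w), 2 * slab_planner.full_dose(w))

    def test_sampled_and_full_dose_agree_at_sampled_voxels(self, phantom_planner):
        w = phantom_planner.initial_weights()
        full = phantom_planner.full_dose(w).ravel()[phantom_planner.point_flat]
        assert np.abs(full - phantom_planner.sampled_dose(w)).max() < 1e-3


class TestOptimizer:
    def test_target_only_plan_meets_boost_coverage(self, phantom_planner):
        objset = ObjectiveSet(standard_target_objectives(phantom_planner.case))
        plan = phantom_planner.optimize(objset, iterations=40)
        assert plan.metrics["v95_boost"] >= 99.0
        assert plan.metrics["v107_comp"] <= 5.0

    def test_objective_log_is_monotone_non_increasing(self, phantom_planner):
        objset = ObjectiveSet(standard_target_objectives(phantom_planner.case))
        plan = phantom_planner.optimize(objset, iterations=25, finalize=False)
        log = np.array(plan.objective_log)
        assert np.all(np.diff(log) <= 1e-9)

    def test_adding_oar_objective_does_not_raise_its_mean(self, phantom_planner):
        case = phantom_planner.case
        oar = next(s for s in case.oars if s.name == "parotid_l")
        base = ObjectiveSet(standard_target_objectives(case))
        with_oar = ObjectiveSet(base.objectives
                                + [Objective("parotid_l@spared", "mean_dose", 0.0, 2.0)])
        p1 = phantom_planner.optimize(base, iterations=25)
        p2 = phantom_planner.optimize(with_oar, iterations=25)
        assert mean_dose(p2.dose.values, oar.mask) <= mean_dose(p1.dose.values, oar.mask) + 1e-6

    def test_optimizer_is_deterministic(self, phantom_planner):
        objset = ObjectiveSet(standard_target_objectives(phantom_planner.case))
        a = phantom_planner.optimize(objset, iterations=15, finalize=False)
        b = phantom_planner.optimize(objset, iterations=15, finalize=False)
        assert np.array_equal(a.weights, b.weights)
        assert a.objective_log == b.objective_log


class TestContinueOptimization:
    def test_converged_plan_is_returned_unchanged(self, phantom_planner):
        objset = ObjectiveSet(standard_target_objectives(phantom_planner.case))
        plan = phantom_planner.optimize(objset, iterations=40)
        if not plan.converged:
            pytest.skip("target-only plan unexpectedly missed the aims")
        cont = continue_optimization(phantom_planner, plan, objset)
        assert cont is plan

    def test_escalation_one_equals_plain_rerun(self, phantom_planner):
        objset = ObjectiveSet(standard_target_objectives(phantom_planner.case))
        short = phantom_planner.optimize(objset, iterations=4, finalize=False)
        short.converged = False  # force the continuation branch
        cont = continue_optimization(phantom_planner, short, objset,
                                     escalation=1.0, iterations=10, finalize=False)
        plain = phantom_planner.optimize(objset, iterations=10, w0=short.weights,
                                         finalize=False)
        assert np.array_equal(cont.weights, plain.weights)

    def test_continuation_does_not_lose_coverage(self, phantom_planner):
        case = phantom_planner.case
        # a deliberately under-optimized plan with strong OAR pull
        priorities = {s.name: 3.0 for s in case.oars if s.name != "spinal_cord"}
        objset = manual_objectives(case, priorities, ManualPlanConfig())
        plan = phantom_planner.optimize(objset, iterations=8, finalize=False)
        v_before = plan.metrics["v95_boost"]
        cont = continue_optimization(phantom_planner, plan, objset,
                                     iterations=25, finalize=False)
        assert cont.metrics["v95_boost"] >= v_before - 1e-9


class TestNormalization:
    def test_mean_matches_reference_exactly(self, phantom_planner):
        objset = ObjectiveSet(standard_target_objectives(phantom_planner.case))
        plan = phantom_planner.optimize(objset, iterations=20)
        boost = phantom_planner.case.targets[0].structure.mask
        ref = 70.0
        normed = normalize_to_mean(phantom_planner, plan, boost, ref)
        assert mean_dose(normed.dose.values, boost) == pytest.approx(ref, abs=1e-9)

    def test_idempotent_and_hi_invariant(self, phantom_planner):
        objset = ObjectiveSet(standard_target_objectives(phantom_planner.case))
        plan = phantom_planner.optimize(objset, iterations=20)
        boost = phantom_planner.case.targets[0].structure.mask
        n1 = normalize_to_mean(phantom_planner, plan, boost, 69.0)
        n2 = normalize_to_mean(phantom_planner, n1, boost, 69.0)
        assert np.allclose(n1.dose.values, n2.dose.values, atol=1e-12)
        hi0 = homogeneity_index(compute_dvh(plan.dose.values, boost))
        hi1 = homogeneity_index(compute_dvh(n1.dose.values, boost))
        assert hi0 == pytest.approx(hi1, abs=0.05)

    def test_zero_reference_rejected(self, phantom_planner):
        objset = ObjectiveSet(standard_target_objectives(phantom_planner.case))
        plan = phantom_planner.optimize(objset, iterations=2)
        with pytest.raises(ValueError):
            normalize_to_mean(phantom_planner, plan,
                              phantom_planner.case.targets[0].structure.mask, 0.0)


class TestManualPlans:
    def test_same_case_and_seed_reproduce_identically(self, phantom_case, phantom_planner):
        cfg = ManualPlanConfig(seed=5, iterations=10, continue_iterations=5)
        a = make_manual_plan(phantom_case, cfg, planner=phantom_planner)
        b = make_manual_plan(phantom_case, cfg, planner=phantom_planner)
        assert np.array_equal(a.weights, b.weights)
        assert a.info["skill"] == b.info["skill"]

    def test_zero_skill_disables_oar_objectives(self, phantom_case):
        cfg = ManualPlanConfig(seed=5, skill_range=(0.0, 0.0))
        priorities, skill = manual_oar_priorities(phantom_case, cfg)
        objset = manual_objectives(phantom_case, {}, cfg)
        kinds = {o.kind for o in objset.objectives}
        assert "mean_dose" not in kinds

    def test_skill_scales_priorities(self, phantom_case):
        p1, s1 = manual_oar_priorities(phantom_case, ManualPlanConfig(seed=1))
        p2, s2 = manual_oar_priorities(phantom_case, ManualPlanConfig(seed=2))
        assert s1 != s2
        assert set(p1) == set(p2)
        assert 0.6 <= s1 <= 1.0
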