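"""PCA parameterization, regression recovery, training, bands, curation."""

from __future__ import annotations

import numpy as np
import pytest

from protonkbp.cases import model_key
from protonkbp.ged import GEDParams, compute_ged
from protonkbp.model import (
    VOLUME_GRID,
    curate_outliers,
    compute_partitions,
    extract_features,
    fit_pca,
    linear_regression,
    load_model,
    predict,
    save_model,
    train,
)
from protonkbp.phantoms import CohortSpec, generate_case


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestPCA:
    def test_identical_curves_have_zero_scores(self):
        curves = np.tile(np.linspace(1, 0, 50), (8, 1))
        res = fit_pca(curves)
        assert np.allclose(res.scores, 0.0)
        assert np.allclose(res.mean, curves[0])

    def test_rank_two_family_reconstructs_exactly(self):
        rng = np.random.default_rng(0)
        m = 60
        base = np.linspace(1, 0, m)
        c1 = np.sin(np.linspace(0, np.pi, m))
        c2 = np.cos(np.linspace(0, 2 * np.pi, m))
        coeffs = rng.normal(size=(25, 2))
        curves = base + coeffs @ np.vstack([c1, c2])
        res = fit_pca(curves, n_components=2)
        recon = res.reconstruct(res.scores)
        assert np.abs(recon - curves).max() < 1e-9

    def test_components_are_orthonormal(self):
        rng = np.random.default_rng(1)
        curves = rng.normal(size=(30, 40)).cumsum(axis=1)
        res = fit_pca(curves, n_components=4)
        gram = res.components @ res.components.T
        assert np.allclose(gram, np.eye(res.n_components), atol=1e-10)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)

    def test_too_many_components_rejected(self):
        curves = np.random.default_rng(2).normal(size=(5, 20))
        with pytest.raises(ValueError):
            fit_pca(curves, n_components=5)

    def test_projection_matches_training_scores(self):
        rng = np.random.default_rng(3)
        curves = rng.normal(size=(20, 30)).cumsum(axis=1)
        res = fit_pca(curves, n_components=3)
        assert np.allclose(res.project(curves), res.scores, atol=1e-9)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------


class TestLinearRegression:
    def test_exact_linear_map_gives_unit_r_squared(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        Y = X @ np.array([[2.0], [-1.0], [0.5]]) + 3.0
        fit = linear_regression(X, Y)
        assert fit.r_squared[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(fit.coef[:, 0], [2.0, -1.0, 0.5], atol=1e-9)

    def test_noisy_recovery_within_three_standard_errors(self):
        hits = total = 0
        truth = np.array([2.0, -1.5, 0.7])
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            X = rng.normal(size=(50, 3))
            Y = (X @ truth + rng.normal(0, 1.0, 50))[:, None]
            fit = linear_regression(X, Y)
            hits += int(np.sum(np.abs(fit.coef[:, 0] - truth) <= 3 * fit.coef_se[:, 0]))
            total += 3
        assert hits / total >= 0.95

    def test_mean_r_squared_matches_analytic_value(self):
        # R^2 = b^2 var(x) / (b^2 var(x) + sigma^2) = 0.8 for b=2, sigma=1
        r2 = []
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            x = rng.normal(size=(50, 1))
            y = 2.0 * x[:, 0] + rng.normal(0, 1.0, 50)
            r2.append(float(linear_regression(x, y[:, None]).r_squared[0]))
        assert np.mean(r2) == pytest.approx(0.8, abs=0.05)

    def test_shuffled_labels_have_near_zero_r_squared(self):
        vals = []
        for rep in range(20):
            rng = np.random.default_rng(300 + rep)
            x = rng.normal(size=(50, 1))
            y = 2.0 * x[:, 0] + rng.normal(0, 0.5, 50)
            y = y[rng.permutation(50)]
            vals.append(float(linear_regression(x, y[:, None]).r_squared[0]))
        assert np.mean(vals) < 0.15
        assert max(vals) < 0.35


# ---------------------------------------------------------------------------
# training on a synthetic GED-driven library (no dose engine needed)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def ged_library():
    """Small library whose 'achieved' dose is a noisy affine map of the GED,
    so dose features are linearly predictable from geometry by construction."""
    spec = CohortSpec(n_cases=18, seed=21, spacing_mm=4.0)
    params = GEDParams()
    library, geds = [], []
    for i in range(spec.n_cases):
        case, _ = generate_case(spec, i)
        ged = compute_ged(case, params)
        rng = np.random.default_rng(500 + i)
        factor = rng.uniform(0.75, 0.95)
        dose = factor * ged.total_smoothed + rng.normal(0.0, 0.4, case.grid.dims).clip(-1, 1)
        library.append((case, np.clip(dose, 0.0, None)))
        geds.append(ged)
    return library, geds, params


@pytest.fixture(scope="module")
def ged_model(ged_library):
    library, geds, params = ged_library
    return train(library, params, min_train=10, geds=geds)


class TestTraining:
    def test_model_covers_recurring_oars(self, ged_model):
        assert len(ged_model.oar_models) >= 5
        for om in ged_model.oar_models.values():
            assert om.n_train >= 10
            assert 0.0 <= om.r_squared <= 1.0

    def test_dose_tracks_geometry_with_high_r_squared(self, ged_model):
        r2 = [om.r_squared for om in ged_model.oar_models.values()]
        assert np.median(r2) > 0.7

    def test_duplicate_case_yields_identical_features(self, ged_library):
        library, geds, params = ged_library
        case, dose = library[0]
        parts = compute_partitions(case, geds[0], params)
        f1 = extract_features(case, dose, geds[0], parts, 70.0, np.arange(0, 77.5, 0.5))
        f2 = extract_features(case, dose, geds[0], parts, 70.0, np.arange(0, 77.5, 0.5))
        for key in f1:
            g1, d1 = f1[key]
            g2, d2 = f2[key]
            assert g1.scalars == g2.scalars
            if g1.ged_curve is not None:
                assert np.array_equal(g1.ged_curve, g2.ged_curve)
                assert np.array_equal(d1.dose_curve, d2.dose_curve)

    def test_overlap_fraction_of_constructed_mask(self, ged_library):
        library, geds, params = ged_library
        case, dose = library[0]
        parts = compute_partitions(case, geds[0], params)
        comp = case.ptv_comp_mask()
        inside = np.argwhere(comp)
        outside = np.argwhere(~comp & (geds[0].total_smoothed < 1.0))
        half = np.zeros(case.grid.dims, dtype=bool)
        half[tuple(inside[:40].T)] = True
        half[tuple(outside[:40].T)] = True
        from protonkbp.cases import Structure
        from protonkbp.ged import partition_oar

        part = partition_oar(Structure("half", half), geds[0], comp, 2.7, 2.7)
        assert part.fractions["overlap"] == pytest.approx(0.5, abs=0.01)

    def test_insufficient_matches_skip_oar(self, ged_library):
        library, geds, params = ged_library
        model = train(library[:4], params, min_train=20, geds=geds[:4])
        assert model.oar_models == {}
        assert model.provenance["skipped_oars"]


class TestPrediction:
    def test_bands_are_valid_dvhs(self, ged_model, ged_library):
        library, geds, _ = ged_library
        case, _ = library[1]
        bands = predict(ged_model, case, ged=geds[1])
        assert bands
        for band in bands.values():
            for curve in (band.lower, band.median, band.upper):
                vf = curve.volume_fraction
                assert np.all(vf >= -1e-12) and np.all(vf <= 1.0 + 1e-12)
                assert np.all(np.diff(vf) <= 1e-9)
            assert np.all(band.lower.volume_fraction <= band.median.volume_fraction + 1e-9)
            assert np.all(band.median.volume_fraction <= band.upper.volume_fraction + 1e-9)

    def test_training_case_dvh_lies_inside_its_own_band(self, ged_model, ged_library):
        """Self-consistency: the achieved in-field DVH of training cases falls
        within the +/-1 SD band for most volume points and most OARs."""
        library, geds, params = ged_library
        good = total = 0
        for (case, dose), ged in zip(library[:6], geds[:6]):
            bands = predict(ged_model, case, ged=ged)
            for oar in case.oars:
                key = model_key(oar)
                if key not in bands:
                    continue
                from protonkbp.dvh import compute_dvh, volume_at_dose

                dvh = compute_dvh(dose, oar.mask)
                grid_d = bands[key].median.dose_edges_Gy
                ach = np.array([volume_at_dose(dvh, d) / 100 for d in grid_d])
                lo = bands[key].lower.volume_fraction - 0.02
                hi = bands[key].upper.volume_fraction + 0.02
                frac_inside = np.mean((ach >= lo) & (ach <= hi))
                total += 1
                good += int(frac_inside >= 0.6)
        assert total >= 20
        assert good / total >= 0.8

    def test_small_volume_triggers_geometric_outlier_flag(self, ged_model, ged_library):
        library, geds, _ = ged_library
        case, _ = library[2]
        # shrink one modeled OAR to a couple of voxels, far below any
        # training volume
        target_key, om = next(iter(ged_model.oar_models.items()))
        oar = next(s for s in case.oars if model_key(s) == target_key)
        keep = np.argwhere(oar.mask)[:2]
        oar.mask[:] = False
        oar.mask[tuple(keep.T)] = True
        bands = predict(ged_model, case)
        assert "volume-out-of-range" in bands[target_key].outlier_flags

    def test_zero_residual_model_collapses_the_band(self, ged_model, ged_library):
        library, geds, _ = ged_library
        import copy

        model = copy.deepcopy(ged_model)
        for om in model.oar_models.values():
            om.residual_sd[:] = 0.0
            for band in om.low_mod_bands.values():
                band["sd"] = np.zeros_like(band["sd"])
        case, _ = library[3]
        bands = predict(model, case, ged=geds[3])
        for band in bands.values():
            assert np.allclose(band.lower.volume_fraction, band.median.volume_fraction,
                               atol=1e-9)
            assert np.allclose(band.upper.volume_fraction, band.median.volume_fraction,
                               atol=1e-9)

    def test_unmatched_oar_names_are_skipped(self, ged_model, ged_library):
        library, geds, _ = ged_library
        case, _ = library[4]
        for s in case.oars:
            s.name = f"renamed_{s.name}"
        bands = predict(ged_model, case, ged=geds[4])
        assert bands == {}


class TestCuration:
    def test_clean_library_flag_rate_is_at_noise_level(self, ged_model):
        """A clean library should only produce the ~0.3% false-positive rate
        expected of a 3-sigma studentized-residual threshold."""
        flags = [f for f in curate_outliers(ged_model)
                 if f["reason"] == "studentized-residual"]
        n_points = sum(om.n_train for om in ged_model.oar_models.values())
        assert len(flags) <= max(0.03 * n_points, 3)

    def test_corrupted_plan_is_flagged(self, ged_library):
        library, geds, params = ged_library
        corrupted = [(c, d.copy()) for c, d in library]
        case, dose = corrupted[5]
        corrupted[5] = (case, dose * 2.0)  # doubled dose: a bad library plan
        model = train(corrupted, params, min_train=10, geds=geds)
        flagged_cases = {f["case_id"] for f in curate_outliers(model)
                         if f["reason"] == "studentized-residual"}
        assert case.id in flagged_cases

    def test_infinite_thresholds_flag_nothing(self, ged_model):
        assert curate_outliers(ged_model, resid_threshold=np.inf,
                               leverage_factor=np.inf) == []


def test_model_archive_round_trip(ged_model, ged_library, tmp_path):
    library, geds, _ = ged_library
    save_model(ged_model, tmp_path / "model")
    back = load_model(tmp_path / "model")
    assert set(back.oar_models) == set(ged_model.oar_models)
    for key, om in ged_model.oar_models.items():
        bm = back.oar_models[key]
        assert bm.n_train == om.n_train
        assert bm.r_squared == pytest.approx(om.r_squared)
        assert np.allclose(bm.fit.coef, om.fit.coef)
        assert np.allclose(bm.dose_pca.components, om.dose_pca.components)
    case, _ = library[1]
    b1 = predict(ged_model, case, ged=geds[1])
    b2 = predict(back, case, ged=geds[1])
    for key in b1:
        assert np.allclose(b1[key].median.volume_fraction, b2[key].median.volume_fraction)
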