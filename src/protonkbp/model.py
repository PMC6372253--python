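"""Knowledge-based DVH prediction: extraction, training and prediction.

Extraction parameterizes every library plan per organ at risk: the achieved
in-field DVH and the in-field GED DVH are each sampled as dose-at-volume
curves on a fixed 100-point volume grid (dose normalized to the boost
prescription) and summarized by principal components, alongside scalar
geometry features (OAR volume, OAR-PTV overlap fraction, out-of-field
fraction, target volume). Training regresses the dose PC scores on the
geometric features with ordinary least squares on standardized features
(ridge fallback for ill-conditioned designs) and stores per-PC residual
SDs, the dose-PC1 R², the scalar training ranges, and mean ± SD
volume-at-dose bands for the low-modulation regions (target overlap,
out-of-field).

Prediction reconstructs the median in-field DVH from the regressed scores;
the band half-width is the quadrature sum of the per-PC residual SDs
propagated through the component curves (equal to the ±1 SD reconstruction
spread for a single component, and guaranteeing lower <= median <= upper).
Region curves are merged volume-weighted into a whole-organ cumulative DVH,
projected to monotone non-increasing. Scalar features outside the training
ranges raise geometric-outlier flags (extrapolation warnings).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .cases import Case, Structure, model_key
from .dvh import DVHCurve
from .ged import GEDParams, GEDResult, OARPartition, compute_ged, partition_oar
from .phantoms import SERIAL_STRUCTURES

__all__ = [
    "VOLUME_GRID",
    "PCAResult",
    "LinearFit",
    "GeometricFeatures",
    "DoseFeatures",
    "OARModel",
    "KBModel",
    "PredictionBand",
    "fit_pca",
    "linear_regression",
    "extract_features",
    "train",
    "predict",
    "curate_outliers",
    "save_model",
    "load_model",
]

VOLUME_GRID = np.linspace(0.005, 0.995, 100)  # volume fractions for DVH sampling
SCALAR_FEATURES = ("oar_volume_cm3", "overlap_fraction", "out_of_field_fraction",
                   "target_volume_cm3")
REGIONS = ("overlap", "out_of_field")


# ---------------------------------------------------------------------------
# parameterization primitives
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    mean: np.ndarray
    components: np.ndarray          # (k, m), orthonormal rows
    scores: np.ndarray              # (n, k) projections of the training curves
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def project(self, curves: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(curves) - self.mean) @ self.components.T

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        return self.mean + np.atleast_2d(scores) @ self.components


def fit_pca(curves: np.ndarray, n_components: int | None = None,
            var_threshold: float = 0.95, cap: int = 5) -> PCAResult:
    """PCA of sampled DVH curves.

    With ``n_components=None`` the smallest k explaining at least
    ``var_threshold`` of the variance is kept, capped at ``cap``. Requesting
    more components than n_curves - 1 is an error.
    """
    curves = np.asarray(curves, dtype=float)
    n, m = curves.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 curves")
    if n_components is not None and n_components > n - 1:
        raise ValueError(f"n_components={n_components} exceeds n_curves-1={n - 1}")
    mean = curves.mean(axis=0)
    centered = curves - mean
    total_var = float((centered ** 2).sum()) / (n - 1)
    if total_var < 1e-24:  # identical curves: one arbitrary component, zero scores
        comp = np.zeros((1, m))
        comp[0, 0] = 1.0
        return PCAResult(mean, comp, np.zeros((n, 1)), np.array([1.0]))
    k_max = min(n - 1, m) if n_components is None else n_components
    pca = PCA(n_components=k_max)
    scores = pca.fit_transform(curves)
    if n_components is None:
        ratios = pca.explained_variance_ratio_
        k = int(np.searchsorted(np.cumsum(ratios), var_threshold) + 1)
        k = min(max(k, 1), cap, k_max)
    else:
        k = n_components
    return PCAResult(mean, pca.components_[:k].copy(), scores[:, :k].copy(),
                     pca.explained_variance_ratio_[:k].copy())


@dataclass
class LinearFit:
    """OLS (or ridge-stabilized) multi-response linear fit with diagnostics."""

    coef: np.ndarray        # (p, k) slopes
    intercept: np.ndarray   # (k,)
    fitted: np.ndarray      # (n, k)
    residuals: np.ndarray   # (n, k)
    residual_sd: np.ndarray  # (k,)
    r_squared: np.ndarray   # (k,) per response column
    coef_se: np.ndarray     # (p, k) standard errors of the slopes
    leverage: np.ndarray    # (n,) hat-matrix diagonal

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.coef + self.intercept


def linear_regression(X: np.ndarray, Y: np.ndarray,
                      ridge_condition: float = 1e8) -> LinearFit:
    """Least-squares fit of responses ``Y`` (n, k) on features ``X`` (n, p)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    X1 = np.column_stack([np.ones(n), X])
    gram = X1.T @ X1
    if np.linalg.cond(gram) > ridge_condition:
        lam = 1e-8 * np.trace(gram) / gram.shape[0]
        gram = gram + lam * np.eye(gram.shape[0])
    gram_inv = np.linalg.inv(gram)
    beta = gram_inv @ X1.T @ Y
    fitted = X1 @ beta
    resid = Y - fitted
    dof = max(n - p - 1, 1)
    sigma2 = (resid ** 2).sum(axis=0) / dof
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - (resid ** 2).sum(axis=0) / ss_tot, 0.0)
    coef_se = np.sqrt(np.outer(np.diag(gram_inv)[1:], sigma2))
    leverage = np.einsum("ij,jk,ik->i", X1, gram_inv, X1)
    return LinearFit(beta[1:], beta[0], fitted, resid, np.sqrt(sigma2), r2,
                     coef_se, leverage)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


@dataclass
class GeometricFeatures:
    ged_curve: np.ndarray | None      # in-field GED DVH (dose-at-volume, normalized)
    scalars: dict[str, float]
    low_mod_only: bool
    ged_dvh_pc_scores: np.ndarray | None = None  # filled once a model exists


@dataclass
class DoseFeatures:
    dose_curve: np.ndarray | None     # in-field achieved DVH (dose-at-volume, normalized)
    region_vf: dict[str, np.ndarray]  # volume-at-dose per low-modulation region
    dvh_pc_scores: np.ndarray | None = None


def _dose_at_volume_curve(values: np.ndarray, norm_Gy: float) -> np.ndarray:
    """Sample dose-at-volume on the fixed 100-point volume grid, normalized."""
    return np.quantile(values, 1.0 - VOLUME_GRID) / norm_Gy


def _volume_at_dose_curve(values: np.ndarray, dose_grid_Gy: np.ndarray) -> np.ndarray:
    vals = np.sort(values)
    return 1.0 - np.searchsorted(vals, dose_grid_Gy, side="left") / vals.size


def _case_scalars(case: Case, oar: Structure, part: OARPartition) -> dict[str, float]:
    return {
        "oar_volume_cm3": oar.volume_cm3(case.grid),
        "overlap_fraction": part.fractions["overlap"],
        "out_of_field_fraction": part.fractions["out_of_field"],
        "target_volume_cm3": float(case.ptv_comp_mask().sum()) * case.grid.voxel_volume_cm3,
    }


def extract_features(
    case: Case,
    plan_dose: np.ndarray | None,
    ged: GEDResult,
    partitions: Mapping[str, OARPartition],
    norm_Gy: float,
    dose_grid_Gy: np.ndarray,
) -> dict[str, tuple[GeometricFeatures, DoseFeatures]]:
    """Per-OAR geometry and dosimetry parameterization of one (case, plan).

    ``plan_dose`` may be None at prediction time (geometry only). OARs whose
    in-field region is empty are marked low-modulation-only and contribute
    no PC curves. Serial structures are excluded from modeling.
    """
    out: dict[str, tuple[GeometricFeatures, DoseFeatures]] = {}
    for oar in case.oars:
        if oar.role != "oar" or oar.name in SERIAL_STRUCTURES:
            continue
        key = model_key(oar)
        part = partitions[oar.name]
        scalars = _case_scalars(case, oar, part)
        in_field = part.in_field_mask
        low_mod_only = not in_field.any()
        geo_curve = None if low_mod_only else _dose_at_volume_curve(
            ged.total_smoothed[in_field], norm_Gy)
        dose_curve = None
        region_vf: dict[str, np.ndarray] = {}
        if plan_dose is not None:
            if not low_mod_only:
                dose_curve = _dose_at_volume_curve(plan_dose[in_field], norm_Gy)
            for region, mask in (("overlap", part.overlap_mask),
                                 ("out_of_field", part.out_of_field_mask)):
                if mask.any():
                    region_vf[region] = _volume_at_dose_curve(plan_dose[mask], dose_grid_Gy)
        out[key] = (GeometricFeatures(geo_curve, scalars, low_mod_only),
                    DoseFeatures(dose_curve, region_vf))
    return out


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclass
class OARModel:
    key: str
    n_train: int
    case_ids: list[str]
    dose_pca: PCAResult
    geo_pca: PCAResult
    scalar_names: tuple[str, ...]
    scalar_mean: np.ndarray
    scalar_std: np.ndarray
    fit: LinearFit
    residual_sd: np.ndarray
    r_squared: float
    training_ranges: dict[str, tuple[float, float]]
    low_mod_bands: dict[str, dict[str, np.ndarray | int]]
    X_std: np.ndarray
    Y: np.ndarray


@dataclass
class KBModel:
    oar_models: dict[str, OARModel]
    ged_params: GEDParams
    norm_Gy: float
    dose_grid_Gy: np.ndarray
    min_train: int
    provenance: dict = dc_field(default_factory=dict)


@dataclass
class PredictionBand:
    oar: str
    lower: DVHCurve
    median: DVHCurve
    upper: DVHCurve
    outlier_flags: list[str]
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        if np.any(self.lower.volume_fraction > self.median.volume_fraction + 1e-9):
            raise ValueError("prediction band lower bound exceeds median")
        if np.any(self.median.volume_fraction > self.upper.volume_fraction + 1e-9):
            raise ValueError("prediction band median exceeds upper bound")

    def predicted_mean_Gy(self) -> float:
        return self.median.mean_dose_Gy()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def compute_partitions(case: Case, ged: GEDResult, params: GEDParams) -> dict[str, OARPartition]:
    tau_in, tau_out = params.resolve_taus(case)
    targets_mask = case.ptv_comp_mask()
    return {
        oar.name: partition_oar(oar, ged, targets_mask, tau_in, tau_out)
        for oar in case.oars
        if oar.role == "oar"
    }


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    return (X - mu) / sd, mu, sd


def train(
    library: Sequence[tuple[Case, np.ndarray]],
    ged_params: GEDParams | None = None,
    min_train: int = 20,
    n_components: int | None = None,
    geds: Sequence[GEDResult] | None = None,
    provenance: Mapping | None = None,
) -> KBModel:
    """Train per-OAR DVH-prediction models from a plan library.

    ``library`` pairs each case with its achieved dose grid. OARs matched by
    fewer than ``min_train`` cases are skipped with a warning recorded in
    the provenance. R² is reported for the dose-PC1 regression.
    """
    if not library:
        raise ValueError("empty library")
    ged_params = ged_params or GEDParams()
    norm_Gy = max(lvl.prescription_Gy for lvl in library[0][0].targets)
    dose_grid_Gy = np.arange(0.0, 1.1 * norm_Gy + 0.5, 0.5)

    acc: dict[str, dict[str, list]] = {}
    for i, (case, dose) in enumerate(library):
        ged = geds[i] if geds is not None else compute_ged(case, ged_params)
        partitions = compute_partitions(case, ged, ged_params)
        feats = extract_features(case, dose, ged, partitions, norm_Gy, dose_grid_Gy)
        for key, (geo, dosef) in feats.items():
            slot = acc.setdefault(key, {"geo": [], "dose": [], "scalars": [],
                                        "ids": [], "regions": {r: [] for r in REGIONS}})
            for region, vf in dosef.region_vf.items():
                slot["regions"][region].append(vf)
            if geo.low_mod_only or dosef.dose_curve is None:
                continue
            slot["geo"].append(geo.ged_curve)
            slot["dose"].append(dosef.dose_curve)
            slot["scalars"].append([geo.scalars[k] for k in SCALAR_FEATURES])
            slot["ids"].append(case.id)

    oar_models: dict[str, OARModel] = {}
    skipped: list[str] = []
    for key, slot in sorted(acc.items()):
        n = len(slot["ids"])
        if n < min_train:
            skipped.append(f"{key} (matched {n} < {min_train})")
            continue
        geo_curves = np.asarray(slot["geo"])
        dose_curves = np.asarray(slot["dose"])
        scalars = np.asarray(slot["scalars"], dtype=float)
        geo_pca = fit_pca(geo_curves, n_components)
        dose_pca = fit_pca(dose_curves, n_components)
        X_raw = np.column_stack([geo_pca.scores, scalars])
        X_std, mu, sd = _standardize(X_raw)
        fit = linear_regression(X_std, dose_pca.scores)
        bands: dict[str, dict] = {}
        for region, curves in slot["regions"].items():
            if curves:
                arr = np.asarray(curves)
                bands[region] = {"mean": arr.mean(axis=0),
                                 "sd": arr.std(axis=0),
                                 "n": len(curves)}
        ranges = {
            name: (float(scalars[:, j].min()), float(scalars[:, j].max()))
            for j, name in enumerate(SCALAR_FEATURES)
        }
        oar_models[key] = OARModel(
            key=key, n_train=n, case_ids=list(slot["ids"]),
            dose_pca=dose_pca, geo_pca=geo_pca,
            scalar_names=SCALAR_FEATURES,
            scalar_mean=mu, scalar_std=sd, fit=fit,
            residual_sd=fit.residual_sd.copy(),
            r_squared=float(fit.r_squared[0]),
            training_ranges=ranges, low_mod_bands=bands,
            X_std=X_std, Y=dose_pca.scores.copy(),
        )
    prov = dict(provenance or {})
    prov["n_library"] = len(library)
    prov["skipped_oars"] = skipped
    return KBModel(oar_models, ged_params, norm_Gy, dose_grid_Gy, min_train, prov)


# ---------------------------------------------------------------------------
# outlier curation
# ---------------------------------------------------------------------------


def curate_outliers(model: KBModel, resid_threshold: float = 3.0,
                    leverage_factor: float = 3.0) -> list[dict]:
    """Flag training points that deviate from the bulk of the population.

    A point is flagged when its dose-PC1 studentized residual exceeds
    ``resid_threshold`` in magnitude or its leverage exceeds
    ``leverage_factor * (p + 1) / n``. Removal is a user action, not
    automatic.
    """
    flags: list[dict] = []
    for key, om in model.oar_models.items():
        n, p = om.X_std.shape
        sd1 = om.residual_sd[0]
        # a residual SD at numerical-noise level (saturated fit, n ~ p)
        # carries no outlier information
        sd_floor = 1e-8 * (float(om.Y[:, 0].std()) + 1e-12)
        lev_cut = leverage_factor * (p + 1) / n
        for i in range(n):
            h = min(float(om.fit.leverage[i]), 1.0 - 1e-9)
            if sd1 > sd_floor:
                stud = om.fit.residuals[i, 0] / (sd1 * np.sqrt(1.0 - h))
                if abs(stud) > resid_threshold:
                    flags.append({"oar": key, "case_id": om.case_ids[i],
                                  "reason": "studentized-residual",
                                  "value": float(stud)})
            if om.fit.leverage[i] > lev_cut:
                flags.append({"oar": key, "case_id": om.case_ids[i],
                              "reason": "leverage", "value": float(om.fit.leverage[i])})
    return flags


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def _curve_dose_to_volume(dose_at_v: np.ndarray, dose_grid: np.ndarray) -> np.ndarray:
    """Convert a non-increasing dose-at-volume curve to volume-at-dose."""
    d_rev = dose_at_v[::-1]
    v_rev = VOLUME_GRID[::-1]
    return np.interp(dose_grid, d_rev, v_rev, left=1.0, right=0.0)


def _monotone_dvh(vf: np.ndarray) -> np.ndarray:
    vf = np.clip(vf, 0.0, 1.0)
    vf = np.minimum.accumulate(vf)
    return vf


def _region_band(om: OARModel, region: str, sign: int, model: KBModel) -> np.ndarray:
    band = om.low_mod_bands.get(region)
    if band is None:
        # fallback for a region never seen in training: overlap is
        # target-like (full volume up to the norm dose), out-of-field cold
        if region == "overlap":
            return (model.dose_grid_Gy <= model.norm_Gy).astype(float)
        return (model.dose_grid_Gy <= 0.0).astype(float)
    return np.clip(band["mean"] + sign * band["sd"], 0.0, 1.0)


def predict(model: KBModel, case: Case, ged: GEDResult | None = None,
            band_multiplier: float = 1.0) -> dict[str, PredictionBand]:
    """Per-OAR DVH prediction bands for a prospective case.

    The GED must be computed with the model's parameter snapshot (done
    internally unless supplied). OARs whose names do not map to a model
    structure are skipped. Scalar features outside the training ranges are
    flagged as geometric outliers.
    """
    if ged is None:
        ged = compute_ged(case, model.ged_params)
    partitions = compute_partitions(case, ged, model.ged_params)
    feats = extract_features(case, None, ged, partitions, model.norm_Gy,
                             model.dose_grid_Gy)
    bands: dict[str, PredictionBand] = {}
    for key, (geo, _) in feats.items():
        om = model.oar_models.get(key)
        if om is None:
            continue
        flags = []
        for j, name in enumerate(om.scalar_names):
            lo, hi = om.training_ranges[name]
            v = geo.scalars[name]
            if v < lo - 1e-9 or v > hi + 1e-9:
                label = "volume" if name == "oar_volume_cm3" else name.replace("_", "-")
                flags.append(f"{label}-out-of-range")
        oar_struct = next(s for s in case.oars if model_key(s) == key)
        frac = partitions[oar_struct.name].fractions

        grid_d = model.dose_grid_Gy
        if geo.low_mod_only:
            v_in = {s: np.zeros_like(grid_d) for s in (-1, 0, 1)}
        else:
            geo_scores = om.geo_pca.project(geo.ged_curve)[0]
            x = np.concatenate([geo_scores, [geo.scalars[k] for k in SCALAR_FEATURES]])
            x_std = (x - om.scalar_mean) / om.scalar_std
            y_hat = om.fit.predict(x_std)[0]
            median_dv = om.dose_pca.reconstruct(y_hat)[0]
            hw = np.sqrt(((om.residual_sd[:, None] * om.dose_pca.components) ** 2).sum(axis=0))
            v_in = {}
            for sign in (-1, 0, 1):
                dv = np.clip(median_dv + sign * band_multiplier * hw, 0.0, None)
                dv = np.minimum.accumulate(dv)  # enforce non-increasing in volume
                v_in[sign] = _curve_dose_to_volume(dv * model.norm_Gy, grid_d)

        curves = {}
        for sign, name in ((-1, "lower"), (0, "median"), (1, "upper")):
            vf = (frac["in_field"] * v_in[sign]
                  + frac["overlap"] * _region_band(om, "overlap", sign, model)
                  + frac["out_of_field"] * _region_band(om, "out_of_field", sign, model))
            curves[name] = _monotone_dvh(vf)
        lower = np.minimum(curves["lower"], curves["median"])
        upper = np.maximum(curves["upper"], curves["median"])
        bands[key] = PredictionBand(
            key,
            DVHCurve(grid_d, lower),
            DVHCurve(grid_d, curves["median"]),
            DVHCurve(grid_d, upper),
            flags,
            dict(frac),
        )
    return bands


# ---------------------------------------------------------------------------
# model archive I/O
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def save_model(model: KBModel, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": _SCHEMA_VERSION,
        "norm_Gy": model.norm_Gy,
        "min_train": model.min_train,
        "ged_params": model.ged_params.to_dict(),
        "provenance": model.provenance,
        "oars": {
            key: {
                "n_train": om.n_train,
                "r_squared": om.r_squared,
                "n_dose_pc": om.dose_pca.n_components,
                "n_geo_pc": om.geo_pca.n_components,
                "training_ranges": om.training_ranges,
                "case_ids": om.case_ids,
            }
            for key, om in model.oar_models.items()
        },
    }
    (path / "model.json").write_text(json.dumps(manifest, indent=2))
    np.save(path / "dose_grid_Gy.npy", model.dose_grid_Gy)
    for key, om in model.oar_models.items():
        arrays = {
            "dose_mean": om.dose_pca.mean, "dose_components": om.dose_pca.components,
            "dose_scores": om.dose_pca.scores, "dose_evr": om.dose_pca.explained_variance_ratio,
            "geo_mean": om.geo_pca.mean, "geo_components": om.geo_pca.components,
            "geo_scores": om.geo_pca.scores, "geo_evr": om.geo_pca.explained_variance_ratio,
            "scalar_mean": om.scalar_mean, "scalar_std": om.scalar_std,
            "coef": om.fit.coef, "intercept": np.atleast_1d(om.fit.intercept),
            "fitted": om.fit.fitted, "residuals": om.fit.residuals,
            "residual_sd": om.residual_sd, "r2": om.fit.r_squared,
            "coef_se": om.fit.coef_se, "leverage": om.fit.leverage,
            "X_std": om.X_std, "Y": om.Y,
        }
        for region, band in om.low_mod_bands.items():
            arrays[f"band_{region}_mean"] = band["mean"]
            arrays[f"band_{region}_sd"] = band["sd"]
            arrays[f"band_{region}_n"] = np.array(band["n"])
        np.savez(path / f"{key}.npz", **arrays)
    return path


def load_model(path: str | Path) -> KBModel:
    path = Path(path)
    manifest = json.loads((path / "model.json").read_text())
    if manifest["schema_version"] != _SCHEMA_VERSION:
        raise ValueError("unsupported model archive schema")
    dose_grid = np.load(path / "dose_grid_Gy.npy")
    oar_models: dict[str, OARModel] = {}
    for key, meta in manifest["oars"].items():
        z = np.load(path / f"{key}.npz")
        dose_pca = PCAResult(z["dose_mean"], z["dose_components"], z["dose_scores"], z["dose_evr"])
        geo_pca = PCAResult(z["geo_mean"], z["geo_components"], z["geo_scores"], z["geo_evr"])
        fit = LinearFit(z["coef"], z["intercept"], z["fitted"], z["residuals"],
                        z["residual_sd"], z["r2"], z["coef_se"], z["leverage"])
        bands = {}
        for region in REGIONS:
            if f"band_{region}_mean" in z:
                bands[region] = {"mean": z[f"band_{region}_mean"],
                                 "sd": z[f"band_{region}_sd"],
                                 "n": int(z[f"band_{region}_n"])}
        oar_models[key] = OARModel(
            key=key, n_train=meta["n_train"], case_ids=list(meta["case_ids"]),
            dose_pca=dose_pca, geo_pca=geo_pca,
            scalar_names=SCALAR_FEATURES,
            scalar_mean=z["scalar_mean"], scalar_std=z["scalar_std"], fit=fit,
            residual_sd=z["residual_sd"], r_squared=meta["r_squared"],
            training_ranges={k: tuple(v) for k, v in meta["training_ranges"].items()},
            low_mod_bands=bands, X_std=z["X_std"], Y=z["Y"],
        )
    return KBModel(oar_models, GEDParams.from_dict(manifest["ged_params"]),
                   manifest["norm_Gy"], dose_grid, manifest["min_train"],
                   manifest["provenance"])
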