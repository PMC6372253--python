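"""Study endpoints: prediction accuracy, plan comparison, model diagnostics.

Reproduces, on any cohort, the evaluation style of a knowledge-based
planning study: (1) per-OAR predicted-vs-achieved mean dose with geometric
outlier flags and the count of OARs within a dose threshold; (2) paired
knowledge-based vs manual plan comparison (target homogeneity/coverage,
individual and composite OAR mean doses, serial-structure max doses), with
the knowledge-based plan normalized to the manual plan's mean boost dose;
(3) regression/residual diagnostics and an R² table per model organ.
Sign convention for all deltas: KBP - manual (achieved - predicted for the
accuracy table).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cases import Case, model_key
from .dvh import compute_dvh, homogeneity_index, max_point_dose, mean_dose, v95_percent
from .model import KBModel, PredictionBand
from .phantoms import SERIAL_STRUCTURES

__all__ = [
    "COMPOSITES",
    "predicted_vs_achieved",
    "compare_plans",
    "model_diagnostics",
]

# composite structures for aggregate mean-dose reporting; membership is a
# configuration choice (salivary = parotids + submandibulars; swallowing =
# constrictors + larynx + cricopharyngeus + upper esophageal sphincter)
COMPOSITES: dict[str, tuple[str, ...]] = {
    "comp_sal": ("parotid_l", "parotid_r", "submandibular_l", "submandibular_r"),
    "comp_swal": ("pcm_superior", "pcm_medial", "pcm_inferior",
                  "larynx_upper", "larynx_lower", "cricopharyngeus", "ues"),
}


def predicted_vs_achieved(
    cases: Sequence[Case],
    bands_by_case: Sequence[Mapping[str, PredictionBand]],
    doses_by_case: Sequence[np.ndarray],
    threshold_Gy: float = 3.0,
) -> tuple[pd.DataFrame, dict]:
    """Predicted (median-band) vs achieved mean dose for every modeled OAR.

    Returns the per-case per-OAR table and a summary with the count and
    fraction of OARs whose |achieved - predicted| is below the threshold.
    """
    if not (len(cases) == len(bands_by_case) == len(doses_by_case)):
        raise ValueError("case mismatch between bands and plans")
    rows = []
    for case, bands, dose in zip(cases, bands_by_case, doses_by_case):
        for oar in case.oars:
            if oar.role != "oar" or oar.name in SERIAL_STRUCTURES:
                continue
            band = bands.get(model_key(oar))
            if band is None:
                continue
            pred = band.predicted_mean_Gy()
            ach = mean_dose(dose, oar.mask)
            rows.append({
                "case_id": case.id,
                "oar": oar.name,
                "model_oar": model_key(oar),
                "predicted_mean_Gy": pred,
                "achieved_mean_Gy": ach,
                "delta_Gy": ach - pred,
                "outlier_flags": ";".join(band.outlier_flags),
            })
    table = pd.DataFrame.from_records(rows)
    n = len(table)
    within = int((table["delta_Gy"].abs() < threshold_Gy).sum()) if n else 0
    summary = {
        "threshold_Gy": threshold_Gy,
        "n_oars": n,
        "n_within": within,
        "fraction_within": within / n if n else float("nan"),
        "n_flagged": int((table["outlier_flags"] != "").sum()) if n else 0,
    }
    return table, summary


def _composite_mean(dose: np.ndarray, case: Case, members: Sequence[str]) -> float | None:
    acc = np.zeros(case.grid.dims, dtype=bool)
    for name in members:
        try:
            acc |= case.oar_by_name(name).mask
        except KeyError:
            continue
    if not acc.any():
        return None
    return mean_dose(dose, acc)


def compare_plans(
    cases: Sequence[Case],
    manual_doses: Sequence[np.ndarray],
    kbp_doses: Sequence[np.ndarray],
    composites: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired comparison of knowledge-based vs manual plans.

    Both plans of a pair are expected on the same normalization (the KBP
    scaled to the manual plan's mean boost dose). Returns a per-case target
    table (HI, V95 and their deltas), a per-OAR/composite mean-dose table
    (max dose for serial structures), and a summary.
    """
    if len(cases) != len(manual_doses) or len(cases) != len(kbp_doses):
        raise ValueError("missing counterpart plan")
    composites = COMPOSITES if composites is None else composites
    case_rows, oar_rows = [], []
    for case, dm, dk in zip(cases, manual_doses, kbp_doses):
        boost, elective = case.targets[0], case.targets[-1]
        rec = {"case_id": case.id}
        for label, d in (("manual", dm), ("kbp", dk)):
            rec[f"hi_b_{label}"] = homogeneity_index(compute_dvh(d, boost.structure.mask))
            rec[f"hi_e_{label}"] = homogeneity_index(compute_dvh(d, elective.structure.mask))
            rec[f"v95_b_{label}"] = v95_percent(d, boost.structure.mask, boost.prescription_Gy)
            rec[f"v95_e_{label}"] = v95_percent(d, elective.structure.mask,
                                                elective.prescription_Gy)
        for m in ("hi_b", "hi_e", "v95_b", "v95_e"):
            rec[f"delta_{m}"] = rec[f"{m}_kbp"] - rec[f"{m}_manual"]
        case_rows.append(rec)

        for oar in case.oars:
            if oar.role != "oar":
                continue
            serial = oar.name in SERIAL_STRUCTURES
            fn = max_point_dose if serial else mean_dose
            vm, vk = fn(dm, oar.mask), fn(dk, oar.mask)
            oar_rows.append({
                "case_id": case.id, "structure": oar.name,
                "kind": "serial_max" if serial else "mean",
                "manual_Gy": vm, "kbp_Gy": vk, "delta_Gy": vk - vm,
            })
        for comp_name, members in composites.items():
            vm = _composite_mean(dm, case, members)
            vk = _composite_mean(dk, case, members)
            if vm is None or vk is None:
                continue
            oar_rows.append({
                "case_id": case.id, "structure": comp_name, "kind": "composite_mean",
                "manual_Gy": vm, "kbp_Gy": vk, "delta_Gy": vk - vm,
            })
    case_table = pd.DataFrame.from_records(case_rows)
    oar_table = pd.DataFrame.from_records(oar_rows)
    individual = oar_table[oar_table["kind"] == "mean"]
    summary = {
        "n_cases": len(cases),
        "mean_abs_delta_hi_b": float(case_table["delta_hi_b"].abs().mean()),
        "mean_abs_delta_hi_e": float(case_table["delta_hi_e"].abs().mean()),
        "n_oars": len(individual),
        "n_oar_mean_increase_gt3Gy": int((individual["delta_Gy"] > 3.0).sum()),
    }
    return case_table, oar_table, summary


def model_diagnostics(model: KBModel) -> dict:
    """Regression/residual plot data and the per-OAR R² table.

    For every model organ: the (geometric score 1, dose score 1) scatter,
    the fitted univariate regression line with a ±1 SD interval, residuals,
    and summary statistics. Fully serializable (lists and floats only).
    """
    per_oar: dict[str, dict] = {}
    rows = []
    for key, om in sorted(model.oar_models.items()):
        geo1 = om.X_std[:, 0] * om.scalar_std[0] + om.scalar_mean[0]
        dose1 = om.Y[:, 0]
        # univariate line for the regression plot
        A = np.column_stack([np.ones_like(geo1), geo1])
        b, *_ = np.linalg.lstsq(A, dose1, rcond=None)
        per_oar[key] = {
            "geo_score_1": geo1.tolist(),
            "dose_score_1": dose1.tolist(),
            "line_intercept": float(b[0]),
            "line_slope": float(b[1]),
            "band_sd": float(om.residual_sd[0]),
            "residuals_pc1": om.fit.residuals[:, 0].tolist(),
            "leverage": om.fit.leverage.tolist(),
            "r_squared": float(om.r_squared),
            "n_train": om.n_train,
        }
        rows.append({"oar": key, "r_squared": float(om.r_squared),
                     "n_train": om.n_train,
                     "n_dose_pc": om.dose_pca.n_components,
                     "n_geo_pc": om.geo_pca.n_components})
    return {"per_oar": per_oar, "r2_table": rows}
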