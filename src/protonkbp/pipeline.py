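"""End-to-end study analog: library planning, training, KBP creation, evaluation.

``run_study`` reproduces the whole knowledge-based-planning workflow on
synthetic cohorts: generate a training cohort and an evaluation cohort,
create manual-style plans for both, train the DVH-prediction model on the
library, then for every evaluation case predict bands, place objectives
(mirroring the manual plan's priorities), optimize the knowledge-based
plan, run a continue-optimization pass if target aims are unmet, normalize
to the manual plan's mean boost dose, and tabulate the study endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .cases import Case
from .engine import (
    ManualPlanConfig,
    Planner,
    PlanResult,
    continue_optimization,
    make_manual_plan,
    normalize_to_mean,
)
from .evaluate import compare_plans, model_diagnostics, predicted_vs_achieved
from .ged import GEDParams, compute_ged
from .model import KBModel, predict, train
from .objectives import place_objectives
from .phantoms import CohortSpec, generate_cohort

__all__ = ["StudyConfig", "StudyResult", "run_study", "make_kbp_plan"]


@dataclass(frozen=True)
class StudyConfig:
    n_train: int = 50
    n_eval: int = 10
    seed: int = 1
    spacing_mm: float = 4.0
    min_train: int = 20
    accuracy_threshold_Gy: float = 3.0
    ged_params: GEDParams = dc_field(default_factory=GEDParams)
    plan_config: ManualPlanConfig | None = None


@dataclass
class StudyResult:
    model: KBModel
    train_manifest: pd.DataFrame
    eval_manifest: pd.DataFrame
    accuracy_table: pd.DataFrame
    accuracy_summary: dict
    case_table: pd.DataFrame
    oar_table: pd.DataFrame
    comparison_summary: dict
    diagnostics: dict
    eval_cases: list[Case]
    eval_bands: list[dict]
    kbp_plans: list[PlanResult]
    manual_plans: list[PlanResult]

    def summary(self) -> dict:
        r2 = [r["r_squared"] for r in self.diagnostics["r2_table"]]
        return {
            "n_model_oars": len(r2),
            "mean_r_squared": float(np.mean(r2)) if r2 else float("nan"),
            **{k: v for k, v in self.accuracy_summary.items()},
            **{k: v for k, v in self.comparison_summary.items()},
        }


def make_kbp_plan(case: Case, planner: Planner, bands, manual_plan: PlanResult,
                  config: ManualPlanConfig) -> PlanResult:
    """Knowledge-based plan: band-driven objectives at the manual priorities."""
    priorities = manual_plan.info.get("priorities", {})
    objset = place_objectives(bands, case, priorities)
    plan = planner.optimize(objset, iterations=config.iterations, finalize=False)
    plan = continue_optimization(planner, plan, objset,
                                 iterations=config.continue_iterations, finalize=False)
    plan = planner.finalize(plan)
    plan.info = dict(plan.info, case_id=case.id, mode="kbp")
    return plan


def run_study(config: StudyConfig | None = None, progress: bool = False) -> StudyResult:
    config = config or StudyConfig()
    plan_cfg = config.plan_config or ManualPlanConfig(seed=config.seed)
    ged_params = config.ged_params

    train_spec = CohortSpec(config.n_train, config.seed, spacing_mm=config.spacing_mm)
    eval_spec = CohortSpec(config.n_eval, config.seed + 1_000_003,
                           spacing_mm=config.spacing_mm)
    train_cases, train_manifest = generate_cohort(train_spec)
    eval_cases, eval_manifest = generate_cohort(eval_spec)

    # --- library: manual plans for the training cohort -------------------
    library, geds = [], []
    for i, case in enumerate(train_cases):
        if progress:
            print(f"[library] {case.id} ({i + 1}/{len(train_cases)})")
        plan = make_manual_plan(case, plan_cfg)
        library.append((case, plan.dose.values))
        geds.append(compute_ged(case, ged_params))

    model = train(library, ged_params, min_train=config.min_train, geds=geds,
                  provenance={"seed": config.seed, "n_train": config.n_train})

    # --- evaluation group -------------------------------------------------
    manual_plans, kbp_plans, bands_list = [], [], []
    for i, case in enumerate(eval_cases):
        if progress:
            print(f"[eval] {case.id} ({i + 1}/{len(eval_cases)})")
        planner = Planner(case)
        manual = make_manual_plan(case, plan_cfg, planner=planner)
        ged = compute_ged(case, ged_params)
        bands = predict(model, case, ged=ged)
        kbp = make_kbp_plan(case, planner, bands, manual, plan_cfg)
        kbp = normalize_to_mean(planner, kbp, case.targets[0].structure.mask,
                                manual.metrics["mean_boost"])
        manual_plans.append(manual)
        kbp_plans.append(kbp)
        bands_list.append(bands)

    kbp_doses = [p.dose.values for p in kbp_plans]
    manual_doses = [p.dose.values for p in manual_plans]
    accuracy_table, accuracy_summary = predicted_vs_achieved(
        eval_cases, bands_list, kbp_doses, config.accuracy_threshold_Gy)
    case_table, oar_table, comparison_summary = compare_plans(
        eval_cases, manual_doses, kbp_doses)
    diagnostics = model_diagnostics(model)

    return StudyResult(
        model=model,
        train_manifest=train_manifest,
        eval_manifest=eval_manifest,
        accuracy_table=accuracy_table,
        accuracy_summary=accuracy_summary,
        case_table=case_table,
        oar_table=oar_table,
        comparison_summary=comparison_summary,
        diagnostics=diagnostics,
        eval_cases=eval_cases,
        eval_bands=bands_list,
        kbp_plans=kbp_plans,
        manual_plans=manual_plans,
    )
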