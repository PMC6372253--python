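"""Toy spot-scanning proton dose engine and spot-weight optimizer.

This is a deliberately simplified stand-in for a clinical multi-field
optimizer and dose algorithm, built for DVH-level realism at desk scale:

* Each field carries a rectangular lateral spot grid (spacing 0.425 x the
  in-air FWHM of the 3.9-mm-sigma spot) and energy layers whose spread-out
  Bragg peak (SOBP) flat tops tile the field-target depth range in 5-mm
  steps, expanded by 2/3/5-mm proximal/distal/lateral margins. A 57-mm
  water-equivalent range-shifter offset lets nominal ranges reach proximal
  targets; with the homogeneous water-equivalent phantom it only shifts the
  energy bookkeeping, not the dose shape.
* A spot's dose is separable: a 1-D SOBP depth profile (flat top of one
  modulation step, exponential distal fall-off, constant entry plateau)
  times a lateral Gaussian whose sigma grows linearly with the layer depth.
* Dose is exactly linear in the nonnegative spot weights. Optimization is
  projected gradient descent with backtracking on a weighted quadratic
  penalty (two-sided for target uniformity, one-sided for max-dose / mean
  dose / upper dose-volume objectives, the latter with the standard
  per-iteration voxel-selection heuristic), so the logged objective is
  monotone non-increasing.
* "Manual-style" library plans emulate an interactive planner with a few
  automated re-weighting rounds and a seeded per-case planner-skill factor
  that scales OAR priorities, injecting the inter-plan variability a
  knowledge-based model is meant to learn.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
from scipy import ndimage, sparse

from ._beamframe import BeamFrame, gather_to_voxels, make_frame, mask_on_lattice
from .cases import Case, DoseGrid
from .dvh import compute_dvh, homogeneity_index, mean_dose, v95_percent, volume_at_dose
from .objectives import Objective, ObjectiveSet, PlanningAims, standard_target_objectives

__all__ = [
    "PlanMargins",
    "EngineParams",
    "SpotGrid",
    "PlanResult",
    "ManualPlanConfig",
    "Planner",
    "sobp_depth_profile",
    "continue_optimization",
    "normalize_to_mean",
    "make_manual_plan",
]

RING_NAME = "__ring__"  # conformity shell outside PTV_COMP


@dataclass(frozen=True)
class PlanMargins:
    proximal_mm: float = 2.0
    distal_mm: float = 3.0
    lateral_mm: float = 5.0

    def __post_init__(self) -> None:
        if min(self.proximal_mm, self.distal_mm, self.lateral_mm) < 0:
            raise ValueError("margins must be nonnegative")


@dataclass(frozen=True)
class EngineParams:
    spot_sigma_mm: float = 3.9          # in-air sigma at isocenter (240 MeV)
    sigma_growth_per_mm: float = 0.015  # lateral sigma growth with depth
    layer_spacing_mm: float = 5.0       # SOBP flat-top step between energy layers
    entry_fraction: float = 0.35        # entry plateau relative to the flat top
    falloff_mm: float = 4.0             # distal fall-off scale (shared with GED)
    range_shifter_wet_mm: float = 57.0  # water-equivalent thickness
    lateral_cutoff_sigmas: float = 3.0
    distal_cutoff_falloffs: float = 8.0  # truncate the distal tail (< 4e-4)
    margins: PlanMargins = dc_field(default_factory=PlanMargins)
    iterations: int = 60

    @property
    def spot_spacing_mm(self) -> float:
        # 0.425 x in-air FWHM, FWHM = 2.355 sigma
        return 0.425 * 2.355 * self.spot_sigma_mm


@dataclass
class SpotGrid:
    """Spot list of one field: lateral positions, layer peak depths, sigmas."""

    field_index: int
    s_mm: np.ndarray
    z_mm: np.ndarray
    layer_depth_mm: np.ndarray  # distal edge of the SOBP flat top, in beam depth
    sigma_mm: np.ndarray

    def __len__(self) -> int:
        return self.s_mm.size


@dataclass
class PlanResult:
    """Optimization outcome: dose = influence @ weights, weights >= 0.

    ``dose`` is None for intermediate (non-finalized) results; target
    metrics are exact either way because every target voxel is a sampled
    optimization point.
    """

    weights: np.ndarray
    dose: DoseGrid | None
    objective_log: list[float]
    converged: bool
    metrics: dict[str, float]
    info: dict = dc_field(default_factory=dict)


def sobp_depth_profile(t_mm: np.ndarray, distal_edge_mm: float | np.ndarray,
                       params: EngineParams) -> np.ndarray:
    """1-D SOBP depth dose: entry plateau, unit flat top, exponential fall-off."""
    t = np.asarray(t_mm, dtype=float)
    R = np.asarray(distal_edge_mm, dtype=float)
    top_start = R - params.layer_spacing_mm
    tail = np.where(t - R > params.distal_cutoff_falloffs * params.falloff_mm,
                    0.0, np.exp(np.clip(-(t - R) / params.falloff_mm, -745.0, 0.0)))
    return np.where(t > R, tail, np.where(t > top_start, 1.0, params.entry_fraction))


def _elliptic_footprint_2d(r0: float, r1: float) -> np.ndarray:
    h0, h1 = int(np.ceil(r0)), int(np.ceil(r1))
    I, J = np.meshgrid(np.arange(-h0, h0 + 1), np.arange(-h1, h1 + 1), indexing="ij")
    return (I / max(r0, 1e-9)) ** 2 + (J / max(r1, 1e-9)) ** 2 <= 1.0 + 1e-9


class Planner:
    """Builds spot grids and the influence matrix for one case; runs MFO.

    The influence is evaluated on a deterministic sample of voxels: all
    target and OAR voxels plus a strided conformity shell around PTV_COMP.
    Spot kernels are sampled at beam-frame-lattice coordinates so that the
    optimizer's sampled dose and the final full-grid dose agree exactly at
    the sampled voxels.
    """

    def __init__(self, case: Case, params: EngineParams | None = None):
        self.case = case
        self.params = params or EngineParams()
        self.frames: list[BeamFrame] = [make_frame(case.grid, f.direction) for f in case.fields]
        self._build_points()
        self._build_spots()
        self._build_influence()

    # -- voxel sampling ---------------------------------------------------
    def _build_points(self) -> None:
        case = self.case
        dims = case.grid.dims
        comp = case.ptv_comp_mask()
        oar_cap = 600  # large OARs are strided; targets are kept complete

        def strided(mask: np.ndarray) -> np.ndarray:
            f = np.flatnonzero(mask)
            if f.size > oar_cap:
                f = f[:: int(np.ceil(f.size / oar_cap))]
            return f

        struct_flat: dict[str, np.ndarray] = {}
        for lvl in case.targets:
            struct_flat[lvl.structure.name] = np.flatnonzero(lvl.structure.mask)
        for s in case.oars:
            struct_flat[s.name] = strided(s.mask)
            # sparable part of each OAR: outside the composite target, so OAR
            # objectives never fight target coverage head-on
            struct_flat[f"{s.name}@spared"] = strided(s.mask & ~comp)
        dist = ndimage.distance_transform_edt(~comp, sampling=case.grid.spacing_mm)
        ring = (dist > 0) & (dist <= 12.0)
        struct_flat[RING_NAME] = np.flatnonzero(ring)[::3]

        flat = np.unique(np.concatenate(list(struct_flat.values())))
        self.point_flat = flat
        lookup = np.full(int(np.prod(dims)), -1, dtype=np.int64)
        lookup[flat] = np.arange(flat.size)
        self.struct_points: dict[str, np.ndarray] = {
            name: lookup[f] for name, f in struct_flat.items()
        }
        self.point_ixyz = np.stack(np.unravel_index(flat, dims), axis=1)

    # -- spot placement ---------------------------------------------------
    def _build_spots(self) -> None:
        p = self.params
        grid = self.case.grid
        zc = grid.axis_coords(2)
        delta = p.spot_spacing_mm
        self.spot_grids: list[SpotGrid] = []
        for fi, frame in enumerate(self.frames):
            B = mask_on_lattice(frame, self.case.fields[fi].field_target.mask)
            occ = B.any(axis=1)  # (n_s, n_z)
            first = np.argmax(B, axis=1)
            last = B.shape[1] - 1 - np.argmax(B[:, ::-1, :], axis=1)
            tmin = np.where(occ, frame.t0 + first * frame.h - p.margins.proximal_mm, np.inf)
            tmax = np.where(occ, frame.t0 + last * frame.h + p.margins.distal_mm, -np.inf)
            fp = _elliptic_footprint_2d(p.margins.lateral_mm / frame.h,
                                        p.margins.lateral_mm / grid.spacing_mm[2])
            occ_d = ndimage.binary_dilation(occ, structure=fp)
            tmin_d = ndimage.minimum_filter(tmin, footprint=fp, mode="nearest")
            tmax_d = ndimage.maximum_filter(tmax, footprint=fp, mode="nearest")

            s_occ = frame.s_samples[occ_d.any(axis=1)]
            z_occ = zc[occ_d.any(axis=0)]
            s_vals = np.arange(s_occ.min(), s_occ.max() + delta, delta)
            z_vals = np.arange(z_occ.min(), z_occ.max() + delta, delta)
            t_entry = tmin_d[np.isfinite(tmin_d)].min() if np.isfinite(tmin_d).any() else 0.0

            ss, zz, RR, sig = [], [], [], []
            for s in s_vals:
                i_s = int(np.clip(np.rint((s - frame.s0) / frame.h), 0, frame.n_s - 1))
                for z in z_vals:
                    i_z = int(np.clip(np.rint((z - zc[0]) / grid.spacing_mm[2]), 0, len(zc) - 1))
                    if not occ_d[i_s, i_z]:
                        continue
                    lo, hi = tmin_d[i_s, i_z], tmax_d[i_s, i_z]
                    n_layers = max(int(np.ceil((hi - lo) / p.layer_spacing_mm)), 1)
                    for k in range(1, n_layers + 1):
                        R = lo + k * p.layer_spacing_mm
                        ss.append(s)
                        zz.append(z)
                        RR.append(R)
                        sig.append(p.spot_sigma_mm + p.sigma_growth_per_mm
                                   * max(R - p.layer_spacing_mm / 2.0 - t_entry, 0.0))
            if not ss:
                raise ValueError(f"empty spot grid for field {fi}")
            self.spot_grids.append(SpotGrid(fi, np.array(ss), np.array(zz),
                                            np.array(RR), np.array(sig)))
        self.n_spots = sum(len(sg) for sg in self.spot_grids)

    # -- influence --------------------------------------------------------
    def _build_influence(self) -> None:
        p = self.params
        grid = self.case.grid
        zc = grid.axis_coords(2)
        ix, iy, iz = self.point_ixyz.T
        n_points = ix.size
        rows_l, cols_l, vals_l = [], [], []
        col_offset = 0
        for frame, sg in zip(self.frames, self.spot_grids):
            s_p = np.asarray(frame.vox_s[ix, iy], dtype=np.float32)
            # depths stay float64: flat-top boundaries coincide exactly with
            # lattice depths, and a float32 cast can flip the comparison that
            # full_dose() evaluates in float64
            t_p = np.asarray(frame.vox_t[ix, iy], dtype=np.float64)
            z_p = np.asarray(zc[iz], dtype=np.float32)
            order = np.argsort(s_p, kind="stable")
            s_sorted = s_p[order]
            spot_s = sg.s_mm.astype(np.float32)
            spot_z = sg.z_mm.astype(np.float32)
            spot_sig = sg.sigma_mm.astype(np.float32)
            spot_R = sg.layer_depth_mm.astype(np.float64)
            cut_max = p.lateral_cutoff_sigmas * float(spot_sig.max())
            for lo in range(0, len(sg), 256):
                sl = slice(lo, min(lo + 256, len(sg)))
                # restrict to points laterally near this chunk of spots
                a = np.searchsorted(s_sorted, spot_s[sl].min() - cut_max)
                b = np.searchsorted(s_sorted, spot_s[sl].max() + cut_max, side="right")
                rows = order[a:b]
                if rows.size == 0:
                    continue
                ds = s_p[rows, None] - spot_s[None, sl]
                dz = z_p[rows, None] - spot_z[None, sl]
                lat2 = ds * ds + dz * dz
                sig = spot_sig[None, sl]
                r_i, c_i = np.nonzero(lat2 <= (p.lateral_cutoff_sigmas * sig) ** 2)
                if r_i.size == 0:
                    continue
                sig_v = spot_sig[sl][c_i]
                kern = np.exp(-lat2[r_i, c_i] / (2.0 * sig_v * sig_v))
                vals = kern * sobp_depth_profile(t_p[rows[r_i]], spot_R[sl][c_i], p)
                keep = vals > 0
                rows_l.append(rows[r_i[keep]])
                cols_l.append((c_i[keep] + lo + col_offset).astype(np.int64))
                vals_l.append(vals[keep].astype(np.float32))
            col_offset += len(sg)
        # float32 influence: halves the matvec bandwidth; ~1e-7 relative
        # rounding is far below any planning tolerance here
        self.A = sparse.coo_matrix(
            (np.concatenate(vals_l),
             (np.concatenate(rows_l), np.concatenate(cols_l))),
            shape=(n_points, self.n_spots), dtype=np.float32).tocsr()
        self._AT = self.A.T.tocsr()
        col_norm2 = np.asarray(self.A.multiply(self.A).sum(axis=0), dtype=float).ravel()
        floor = max(col_norm2.max(), 1e-30) * 1e-6
        self._precond = 1.0 / np.maximum(col_norm2, floor)

    def sampled_dose(self, w: np.ndarray) -> np.ndarray:
        """Dose at the sampled optimization points for a weight vector."""
        return (self.A @ np.asarray(w, dtype=np.float32)).astype(np.float64)

    def _grad_weights(self, gd: np.ndarray) -> np.ndarray:
        return (self._AT @ gd.astype(np.float32)).astype(np.float64)

    # -- dose -------------------------------------------------------------
    def full_dose(self, w: np.ndarray) -> np.ndarray:
        """Accumulate the full-grid dose of a weight vector (Gy)."""
        p = self.params
        grid = self.case.grid
        zc = grid.axis_coords(2)
        dose = np.zeros(grid.dims)
        offset = 0
        for frame, sg in zip(self.frames, self.spot_grids):
            wf = w[offset:offset + len(sg)]
            offset += len(sg)
            bf = np.zeros((frame.n_s, frame.n_t, grid.dims[2]))
            s_lat = frame.s_samples
            for R in np.unique(sg.layer_depth_mm):
                idx = np.flatnonzero(sg.layer_depth_mm == R)
                if not wf[idx].any():
                    continue
                lat = np.zeros((frame.n_s, grid.dims[2]))
                for j in idx:
                    if wf[j] == 0.0:
                        continue
                    sig = sg.sigma_mm[j]
                    cut = p.lateral_cutoff_sigmas * sig
                    s0, z0 = sg.s_mm[j], sg.z_mm[j]
                    a = np.searchsorted(s_lat, s0 - cut)
                    b = np.searchsorted(s_lat, s0 + cut, side="right")
                    c = np.searchsorted(zc, z0 - cut)
                    d = np.searchsorted(zc, z0 + cut, side="right")
                    ds = s_lat[a:b, None] - s0
                    dz = zc[None, c:d] - z0
                    lat2 = ds * ds + dz * dz
                    kern = np.exp(-lat2 / (2.0 * sig * sig))
                    kern[lat2 > cut * cut] = 0.0
                    lat[a:b, c:d] += wf[j] * kern
                prof = sobp_depth_profile(frame.t_samples, R, p)
                bf += lat[:, None, :] * prof[None, :, None]
            dose += gather_to_voxels(frame, bf)
        return dose

    # -- objective --------------------------------------------------------
    def _objective(self, d: np.ndarray, objset: ObjectiveSet
                   ) -> tuple[float, np.ndarray, list]:
        """Objective value, gradient w.r.t. sampled dose, and the quadratic
        terms (coefficient, active point indices, is_mean) of the current
        active sets, used for the exact line search."""
        f = 0.0
        g = np.zeros_like(d)
        quads: list[tuple[float, np.ndarray, bool]] = []
        for o in objset.objectives:
            idx = self.struct_points.get(o.structure)
            if idx is None or idx.size == 0:
                continue
            dd = d[idx]
            n = dd.size
            if o.kind == "target_uniform":
                r = dd - o.dose_Gy
                over = r > 0
                wv = np.where(over, o.overdose_weight, 1.0)
                f += o.priority * float((wv * r) @ r) / n
                g[idx] += (2.0 * o.priority / n) * wv * r
                quads.append((o.priority / n, idx[~over], False))
                if o.overdose_weight > 0:
                    quads.append((o.priority * o.overdose_weight / n, idx[over], False))
            elif o.kind == "max_point":
                r = np.clip(dd - o.dose_Gy, 0.0, None)
                f += o.priority * float(r @ r) / n
                g[idx] += (2.0 * o.priority / n) * r
                quads.append((o.priority / n, idx[r > 0], False))
            elif o.kind == "mean_dose":
                m = float(dd.mean())
                r = max(m - o.dose_Gy, 0.0)
                f += o.priority * r * r
                g[idx] += (2.0 * o.priority * r) / n
                if r > 0:
                    quads.append((o.priority, idx, True))
            elif o.kind == "upper_dose_volume":
                k_allowed = int(np.floor(o.volume_percent / 100.0 * n))
                over = dd > o.dose_Gy
                if int(over.sum()) <= k_allowed:
                    continue
                order = np.argsort(-dd, kind="stable")
                sel = order[k_allowed:]
                sel = sel[dd[sel] > o.dose_Gy]
                r = dd[sel] - o.dose_Gy
                f += o.priority * float(r @ r) / n
                g[idx[sel]] += (2.0 * o.priority / n) * r
                quads.append((o.priority / n, idx[sel], False))
        return f, g, quads

    @staticmethod
    def _curvature(ad: np.ndarray, quads: list) -> float:
        curv = 0.0
        for coeff, idx, is_mean in quads:
            if idx.size == 0:
                continue
            if is_mean:
                curv += coeff * float(ad[idx].mean()) ** 2
            else:
                v = ad[idx]
                curv += coeff * float(v @ v)
        return curv

    # -- optimization -----------------------------------------------------
    def initial_weights(self) -> np.ndarray:
        """Uniform weights scaled so mean target dose matches the prescriptions."""
        w = np.ones(self.n_spots)
        d = self.sampled_dose(w)
        num, den = 0.0, 0.0
        for lvl in self.case.targets:
            idx = self.struct_points[lvl.structure.name]
            num += float(d[idx].sum()) * lvl.prescription_Gy
            den += float(d[idx] @ d[idx])
        scale = num / den if den > 0 else 1.0
        return w * scale

    def optimize(self, objectives: ObjectiveSet, iterations: int | None = None,
                 w0: np.ndarray | None = None, finalize: bool = True) -> PlanResult:
        """Projected-gradient descent on the weighted quadratic penalty.

        Deterministic given inputs and iteration count; the convergence log
        records the (non-increasing) objective per accepted iteration. The
        ``converged`` flag reports whether the target planning aims are met;
        failure to meet them is flagged, not raised.
        """
        iterations = iterations if iterations is not None else self.params.iterations
        w = self.initial_weights() if w0 is None else np.asarray(w0, dtype=float).copy()
        d = self.sampled_dose(w)
        f, gd, quads = self._objective(d, objectives)
        log = [f]
        for _ in range(iterations):
            gw = self._grad_weights(gd)
            gnorm = float(np.linalg.norm(gw))
            if gnorm < 1e-14 or f < 1e-12:
                log.append(f)
                continue
            # diagonally preconditioned direction with an exact step for the
            # current active sets, then backtrack through the projection to
            # guarantee monotone descent
            dirn = gw * self._precond
            ad = self.sampled_dose(dirn)
            curv = self._curvature(ad, quads)
            slope = float(gd @ ad)  # = gw . dirn > 0
            eta = slope / (2.0 * curv) if curv > 0 else 1.0 / gnorm
            accepted = False
            for _try in range(30):
                w_new = np.maximum(w - eta * dirn, 0.0)
                d_new = self.sampled_dose(w_new)
                f_new, gd_new, quads_new = self._objective(d_new, objectives)
                if f_new <= f:
                    accepted = True
                    break
                eta *= 0.5
            if accepted:
                w, d, f, gd, quads = w_new, d_new, f_new, gd_new, quads_new
            log.append(f)
        metrics = self._metrics_from_points(d)
        result = PlanResult(w, None, log, self.aims_met(metrics, objectives.aims),
                            metrics, {})
        return self.finalize(result) if finalize else result

    def finalize(self, plan: PlanResult) -> PlanResult:
        """Compute the full-grid dose of a plan (idempotent)."""
        if plan.dose is None:
            dose = self.full_dose(plan.weights)
            plan.dose = DoseGrid(dose)
            plan.metrics = self.plan_metrics(dose)
        return plan

    def _target_metrics(self, doses: Mapping[str, np.ndarray]) -> dict[str, float]:
        case = self.case
        boost, elective = case.targets[0], case.targets[-1]
        full = np.ones  # DVH helpers take (values, mask); values are 1-D here
        db, de = doses[boost.structure.name], doses[elective.structure.name]
        m = {
            "v95_boost": v95_percent(db, full(db.shape, bool), boost.prescription_Gy),
            "v95_elective": v95_percent(de, full(de.shape, bool), elective.prescription_Gy),
            "hi_boost": homogeneity_index(compute_dvh(db, full(db.shape, bool))),
            "hi_elective": homogeneity_index(compute_dvh(de, full(de.shape, bool))),
            "mean_boost": float(db.mean()),
        }
        dc = doses["__comp__"]
        m["v107_comp"] = volume_at_dose(compute_dvh(dc, full(dc.shape, bool)),
                                        1.07 * boost.prescription_Gy)
        return m

    def _metrics_from_points(self, d: np.ndarray) -> dict[str, float]:
        names = [lvl.structure.name for lvl in self.case.targets]
        doses = {n: d[self.struct_points[n]] for n in names}
        doses["__comp__"] = np.concatenate([doses[n] for n in names])
        return self._target_metrics(doses)

    def plan_metrics(self, dose: np.ndarray) -> dict[str, float]:
        names = [lvl.structure.name for lvl in self.case.targets]
        doses = {lvl.structure.name: dose[lvl.structure.mask] for lvl in self.case.targets}
        doses["__comp__"] = np.concatenate([doses[n] for n in names])
        return self._target_metrics(doses)

    def aims_met(self, metrics: Mapping[str, float], aims: PlanningAims) -> bool:
        return (metrics["v95_boost"] >= aims.v95_boost_percent
                and metrics["v95_elective"] >= aims.v95_elective_percent
                and metrics["v107_comp"] <= aims.v107_max_percent)


def continue_optimization(planner: Planner, plan: PlanResult, objectives: ObjectiveSet,
                          escalation: float = 4.0, iterations: int = 40,
                          finalize: bool = True) -> PlanResult:
    """Warm-start re-optimization with escalated target priorities.

    A plan that already meets the planning aims is returned unchanged; for
    the rest, target-uniformity priorities are multiplied by ``escalation``
    and the optimizer continues from the existing weights.
    """
    if plan.converged:
        return planner.finalize(plan) if finalize else plan
    boosted = objectives.scaled_targets(escalation)
    result = planner.optimize(boosted, iterations=iterations, w0=plan.weights,
                              finalize=finalize)
    result.info = dict(plan.info, continued=True)
    return result


def normalize_to_mean(planner: Planner, plan: PlanResult, structure_mask: np.ndarray,
                      reference_mean_Gy: float) -> PlanResult:
    """Scale weights and dose so the structure mean equals the reference."""
    if reference_mean_Gy <= 0:
        raise ValueError("reference mean must be positive")
    plan = planner.finalize(plan)
    current = mean_dose(plan.dose.values, structure_mask)
    if current <= 0:
        raise ValueError("cannot normalize a plan with zero structure mean")
    scale = reference_mean_Gy / current
    dose = plan.dose.values * scale
    metrics = planner.plan_metrics(dose)
    return PlanResult(plan.weights * scale, DoseGrid(dose), list(plan.objective_log),
                      plan.converged, metrics, dict(plan.info, normalization_scale=scale))


# ---------------------------------------------------------------------------
# manual-style library planning
# ---------------------------------------------------------------------------

DEFAULT_OAR_PRIORITY: dict[str, float] = {
    "parotid": 1.2,
    "submandibular": 1.0,
    "oral_cavity": 0.6,
    "pcm_inferior": 0.9,
    "pcm_medial": 0.9,
    "pcm_superior": 0.9,
    "larynx_lower": 0.9,
    "larynx_upper": 0.9,
    "cricopharyngeus": 0.9,
    "ues": 0.9,
}


@dataclass(frozen=True)
class ManualPlanConfig:
    seed: int = 0
    iterations: int = 40
    rounds: int = 2
    continue_iterations: int = 30
    skill_range: tuple[float, float] = (0.6, 1.0)
    oar_base_priority: Mapping[str, float] | None = None
    ring_dose_Gy: float = 55.0
    ring_priority: float = 0.5


def _base_priority(name: str, table: Mapping[str, float]) -> float | None:
    if name in table:
        return table[name]
    for suffix in ("_l", "_r"):
        if name.endswith(suffix) and name[: -len(suffix)] in table:
            return table[name[: -len(suffix)]]
    return None


def manual_oar_priorities(case: Case, config: ManualPlanConfig) -> tuple[dict[str, float], float]:
    """Seeded per-case OAR priorities: base x case skill x small per-OAR jitter."""
    rng = np.random.default_rng([int(config.seed) % (2**31), zlib.crc32(case.id.encode()) % (2**31)])
    skill = float(rng.uniform(*config.skill_range))
    table = dict(DEFAULT_OAR_PRIORITY if config.oar_base_priority is None
                 else config.oar_base_priority)
    priorities: dict[str, float] = {}
    for s in case.oars:
        base = _base_priority(s.name, table)
        if base is None:
            continue
        priorities[s.name] = base * skill * float(rng.uniform(0.85, 1.15))
    return priorities, skill


def manual_objectives(case: Case, priorities: Mapping[str, float],
                      config: ManualPlanConfig) -> ObjectiveSet:
    objs = standard_target_objectives(case)
    objs.append(Objective(RING_NAME, "max_point", config.ring_dose_Gy, config.ring_priority))
    for name, pri in priorities.items():
        # aim at zero mean over the sparable (non-target-overlapping) part
        objs.append(Objective(f"{name}@spared", "mean_dose", 0.0, pri))
    return ObjectiveSet(objs)


def make_manual_plan(case: Case, config: ManualPlanConfig | None = None,
                     planner: Planner | None = None) -> PlanResult:
    """Library-grade plan emulating interactive planning.

    Skill factor 0 disables OAR objectives entirely; otherwise OAR mean-dose
    objectives run at skill-scaled priorities over a couple of re-weighting
    rounds (pushing harder on organs that remain hot), followed by a
    continue-optimization pass if target aims are unmet.
    """
    config = config or ManualPlanConfig()
    planner = planner or Planner(case)
    priorities, skill = manual_oar_priorities(case, config)
    if config.skill_range == (0.0, 0.0):
        priorities, skill = {}, 0.0
    objset = manual_objectives(case, priorities, config)
    plan = planner.optimize(objset, iterations=config.iterations, finalize=False)
    for _ in range(max(config.rounds - 1, 0)):
        # interactive emulation: lean harder on organs still above half the
        # elective prescription, then re-optimize from the current weights
        bumped = dict(priorities)
        elective_rx = case.targets[-1].prescription_Gy
        d_now = planner.sampled_dose(plan.weights)
        for name in priorities:
            idx = planner.struct_points[f"{name}@spared"]
            if idx.size and float(d_now[idx].mean()) > 0.5 * elective_rx:
                bumped[name] = priorities[name] * 1.5
        priorities = bumped
        objset = manual_objectives(case, priorities, config)
        plan = planner.optimize(objset, iterations=max(config.iterations // 2, 20),
                                w0=plan.weights, finalize=False)
    plan = continue_optimization(planner, plan, objset,
                                 iterations=config.continue_iterations, finalize=False)
    plan = planner.finalize(plan)
    plan.info = dict(plan.info, skill=skill, priorities=priorities, case_id=case.id)
    return plan
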