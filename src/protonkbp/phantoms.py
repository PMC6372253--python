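"""Seeded generator of head-and-neck-like synthetic planning cases.

Each case emulates a simultaneous-integrated-boost (SIB) neck geometry:

* an elliptical water-equivalent body;
* an irregular boost volume PTV_B, its 5-mm transition shell
  PTV_O = dilate(PTV_B, 5 mm) \\ PTV_B, and an elective volume PTV_E that
  surrounds the shell with a sampled margin plus a nodal extension
  (the three stored levels are pairwise disjoint);
* paired lateral salivary organs (parotids, submandibulars) and midline
  swallowing organs (oral cavity, pharyngeal constrictors, larynx,
  cricopharyngeus, upper esophageal sphincter) with volumes drawn from
  truncated normals matched to a published head-and-neck cohort
  (mean ± SD clipped to the printed min-max), sampled target-overlap
  fractions, and per-organ presence probabilities so that a 50-case library
  matches each model organ in only ~43-50 cases;
* a serial spinal-cord analog (fixed-radius posterior midline cylinder);
* three coplanar proton fields with gantry angles sampled in the ranges
  35-55, 180 and 305-330 degrees.

Everything is deterministic given (seed, index). Shapes are ellipsoids with
smooth ("Perlin-style") boundary noise: cheap, controllable overlap, no
meshes. An optional ``u_shape`` case replaces the boost with a horseshoe
wrapping the oral cavity so that lateral beams cross it in two disjoint
runs, exercising the GED sub-target rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .cases import (
    BeamField,
    Case,
    Structure,
    TargetLevel,
    VoxelGrid,
    assign_laterality,
)

__all__ = ["OARSpec", "CohortSpec", "generate_case", "generate_cohort", "SERIAL_STRUCTURES"]

SERIAL_STRUCTURES = ("spinal_cord", "brainstem")


@dataclass(frozen=True)
class OARSpec:
    """Sampling spec for one organ: volume statistics (cm^3), placement and shape."""

    name: str
    paired: bool
    mean_cm3: float
    sd_cm3: float
    min_cm3: float
    max_cm3: float
    base_pos_mm: tuple[float, float, float]  # (|x|, y, z); x mirrored for pairs
    aspect: tuple[float, float, float] = (1.0, 1.0, 1.0)
    overlap_range: tuple[float, float] = (0.0, 0.3)
    presence_prob: float = 1.0

    def sample_volume(self, rng: np.random.Generator) -> float:
        a = (self.min_cm3 - self.mean_cm3) / self.sd_cm3
        b = (self.max_cm3 - self.mean_cm3) / self.sd_cm3
        return float(stats.truncnorm.rvs(a, b, loc=self.mean_cm3, scale=self.sd_cm3,
                                         random_state=rng))


# Volume statistics mirror a published 50-patient head-and-neck model library
# (mean ± SD with printed min-max); positions/aspects are generator choices.
DEFAULT_OAR_MENU: tuple[OARSpec, ...] = (
    OARSpec("parotid", True, 27.8, 8.6, 11.6, 47.1, (56.0, 6.0, 12.0),
            (1.0, 1.4, 1.7), (0.0, 0.30), 0.93),
    OARSpec("submandibular", True, 9.3, 2.6, 4.1, 14.9, (36.0, -16.0, -6.0),
            (1.2, 1.0, 1.0), (0.0, 0.35), 0.88),
    OARSpec("oral_cavity", False, 152.8, 84.9, 21.1, 362.3, (0.0, -26.0, 14.0),
            (1.3, 1.0, 0.9), (0.0, 0.35), 1.0),
    OARSpec("cricopharyngeus", False, 3.1, 1.4, 0.7, 7.8, (0.0, 16.0, -30.0),
            (1.6, 1.0, 0.8), (0.0, 0.45), 1.0),
    OARSpec("larynx_lower", False, 6.3, 5.5, 1.5, 27.3, (0.0, 6.0, -24.0),
            (1.3, 1.1, 1.0), (0.0, 0.45), 0.98),
    OARSpec("larynx_upper", False, 11.6, 5.5, 4.4, 30.3, (0.0, 4.0, -12.0),
            (1.3, 1.1, 1.0), (0.0, 0.45), 0.96),
    OARSpec("pcm_inferior", False, 4.2, 1.8, 1.4, 9.7, (0.0, 18.0, -10.0),
            (2.2, 0.7, 1.2), (0.0, 0.50), 0.98),
    OARSpec("pcm_medial", False, 3.5, 2.6, 0.8, 12.9, (0.0, 18.0, 6.0),
            (2.2, 0.7, 1.2), (0.0, 0.50), 0.98),
    OARSpec("pcm_superior", False, 7.3, 3.5, 0.8, 17.4, (0.0, 16.0, 22.0),
            (2.2, 0.7, 1.2), (0.0, 0.50), 0.98),
    OARSpec("ues", False, 1.6, 0.9, 0.7, 5.9, (0.0, 16.0, -38.0),
            (1.5, 1.0, 0.8), (0.0, 0.45), 0.94),
)


@dataclass(frozen=True)
class CohortSpec:
    """Sampling specification for a synthetic cohort.

    ``spacing_mm`` defaults to the 2.5-mm calculation-grid convention;
    coarser grids (4-5 mm) are the intended desk-scale setting.
    """

    n_cases: int
    seed: int
    spacing_mm: float = 2.5
    extent_mm: tuple[float, float, float] = (192.0, 152.0, 96.0)
    boost_rx_Gy: float = 70.0
    elective_rx_Gy: float = 54.25
    n_fractions: int = 35
    transition_mm: float = 5.0
    ptv_b_volume_range_cm3: tuple[float, float] = (25.0, 90.0)
    elective_margin_range_mm: tuple[float, float] = (8.0, 18.0)
    gantry_ranges_deg: tuple[tuple[float, float], ...] = ((35.0, 55.0), (180.0, 180.0), (305.0, 330.0))
    oar_menu: tuple[OARSpec, ...] = DEFAULT_OAR_MENU
    cord_radius_mm: float = 4.5
    noise_amplitude: float = 0.22
    u_shape: bool = False

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        for lo, hi in (self.ptv_b_volume_range_cm3, self.elective_margin_range_mm):
            if hi < lo:
                raise ValueError("empty sampling range")
        for lo, hi in self.gantry_ranges_deg:
            if hi < lo:
                raise ValueError("empty gantry-angle range")
        if self.elective_rx_Gy >= self.boost_rx_Gy:
            raise ValueError("boost prescription must exceed elective prescription")

    def make_grid(self) -> VoxelGrid:
        dims = tuple(max(int(round(e / self.spacing_mm)), 1) for e in self.extent_mm)
        origin = tuple(-(d - 1) * self.spacing_mm / 2.0 for d in dims)
        return VoxelGrid(dims, (self.spacing_mm,) * 3, origin)


# ---------------------------------------------------------------------------
# shape primitives
# ---------------------------------------------------------------------------


def _coords(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.meshgrid(grid.axis_coords(0), grid.axis_coords(1), grid.axis_coords(2),
                       indexing="ij")


def _smooth_noise(grid: VoxelGrid, rng: np.random.Generator, corr_mm: float = 9.0) -> np.ndarray:
    raw = rng.standard_normal(grid.dims)
    sm = ndimage.gaussian_filter(raw, sigma=[corr_mm / s for s in grid.spacing_mm])
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _semiaxes(volume_cm3: float, aspect: tuple[float, float, float]) -> np.ndarray:
    p = np.asarray(aspect, dtype=float)
    k = (volume_cm3 * 1000.0 * 3.0 / (4.0 * np.pi * np.prod(p))) ** (1.0 / 3.0)
    return p * k


def _blob(coords, center, semiaxes, noise=None, amplitude=0.0) -> np.ndarray:
    X, Y, Z = coords
    f = (((X - center[0]) / semiaxes[0]) ** 2
         + ((Y - center[1]) / semiaxes[1]) ** 2
         + ((Z - center[2]) / semiaxes[2]) ** 2)
    if noise is not None and amplitude > 0:
        f = f + amplitude * noise
    return f <= 1.0


def _dilate_mm(mask: np.ndarray, radius_mm: float, grid: VoxelGrid) -> np.ndarray:
    # Euclidean dilation via the distance transform of the complement
    if radius_mm <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=grid.spacing_mm)
    return dist <= radius_mm + 1e-9


# ---------------------------------------------------------------------------
# case generation
# ---------------------------------------------------------------------------


def _place_with_overlap(
    coords,
    body: np.ndarray,
    ptv_comp: np.ndarray,
    base_center: np.ndarray,
    semiaxes: np.ndarray,
    noise: np.ndarray,
    amplitude: float,
    target_overlap: float,
    ptv_centroid: np.ndarray,
) -> np.ndarray:
    """Shift an organ from its base position toward the target centroid until
    its PTV-overlap fraction approximates the sampled value (coarse search)."""
    best_mask, best_err = None, np.inf
    for lam in np.linspace(0.0, 0.85, 8):
        center = base_center + lam * (ptv_centroid - base_center)
        m = _blob(coords, center, semiaxes, noise, amplitude) & body
        n = m.sum()
        if n == 0:
            continue
        ov = float((m & ptv_comp).sum()) / n
        err = abs(ov - target_overlap)
        if err < best_err:
            best_mask, best_err = m, err
        if target_overlap == 0.0 and ov == 0.0:
            break
    return best_mask if best_mask is not None else np.zeros_like(body)


def _horseshoe_mask(coords, center, r_inner, r_outer, half_height, gap_halfwidth) -> np.ndarray:
    """C-shaped (horseshoe) volume opening anteriorly around ``center``."""
    X, Y, Z = coords
    r = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2)
    ring = (r >= r_inner) & (r <= r_outer) & (np.abs(Z - center[2]) <= half_height)
    gap = (np.abs(X - center[0]) < gap_halfwidth) & (Y < center[1])
    return ring & ~gap


def generate_case(spec: CohortSpec, index: int) -> tuple[Case, dict]:
    """Generate one deterministic case; returns (case, sampled-parameter record)."""
    rng = np.random.default_rng([int(spec.seed), int(index)])
    grid = spec.make_grid()
    coords = _coords(grid)
    X, Y, Z = coords
    record: dict = {"case_id": f"case_{spec.seed:d}_{index:03d}", "index": index}

    body_ax = rng.uniform(80.0, 90.0)
    body_ay = rng.uniform(60.0, 70.0)
    body = ((X / body_ax) ** 2 + (Y / body_ay) ** 2) <= 1.0
    body_volume = body.sum() * grid.voxel_volume_cm3
    max_oar = max(o.max_cm3 for o in spec.oar_menu)
    if max_oar > body_volume:
        raise ValueError("infeasible spec: OAR volume range exceeds the body volume")
    record.update(body_ax_mm=body_ax, body_ay_mm=body_ay)

    noise = _smooth_noise(grid, rng)

    # --- targets ---------------------------------------------------------
    if spec.u_shape:
        center = np.array([0.0, 8.0, 0.0])
        ptv_b = _horseshoe_mask(coords, center, 18.0, 32.0, 22.0, 11.0) & body
        record.update(ptv_b_volume_cm3=float(ptv_b.sum() * grid.voxel_volume_cm3),
                      ptv_b_center=list(center))
    else:
        v_b = rng.uniform(*spec.ptv_b_volume_range_cm3)
        side = rng.choice([-1.0, 1.0])
        center = np.array([side * rng.uniform(10.0, 32.0),
                           rng.uniform(-2.0, 18.0),
                           rng.uniform(-10.0, 14.0)])
        ptv_b = _blob(coords, center, _semiaxes(v_b, (1.0, 0.9, 1.1)),
                      noise, spec.noise_amplitude) & body
        record.update(ptv_b_volume_cm3=float(v_b), ptv_b_center=list(np.round(center, 2)),
                      ptv_b_side=float(side))

    dil5 = _dilate_mm(ptv_b, spec.transition_mm, grid) & body
    ptv_o = dil5 & ~ptv_b
    margin = rng.uniform(*spec.elective_margin_range_mm)
    e_full = _dilate_mm(ptv_b, spec.transition_mm + margin, grid)
    node_center = np.array([center[0] * 0.4, center[1] + rng.uniform(-6, 10),
                            center[2] - rng.uniform(8, 22)])
    node = _blob(coords, node_center, _semiaxes(rng.uniform(15, 40), (1.1, 1.0, 1.4)),
                 noise, spec.noise_amplitude)
    ptv_e = (e_full | node) & body & ~dil5
    record.update(elective_margin_mm=float(margin))
    for name, m in (("ptv_b", ptv_b), ("ptv_o", ptv_o), ("ptv_e", ptv_e)):
        if not m.any():
            raise ValueError(f"degenerate case: empty {name}")

    ptv_comp = ptv_b | ptv_o | ptv_e
    ptv_centroid = grid.index_to_world(np.argwhere(ptv_comp).mean(axis=0))

    # --- organs at risk --------------------------------------------------
    oars: list[Structure] = []
    for ospec in spec.oar_menu:
        sides = (-1.0, 1.0) if ospec.paired else (0.0,)
        placed: list[Structure] = []
        for side in sides:
            if rng.uniform() > ospec.presence_prob:
                continue
            vol = ospec.sample_volume(rng)
            ov = rng.uniform(*ospec.overlap_range)
            jitter = rng.uniform(-4.0, 4.0, size=3)
            base = np.array([side * ospec.base_pos_mm[0] if ospec.paired else ospec.base_pos_mm[0],
                             ospec.base_pos_mm[1], ospec.base_pos_mm[2]]) + jitter
            m = _place_with_overlap(coords, body, ptv_comp, base,
                                    _semiaxes(vol, ospec.aspect), noise,
                                    spec.noise_amplitude * 0.7, ov, ptv_centroid)
            if not m.any():
                continue
            suffix = {-1.0: "_r", 1.0: "_l"}.get(side, "")
            name = f"{ospec.name}{suffix}"
            placed.append(Structure(name, m, role="oar",
                                    laterality="n/a" if ospec.paired else "midline"))
            record[f"{name}_volume_cm3"] = float(vol)
            record[f"{name}_overlap_target"] = float(ov)
        if ospec.paired and len(placed) == 2:
            lat = assign_laterality(placed[0], placed[1], ptv_comp, grid)
            placed[0].laterality, placed[1].laterality = lat
        elif ospec.paired and len(placed) == 1:
            # single survivor of a pair: side label from the target's side
            cx = placed[0].centroid_mm(grid)[0]
            same_side = cx * ptv_centroid[0] >= 0
            placed[0].laterality = "ipsilateral" if same_side else "contralateral"
        oars.extend(placed)

    cord = (np.sqrt(X**2 + (Y - 42.0) ** 2) <= spec.cord_radius_mm) & body
    if cord.any():
        oars.append(Structure("spinal_cord", cord, role="oar", laterality="midline"))

    # --- fields ----------------------------------------------------------
    angles = [float(rng.uniform(lo, hi)) for lo, hi in spec.gantry_ranges_deg]
    record["gantry_deg"] = list(np.round(angles, 2))
    comp = Structure("ptv_comp", ptv_comp, role="composite")
    fields = [BeamField(a, comp) for a in angles]

    case = Case(
        id=record["case_id"],
        grid=grid,
        targets=[
            TargetLevel(Structure("ptv_b", ptv_b, role="target"), spec.boost_rx_Gy),
            TargetLevel(Structure("ptv_o", ptv_o, role="target"),
                        (spec.boost_rx_Gy + spec.elective_rx_Gy) / 2.0),
            TargetLevel(Structure("ptv_e", ptv_e, role="target"), spec.elective_rx_Gy),
        ],
        oars=oars,
        fields=fields,
        n_fractions=spec.n_fractions,
    )
    return case, record


def generate_cohort(spec: CohortSpec) -> tuple[list[Case], pd.DataFrame]:
    """Generate ``spec.n_cases`` cases plus a manifest of sampled parameters."""
    cases, records = [], []
    for i in range(spec.n_cases):
        case, rec = generate_case(spec, i)
        cases.append(case)
        records.append(rec)
    return cases, pd.DataFrame.from_records(records)
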