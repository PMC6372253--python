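"""Core data model for voxelized treatment-planning cases.

Conventions used throughout the package:

* Voxel indices are 0-based and masks are cell-centered on the grid.
* World coordinates are in millimetres, patient axes x = left,
  y = posterior, z = superior.
* Gantry angles follow IEC 61217 (0 deg = beam entering from anterior,
  increasing clockwise viewed from the patient's feet); beams are confined
  to the axial plane (couch = 0).
* Dose is total physical dose in Gy.

A *case* is a simultaneous-integrated-boost head-and-neck-like geometry:
three nested target levels (boost PTV_B, a 5-mm transition shell PTV_O and
the elective PTV_E, pairwise disjoint as stored), a set of organ-at-risk
masks, and a small number of coplanar proton fields whose shared field
target is PTV_COMP = PTV_B | PTV_O | PTV_E.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "Structure",
    "TargetLevel",
    "BeamField",
    "Case",
    "DoseGrid",
    "gantry_direction",
    "assign_laterality",
    "read_case",
    "write_case",
    "read_dose",
    "write_dose",
    "model_key",
]

ROLES = ("target", "oar", "composite")
LATERALITIES = ("ipsilateral", "contralateral", "midline", "n/a")

GEOM_TOL_MM = 1e-3  # header mismatch beyond this is rejected at load time


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid: dims (nx, ny, nz), spacing and origin in mm.

    ``origin_mm`` is the world position of the *center* of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"grid dims must be three integers >= 1, got {self.dims}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"grid spacing must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(self.dims[axis])

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world affine (used for NIfTI headers)."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing_mm)
        a[:3, 3] = self.origin_mm
        return a

    def close_to(self, other: "VoxelGrid", tol_mm: float = GEOM_TOL_MM) -> bool:
        return (
            self.dims == other.dims
            and all(abs(a - b) <= tol_mm for a, b in zip(self.spacing_mm, other.spacing_mm))
            and all(abs(a - b) <= tol_mm for a, b in zip(self.origin_mm, other.origin_mm))
        )


@dataclass
class Structure:
    """Named binary mask on the case grid.

    ``role`` is one of target / oar / composite; ``laterality`` follows the
    ipsilateral/contralateral convention of paired organs (the member of a
    left/right pair closer to or more overlapping the target is ipsilateral),
    midline for unpaired organs, "n/a" where the notion does not apply.
    Composite structures (e.g. combined salivary glands) carry the member
    names they were built from.
    """

    name: str
    mask: np.ndarray
    role: str = "oar"
    laterality: str = "n/a"
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role label {self.role!r} for structure {self.name!r}")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"unknown laterality {self.laterality!r} for {self.name!r}")
        self.mask = np.asarray(self.mask, dtype=bool)
        self.members = tuple(self.members)

    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def volume_cm3(self, grid: VoxelGrid) -> float:
        return self.voxel_count() * grid.voxel_volume_cm3

    def centroid_mm(self, grid: VoxelGrid) -> np.ndarray:
        idx = np.argwhere(self.mask)
        if idx.size == 0:
            raise ValueError(f"structure {self.name!r} is empty")
        return grid.index_to_world(idx.mean(axis=0))


@dataclass
class TargetLevel:
    """One prescription level of an SIB scheme (total dose over all fractions)."""

    structure: Structure
    prescription_Gy: float

    def __post_init__(self) -> None:
        if self.prescription_Gy <= 0:
            raise ValueError("prescription must be positive")


def gantry_direction(gantry_deg: float) -> np.ndarray:
    """Unit beam-travel direction in the axial plane for an IEC gantry angle."""
    th = np.deg2rad(float(gantry_deg) % 360.0)
    return np.array([-np.sin(th), np.cos(th), 0.0])


@dataclass
class BeamField:
    """Coplanar proton field: gantry angle plus its (union) field target."""

    gantry_deg: float
    field_target: Structure

    def __post_init__(self) -> None:
        self.gantry_deg = float(self.gantry_deg) % 360.0
        if self.field_target.voxel_count() == 0:
            raise ValueError("field target is empty")

    @property
    def direction(self) -> np.ndarray:
        return gantry_direction(self.gantry_deg)


@dataclass
class DoseGrid:
    """Total physical dose (Gy) on the case grid; finite and nonnegative."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose grid contains non-finite values")
        if self.values.min() < 0:
            raise ValueError("dose grid contains negative values")


@dataclass
class Case:
    id: str
    grid: VoxelGrid
    targets: list[TargetLevel]
    oars: list[Structure] = field(default_factory=list)
    fields: list[BeamField] = field(default_factory=list)
    n_fractions: int = 35

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        dims = self.grid.dims
        for lvl in self.targets:
            if lvl.structure.mask.shape != dims:
                raise ValueError(
                    f"grid mismatch: target {lvl.structure.name!r} mask shape "
                    f"{lvl.structure.mask.shape} != grid dims {dims}"
                )
        for s in self.oars:
            if s.mask.shape != dims:
                raise ValueError(
                    f"grid mismatch: structure {s.name!r} mask shape "
                    f"{s.mask.shape} != grid dims {dims}"
                )
        rx = [lvl.prescription_Gy for lvl in self.targets]
        if any(a <= b for a, b in zip(rx, rx[1:])):
            raise ValueError(
                f"prescription order violated: levels must be strictly decreasing "
                f"(boost first), got {rx}"
            )
        acc = np.zeros(dims, dtype=bool)
        for lvl in self.targets:
            if np.any(acc & lvl.structure.mask):
                raise ValueError("target levels are not pairwise disjoint")
            acc |= lvl.structure.mask
        names = [s.name for s in self.oars]
        if len(names) != len(set(names)):
            raise ValueError("duplicate OAR names in case")

    # -- conveniences -----------------------------------------------------
    def ptv_comp_mask(self) -> np.ndarray:
        """Union of all target levels (the per-field target, PTV_COMP)."""
        acc = np.zeros(self.grid.dims, dtype=bool)
        for lvl in self.targets:
            acc |= lvl.structure.mask
        return acc

    def target_by_name(self, name: str) -> TargetLevel:
        for lvl in self.targets:
            if lvl.structure.name == name:
                return lvl
        raise KeyError(name)

    def oar_by_name(self, name: str) -> Structure:
        for s in self.oars:
            if s.name == name:
                return s
        raise KeyError(name)


def model_key(structure: Structure) -> str:
    """Model-structure name an OAR maps to across cases.

    Paired organs are pooled by laterality (``parotid_ipsi`` rather than
    left/right) so that the training library matches anatomy by its relation
    to the target, not by patient side.
    """
    base = structure.name
    for suffix in ("_l", "_r", "_left", "_right"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    if structure.laterality == "ipsilateral":
        return f"{base}_ipsi"
    if structure.laterality == "contralateral":
        return f"{base}_contra"
    return base


def assign_laterality(
    oar_a: Structure,
    oar_b: Structure | None,
    ptv_mask: np.ndarray,
    grid: VoxelGrid,
) -> tuple[str, ...]:
    """Assign ipsilateral/contralateral labels to a left/right organ pair.

    Of the pair, the member with the greater PTV overlap fraction is
    ipsilateral; ties are broken by smaller centroid distance to the PTV
    centroid. A single (unpaired) structure is midline. Swapping the two
    inputs swaps the labels. Raises if both criteria tie exactly.
    """
    if oar_b is None:
        return ("midline",)
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    if not ptv_mask.any():
        raise ValueError("empty PTV mask")

    def overlap_fraction(s: Structure) -> float:
        n = s.voxel_count()
        if n == 0:
            raise ValueError(f"structure {s.name!r} is empty")
        return float((s.mask & ptv_mask).sum()) / n

    fa, fb = overlap_fraction(oar_a), overlap_fraction(oar_b)
    if fa > fb:
        return ("ipsilateral", "contralateral")
    if fb > fa:
        return ("contralateral", "ipsilateral")
    ptv_centroid = grid.index_to_world(np.argwhere(ptv_mask).mean(axis=0))
    da = float(np.linalg.norm(oar_a.centroid_mm(grid) - ptv_centroid))
    db = float(np.linalg.norm(oar_b.centroid_mm(grid) - ptv_centroid))
    if da < db:
        return ("ipsilateral", "contralateral")
    if db < da:
        return ("contralateral", "ipsilateral")
    raise ValueError(
        f"ambiguous laterality: {oar_a.name!r} and {oar_b.name!r} tie on both "
        "overlap fraction and centroid distance"
    )


# ---------------------------------------------------------------------------
# Case bundle I/O: case.json + one NIfTI file per mask
# ---------------------------------------------------------------------------


def _write_mask(path: Path, mask: np.ndarray, grid: VoxelGrid) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), grid.affine())
    nib.save(img, str(path))


def _read_volume(path: Path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    aff = img.affine
    grid = VoxelGrid(
        dims=tuple(int(d) for d in data.shape),
        spacing_mm=tuple(float(aff[i, i]) for i in range(3)),
        origin_mm=tuple(float(aff[i, 3]) for i in range(3)),
    )
    return data, grid


def write_case(case: Case, path: str | Path) -> Path:
    """Serialize a case to a directory bundle (case.json + NIfTI masks)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "id": case.id,
        "n_fractions": case.n_fractions,
        "grid": {
            "dims": list(case.grid.dims),
            "spacing_mm": list(case.grid.spacing_mm),
            "origin_mm": list(case.grid.origin_mm),
        },
        "targets": [
            {"name": lvl.structure.name, "prescription_Gy": lvl.prescription_Gy}
            for lvl in case.targets
        ],
        "structures": [
            {
                "name": s.name,
                "role": s.role,
                "laterality": s.laterality,
                "members": list(s.members),
            }
            for s in case.oars
        ],
        "fields": [{"gantry_deg": f.gantry_deg} for f in case.fields],
    }
    (path / "case.json").write_text(json.dumps(meta, indent=2))
    for lvl in case.targets:
        _write_mask(path / f"{lvl.structure.name}.nii.gz", lvl.structure.mask, case.grid)
    for s in case.oars:
        if s.role == "composite":
            continue  # rebuilt from members on load
        _write_mask(path / f"{s.name}.nii.gz", s.mask, case.grid)
    return path


def read_case(path: str | Path) -> Case:
    """Load a case bundle written by :func:`write_case`.

    All masks must share one grid; geometry-header mismatches beyond
    1e-3 mm are rejected.
    """
    path = Path(path)
    meta_path = path / "case.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no case.json in {path}")
    meta = json.loads(meta_path.read_text())
    grid = VoxelGrid(
        dims=tuple(meta["grid"]["dims"]),
        spacing_mm=tuple(meta["grid"]["spacing_mm"]),
        origin_mm=tuple(meta["grid"]["origin_mm"]),
    )

    def load_mask(name: str) -> np.ndarray:
        f = path / f"{name}.nii.gz"
        if not f.exists():
            raise FileNotFoundError(f"missing mask file for structure {name!r}: {f}")
        data, g = _read_volume(f)
        if not g.close_to(grid):
            raise ValueError(f"grid mismatch for structure {name!r}")
        return data.astype(bool)

    targets = [
        TargetLevel(
            Structure(t["name"], load_mask(t["name"]), role="target"),
            t["prescription_Gy"],
        )
        for t in meta["targets"]
    ]
    oars: list[Structure] = []
    simple = {}
    for rec in meta["structures"]:
        if rec["role"] == "composite":
            continue
        m = load_mask(rec["name"])
        s = Structure(rec["name"], m, role=rec["role"], laterality=rec["laterality"])
        simple[rec["name"]] = s
        oars.append(s)
    for rec in meta["structures"]:
        if rec["role"] != "composite":
            continue
        acc = np.zeros(grid.dims, dtype=bool)
        for member in rec["members"]:
            if member not in simple:
                raise ValueError(f"composite {rec['name']!r} references unknown member {member!r}")
            acc |= simple[member].mask
        oars.append(
            Structure(rec["name"], acc, role="composite",
                      laterality=rec["laterality"], members=tuple(rec["members"]))
        )
    case = Case(
        id=meta["id"],
        grid=grid,
        targets=targets,
        oars=oars,
        fields=[],
        n_fractions=int(meta.get("n_fractions", 35)),
    )
    comp = Structure("ptv_comp", case.ptv_comp_mask(), role="composite")
    case.fields = [BeamField(f["gantry_deg"], comp) for f in meta["fields"]]
    return case


def write_dose(dose: DoseGrid, grid: VoxelGrid, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(dose.values.astype(np.float32), grid.affine())
    nib.save(img, str(path))
    return path


def read_dose(path: str | Path, grid: VoxelGrid | None = None) -> DoseGrid:
    data, g = _read_volume(Path(path))
    if grid is not None and not g.close_to(grid):
        raise ValueError("dose grid geometry does not match case grid")
    return DoseGrid(np.asarray(data, dtype=float))
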