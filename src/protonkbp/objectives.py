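"""Optimization objectives and their automated placement from DVH predictions.

A knowledge-based plan is driven by upper dose-volume objectives placed at
the lower boundary of each OAR's predicted DVH band (minus an optional
offset), alongside fixed target-uniformity objectives at the prescriptions
and maximum-point-dose objectives for serial structures (spinal cord /
brainstem analogs). Objective priorities are mirrored from the manual plan
of the same case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

from .cases import Case
from .dvh import dose_at_volume

__all__ = [
    "Objective",
    "PlanningAims",
    "ObjectiveSet",
    "standard_target_objectives",
    "place_objectives",
    "save_objectives",
    "load_objectives",
    "SERIAL_MAX_DOSE_GY",
]

OBJECTIVE_KINDS = ("target_uniform", "upper_dose_volume", "mean_dose", "max_point")

# fixed maximum-point-dose aims for serial structures (total dose, Gy)
SERIAL_MAX_DOSE_GY: dict[str, float] = {"spinal_cord": 45.0, "brainstem": 54.0}

DEFAULT_ANCHORS_PERCENT = (10.0, 50.0, 85.0)


@dataclass(frozen=True)
class Objective:
    """One optimization objective.

    ``overdose_weight`` only affects ``target_uniform``: underdose is always
    penalized at full weight while overdose is down-weighted by this factor,
    so elective/transition levels tolerate the unavoidable hot gradient next
    to the boost while still being pulled toward their prescription.
    """

    structure: str
    kind: str
    dose_Gy: float
    priority: float
    volume_percent: float | None = None
    overdose_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in OBJECTIVE_KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.dose_Gy < 0:
            raise ValueError("objective dose must be nonnegative")
        if self.priority < 0:
            raise ValueError("objective priority must be nonnegative")
        if not 0 <= self.overdose_weight <= 1:
            raise ValueError("overdose_weight must lie in [0, 1]")
        if self.kind == "upper_dose_volume":
            if self.volume_percent is None or not 0 < self.volume_percent <= 100:
                raise ValueError("dose-volume objective needs volume_percent in (0, 100]")


@dataclass(frozen=True)
class PlanningAims:
    """Target planning aims: V95 coverage thresholds and the hot-volume cap."""

    v95_boost_percent: float = 99.0
    v95_elective_percent: float = 98.0
    v107_max_percent: float = 5.0


@dataclass
class ObjectiveSet:
    objectives: list[Objective]
    aims: PlanningAims = dc_field(default_factory=PlanningAims)

    def __post_init__(self) -> None:
        if not any(o.kind == "target_uniform" for o in self.objectives):
            raise ValueError("objective set must contain at least one target objective")

    def scaled_targets(self, factor: float) -> "ObjectiveSet":
        """Copy with target-objective priorities multiplied by ``factor``."""
        objs = [
            Objective(o.structure, o.kind, o.dose_Gy, o.priority * factor,
                      o.volume_percent, o.overdose_weight)
            if o.kind == "target_uniform" else o
            for o in self.objectives
        ]
        return ObjectiveSet(objs, self.aims)


def standard_target_objectives(
    case: Case,
    target_priority: float = 100.0,
    elective_priority: float = 300.0,
    transition_priority: float = 20.0,
    serial_priority: float = 25.0,
) -> list[Objective]:
    """Uniform-dose objectives at the prescriptions plus serial max-point caps.

    The boost level is penalized two-sided (homogeneity); transition and
    elective levels carry a small overdose weight because their voxels next
    to the boost are legitimately hot. Priorities weigh mean-per-voxel
    penalties, so the larger elective volume gets a higher priority to keep
    its per-voxel coverage pull comparable to the boost's.
    """
    objs: list[Objective] = []
    for lvl in case.targets:
        if lvl is case.targets[0]:
            objs.append(Objective(lvl.structure.name, "target_uniform",
                                  lvl.prescription_Gy, target_priority))
        elif lvl is case.targets[-1]:
            objs.append(Objective(lvl.structure.name, "target_uniform",
                                  lvl.prescription_Gy, elective_priority,
                                  overdose_weight=0.05))
        else:
            objs.append(Objective(lvl.structure.name, "target_uniform",
                                  lvl.prescription_Gy, transition_priority,
                                  overdose_weight=0.1))
    present = {s.name for s in case.oars}
    for name, dmax in SERIAL_MAX_DOSE_GY.items():
        if name in present:
            objs.append(Objective(name, "max_point", dmax, serial_priority))
    return objs


def place_objectives(
    bands: Mapping[str, "PredictionBand"],  # noqa: F821 - kbp model band type
    case: Case,
    priorities: Mapping[str, float],
    anchors_percent: Sequence[float] = DEFAULT_ANCHORS_PERCENT,
    offset_Gy: float = 0.0,
    priority_scale: float = 16.0,
    aims: PlanningAims | None = None,
) -> ObjectiveSet:
    """Build the KBP objective set from per-OAR prediction bands.

    For every OAR with a band, one upper dose-volume objective per volume
    anchor is placed at the lower-boundary dose at that volume minus
    ``offset_Gy`` (floored at 0). ``priorities`` maps OAR names to the
    priorities mirrored from the manual plan; ``priority_scale`` converts
    them to the dose-volume penalty scale, whose active-subset pull is much
    weaker per unit priority than a mean-dose penalty. OARs without a band
    or a priority emit no objective (a warning-level situation handled
    upstream).
    """
    from .cases import model_key  # local import to keep module deps light

    objs = standard_target_objectives(case)
    for s in case.oars:
        if s.role != "oar" or s.name in SERIAL_MAX_DOSE_GY:
            continue
        band = bands.get(model_key(s)) or bands.get(s.name)
        if band is None or s.name not in priorities:
            continue
        for v in anchors_percent:
            d = max(dose_at_volume(band.lower, float(v)) - offset_Gy, 0.0)
            objs.append(Objective(s.name, "upper_dose_volume", d,
                                  priority_scale * float(priorities[s.name]), float(v)))
    return ObjectiveSet(objs, aims or PlanningAims())


def save_objectives(objective_set: ObjectiveSet, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "aims": vars(objective_set.aims),
        "objectives": [
            {
                "structure": o.structure,
                "kind": o.kind,
                "dose_Gy": o.dose_Gy,
                "priority": o.priority,
                "volume_percent": o.volume_percent,
                "overdose_weight": o.overdose_weight,
            }
            for o in objective_set.objectives
        ],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_objectives(path: str | Path) -> ObjectiveSet:
    payload = json.loads(Path(path).read_text())
    return ObjectiveSet(
        [Objective(**rec) for rec in payload["objectives"]],
        PlanningAims(**payload["aims"]),
    )
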