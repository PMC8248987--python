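"""Experimental design tables.

A *library* is one RNA-seq sample: (individual, cell_type, treatment, plate).
Every treatment is delivered in a solvent, so each treatment label maps to
exactly one vehicle-control label (water or ethanol).  The vehicle controls
themselves appear as treatments whose label equals their vehicle label, which
lets a single design table describe both treated and control libraries.
"""

from __future__ import annotations

import itertools

import pandas as pd

CELL_TYPES = ("LCL", "IPSC", "CM")

#: treatment -> vehicle-control label
VEHICLE_MAP = {
    "caffeine": "water",
    "nicotine": "water",
    "copper": "water",
    "zinc": "water",
    "selenium": "water",
    "insulin": "water",
    "cadmium": "water",
    "acetaminophen": "water",
    "dexamethasone": "ethanol",
    "aldosterone": "ethanol",
    "retinoic_acid": "ethanol",
    "tunicamycin": "ethanol",
    # vehicle controls are their own treatment
    "water": "water",
    "ethanol": "ethanol",
}

CONTROL_LABELS = ("water", "ethanol")

DESIGN_COLUMNS = ["individual", "cell_type", "treatment", "vehicle", "plate", "is_control"]

LIBRARY_KEY = ["individual", "cell_type", "treatment", "plate"]


class DesignError(ValueError):
    """Raised when a design table violates its invariants."""


def default_design(
    n_individuals: int = 6,
    cell_types: tuple[str, ...] = CELL_TYPES,
    treatments: dict[str, str] | None = None,
    n_plates: int = 2,
) -> pd.DataFrame:
    """Fully crossed design: individuals x cell types x treatments x plates.

    ``treatments`` maps treatment label to vehicle label and must contain the
    vehicle controls as self-mapped entries; the default is the 12-treatment,
    2-control panel.
    """
    if treatments is None:
        treatments = VEHICLE_MAP
    individuals = [f"ind{i + 1}" for i in range(n_individuals)]
    plates = [f"plate{p + 1}" for p in range(n_plates)]
    rows = [
        {
            "individual": ind,
            "cell_type": ct,
            "treatment": tr,
            "vehicle": veh,
            "plate": pl,
            "is_control": tr == veh,
        }
        for ind, ct, (tr, veh), pl in itertools.product(
            individuals, cell_types, treatments.items(), plates
        )
    ]
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    validate_design(design)
    return design


def validate_design(design: pd.DataFrame) -> None:
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise DesignError(f"design table missing columns: {missing}")
    vmap = design.groupby("treatment")["vehicle"].nunique()
    bad = vmap[vmap > 1]
    if len(bad):
        raise DesignError(
            f"treatments mapped to more than one vehicle: {list(bad.index)}"
        )
    ctl = design[design["is_control"]]
    mismatched = ctl[ctl["treatment"] != ctl["vehicle"]]
    if len(mismatched):
        raise DesignError("control libraries must have treatment == vehicle")
    dup = design.duplicated(subset=LIBRARY_KEY)
    if dup.any():
        raise DesignError(f"{int(dup.sum())} duplicate library rows in design")


def control_labels(design: pd.DataFrame) -> list[str]:
    """Distinct vehicle labels, sorted; the first is the reference level."""
    return sorted(design["vehicle"].unique())
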