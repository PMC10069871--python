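"""Model variants: production profiles, division and differentiation rules.

Nine named rule bundles describe the simulated genotypes:

* ``M1``   — minimal model: phloem produces CLE41, cambium produces PXY;
  cambium divides when [PXY_active] exceeds a threshold and differentiates
  into xylem when large with low [PXY_active].  No phloem is produced.
* ``M2A``  — adds phloem formation: large cells with high [PXY_active]
  become phloem (positional "French flag" readout of the CLE41 gradient).
* ``M2B``  — M2A with ectopic CLE41 production in xylem (transgene analog).
* ``M2C``  — M2A with PXY production eliminated (receptor null).
* ``M2D``  — M2A with PXY production strongly reduced.
* ``M3A``  — extended model: divisions gated by a division factor DF
  (driven by PXY_active and the pole-derived factor PF), xylem fate read
  from positional [PXY], phloem split into parenchyma and poles patterned
  by PF lateral inhibition, PXY suppressed by the phloem-derived RP.
* ``M3B``  — M3A with ectopic CLE41 in xylem.
* ``M3C``  — M3A without CLE41-PXY binding (receptor null that keeps the
  positional PXY field intact).
* ``M4``   — M3A plus cell-type-specific wall stiffness.

One simulation step applies, in order: growth -> mechanical relaxation ->
wall yielding -> signaling integration -> differentiation pass ->
division pass.  A cell that differentiates in a step cannot divide in
that same step, and rule passes visit cells in randomized order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import mechanics, signaling
from .mesh import GeometryError, TissueMesh

__all__ = [
    "RuleThresholds",
    "ModelVariant",
    "VARIANTS",
    "get_variant",
    "default_thresholds",
    "default_params",
    "initialize_chemicals",
    "check_division",
    "check_differentiation",
    "step",
]

# Baseline production rates (concentration per unit time, model units).
PROD_PXY = 1.0
PROD_CLE41_PHLOEM = 1.0
PROD_CLE41_POLE = 1.0
PROD_CLE41_PARENCHYMA = 0.4
PROD_PF_POLE = 1.0
PROD_RP_PHLOEM = 1.0


@dataclass
class RuleThresholds:
    """Size and concentration gates for division and differentiation.

    Areas are in model units (the template's initial mean cell area is
    1).  ``div_area`` sits below ``diff_area_xylem`` so that actively
    dividing cells cycle below the differentiation sizes; cells that
    stop dividing grow past them and commit to a fate.
    ``diff_area_phloem`` must exceed ``diff_area_xylem``.
    """

    div_area: float = 1.3
    div_PXYactive: float = 0.15
    div_DF: float = 1.2
    diff_area_xylem: float = 2.1
    diff_area_phloem: float = 2.6
    diff_PXYactive: float = 0.6
    diff_PXY_positional: float = 0.6
    pole_PF_inhibit: float = 0.5

    def __post_init__(self) -> None:
        if self.diff_area_phloem <= self.diff_area_xylem:
            raise ValueError(
                "phloem differentiation size must exceed the xylem one")


@dataclass(frozen=True)
class ModelVariant:
    """A named rule bundle (production profile + predicates + switches)."""

    name: str
    family: int                       # 1, 2, 3 or 4
    pxy_scale: float = 1.0            # multiplier on cambial PXY production
    cle41_binding: bool = True        # CLE41 + PXY -> PXY_active active?
    xylem_cle41: bool = False         # ectopic CLE41 production in xylem
    stiffness_enabled: bool = False   # per-type wall stiffness (M4)

    @property
    def chemicals(self) -> tuple[str, ...]:
        if self.family <= 2:
            return ("CLE41", "PXY", "PXY_active")
        return ("CLE41", "PXY", "PXY_active", "PF", "DF", "RP")

    @property
    def pxy_suppressor(self) -> str:
        """Which species feeds the PXY-production inhibition term."""
        return "PXY_active" if self.family <= 2 else "RP"

    @property
    def df_in_types(self) -> tuple[str, ...] | None:
        """Cell types in which DF is produced (None = everywhere)."""
        if self.family <= 2:
            return None
        return ("cambium", "phloem_parenchyma")

    @property
    def division_types(self) -> tuple[str, ...]:
        if self.family <= 2:
            return ("cambium",)
        return ("cambium", "phloem_parenchyma")

    def production_profile(self, cell_type: str) -> dict[str, float]:
        """Per-chemical production rates for a cell type under this variant."""
        prod: dict[str, float] = {}
        if cell_type == "cambium":
            prod["PXY"] = PROD_PXY * self.pxy_scale
        if self.family <= 2:
            if cell_type == "phloem":
                prod["CLE41"] = PROD_CLE41_PHLOEM
            if self.xylem_cle41 and cell_type == "xylem":
                prod["CLE41"] = PROD_CLE41_PHLOEM
        else:
            if cell_type == "phloem_pole":
                prod["CLE41"] = PROD_CLE41_POLE
                prod["PF"] = PROD_PF_POLE
                prod["RP"] = PROD_RP_PHLOEM
            elif cell_type == "phloem_parenchyma":
                prod["CLE41"] = PROD_CLE41_PARENCHYMA
                prod["RP"] = PROD_RP_PHLOEM
            if self.xylem_cle41 and cell_type == "xylem":
                prod["CLE41"] = PROD_CLE41_POLE
        return prod


VARIANTS: dict[str, ModelVariant] = {
    "M1": ModelVariant("M1", family=1),
    "M2A": ModelVariant("M2A", family=2),
    "M2B": ModelVariant("M2B", family=2, xylem_cle41=True),
    "M2C": ModelVariant("M2C", family=2, pxy_scale=0.0),
    "M2D": ModelVariant("M2D", family=2, pxy_scale=0.05),
    "M3A": ModelVariant("M3A", family=3),
    "M3B": ModelVariant("M3B", family=3, xylem_cle41=True),
    "M3C": ModelVariant("M3C", family=3, cle41_binding=False),
    "M4": ModelVariant("M4", family=4, stiffness_enabled=True),
}


def get_variant(name: str) -> ModelVariant:
    try:
        return VARIANTS[name]
    except KeyError:
        raise KeyError(f"unknown model variant {name!r}; "
                       f"choose one of {sorted(VARIANTS)}") from None


def default_thresholds(variant: ModelVariant | str) -> RuleThresholds:
    return RuleThresholds()


def default_params(variant: ModelVariant | str):
    """Shipped default parameter bundle for a variant.

    Returns ``(mechanics_params, growth_params, signaling_params,
    thresholds)``.  M4 enables the cell-type-specific stiffness map
    (cambium half as stiff as surrounding tissue); the other variants
    use uniform wall stiffness.
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    mech = mechanics.MechanicsParams()
    if not variant.stiffness_enabled:
        mech.per_type_stiffness = {t: 1.0 for t in mech.per_type_stiffness}
    growth = mechanics.GrowthParams()
    sig = signaling.SignalingParams()
    thr = default_thresholds(variant)
    return mech, growth, sig, thr


def initialize_chemicals(tissue: TissueMesh, variant: ModelVariant,
                         sig: signaling.SignalingParams) -> None:
    """Set the initial chemical state of a fresh template.

    Cambium cells start at the CLE41-free PXY steady state
    ``prod_PXY / deg_PXY``; every other species starts at zero.
    """
    for cell in tissue.cells.values():
        cell.chemicals = {name: 0.0 for name in variant.chemicals}
        if cell.cell_type == "cambium":
            prod = variant.production_profile("cambium").get("PXY", 0.0)
            cell.chemicals["PXY"] = prod / sig.degradation["PXY"]


# ---------------------------------------------------------------------------
# Predicates
# ---------------------------------------------------------------------------

def check_division(cell, variant: ModelVariant, thresholds: RuleThresholds,
                   area: float | None = None,
                   tissue: TissueMesh | None = None) -> bool:
    """True iff the cell may divide this step.

    Only cambium (and, in the extended models, phloem parenchyma) cells
    divide, and only when large enough and when the variant's chemical
    gate passes: [PXY_active] above threshold for the basic models,
    [DF] above threshold for the extended ones.  In the family-2 models
    high [PXY_active] additionally inhibits division (the distal cambium
    layers stop cycling and can reach phloem size), so the gate there is
    a band bounded above by the phloem-fate threshold.
    """
    if cell.cell_type not in variant.division_types:
        return False
    if area is None:
        area = tissue.cell_area(cell)
    if area < thresholds.div_area:
        return False
    if variant.family <= 2:
        act = cell.conc("PXY_active")
        if act <= thresholds.div_PXYactive:
            return False
        if variant.family == 2 and act >= thresholds.diff_PXYactive:
            return False
        return True
    return cell.conc("DF") > thresholds.div_DF


def check_differentiation(cell, variant: ModelVariant,
                          thresholds: RuleThresholds,
                          tissue: TissueMesh,
                          area: float | None = None) -> str | None:
    """New cell type for a cambium cell, or None if it stays cambium.

    Basic models read cell fate from [PXY_active] (xylem when low,
    phloem — families 2+ only — when high and the cell is larger).
    Extended models use positional [PXY] instead: high [PXY] marks the
    proximal (xylem) domain; phloem-fated cells become poles by default
    unless inhibited by PF, in which case parenchyma.
    """
    if cell.cell_type != "cambium":
        return None
    if area is None:
        area = tissue.cell_area(cell)
    if variant.family <= 2:
        act = cell.conc("PXY_active")
        if area >= thresholds.diff_area_xylem and act < thresholds.diff_PXYactive:
            return "xylem"
        if (variant.family == 2
                and act >= thresholds.diff_PXYactive
                and area >= thresholds.diff_area_phloem):
            return "phloem"
        return None
    pxy = cell.conc("PXY")
    if area >= thresholds.diff_area_xylem and pxy >= thresholds.diff_PXY_positional:
        return "xylem"
    if area >= thresholds.diff_area_phloem and pxy < thresholds.diff_PXY_positional:
        if cell.conc("PF") > thresholds.pole_PF_inhibit:
            return "phloem_parenchyma"
        return "phloem_pole"
    return None


# ---------------------------------------------------------------------------
# Master update loop
# ---------------------------------------------------------------------------

def step(tissue: TissueMesh, variant: ModelVariant,
         thresholds: RuleThresholds, mech: mechanics.MechanicsParams,
         growth: mechanics.GrowthParams, sig: signaling.SignalingParams,
         rng: np.random.Generator,
         event_log: list | None = None) -> None:
    """Advance the simulation by one step (in place).

    Order: growth -> relax -> wall yielding -> signaling -> a
    differentiation pass -> a division pass.  Cells are visited in
    randomized order during the rule passes; a cell that changed type
    this step is skipped by the division pass.
    """
    mechanics.apply_growth(tissue, growth)
    mechanics.relax(tissue, mech, rng)
    mechanics.yield_walls(tissue, mech)
    signaling.integrate(tissue, sig, variant)

    areas = {cid: tissue.cell_area(c) for cid, c in tissue.cells.items()}

    changed: set[int] = set()
    cids = list(tissue.cells.keys())
    rng.shuffle(cids)
    for cid in cids:
        cell = tissue.cells[cid]
        new_type = check_differentiation(cell, variant, thresholds, tissue,
                                         area=areas[cid])
        if new_type is not None:
            cell.cell_type = new_type
            changed.add(cid)
            if event_log is not None:
                cx, cy = tissue.centroid(cell)
                event_log.append({
                    "step": tissue.step, "event": "differentiation",
                    "cell_id": cid, "new_type": new_type,
                    "x": cx, "y": cy,
                })

    cids = [c for c in tissue.cells.keys() if c not in changed]
    rng.shuffle(cids)
    for cid in cids:
        cell = tissue.cells[cid]
        if check_division(cell, variant, thresholds, area=areas[cid]):
            try:
                d1, d2 = tissue.divide_cell(cell, rng)
            except GeometryError:
                continue  # no valid balanced cut this step; retry next step
            if event_log is not None:
                ev = tissue.division_log[-1]
                event_log.append({
                    "step": tissue.step, "event": "division",
                    "cell_id": cid, "new_type": cell.cell_type,
                    "x": ev.parent_centroid[0], "y": ev.parent_centroid[1],
                })
    tissue.step += 1
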