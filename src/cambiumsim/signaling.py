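"""Intercellular signaling dynamics.

Each cell carries concentrations of up to six chemical species:

* ``CLE41`` — mobile peptide ligand produced by phloem-type cells,
* ``PXY``   — non-diffusing receptor produced by cambium cells,
* ``PXY_active`` — the ligand-bound receptor complex,
* ``PF``    — phloem-pole-derived proliferation factor (extended models),
* ``DF``    — intracellular division factor (extended models),
* ``RP``    — diffusible repressor of PXY production (extended models).

Local reactions per cell (production terms come from the active model
variant's per-type profile)::

    d[PXY_active]/dt = [PXY][CLE41] - deg_act [PXY_active]
    d[PXY]/dt        = prod_PXY / (1 + suppress_rate * S)
                       - [PXY][CLE41] - deg_PXY [PXY]
    d[CLE41]/dt      = prod_CLE41 - [PXY][CLE41] - deg_CLE41 [CLE41]
    d[PF]/dt         = prod_PF - deg_PF [PF]
    d[DF]/dt         = v_DF * Q / (1 + Q / K_DF) - deg_DF [DF]
    d[RP]/dt         = prod_RP - deg_RP [RP]

with ``S = [PXY_active]`` (basic models) or ``S = [RP]`` (extended
models), and ``Q = [PXY_active] + alpha_PF * [PF]`` — a saturating DF
production capped at ``v_DF * K_DF``.  Diffusive species exchange amount
across shared walls at rate ``D * wall_length * (c_nb - c_self)``; the
concentration form divides the net flux by cell area, so total amount is
conserved and the outer boundary is no-flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mesh import CHEMICALS, TissueMesh

__all__ = [
    "SignalingParams",
    "IntegrationError",
    "diffusion_rates",
    "reaction_rates",
    "integrate",
]

#: Species allowed to move between cells; the receptor and its complex stay put.
DIFFUSIVE = ("CLE41", "PF", "DF", "RP")


class IntegrationError(RuntimeError):
    """The explicit integrator went unstable (NaN or a large undershoot)."""


@dataclass
class SignalingParams:
    """Rates and integration controls for the chemical dynamics.

    All rates are per simulation-step time units; one tissue step spans
    ``dt`` time integrated in ``substeps`` explicit sub-steps.
    """

    degradation: dict[str, float] = field(default_factory=lambda: {
        "CLE41": 0.2,
        "PXY": 1.0,
        "PXY_active": 0.5,
        "PF": 0.3,
        "DF": 0.3,
        "RP": 0.3,
    })
    diffusion: dict[str, float] = field(default_factory=lambda: {
        "CLE41": 0.30,
        "PF": 0.10,
        "DF": 0.05,
        "RP": 0.30,
    })
    suppress_rate: float = 0.5
    v_DF: float = 1.0
    K_DF: float = 2.0
    alpha_PF: float = 2.0
    dt: float = 1.0
    substeps: int = 10
    method: str = "euler"  # "euler" (default) or "rk4" for convergence checks

    def __post_init__(self) -> None:
        for name, d in self.diffusion.items():
            if d < 0:
                raise ValueError(f"negative diffusion coefficient for {name}")
        for name, d in self.degradation.items():
            if d < 0:
                raise ValueError(f"negative degradation rate for {name}")


# ---------------------------------------------------------------------------
# Assembled state (arrays over cells)
# ---------------------------------------------------------------------------

class _Assembled:
    """Vectorized view of the tissue for one integrate() call."""

    def __init__(self, tissue: TissueMesh, chemicals: tuple[str, ...],
                 production: dict[str, np.ndarray]):
        self.cids = sorted(tissue.cells.keys())
        self.index = {cid: i for i, cid in enumerate(self.cids)}
        n = len(self.cids)
        self.areas = np.array([tissue.cell_area(c) for c in self.cids])
        self.conc = np.zeros((len(chemicals), n))
        for k, name in enumerate(chemicals):
            self.conc[k] = [tissue.cells[c].conc(name) for c in self.cids]
        self.production = production  # chem -> per-cell rate array
        # adjacency: for each shared wall, (i, j, length)
        em = tissue.edge_map()
        ii, jj, ll = [], [], []
        for key, owners in em.items():
            if len(owners) == 2:
                a, b = tuple(key)
                ii.append(self.index[owners[0]])
                jj.append(self.index[owners[1]])
                ll.append(tissue.wall_length(a, b))
        self.adj_i = np.array(ii, dtype=np.intp)
        self.adj_j = np.array(jj, dtype=np.intp)
        self.adj_len = np.array(ll)


def diffusion_rates(tissue: TissueMesh, chemical: str, D: float) -> dict[int, float]:
    """Per-cell d[c]/dt from wall-mediated diffusion alone.

    The amount flux across each shared wall is
    ``D * wall_length * (c_neighbor - c_self)``; a cell's concentration
    rate is the net flux divided by its area.  Boundary walls carry no
    flux.
    """
    if D < 0:
        raise ValueError("negative diffusion coefficient")
    cids = sorted(tissue.cells.keys())
    conc = {cid: tissue.cells[cid].conc(chemical) for cid in cids}
    flux = {cid: 0.0 for cid in cids}
    em = tissue.edge_map()
    for key, owners in em.items():
        if len(owners) != 2:
            continue
        a, b = tuple(key)
        ca, cb = owners
        f = D * tissue.wall_length(a, b) * (conc[cb] - conc[ca])
        flux[ca] += f
        flux[cb] -= f
    return {cid: flux[cid] / tissue.cell_area(cid) for cid in cids}


def reaction_rates(cell, params: SignalingParams, variant) -> dict[str, float]:
    """Local (non-diffusive) d[c]/dt for a single cell under a variant."""
    prod = variant.production_profile(cell.cell_type)
    chems = variant.chemicals
    c = {name: cell.conc(name) for name in chems}
    conv = (c.get("PXY", 0.0) * c.get("CLE41", 0.0)
            if variant.cle41_binding else 0.0)
    deg = params.degradation
    out: dict[str, float] = {}
    if "PXY_active" in chems:
        out["PXY_active"] = conv - deg["PXY_active"] * c["PXY_active"]
    if "PXY" in chems:
        s = c.get("RP", 0.0) if variant.pxy_suppressor == "RP" \
            else c.get("PXY_active", 0.0)
        out["PXY"] = (prod.get("PXY", 0.0) / (1.0 + params.suppress_rate * s)
                      - conv - deg["PXY"] * c["PXY"])
    if "CLE41" in chems:
        out["CLE41"] = (prod.get("CLE41", 0.0) - conv
                        - deg["CLE41"] * c["CLE41"])
    if "PF" in chems:
        out["PF"] = prod.get("PF", 0.0) - deg["PF"] * c["PF"]
    if "DF" in chems:
        q = c.get("PXY_active", 0.0) + params.alpha_PF * c.get("PF", 0.0)
        if variant.df_in_types is None or cell.cell_type in variant.df_in_types:
            prod_df = params.v_DF * q / (1.0 + q / params.K_DF)
        else:
            prod_df = 0.0
        out["DF"] = prod_df - deg["DF"] * c["DF"]
    if "RP" in chems:
        out["RP"] = prod.get("RP", 0.0) - deg["RP"] * c["RP"]
    return out


def _rates(asm: _Assembled, params: SignalingParams, variant,
           conc: np.ndarray, types: list[str]) -> np.ndarray:
    """Vectorized reaction + diffusion rates for all cells at once."""
    chems = variant.chemicals
    k = {name: i for i, name in enumerate(chems)}
    deg = params.degradation
    rates = np.zeros_like(conc)
    get = lambda name: conc[k[name]] if name in k else 0.0
    conv = get("PXY") * get("CLE41") if variant.cle41_binding else 0.0
    if "PXY_active" in k:
        rates[k["PXY_active"]] = conv - deg["PXY_active"] * conc[k["PXY_active"]]
    if "PXY" in k:
        s = get("RP") if variant.pxy_suppressor == "RP" else get("PXY_active")
        rates[k["PXY"]] = (asm.production["PXY"]
                           / (1.0 + params.suppress_rate * s)
                           - conv - deg["PXY"] * conc[k["PXY"]])
    if "CLE41" in k:
        rates[k["CLE41"]] = (asm.production["CLE41"] - conv
                             - deg["CLE41"] * conc[k["CLE41"]])
    if "PF" in k:
        rates[k["PF"]] = asm.production["PF"] - deg["PF"] * conc[k["PF"]]
    if "DF" in k:
        q = get("PXY_active") + params.alpha_PF * get("PF")
        prod_df = params.v_DF * q / (1.0 + q / params.K_DF)
        rates[k["DF"]] = prod_df * asm.df_mask - deg["DF"] * conc[k["DF"]]
    if "RP" in k:
        rates[k["RP"]] = asm.production["RP"] - deg["RP"] * conc[k["RP"]]
    # wall-mediated diffusion
    for name in chems:
        d = params.diffusion.get(name, 0.0)
        if name not in DIFFUSIVE or d == 0.0 or len(asm.adj_i) == 0:
            continue
        ci = conc[k[name]]
        f = d * asm.adj_len * (ci[asm.adj_j] - ci[asm.adj_i])
        net = np.zeros(len(ci))
        np.add.at(net, asm.adj_i, f)
        np.add.at(net, asm.adj_j, -f)
        rates[k[name]] += net / asm.areas
    return rates


def integrate(tissue: TissueMesh, params: SignalingParams, variant) -> None:
    """Advance all chemical concentrations by one tissue step (in place).

    Explicit integration over ``substeps`` sub-steps; tiny negative
    undershoots (< 1e-12) are clamped to zero, anything larger raises
    :class:`IntegrationError` naming the offending chemical.
    """
    chems = variant.chemicals
    production = {}
    for name in ("PXY", "CLE41", "PF", "RP"):
        production[name] = np.array([
            variant.production_profile(tissue.cells[c].cell_type).get(name, 0.0)
            for c in sorted(tissue.cells.keys())])
    asm = _Assembled(tissue, chems, production)
    types = [tissue.cells[c].cell_type for c in asm.cids]
    asm.df_mask = np.array([
        1.0 if (variant.df_in_types is None or t in variant.df_in_types)
        else 0.0 for t in types])
    conc = asm.conc
    # substep refinement: bound the stiffest local rate so explicit
    # stepping stays stable even for very small cells (D * perimeter / A)
    d_max = max((params.diffusion.get(n, 0.0) for n in chems
                 if n in DIFFUSIVE), default=0.0)
    rate = 0.0
    if d_max > 0.0 and len(asm.adj_i):
        load = np.zeros(len(asm.cids))
        np.add.at(load, asm.adj_i, asm.adj_len)
        np.add.at(load, asm.adj_j, asm.adj_len)
        rate = d_max * float(np.max(load / asm.areas))
    if "PXY" in chems and variant.cle41_binding:
        k = {name: i for i, name in enumerate(chems)}
        rate += float(max(conc[k["PXY"]].max(), conc[k["CLE41"]].max()))
    rate += max(params.degradation.values(), default=0.0)
    substeps = max(params.substeps, int(math.ceil(params.dt * rate / 0.5)))
    h = params.dt / substeps
    for _ in range(substeps):
        if params.method == "rk4":
            k1 = _rates(asm, params, variant, conc, types)
            k2 = _rates(asm, params, variant, conc + 0.5 * h * k1, types)
            k3 = _rates(asm, params, variant, conc + 0.5 * h * k2, types)
            k4 = _rates(asm, params, variant, conc + h * k3, types)
            conc = conc + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        else:
            conc = conc + h * _rates(asm, params, variant, conc, types)
        if not np.all(np.isfinite(conc)):
            bad = chems[int(np.argwhere(~np.isfinite(conc))[0][0])]
            raise IntegrationError(f"non-finite concentration of {bad}")
        low = conc.min(axis=1)
        for i, name in enumerate(chems):
            if low[i] < -1e-12:
                raise IntegrationError(
                    f"[{name}] undershot to {low[i]:.3e}; reduce dt or rates")
        np.clip(conc, 0.0, None, out=conc)
    for i, cid in enumerate(asm.cids):
        cell = tissue.cells[cid]
        for kk, name in enumerate(chems):
            cell.chemicals[name] = float(conc[kk, i])
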