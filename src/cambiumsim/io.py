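"""Snapshots, configuration, and the simulation driver.

Tissue state is serialized to a VirtualLeaf-style XML dialect::

    <tissue step="...">
      <nodes>    <node id= x= y=/> ... </nodes>
      <cells>    <cell id= type= target_area= lineage= born_at=>
                   <node ref=/>...  <chemical name= value=/>... </cell> ...
      <walls>    <wall id= n1= n2= c1= c2= stiffness=/> ... </walls>
      <boundary> <wall ref=/> ... </boundary>
    </tissue>

Round trips are lossless for all fields.  Run configuration is a flat
YAML mapping of sections (variant, template, mechanics, growth,
signaling, thresholds, run); unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import yaml

from . import analysis, cellrules, mechanics, signaling, template
from .mesh import BOUNDARY, TissueMesh

__all__ = [
    "read_tissue",
    "write_tissue",
    "RunConfig",
    "load_config",
    "simulate",
    "render_snapshot",
]

log = logging.getLogger("cambiumsim")

_FLOAT_FMT = "%.9g"  # stable 9-significant-digit float serialization


def _f(x: float) -> str:
    return _FLOAT_FMT % x


# ---------------------------------------------------------------------------
# XML snapshots
# ---------------------------------------------------------------------------

def write_tissue(tissue: TissueMesh, path: str | Path) -> None:
    """Write a tissue snapshot to the XML dialect described above."""
    root = ET.Element("tissue", step=str(tissue.step))
    nodes = ET.SubElement(root, "nodes")
    for vid in sorted(tissue.vertices):
        x, y = tissue.vertices[vid]
        ET.SubElement(nodes, "node", id=str(vid), x=_f(x), y=_f(y))
    cells = ET.SubElement(root, "cells")
    for cid in sorted(tissue.cells):
        cell = tissue.cells[cid]
        el = ET.SubElement(cells, "cell", id=str(cid), type=cell.cell_type,
                           target_area=_f(cell.target_area),
                           lineage=str(cell.lineage_id),
                           born_at=str(cell.born_at))
        for v in cell.ring:
            ET.SubElement(el, "node", ref=str(v))
        for name in sorted(cell.chemicals):
            ET.SubElement(el, "chemical", name=name,
                          value=_f(cell.chemicals[name]))
    walls = ET.SubElement(root, "walls")
    wall_list = tissue.walls()
    for w in wall_list:
        ET.SubElement(walls, "wall", id=str(w.id), n1=str(w.a), n2=str(w.b),
                      c1=str(w.owners[0]), c2=str(w.owners[1]),
                      stiffness=_f(w.stiffness_multiplier))
    boundary = ET.SubElement(root, "boundary")
    bykey = {frozenset((w.a, w.b)): w.id for w in wall_list}
    for a, b in tissue.boundary_ring():
        ET.SubElement(boundary, "wall", ref=str(bykey[frozenset((a, b))]))
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode",
                               xml_declaration=True)


def read_tissue(path: str | Path) -> TissueMesh:
    """Read an XML tissue snapshot; validates the mesh on load.

    A cell missing a concentration attribute defaults that chemical to 0
    with a logged warning; schema violations raise ``ValueError`` naming
    the offending element.
    """
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed XML in {path}: {exc}") from exc
    if root.tag != "tissue":
        raise ValueError(f"{path}: root element is <{root.tag}>, "
                         "expected <tissue>")
    tissue = TissueMesh()
    tissue.step = int(root.get("step", "0"))
    nodes = root.find("nodes")
    if nodes is None:
        raise ValueError(f"{path}: missing <nodes>")
    for el in nodes:
        try:
            tissue.add_vertex(float(el.get("x")), float(el.get("y")),
                              vid=int(el.get("id")))
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: bad <node> at tissue/nodes: {exc}") from exc
    cells_el = root.find("cells")
    if cells_el is None:
        raise ValueError(f"{path}: missing <cells>")
    for el in cells_el:
        cid = int(el.get("id"))
        ring = [int(n.get("ref")) for n in el.findall("node")]
        chem = {n.get("name"): float(n.get("value"))
                for n in el.findall("chemical")}
        try:
            cell = tissue.add_cell(ring, el.get("type"), cid=cid,
                                   chemicals=chem,
                                   lineage_id=int(el.get("lineage", cid)),
                                   born_at=int(el.get("born_at", "0")))
        except ValueError as exc:
            raise ValueError(f"{path}: bad <cell id={cid}>: {exc}") from exc
        ta = el.get("target_area")
        if ta is None:
            log.warning("cell %d: missing target_area, defaulting to area",
                        cid)
            cell.target_area = tissue.cell_area(cell)
        else:
            cell.target_area = float(ta)
    walls_el = root.find("walls")
    if walls_el is not None:
        for el in walls_el:
            s = float(el.get("stiffness", "1"))
            if s != 1.0:
                key = frozenset((int(el.get("n1")), int(el.get("n2"))))
                tissue.wall_extra[key] = s
    try:
        tissue.validate()
    except ValueError as exc:
        raise ValueError(f"{path}: invalid mesh: {exc}") from exc
    return tissue


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation run."""

    variant: str = "M1"
    template_spec: template.TemplateSpec = field(
        default_factory=template.TemplateSpec)
    mechanics_params: mechanics.MechanicsParams | None = None
    growth_params: mechanics.GrowthParams | None = None
    signaling_params: signaling.SignalingParams | None = None
    thresholds: cellrules.RuleThresholds | None = None
    n_steps: int = 300
    snapshot_every: int = 0  # 0 = final snapshot only
    replicates: int = 1
    master_seed: int = 0
    outdir: str = "out"

    def resolved(self):
        """Fill unset sections with the variant's defaults."""
        mech, growth, sig, thr = cellrules.default_params(self.variant)
        return (self.mechanics_params or mech,
                self.growth_params or growth,
                self.signaling_params or sig,
                self.thresholds or thr)


_SECTION_TYPES = {
    "template": template.TemplateSpec,
    "mechanics": mechanics.MechanicsParams,
    "growth": mechanics.GrowthParams,
    "signaling": signaling.SignalingParams,
    "thresholds": cellrules.RuleThresholds,
}
_SECTION_ATTRS = {
    "template": "template_spec",
    "mechanics": "mechanics_params",
    "growth": "growth_params",
    "signaling": "signaling_params",
    "thresholds": "thresholds",
}


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    run_keys = {"variant", "n_steps", "snapshot_every", "replicates",
                "master_seed", "outdir"}
    for key, val in raw.items():
        if key in run_keys:
            setattr(cfg, key, val)
        elif key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            base = cls()
            names = {f.name for f in dataclasses.fields(cls)}
            for k, v in (val or {}).items():
                if k not in names:
                    raise ValueError(
                        f"unknown key {key}.{k} in config {path}")
                setattr(base, k, v)
            setattr(cfg, _SECTION_ATTRS[key], base)
        else:
            raise ValueError(f"unknown config section {key!r} in {path}")
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

def _config_digest(cfg: RunConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        return str(obj)
    payload = json.dumps(dataclasses.asdict(cfg), default=enc, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate(cfg: RunConfig) -> list[Path]:
    """Run ``cfg.replicates`` seeded simulations and write artifacts.

    Per replicate directory: XML snapshots (every ``snapshot_every``
    steps plus the final state), the per-step event log, the final
    per-cell table and a manifest (config hash + seeds).  Child seeds
    derive from the master seed so replicates are independent streams;
    returns the replicate directories.
    """
    variant = cellrules.get_variant(cfg.variant)
    outroot = Path(cfg.outdir)
    outroot.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.master_seed)
    children = ss.spawn(cfg.replicates)
    dirs = []
    for rep, child in enumerate(children):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        repdir = outroot / f"rep{rep:03d}"
        repdir.mkdir(parents=True, exist_ok=True)
        tissue, events = run_simulation(cfg, variant, rep_seed,
                                        snapshot_dir=repdir)
        write_tissue(tissue, repdir / "final.xml")
        pdf = analysis.cells_table(tissue)
        pdf.to_csv(repdir / "cells.csv", index=False,
                   float_format=_FLOAT_FMT)
        import pandas as pd
        pd.DataFrame(events).to_csv(repdir / "events.csv", index=False,
                                    float_format=_FLOAT_FMT)
        manifest = {
            "config_digest": _config_digest(cfg),
            "variant": cfg.variant,
            "master_seed": cfg.master_seed,
            "replicate": rep,
            "replicate_seed": rep_seed,
            "n_steps": cfg.n_steps,
            "final_cells": len(tissue.cells),
        }
        (repdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        dirs.append(repdir)
    return dirs


def run_simulation(cfg: RunConfig, variant=None, seed: int | None = None,
                   snapshot_dir: Path | None = None):
    """Run one simulation in memory; returns (tissue, event_log)."""
    if variant is None:
        variant = cellrules.get_variant(cfg.variant)
    if seed is None:
        seed = cfg.master_seed
    mech, growth, sig, thr = cfg.resolved()
    spec = dataclasses.replace(cfg.template_spec, seed=seed)
    tissue = template.make_template(spec, variant, sig)
    rng = np.random.default_rng(seed)
    events: list[dict] = []
    for i in range(cfg.n_steps):
        cellrules.step(tissue, variant, thr, mech, growth, sig, rng,
                       event_log=events)
        if (snapshot_dir is not None and cfg.snapshot_every
                and tissue.step % cfg.snapshot_every == 0):
            write_tissue(tissue,
                         snapshot_dir / f"step{tissue.step:05d}.xml")
    return tissue, events


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

TYPE_COLORS = {
    "cambium": "#4878cf",
    "xylem": "#d1422f",
    "phloem": "#7b3294",
    "phloem_parenchyma": "#c2a5cf",
    "phloem_pole": "#5e3c99",
}


def render_snapshot(tissue: TissueMesh, channel: str,
                    path: str | Path) -> None:
    """Render the polygon tessellation to a PNG.

    ``channel`` is either ``"type"`` (cell-type colors) or a chemical
    name (heat map normalized to the maximum cell).  Deterministic.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    polys = []
    colors = []
    chems = set()
    for c in tissue.cells.values():
        chems.update(c.chemicals)
    if channel != "type" and channel not in chems:
        raise ValueError(f"unknown channel {channel!r}; "
                         f"use 'type' or one of {sorted(chems)}")
    if channel == "type":
        for cell in tissue.cells.values():
            polys.append(tissue.ring_coords(cell))
            colors.append(TYPE_COLORS.get(cell.cell_type, "#999999"))
        coll = PolyCollection(polys, facecolors=colors,
                              edgecolors="black", linewidths=0.3)
    else:
        vals = []
        for cell in tissue.cells.values():
            polys.append(tissue.ring_coords(cell))
            vals.append(cell.conc(channel))
        vmax = max(vals) or 1.0
        coll = PolyCollection(polys, array=np.array(vals) / vmax,
                              cmap="viridis", edgecolors="black",
                              linewidths=0.3)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.add_collection(coll)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_title(channel)
    fig.savefig(path, dpi=150, metadata={"Software": None})
    plt.close(fig)
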