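"""Synthetic initial-tissue generator.

The starting tissue is a disk of concentric cell rings: a xylem core,
a deliberately broad cambium ring (so the stem-cell pool is not lost to
early stochastic differentiation), and an outer phloem ring.  For the
extended model family the outer ring is split into phloem parenchyma
and regularly spaced phloem poles.  Ring radii follow sqrt(k) spacing so
every cell starts with (approximately) the same area, which defines the
model's unit of area; small vertex jitter breaks the rotational symmetry
that the stochastic simulations need to diverge between seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cellrules, signaling
from .mesh import TissueMesh

__all__ = ["TemplateSpec", "make_template", "template_report"]


@dataclass
class TemplateSpec:
    """Geometry and typing of the initial tissue.

    ``radius`` is the outer tissue radius in model length units; with
    the defaults (5 rings of 16 cells inside radius 5) the mean initial
    cell area is ~pi*25/80 ~ 0.98.  ``jitter`` is the vertex noise as a
    fraction of the local cell size; ``pole_fraction`` is the fraction
    of outer-ring cells initialized as phloem poles for the extended
    model family.
    """

    n_rings_xylem: int = 1
    n_rings_cambium: int = 3
    n_rings_phloem: int = 1
    cells_per_ring: int = 16
    radius: float = 5.0
    jitter: float = 0.05
    pole_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_rings_xylem, self.n_rings_cambium,
               self.n_rings_phloem) < 1:
            raise ValueError("each tissue zone needs at least one ring")
        if self.cells_per_ring < 3:
            raise ValueError("need at least 3 cells per ring")
        if not 0.0 <= self.pole_fraction <= 1.0:
            raise ValueError("pole_fraction must be in [0, 1]")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def make_template(spec: TemplateSpec,
                  variant: cellrules.ModelVariant | str = "M1",
                  sig: signaling.SignalingParams | None = None) -> TissueMesh:
    """Build the concentric-ring starting tissue for a model variant.

    The innermost ring consists of wedge cells sharing a central vertex,
    so the mesh tiles the full disk.  Cell types are assigned by ring
    (xylem inside, then cambium, then phloem or parenchyma/poles), the
    chemical state is initialized per variant, and every cell's target
    area is set to its realized area.  Deterministic for a given seed.
    """
    if isinstance(variant, str):
        variant = cellrules.get_variant(variant)
    if sig is None:
        sig = signaling.SignalingParams()
    n_rings = spec.n_rings_xylem + spec.n_rings_cambium + spec.n_rings_phloem
    m = spec.cells_per_ring
    if n_rings * m > 20000:
        raise ValueError("template too large: rings x cells exceeds budget")
    rng = np.random.default_rng(spec.seed)

    tissue = TissueMesh()
    radii = [spec.radius * math.sqrt(k / n_rings) for k in range(n_rings + 1)]
    angles = [2.0 * math.pi * i / m for i in range(m)]

    # vertex grid: center + one ring of m vertices per radius level
    center = tissue.add_vertex(0.0, 0.0)
    grid: list[list[int]] = []
    for k in range(1, n_rings + 1):
        ring_vids = []
        # jitter scale: a fraction of the local radial ring width
        width = radii[k] - radii[k - 1]
        for th in angles:
            dr = rng.normal(0.0, spec.jitter * width)
            dth = rng.normal(0.0, spec.jitter * width / max(radii[k], 1e-9))
            r = radii[k] + dr
            a = th + dth
            ring_vids.append(tissue.add_vertex(r * math.cos(a),
                                               r * math.sin(a)))
        grid.append(ring_vids)

    phloem_rings = set(range(n_rings - spec.n_rings_phloem, n_rings))
    cambium_rings = set(range(spec.n_rings_xylem,
                              n_rings - spec.n_rings_phloem))
    pole_every = (max(1, round(1.0 / spec.pole_fraction))
                  if spec.pole_fraction > 0 else 0)

    for k in range(n_rings):
        if k in cambium_rings:
            base_type = "cambium"
        elif k in phloem_rings:
            base_type = "phloem"
        else:
            base_type = "xylem"
        outer = grid[k]
        inner = grid[k - 1] if k > 0 else None
        for i in range(m):
            j = (i + 1) % m
            ctype = base_type
            if base_type == "phloem" and variant.family >= 3:
                ctype = ("phloem_pole"
                         if pole_every and i % pole_every == 0
                         else "phloem_parenchyma")
            if inner is None:
                ring = [center, outer[i], outer[j]]
            else:
                # CCW: inner i -> inner j is CCW along the inner circle,
                # so the quad inner_i, outer_i reversed keeps CCW winding
                ring = [inner[i], outer[i], outer[j], inner[j]]
            tissue.add_cell(ring, ctype)

    # fix winding: ensure every cell is CCW (jitter cannot flip quads at
    # 5% noise, but be safe for extreme specs)
    from .mesh import polygon_area
    for cell in tissue.cells.values():
        if polygon_area(tissue.ring_coords(cell)) < 0:
            cell.ring.reverse()

    for cell in tissue.cells.values():
        cell.target_area = tissue.cell_area(cell)
        cell.lineage_id = cell.id
    cellrules.initialize_chemicals(tissue, variant, sig)
    tissue.validate()
    return tissue


def template_report(tissue: TissueMesh) -> pd.DataFrame:
    """Composition summary: count, fraction and total area per cell type."""
    rows = []
    total = len(tissue.cells)
    by_type: dict[str, list] = {}
    for cell in tissue.cells.values():
        by_type.setdefault(cell.cell_type, []).append(tissue.cell_area(cell))
    for ctype in sorted(by_type):
        areas = by_type[ctype]
        rows.append({
            "cell_type": ctype,
            "count": len(areas),
            "fraction": len(areas) / total,
            "total_area": float(np.sum(areas)),
        })
    return pd.DataFrame(rows)
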