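"""Energy-based tissue mechanics.

The tissue energy is a Hamiltonian with a turgor term (quadratic in the
deviation of each cell's area from its target area) and a wall term
(quadratic in the deviation of each wall element's length from a global
target length)::

    H = lambda_area * sum_cells (A_c - A_c^target)^2
      + sum_walls   lambda_L(w) * (l_w - L_T)^2

``lambda_L`` is cell-type specific ("cellwallstiffness"): a shared wall
uses the stiffer of its two owners' multipliers, and perimeter walls use
the boundary (epidermis) multiplier.  The energy is minimized
stochastically by Metropolis single-vertex moves; cells grow by
incrementing their target area, and overstretched wall elements yield by
midpoint vertex insertion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mesh import BOUNDARY, TissueMesh

__all__ = [
    "MechanicsParams",
    "GrowthParams",
    "hamiltonian",
    "relax",
    "apply_growth",
    "yield_walls",
]


def _default_stiffness() -> dict[str, float]:
    # cambium stem cells are assumed half as stiff as the surrounding tissue
    return {
        "cambium": 0.5,
        "xylem": 1.0,
        "phloem": 1.0,
        "phloem_parenchyma": 1.0,
        "phloem_pole": 1.0,
        "boundary": 1.0,
    }


@dataclass
class MechanicsParams:
    """Parameters of the tissue Hamiltonian and its stochastic relaxation.

    lambda_area : energy per area^2, weight of the turgor term.
    lambda_length_base : energy per length^2, baseline wall weight (lambda_L).
    per_type_stiffness : multiplier of lambda_L per owning cell type.
    boundary_stiffness : multiplier for perimeter ("epidermis") walls.
    target_element_length : rest length L_T of a wall element.
    yield_threshold : stretch ratio l/L_T above which a wall element is split.
    mc_step : scale (s.d.) of proposed Gaussian vertex displacements.
    mc_temperature : Metropolis energy scale; 0 means greedy descent.
    moves_per_step : proposals per relax call; None = one per vertex.
    """

    lambda_area: float = 1.0
    lambda_length_base: float = 0.2
    per_type_stiffness: dict[str, float] = field(default_factory=_default_stiffness)
    boundary_stiffness: float = 1.0
    target_element_length: float = 1.0
    yield_threshold: float = 2.0
    mc_step: float = 0.12
    mc_temperature: float = 0.001
    moves_per_step: int | None = None

    def wall_lambda(self, type_a: str | None, type_b: str | None,
                    extra: float = 1.0) -> float:
        """Effective lambda_L of a wall owned by the given cell types.

        ``None`` stands for the outside of the tissue (perimeter wall).
        """
        if type_a is None or type_b is None:
            mult = self.boundary_stiffness
        else:
            mult = max(self.per_type_stiffness[type_a],
                       self.per_type_stiffness[type_b])
        return self.lambda_length_base * mult * extra


@dataclass
class GrowthParams:
    """Target-area growth: each non-boundary cell's target area grows by
    ``growth_rate`` per step until the type-specific cap ``max_area``."""

    growth_rate: float = 0.02
    max_area: dict[str, float] = field(default_factory=lambda: {
        "cambium": 4.5,
        "xylem": 3.0,
        "phloem": 3.2,
        "phloem_parenchyma": 3.2,
        "phloem_pole": 3.2,
    })


# ---------------------------------------------------------------------------
# Hamiltonian
# ---------------------------------------------------------------------------

def _wall_entries(tissue: TissueMesh, params: MechanicsParams):
    """Unique walls as (vid_a, vid_b, effective_lambda) triples."""
    em = tissue.edge_map()
    entries = []
    for key, owners in em.items():
        a, b = tuple(key)
        extra = tissue.wall_extra.get(key, 1.0)
        if len(owners) == 1:
            lam = params.wall_lambda(None, None, extra)
        else:
            lam = params.wall_lambda(tissue.cells[owners[0]].cell_type,
                                     tissue.cells[owners[1]].cell_type, extra)
        entries.append((a, b, lam))
    return entries

def hamiltonian(tissue: TissueMesh, params: MechanicsParams) -> float:
    """Total tissue energy (non-negative; zero at the global rest state)."""
    h = 0.0
    for cell in tissue.cells.values():
        da = tissue.cell_area(cell) - cell.target_area
        h += params.lambda_area * da * da
    lt = params.target_element_length
    for a, b, lam in _wall_entries(tissue, params):
        dl = tissue.wall_length(a, b) - lt
        h += lam * dl * dl
    return h


# ---------------------------------------------------------------------------
# Metropolis relaxation
# ---------------------------------------------------------------------------

def _move_breaks_ring(ring_xy: np.ndarray, iv: int,
                      newpt: tuple[float, float]) -> bool:
    """True if moving ring vertex ``iv`` to ``newpt`` makes the polygon
    self-intersect (the two moved edges tested against all ring edges)."""
    n = len(ring_xy)
    if n <= 3:
        return False
    sx = ring_xy[:, 0]
    sy = ring_xy[:, 1]
    ex = np.concatenate((sx[1:], sx[:1]))
    ey = np.concatenate((sy[1:], sy[:1]))
    nx, ny = newpt
    prev = (iv - 1) % n
    for edge in (prev, iv):
        # edge prev: p -> v and edge iv: v -> next, with v replaced
        if edge == iv:
            ax, ay = nx, ny
            bx, by = ex[iv], ey[iv]
        else:
            ax, ay = sx[prev], sy[prev]
            bx, by = nx, ny
        # proper-intersection orientation tests (no division, endpoint
        # touching does not count)
        dx, dy = bx - ax, by - ay
        o1 = dx * (sy - ay) - dy * (sx - ax)
        o2 = dx * (ey - ay) - dy * (ex - ax)
        gx, gy = ex - sx, ey - sy
        o3 = gx * (ay - sy) - gy * (ax - sx)
        o4 = gx * (by - sy) - gy * (bx - sx)
        hit = (o1 * o2 < 0.0) & (o3 * o4 < 0.0)
        hit[prev] = False
        hit[iv] = False
        if hit.any():
            return True
    return False


def relax(tissue: TissueMesh, params: MechanicsParams,
          rng: np.random.Generator) -> int:
    """One relaxation pass: ``moves_per_step`` Metropolis vertex moves.

    A move is accepted when it lowers the energy, or with probability
    ``exp(-dH / mc_temperature)`` otherwise.  Moves that would invert a
    cell (non-positive area), collapse a wall, displace a vertex by more
    than half its shortest incident wall, or self-intersect any incident
    cell's ring are rejected.  Returns the number of accepted moves.
    """
    vids = list(tissue.vertices.keys())
    nv = len(vids)
    if nv == 0:
        return 0
    pos = dict(tissue.vertices)

    # incident cells per vertex: (cell_id, prev_vid, next_vid, ring_index)
    vcells: dict[int, list[tuple[int, int, int, int]]] = {v: [] for v in vids}
    areas: dict[int, float] = {}
    targets: dict[int, float] = {}
    rings_xy: dict[int, np.ndarray] = {}
    for cell in tissue.cells.values():
        ring = cell.ring
        n = len(ring)
        areas[cell.id] = tissue.cell_area(cell)
        targets[cell.id] = cell.target_area
        rings_xy[cell.id] = tissue.ring_coords(cell)
        for i in range(n):
            vcells[ring[i]].append((cell.id, ring[i - 1], ring[(i + 1) % n], i))

    # incident walls per vertex: (other_vid, lambda_eff)
    vwalls: dict[int, list[tuple[int, float]]] = {v: [] for v in vids}
    for a, b, lam in _wall_entries(tissue, params):
        vwalls[a].append((b, lam))
        vwalls[b].append((a, lam))

    la = params.lambda_area
    lt = params.target_element_length
    temp = params.mc_temperature
    nmoves = params.moves_per_step if params.moves_per_step else nv

    pick = rng.integers(0, nv, nmoves)
    disp = rng.normal(0.0, params.mc_step, (nmoves, 2))
    uacc = rng.random(nmoves)

    accepted = 0
    exp = math.exp
    hyp = math.hypot
    for k in range(nmoves):
        v = vids[pick[k]]
        x0, y0 = pos[v]
        dx = disp[k, 0]
        dy = disp[k, 1]
        x1 = x0 + dx
        y1 = y0 + dy
        dh = 0.0
        # wall terms + displacement guard
        ok = True
        min_len = 1e30
        for u, lam in vwalls[v]:
            ux, uy = pos[u]
            l_old = hyp(ux - x0, uy - y0)
            l_new = hyp(ux - x1, uy - y1)
            if l_new < 1e-9:
                ok = False
                break
            if l_old < min_len:
                min_len = l_old
            d0 = l_old - lt
            d1 = l_new - lt
            dh += lam * (d1 * d1 - d0 * d0)
        if not ok or hyp(dx, dy) > 0.5 * min_len:
            continue
        # area terms
        das = []
        for cid, p, n, _ in vcells[v]:
            px, py = pos[p]
            nx, ny = pos[n]
            da = 0.5 * ((px - nx) * dy + (ny - py) * dx)
            a_old = areas[cid]
            a_new = a_old + da
            if a_new <= 1e-9:
                ok = False
                break
            t = targets[cid]
            d0 = a_old - t
            d1 = a_new - t
            dh += la * (d1 * d1 - d0 * d0)
            das.append((cid, da))
        if not ok:
            continue
        if dh > 0.0:
            if temp <= 0.0:
                continue
            if uacc[k] >= exp(-dh / temp):
                continue
        # geometric validity only for otherwise-accepted moves (cheaper)
        bad = False
        for cid, _, _, iv in vcells[v]:
            if _move_breaks_ring(rings_xy[cid], iv, (x1, y1)):
                bad = True
                break
        if bad:
            continue
        pos[v] = (x1, y1)
        for cid, da in das:
            areas[cid] += da
        for cid, _, _, iv in vcells[v]:
            rings_xy[cid][iv, 0] = x1
            rings_xy[cid][iv, 1] = y1
        accepted += 1

    tissue.vertices.update(pos)
    return accepted


# ---------------------------------------------------------------------------
# Growth and wall yielding
# ---------------------------------------------------------------------------

def apply_growth(tissue: TissueMesh, growth: GrowthParams) -> None:
    """Increment every cell's target area, capped per cell type."""
    for cell in tissue.cells.values():
        cap = growth.max_area.get(cell.cell_type, math.inf)
        if cell.target_area < cap:
            cell.target_area = min(cell.target_area + growth.growth_rate, cap)


def yield_walls(tissue: TissueMesh, params: MechanicsParams) -> int:
    """Split every overstretched wall element at its midpoint.

    An element yields when its length exceeds
    ``yield_threshold * target_element_length``.  Both halves inherit the
    owners and any extra stiffness multiplier.  Returns the number of
    inserted vertices (one pass; call repeatedly to reach a fixed point).
    """
    limit = params.yield_threshold * params.target_element_length
    em = tissue.edge_map()
    n_split = 0
    for key in list(em.keys()):
        a, b = tuple(key)
        if tissue.wall_length(a, b) > limit:
            ax, ay = tissue.vertices[a]
            bx, by = tissue.vertices[b]
            tissue.split_edge(a, b, 0.5 * (ax + bx), 0.5 * (ay + by))
            n_split += 1
    return n_split
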