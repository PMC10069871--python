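"""Planar polygonal tissue mesh.

The tissue is a planar partition into simple polygonal cells that share
vertices and wall elements, in the style of vertex/cell-based frameworks
for plant tissue simulation.  Cells carry a type, per-cell chemical
concentrations, a target area and a lineage identity.  The only
topological operations are cell division (a straight cut through the
centroid, normal to the cell's major axis) and wall-element splitting
(vertex insertion on an edge); there are no T1/T2 rearrangements and no
cell removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "BOUNDARY",
    "CELL_TYPES",
    "CHEMICALS",
    "Cell",
    "WallElement",
    "TissueMesh",
    "DivisionEvent",
    "GeometryError",
    "MeshError",
    "polygon_area",
    "polygon_centroid",
    "polygon_second_moments",
]

#: Sentinel cell id for "outside the tissue" (one side of a boundary wall).
BOUNDARY = -1

#: Recognized cell types.  ``boundary`` only ever appears as a wall owner.
CELL_TYPES = (
    "cambium",
    "xylem",
    "phloem",
    "phloem_parenchyma",
    "phloem_pole",
    "boundary",
)

#: Canonical chemical species names, in serialization order.
CHEMICALS = ("CLE41", "PXY", "PXY_active", "PF", "DF", "RP")


class GeometryError(ValueError):
    """A polygon is degenerate or an operation on it is ill-posed."""


class MeshError(ValueError):
    """The tissue mesh violates a structural invariant."""


# ---------------------------------------------------------------------------
# Polygon geometry
# ---------------------------------------------------------------------------

def polygon_area(xy: np.ndarray) -> float:
    """Signed shoelace area of a polygon given as an (n, 2) array.

    Positive for counter-clockwise winding.
    """
    x = xy[:, 0]
    y = xy[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def polygon_centroid(xy: np.ndarray) -> tuple[float, float]:
    """Area-weighted centroid of a simple polygon (not the vertex mean)."""
    x = xy[:, 0]
    y = xy[:, 1]
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * float(np.sum(cross))
    if abs(a) < 1e-14:
        raise GeometryError("degenerate polygon: zero area")
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)
    return cx, cy


def polygon_second_moments(xy: np.ndarray) -> np.ndarray:
    """Area covariance matrix of a simple polygon about its centroid.

    Returns the 2x2 matrix ``[[Cxx, Cxy], [Cxy, Cyy]]`` with
    ``Cxx = (1/A) * integral (x - cx)^2 dA`` etc.  Its eigenvectors are
    the principal axes of the polygon: the major axis belongs to the
    larger eigenvalue.
    """
    cx, cy = polygon_centroid(xy)
    x = xy[:, 0] - cx
    y = xy[:, 1] - cy
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * float(np.sum(cross))
    ixx = float(np.sum((y * y + y * yn + yn * yn) * cross)) / 12.0
    iyy = float(np.sum((x * x + x * xn + xn * xn) * cross)) / 12.0
    ixy = float(np.sum((x * yn + 2.0 * x * y + 2.0 * xn * yn + xn * y) * cross)) / 24.0
    return np.array([[iyy / a, ixy / a], [ixy / a, ixx / a]])


def _segments_intersect(p1, p2, q1, q2) -> bool:
    """Proper or improper intersection of open segments (shared endpoints excluded)."""
    d1x, d1y = p2[0] - p1[0], p2[1] - p1[1]
    d2x, d2y = q2[0] - q1[0], q2[1] - q1[1]
    denom = d1x * d2y - d1y * d2x
    rx, ry = q1[0] - p1[0], q1[1] - p1[1]
    if denom == 0.0:
        return False
    t = (rx * d2y - ry * d2x) / denom
    u = (rx * d1y - ry * d1x) / denom
    eps = 1e-12
    return eps < t < 1.0 - eps and eps < u < 1.0 - eps


def polygon_is_simple(xy: np.ndarray) -> bool:
    """True if no two non-adjacent edges of the polygon intersect."""
    n = len(xy)
    pts = [(float(p[0]), float(p[1])) for p in xy]
    for i in range(n):
        a1, a2 = pts[i], pts[(i + 1) % n]
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            if _segments_intersect(a1, a2, pts[j], pts[(j + 1) % n]):
                return False
    return True


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Cell:
    """A typed polygonal cell.

    ``ring`` is the ordered (counter-clockwise) list of vertex ids;
    ``chemicals`` maps chemical name to concentration (amount per area in
    model units).  ``lineage_id`` is the founder cell the lineage traces
    back to; daughters inherit it on division.
    """

    id: int
    cell_type: str
    ring: list[int]
    chemicals: dict[str, float] = field(default_factory=dict)
    target_area: float = 1.0
    lineage_id: int = -1
    born_at: int = 0

    def conc(self, name: str) -> float:
        return self.chemicals.get(name, 0.0)


@dataclass(frozen=True)
class WallElement:
    """A straight wall element between two vertices.

    ``owners`` are the two cell ids sharing it; one may be the
    :data:`BOUNDARY` sentinel for perimeter elements.
    ``stiffness_multiplier`` is an extra, per-element factor on top of
    the cell-type stiffness (default 1)."""

    id: int
    a: int
    b: int
    owners: tuple[int, int]
    stiffness_multiplier: float = 1.0


@dataclass(frozen=True)
class DivisionEvent:
    step: int
    lineage_id: int
    parent_id: int
    parent_centroid: tuple[float, float]
    daughter_ids: tuple[int, int]
    daughter_centroids: tuple[tuple[float, float], tuple[float, float]]


class TissueMesh:
    """Simulation state: vertices, cells, derived walls, event log."""

    def __init__(self) -> None:
        self.vertices: dict[int, tuple[float, float]] = {}
        self.cells: dict[int, Cell] = {}
        # extra per-wall stiffness multipliers keyed by frozenset({a, b})
        self.wall_extra: dict[frozenset, float] = {}
        self.step: int = 0
        self.division_log: list[DivisionEvent] = []
        self._next_vid: int = 0
        self._next_cid: int = 0
        self._topology_version: int = 0

    # -- construction ------------------------------------------------------

    def add_vertex(self, x: float, y: float, vid: int | None = None) -> int:
        if vid is None:
            vid = self._next_vid
        if vid in self.vertices:
            raise MeshError(f"duplicate vertex id {vid}")
        if not (math.isfinite(x) and math.isfinite(y)):
            raise MeshError(f"non-finite coordinates for vertex {vid}")
        self.vertices[vid] = (float(x), float(y))
        self._next_vid = max(self._next_vid, vid + 1)
        self._topology_version += 1
        return vid

    def add_cell(self, ring: Iterable[int], cell_type: str,
                 cid: int | None = None, **kw) -> Cell:
        ring = list(ring)
        if len(ring) < 3:
            raise GeometryError("cell ring needs at least 3 vertices")
        if cell_type not in CELL_TYPES:
            raise MeshError(f"unknown cell type {cell_type!r}")
        if cid is None:
            cid = self._next_cid
        if cid in self.cells:
            raise MeshError(f"duplicate cell id {cid}")
        cell = Cell(id=cid, cell_type=cell_type, ring=ring, **kw)
        if cell.lineage_id < 0:
            cell.lineage_id = cid
        self.cells[cid] = cell
        self._next_cid = max(self._next_cid, cid + 1)
        self._topology_version += 1
        return cell

    # -- geometry queries --------------------------------------------------

    def ring_coords(self, cell: Cell | int) -> np.ndarray:
        if isinstance(cell, int):
            cell = self.cells[cell]
        return np.array([self.vertices[v] for v in cell.ring], dtype=float)

    def cell_area(self, cell: Cell | int) -> float:
        """Positive area of the cell polygon (cells are wound CCW)."""
        if isinstance(cell, int):
            cell = self.cells[cell]
        ring = cell.ring
        if len(ring) < 3:
            raise GeometryError("degenerate ring")
        verts = self.vertices
        s = 0.0
        xp, yp = verts[ring[-1]]
        for v in ring:
            x, y = verts[v]
            s += xp * y - x * yp
            xp, yp = x, y
        return abs(0.5 * s)

    def centroid(self, cell: Cell | int) -> tuple[float, float]:
        return polygon_centroid(self.ring_coords(cell))

    def shortest_axis(self, cell: Cell | int,
                      tie_tol: float = 1e-9) -> np.ndarray:
        """Unit direction of the minor principal axis of the cell.

        Division planes run along this direction (i.e. normal to the
        major axis), mimicking shortest-axis division.  For isotropic
        polygons (equal second moments) the tie is broken by the radial
        direction from the tissue center through the cell centroid,
        falling back to the x-axis.
        """
        if isinstance(cell, int):
            cell = self.cells[cell]
        cov = polygon_second_moments(self.ring_coords(cell))
        evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
        if evals[1] - evals[0] <= tie_tol * max(evals[1], 1e-300):
            cx, cy = self.centroid(cell)
            tx, ty = self.center_of_mass()
            d = np.array([cx - tx, cy - ty])
            nrm = np.linalg.norm(d)
            if nrm > 1e-12:
                return d / nrm
            return np.array([1.0, 0.0])
        v = evecs[:, 0]  # minor axis: smaller eigenvalue
        return v / np.linalg.norm(v)

    def center_of_mass(self) -> tuple[float, float]:
        """Unweighted mean of all vertex coordinates (cheap tissue center)."""
        xy = np.array(list(self.vertices.values()), dtype=float)
        return float(xy[:, 0].mean()), float(xy[:, 1].mean())

    # -- derived topology --------------------------------------------------

    def edge_map(self) -> dict[frozenset, list[int]]:
        """Map of undirected edge -> owning cell ids (1 or 2 owners).

        Cached between topological changes (vertex moves do not affect it).
        """
        cached = getattr(self, "_edge_map_cache", None)
        if cached is not None and cached[0] == self._topology_version:
            return cached[1]
        em: dict[frozenset, list[int]] = {}
        for cell in self.cells.values():
            ring = cell.ring
            n = len(ring)
            for i in range(n):
                key = frozenset((ring[i], ring[(i + 1) % n]))
                em.setdefault(key, []).append(cell.id)
        self._edge_map_cache = (self._topology_version, em)
        return em

    def walls(self) -> list[WallElement]:
        """Enumerate wall elements deterministically (sorted endpoints)."""
        em = self.edge_map()
        out = []
        for wid, key in enumerate(sorted(em, key=lambda k: tuple(sorted(k)))):
            owners = em[key]
            if len(owners) > 2:
                raise MeshError(f"edge {tuple(sorted(key))} shared by >2 cells")
            a, b = sorted(key)
            pair = (owners[0], owners[1]) if len(owners) == 2 else (owners[0], BOUNDARY)
            out.append(WallElement(wid, a, b, pair,
                                   self.wall_extra.get(key, 1.0)))
        return out

    def wall_length(self, a: int, b: int) -> float:
        ax, ay = self.vertices[a]
        bx, by = self.vertices[b]
        return math.hypot(bx - ax, by - ay)

    def neighbors(self, cell: Cell | int) -> list[tuple[int, float]]:
        """Adjacent cells with total shared wall length (boundary excluded)."""
        if isinstance(cell, int):
            cell = self.cells[cell]
        em = self.edge_map()
        shared: dict[int, float] = {}
        ring = cell.ring
        n = len(ring)
        for i in range(n):
            a, b = ring[i], ring[(i + 1) % n]
            owners = em[frozenset((a, b))]
            for o in owners:
                if o != cell.id:
                    shared[o] = shared.get(o, 0.0) + self.wall_length(a, b)
        return sorted(shared.items())

    def boundary_ring(self) -> list[tuple[int, int]]:
        """Perimeter edges ordered into a closed ring."""
        em = self.edge_map()
        bedges = [tuple(sorted(k)) for k, own in em.items() if len(own) == 1]
        if not bedges:
            return []
        succ: dict[int, list[int]] = {}
        for a, b in bedges:
            succ.setdefault(a, []).append(b)
            succ.setdefault(b, []).append(a)
        start = bedges[0][0]
        ring = [start]
        prev = None
        cur = start
        for _ in range(len(bedges)):
            nxts = [v for v in succ[cur] if v != prev]
            if not nxts:
                raise MeshError("boundary ring is not closed")
            prev, cur = cur, nxts[0]
            if cur == start:
                break
            ring.append(cur)
        edges = [(ring[i], ring[(i + 1) % len(ring)]) for i in range(len(ring))]
        if len(edges) != len(bedges):
            raise MeshError("boundary is not a single closed ring")
        return edges

    # -- topological operations -------------------------------------------

    def split_edge(self, a: int, b: int, x: float, y: float) -> int:
        """Insert a new vertex at (x, y) on edge (a, b) in every owning cell."""
        key = frozenset((a, b))
        w = self.add_vertex(x, y)
        found = False
        for cell in self.cells.values():
            ring = cell.ring
            n = len(ring)
            for i in range(n):
                if {ring[i], ring[(i + 1) % n]} == {a, b}:
                    ring.insert(i + 1, w)
                    found = True
                    break
        if not found:
            raise MeshError(f"edge ({a}, {b}) not found")
        extra = self.wall_extra.pop(key, None)
        if extra is not None:
            self.wall_extra[frozenset((a, w))] = extra
            self.wall_extra[frozenset((w, b))] = extra
        self._topology_version += 1
        return w

    def divide_cell(self, cell: Cell | int, rng: np.random.Generator,
                    max_retries: int = 10) -> tuple[int, int]:
        """Divide a cell by a straight cut through its centroid normal to
        the major axis.

        Both daughters inherit the mother's chemical concentrations
        unchanged (growth dilution is deliberately omitted from the
        model) and the mother's lineage id; each daughter's target area
        is reset to its realized area.  Returns the two daughter ids.
        """
        if isinstance(cell, int):
            cell = self.cells[cell]
        cx, cy = self.centroid(cell)
        axis = self.shortest_axis(cell)
        for attempt in range(max_retries):
            if attempt > 0:
                ang = rng.normal(0.0, 0.2)
                c, s = math.cos(ang), math.sin(ang)
                use_axis = np.array([axis[0] * c - axis[1] * s,
                                     axis[0] * s + axis[1] * c])
            else:
                use_axis = axis
            cuts = self._find_cut(cell, cx, cy, use_axis)
            if cuts is not None:
                return self._apply_cut(cell, cuts)
        raise GeometryError(
            f"could not find a valid division cut for cell {cell.id}")

    def _find_cut(self, cell: Cell, cx: float, cy: float, axis: np.ndarray):
        """Locate two ring edges crossed by the cut line whose chord lies
        inside the polygon.

        For convex cells the line crosses exactly twice.  For concave
        cells with more crossings, the crossings are sorted along the
        cut direction; by parity, consecutive pairs (0,1), (2,3), ...
        bound inside-the-polygon chords, and the pair whose interval
        contains the centroid (falling back to the first pair) is used.
        """
        ring = cell.ring
        n = len(ring)
        # signed side of each vertex w.r.t. the cut line through (cx, cy)
        side = []
        for v in ring:
            x, y = self.vertices[v]
            side.append(axis[0] * (y - cy) - axis[1] * (x - cx))
        crossings = []
        for i in range(n):
            s1, s2 = side[i], side[(i + 1) % n]
            if s1 == 0.0 or s2 == 0.0:
                return None  # vertex exactly on the line: jitter and retry
            if (s1 > 0) != (s2 > 0):
                t = s1 / (s1 - s2)
                a, b = ring[i], ring[(i + 1) % n]
                ax, ay = self.vertices[a]
                bx, by = self.vertices[b]
                px, py = ax + t * (bx - ax), ay + t * (by - ay)
                proj = axis[0] * (px - cx) + axis[1] * (py - cy)
                crossings.append((proj, i, a, b, px, py))
        if len(crossings) < 2 or len(crossings) % 2 != 0:
            return None
        crossings.sort(key=lambda c: c[0])
        pair = crossings[0:2]
        for j in range(0, len(crossings), 2):
            if crossings[j][0] <= 0.0 <= crossings[j + 1][0]:
                pair = crossings[j:j + 2]
                break
        # reject strongly unbalanced cuts (sliver daughters destabilize
        # both the mesh and explicit diffusion): both sides >= 20%
        (_, i1, _, _, x1, y1), (_, i2, _, _, x2, y2) = pair
        lo, hi = sorted((i1, i2))
        side_a = ([(x1, y1) if lo == i1 else (x2, y2)]
                  + [self.vertices[v] for v in ring[lo + 1:hi + 1]]
                  + [(x2, y2) if lo == i1 else (x1, y1)])
        xy = np.array(side_a)
        area_a = abs(polygon_area(xy))
        total = self.cell_area(cell)
        if not 0.2 <= area_a / total <= 0.8:
            return None
        return [c[1:] for c in pair]

    def _apply_cut(self, cell: Cell, crossings) -> tuple[int, int]:
        (_, a1, b1, x1, y1), (_, a2, b2, x2, y2) = crossings
        w1 = self.split_edge(a1, b1, x1, y1)
        w2 = self.split_edge(a2, b2, x2, y2)
        ring = cell.ring  # now contains w1 and w2
        i1 = ring.index(w1)
        i2 = ring.index(w2)
        if i1 > i2:
            i1, i2 = i2, i1
            w1, w2 = w2, w1
        ring_a = ring[i1:i2 + 1]          # w1 .. w2, closed by edge w2->w1
        ring_b = ring[i2:] + ring[:i1 + 1]  # w2 .. w1, closed by edge w1->w2
        if len(ring_a) < 3 or len(ring_b) < 3:
            raise GeometryError("division produced a degenerate daughter")
        parent_centroid = self.centroid(cell)
        lid = cell.lineage_id
        chem = dict(cell.chemicals)
        ctype = cell.cell_type
        del self.cells[cell.id]
        daughters = []
        for r in (ring_a, ring_b):
            d = self.add_cell(r, ctype, chemicals=dict(chem),
                              lineage_id=lid, born_at=self.step)
            d.target_area = self.cell_area(d)
            daughters.append(d)
        d1, d2 = daughters
        self.division_log.append(DivisionEvent(
            step=self.step, lineage_id=lid, parent_id=cell.id,
            parent_centroid=parent_centroid,
            daughter_ids=(d1.id, d2.id),
            daughter_centroids=(self.centroid(d1), self.centroid(d2)),
        ))
        self._topology_version += 1
        return d1.id, d2.id

    # -- validation --------------------------------------------------------

    def total_cell_area(self) -> float:
        return sum(self.cell_area(c) for c in self.cells.values())

    def validate(self, check_simple: bool = True) -> None:
        """Raise :class:`MeshError` on any structural invariant violation."""
        for vid, (x, y) in self.vertices.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise MeshError(f"vertex {vid} has non-finite coordinates")
        for cell in self.cells.values():
            if len(cell.ring) < 3:
                raise MeshError(f"cell {cell.id} ring too short")
            if len(set(cell.ring)) != len(cell.ring):
                raise MeshError(f"cell {cell.id} repeats a vertex")
            xy = self.ring_coords(cell)
            if polygon_area(xy) <= 0:
                raise MeshError(f"cell {cell.id} is not counter-clockwise")
            if check_simple and not polygon_is_simple(xy):
                raise MeshError(f"cell {cell.id} is self-intersecting")
            for name, c in cell.chemicals.items():
                if c < 0:
                    raise MeshError(
                        f"cell {cell.id} has negative [{name}] = {c}")
            if cell.target_area <= 0:
                raise MeshError(f"cell {cell.id} has non-positive target area")
        em = self.edge_map()
        for key, owners in em.items():
            if len(owners) > 2:
                raise MeshError(
                    f"edge {tuple(sorted(key))} shared by {len(owners)} cells")
        self.boundary_ring()  # raises if not a single closed ring
        # no overlaps/gaps: cells must tile the region enclosed by the boundary
        bring = self.boundary_ring()
        if bring:
            pts = np.array([self.vertices[a] for a, _ in bring], dtype=float)
            outer = abs(polygon_area(pts))
            total = self.total_cell_area()
            if not math.isclose(outer, total, rel_tol=1e-6, abs_tol=1e-9):
                raise MeshError(
                    f"cells do not tile the boundary region "
                    f"(outer {outer:.9g} vs cell sum {total:.9g})")
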