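"""Tissue Hamiltonian, Metropolis relaxation, growth and wall yielding."""

import math

import numpy as np
import pytest

import cambiumsim as cs
from cambiumsim import mechanics
from cambiumsim.mesh import TissueMesh


def single_cell_tissue(n=8, r=1.0, cell_type="cambium"):
    t = TissueMesh()
    ids = [t.add_vertex(r * math.cos(a), r * math.sin(a))
           for a in np.linspace(0, 2 * math.pi, n, endpoint=False)]
    t.add_cell(ids, cell_type)
    return t


def brute_force_hamiltonian(tissue, params):
    """Independent term-by-term energy oracle using only public queries."""
    h = 0.0
    for cell in tissue.cells.values():
        h += params.lambda_area * (tissue.cell_area(cell)
                                   - cell.target_area) ** 2
    for w in tissue.walls():
        if w.owners[1] == cs.mesh.BOUNDARY:
            lam = params.lambda_length_base * params.boundary_stiffness
        else:
            ta = tissue.cells[w.owners[0]].cell_type
            tb = tissue.cells[w.owners[1]].cell_type
            lam = params.lambda_length_base * max(
                params.per_type_stiffness[ta], params.per_type_stiffness[tb])
        lam *= w.stiffness_multiplier
        h += lam * (tissue.wall_length(w.a, w.b)
                    - params.target_element_length) ** 2
    return h


class TestHamiltonian:
    def test_zero_at_rest_state(self):
        t = TissueMesh()
        ids = [t.add_vertex(x, y) for x, y in
               [(0, 0), (1, 0), (1, 1), (0, 1)]]
        c = t.add_cell(ids, "cambium")
        c.target_area = 1.0
        p = mechanics.MechanicsParams(target_element_length=1.0)
        assert mechanics.hamiltonian(t, p) == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_wall_stiffness(self):
        t = cs.make_template(cs.TemplateSpec(seed=0), "M1")
        p = mechanics.MechanicsParams()
        h0 = mechanics.hamiltonian(t, p)
        w = t.walls()[5]
        key = frozenset((w.a, w.b))
        lt = p.target_element_length
        if w.owners[1] == cs.mesh.BOUNDARY:
            lam = p.wall_lambda(None, None)
        else:
            lam = p.wall_lambda(t.cells[w.owners[0]].cell_type,
                                t.cells[w.owners[1]].cell_type)
        term = lam * (t.wall_length(w.a, w.b) - lt) ** 2
        t.wall_extra[key] = 2.0
        assert mechanics.hamiltonian(t, p) == pytest.approx(h0 + term,
                                                            rel=1e-10)

    def test_matches_brute_force_oracle(self):
        t = cs.make_template(cs.TemplateSpec(seed=3), "M3A")
        p = mechanics.MechanicsParams()
        assert mechanics.hamiltonian(t, p) == pytest.approx(
            brute_force_hamiltonian(t, p), rel=1e-10)


class TestRelax:
    def test_greedy_limit_never_increases_energy(self):
        t = single_cell_tissue()
        t.cells[0].target_area = 3.0
        p = mechanics.MechanicsParams(mc_temperature=0.0)
        rng = np.random.default_rng(0)
        h = mechanics.hamiltonian(t, p)
        for _ in range(20):
            mechanics.relax(t, p, rng)
            h2 = mechanics.hamiltonian(t, p)
            assert h2 <= h + 1e-9
            h = h2

    def test_cell_below_target_expands(self):
        grew = 0
        for seed in range(30):
            t = single_cell_tissue()
            a0 = t.cell_area(0)
            t.cells[0].target_area = 2.0 * a0
            p = mechanics.MechanicsParams()
            rng = np.random.default_rng(seed)
            for _ in range(1000):
                mechanics.relax(t, p, rng)
                mechanics.yield_walls(t, p)
            if t.cell_area(0) > a0:
                grew += 1
        assert grew >= 29  # >= 95% of seeds

    def test_reaches_target_within_500_steps(self):
        t = single_cell_tissue()
        t.cells[0].target_area = 3.0 * t.cell_area(0)
        p = mechanics.MechanicsParams()
        rng = np.random.default_rng(1)
        for _ in range(500):
            mechanics.relax(t, p, rng)
            mechanics.yield_walls(t, p)
        assert t.cell_area(0) >= 0.95 * t.cells[0].target_area

    def test_stiffer_walls_slow_growth(self):
        """A 10x perimeter stiffness reduces realized growth (median over
        paired seeds at a fixed horizon)."""
        def grown(bmult, seed):
            t = single_cell_tissue()
            t.cells[0].target_area = 3.0 * t.cell_area(0)
            p = mechanics.MechanicsParams()
            p.boundary_stiffness *= bmult
            rng = np.random.default_rng(seed)
            for _ in range(40):
                mechanics.relax(t, p, rng)
                mechanics.yield_walls(t, p)
            return t.cell_area(0)

        soft = np.median([grown(1.0, s) for s in range(7)])
        stiff = np.median([grown(10.0, s) for s in range(7)])
        assert stiff < soft

    def test_preserves_mesh_validity(self):
        t = cs.make_template(cs.TemplateSpec(seed=4), "M1")
        p = mechanics.MechanicsParams()
        rng = np.random.default_rng(4)
        for c in t.cells.values():
            c.target_area *= 1.5
        for _ in range(50):
            mechanics.relax(t, p, rng)
        t.validate()


class TestGrowth:
    def test_increment_and_cap(self):
        t = single_cell_tissue(cell_type="xylem")
        g = mechanics.GrowthParams(growth_rate=0.05,
                                   max_area={"xylem": 1.0})
        t.cells[0].target_area = 0.9
        mechanics.apply_growth(t, g)
        assert t.cells[0].target_area == pytest.approx(0.95)
        mechanics.apply_growth(t, g)
        assert t.cells[0].target_area == pytest.approx(1.0)
        mechanics.apply_growth(t, g)  # at cap: unchanged
        assert t.cells[0].target_area == pytest.approx(1.0)

    def test_closed_form_after_k_steps(self):
        t = single_cell_tissue(cell_type="cambium")
        rate, cap = 0.07, 1.3
        g = mechanics.GrowthParams(growth_rate=rate,
                                   max_area={"cambium": cap})
        t.cells[0].target_area = 1e-12  # effectively zero
        for k in range(1, 40):
            mechanics.apply_growth(t, g)
            assert t.cells[0].target_area == pytest.approx(
                min(k * rate, cap), abs=1e-9)


class TestYieldWalls:
    def test_no_op_below_threshold(self):
        t = single_cell_tissue(n=8, r=1.0)
        p = mechanics.MechanicsParams(target_element_length=1.0,
                                      yield_threshold=2.0)
        n0 = len(t.vertices)
        assert mechanics.yield_walls(t, p) == 0
        assert len(t.vertices) == n0

    def test_overstretched_element_split_at_midpoint(self):
        t = TissueMesh()
        ids = [t.add_vertex(x, y) for x, y in
               [(0, 0), (2.01, 0), (2.01, 1), (0, 1)]]
        t.add_cell(ids, "cambium")
        p = mechanics.MechanicsParams(target_element_length=1.0,
                                      yield_threshold=2.0)
        n = mechanics.yield_walls(t, p)
        assert n == 2  # the two long sides both exceed 2.0
        xs = sorted(x for x, y in t.vertices.values())
        assert any(abs(x - 1.005) < 1e-12 for x in xs)

    def test_repeated_application_reaches_fixed_point(self):
        rng = np.random.default_rng(9)
        t = cs.make_template(cs.TemplateSpec(seed=9, radius=12.0), "M1")
        p = mechanics.MechanicsParams(target_element_length=1.0,
                                      yield_threshold=1.5)
        for _ in range(20):
            if mechanics.yield_walls(t, p) == 0:
                break
        limit = p.yield_threshold * p.target_element_length
        for w in t.walls():
            assert t.wall_length(w.a, w.b) <= limit + 1e-12
        t.validate()

    def test_preserves_cell_areas(self):
        t = cs.make_template(cs.TemplateSpec(seed=1, radius=9.0), "M1")
        areas = {cid: t.cell_area(c) for cid, c in t.cells.items()}
        p = mechanics.MechanicsParams(yield_threshold=1.2)
        mechanics.yield_walls(t, p)
        for cid, a in areas.items():
            assert t.cell_area(cid) == pytest.approx(a, rel=1e-12)


class TestStiffnessSweep:
    def test_xylem_stiffness_shrinks_xylem_cells(self):
        """Raising the xylem wall-stiffness multiplier across
        {0.5, 1, 10, 50}x lowers the median xylem cell area and the
        xylem cell count, while the cambium pool stays within 20% of
        the 1x regime (3 seeds per regime, desk scale)."""
        from cambiumsim import cellrules

        def run(seed, mult):
            variant = cs.get_variant("M4")
            mech, growth, sig, thr = cellrules.default_params(variant)
            mech.per_type_stiffness = dict(mech.per_type_stiffness)
            mech.per_type_stiffness["xylem"] *= mult
            t = cs.make_template(cs.TemplateSpec(seed=seed), variant, sig)
            rng = np.random.default_rng(seed)
            for _ in range(300):
                cellrules.step(t, variant, thr, mech, growth, sig, rng)
            areas = [t.cell_area(c) for c in t.cells.values()
                     if c.cell_type == "xylem"]
            n_camb = sum(1 for c in t.cells.values()
                         if c.cell_type == "cambium")
            return float(np.median(areas)), len(areas), n_camb

        med_area, med_n, med_camb = {}, {}, {}
        for mult in (0.5, 1, 10, 50):
            res = [run(seed, mult) for seed in (1, 2, 3)]
            med_area[mult] = float(np.median([r[0] for r in res]))
            med_n[mult] = float(np.median([r[1] for r in res]))
            med_camb[mult] = float(np.median([r[2] for r in res]))
        assert med_area[0.5] > med_area[1] > med_area[10] > med_area[50]
        assert med_n[50] < med_n[0.5]
        for mult in (0.5, 10, 50):
            assert abs(med_camb[mult] - med_camb[1]) <= 0.2 * med_camb[1]
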