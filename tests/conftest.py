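"""Shared fixtures: cached multi-seed simulation runs.

The behavioral tests all consume the same small-template runs (10 seeds
per model variant), so the runs are executed once per session and shared.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pytest

import cambiumsim as cs
from cambiumsim import cellrules


N_SEEDS = 10
SEEDS = tuple(range(1, N_SEEDS + 1))

#: steps per variant for the behavioral contract runs
VARIANT_STEPS = {
    "M1": 300, "M2A": 300, "M2C": 300, "M2D": 300,
    "M3A": 300, "M3B": 450, "M3C": 300,
}


@dataclass
class RunResult:
    """Summary of one finished simulation."""

    tissue: object
    counts: Counter
    min_cambium: int
    # type counts sampled every 25 steps (list of Counters)
    trajectory: list = field(default_factory=list)


def run_variant(name: str, seed: int, steps: int,
                xylem_mult: float = 1.0,
                boundary_mult: float = 1.0,
                template_spec: cs.TemplateSpec | None = None) -> RunResult:
    variant = cs.get_variant(name)
    mech, growth, sig, thr = cellrules.default_params(variant)
    if xylem_mult != 1.0:
        mech.per_type_stiffness = dict(mech.per_type_stiffness)
        mech.per_type_stiffness["xylem"] *= xylem_mult
    mech.boundary_stiffness *= boundary_mult
    spec = template_spec or cs.TemplateSpec()
    spec = cs.TemplateSpec(**{**spec.__dict__, "seed": seed})
    tissue = cs.make_template(spec, variant, sig)
    rng = np.random.default_rng(seed)
    min_cambium = sum(1 for c in tissue.cells.values()
                      if c.cell_type == "cambium")
    trajectory = [Counter(c.cell_type for c in tissue.cells.values())]
    for i in range(steps):
        cellrules.step(tissue, variant, thr, mech, growth, sig, rng)
        nc = sum(1 for c in tissue.cells.values()
                 if c.cell_type == "cambium")
        min_cambium = min(min_cambium, nc)
        if (i + 1) % 25 == 0:
            trajectory.append(
                Counter(c.cell_type for c in tissue.cells.values()))
    return RunResult(tissue=tissue,
                     counts=Counter(c.cell_type
                                    for c in tissue.cells.values()),
                     min_cambium=min_cambium,
                     trajectory=trajectory)


@pytest.fixture(scope="session")
def variant_runs():
    """10-seed desk runs for every variant in the behavioral contract."""
    out: dict[str, list[RunResult]] = {}
    for name, steps in VARIANT_STEPS.items():
        out[name] = [run_variant(name, seed, steps) for seed in SEEDS]
    return out


#: template for the stiffness/radiality study: relatively more radial
#: expansion per step than the default disk, same concentric layout
RADIALITY_SPEC = cs.TemplateSpec(
    n_rings_xylem=1, n_rings_cambium=4, n_rings_phloem=1,
    cells_per_ring=16, radius=5.5)
RADIALITY_STEPS = 400


@pytest.fixture(scope="session")
def stiffness_runs():
    """M4 runs for the wall-stiffness regimes: baseline, 10x xylem,
    10x boundary (epidermis), 10 seeds each."""
    out = {}
    for label, (xm, bm) in {
        "base": (1.0, 1.0), "xylem10": (10.0, 1.0), "epidermis10": (1.0, 10.0),
    }.items():
        out[label] = [
            run_variant("M4", seed, RADIALITY_STEPS, xylem_mult=xm,
                        boundary_mult=bm, template_spec=RADIALITY_SPEC)
            for seed in SEEDS
        ]
    return out


def radial_distance(tissue, cell, center=None):
    if center is None:
        from cambiumsim import analysis
        center = analysis.tissue_center(tissue)
    x, y = tissue.centroid(cell)
    return math.hypot(x - center[0], y - center[1])
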