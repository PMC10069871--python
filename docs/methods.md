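# Methods

## The model

`cambiumsim` simulates radial plant growth as a two-dimensional planar
tissue of polygonal cells, the standard cell-based (vertex-model)
abstraction for plant tissues whose cells cannot slide past each other.
The simulation couples three layers, applied in a fixed order each step:

1. **Growth** — every cell's target area increases by `growth_rate`
   (default 0.02 area units/step) up to a type-specific cap.
2. **Mechanics** — vertex positions relax by Metropolis Monte Carlo
   against the energy
   `H = λ_A Σ (A_c − A_c*)² + Σ λ_L(w) (l_w − L_T)²`.
   The first term models turgor pressure driving each cell toward its
   target area; the second penalizes stretching of individual wall
   elements away from the rest length `L_T`. Wall elements stretched past
   `yield_threshold · L_T` yield irreversibly by midpoint vertex
   insertion — this is how walls "grow". `λ_L` is cell-type-specific
   ("cellwallstiffness"); a wall shared by two types uses the stiffer
   multiplier, and the outer perimeter ("epidermis") has its own
   multiplier.
3. **Signaling** — per-cell ordinary differential equations for up to six
   species, with wall-length-weighted diffusion on the cell-adjacency
   graph, then cell-type transition rules (differentiation before
   division; randomized visiting order).

The signaling core is the receptor–ligand pair PXY/CLE41: CLE41 is
produced by phloem-type cells and diffuses; PXY is produced by cambium
cells and does not move; their mass-action product forms the active
complex `PXY_active`, which gates cambial proliferation and represses
further PXY production. The extended model family adds a phloem-pole
derived proliferation factor PF, an intracellular division factor DF
produced at rate `v_DF·Q/(1 + Q/K_DF)` with `Q = [PXY_active] +
α_PF·[PF]` (a saturating form capped at `v_DF·K_DF`), and a diffusible
repressor RP that takes over PXY suppression. Growth dilution of
concentrations is deliberately omitted: daughters inherit the mother's
concentrations unchanged.

## Model variants

Nine rule bundles encode the simulated genotypes. `M1` (xylem-only
growth), `M2A` (bidirectional wild type), `M2B` (ectopic CLE41 in xylem),
`M2C`/`M2D` (receptor null / strongly reduced), `M3A`–`M3C` (extended
network and its perturbations) and `M4` (`M3A` plus cell-type-specific
wall stiffness, cambium half as stiff as its surroundings). Division
gates: `[PXY_active]` above a threshold for the basic family — with an
upper bound at the phloem-fate threshold in the `M2` family, because high
complex levels inhibit distal divisions and instruct phloem fate — and
`[DF]` above a threshold (cambium and phloem parenchyma) in the extended
family. Fate rules: basic family reads `[PXY_active]` (low → xylem, high
and larger → phloem); extended family reads positional `[PXY]` (high →
xylem) and resolves phloem-fated cells to poles unless inhibited by
local PF (lateral inhibition producing the patchy pole pattern).

## Parameter choices

All rates are in model units (the initial mean cell area defines the area
unit; one step defines the time unit). The shipped defaults were
calibrated once so that the variant family reproduces its qualitative
phenotypes on the 80-cell desk template, and are recorded in
`SignalingParams`, `MechanicsParams`, `GrowthParams` and
`RuleThresholds`:

* CLE41: production 1.0 in phloem (poles 1.0, parenchyma 0.4 in the
  extended family), degradation 0.2, diffusion 0.3. Together with
  receptor binding this yields a ligand decay length of about one cell
  diameter inside the cambium, so the activity gradient spans the
  stem-cell zone.
* PXY: production 1.0 (cambium), degradation 1.0, suppression 0.5.
  With these values `[PXY_active]` has a closed-form ceiling
  (`0.5a² + a = 2·p_PXY` at ligand saturation, ≈1.24 at p=1): the
  division band (0.15, 0.6) sits well inside it for the wild type while
  the reduced-receptor variant `M2D` (p=0.05, ceiling ≈0.09) falls
  entirely below the division gate — which is exactly the observed
  phenotype (no divisions, phloem abolished, all cambium converting to
  xylem). This ceiling analysis is why `M2D` ships with `pxy_scale=0.05`.
* Extended family: PF tight around poles (D 0.1, deg 0.3), DF slow-moving
  (D 0.05, deg 0.3, `v_DF=1`, `K_DF=2`, `α_PF=2`), RP broad (D 0.3,
  deg 0.3). The DF division threshold 1.2 concentrates divisions in the
  distal cambium and near poles; with receptor binding removed (`M3C`)
  only the PF contribution remains and divisions collapse onto pole
  sectors (angular clustering index ≈0.46 vs ≈1.0 for `M3A`).
* Mechanics: `λ_A=1`, `λ_L=0.2`, `L_T=1`, yield threshold 2.0, Metropolis
  step 0.12 and temperature 0.001 with one proposal per vertex per step.
  These let a lone cell reach 95% of a 3× target within 500 steps while a
  10× stiffer perimeter measurably slows the same growth.

Integration is forward Euler with automatic sub-step refinement: the
number of sub-steps grows with the stiffest local rate (diffusion
`D·perimeter/area` of the smallest cell plus reaction scales), so the
integrator stays stable as divisions produce small cells. A fourth-order
Runge–Kutta mode exists for convergence checks.

## Synthetic template

The initial tissue is a disk of concentric rings (default 1 xylem /
3 cambium / 1 phloem ring × 16 cells, radius 5): ring radii follow
`√k` spacing so all cells start with area ≈1, the innermost ring is made
of wedges sharing a center vertex so the disk is tiled without holes, and
5% vertex jitter breaks rotational symmetry so replicate seeds diverge.
The deliberately broad cambium ring (48 cells) keeps the stem-cell pool
from stochastic extinction. The template emulates an established
secondary-anatomy cross-section; it does not model the primary-to-
secondary transition, real cell-size heterogeneity, or any
three-dimensional structure, so passing desk tests demonstrate the
network logic and mechanics of the ring geometry, not anatomical realism.

## Analyses

* **Radial bins** — cells are assigned to equal-width distance bins from
  the tissue center (the unweighted mean of cell centroids); per-bin
  chemical means are normalized to each chemical's maximum bin (percent)
  and averaged across simulations with min/max envelopes. Division rates
  use a trailing 100-step window.
* **Lineage radiality** — every founder cell defines a lineage; R² is
  the squared Pearson correlation between the x and y coordinates of the
  lineage's cell centroids (axis-symmetric; defined for ≥3 distinct
  centroids; exactly-degenerate one-coordinate lineages are perfectly
  straight files and score 1). Fractions are reported over the partition
  (0,0.25], (0.25,0.5], (0.5,0.75], (0.75,1] with R²=0 in the first
  interval.
* **Regime comparison** — per-interval Kruskal–Wallis omnibus across
  stiffness regimes after seeded equal-size subsampling, Dunn's post-hoc
  (rank-based z with tie correction, Holm adjustment) only when the
  omnibus is significant, a compact letter display, and bootstrap
  medians with percentile 95% intervals.
* **Edge instability** — coefficient of variation of cambium-centroid
  distances from the tissue center (0 = perfectly circular front).

## Parameter search

Candidates are drawn independently and uniformly on `[v/3, 3v]` around
the `M3A` base values (log-uniform optional), simulated for a fixed
number of steps, and scored with the weighted least-squares function
with weights `1/0.01`, `1/0.05676`, `1/0.4225` on the xylem, cambium and
phloem fraction deviations plus `(1 − cells/3000)²`. The cambium weight
is implemented exactly as specified even though `0.24² = 0.0576`
suggests a transposition; `corrected_cambium_weight=True` switches to
`1/0.0576`. Runs with fewer than 300 cells, fewer than 30 cambium cells,
or a cambium-front coefficient of variation above 0.2 are discarded
("retain" requires all three). Desk profiles use 10–20 candidates at
150–300 steps; the full-scale campaign the method is designed for runs
thousands of candidates at 2,200 steps.

## Problem sizes and known limitations

Desk-scale runs use the 80-cell template for 300 steps (450 for the
ectopic-ligand variant `M3B`, whose proximal phloem-parenchyma signature
needs the longer horizon, and for the radiality study, which uses a
96-cell template to reach ≥30 analyzable lineages per run). At this
scale the organ grows to roughly 300–700 cells — about a tenth of the
full-scale campaigns the scoring targets assume.

Two phenomena require full scale and are not reproduced at desk scale:

* The cambium front instability grows with tissue size; desk runs show
  only its onset.
* The shift of lineage-radiality distributions under increased xylem
  wall stiffness. The morphometric effects of stiffness are reproduced
  (median xylem cell area falls monotonically across 0.5–50× multipliers,
  xylem cell count falls, cambium count stays within ±20%), but the
  division-orientation anisotropy that builds radial cell files does not
  emerge in 450-step runs: dividing cells sit in the distal cambium,
  two or more cell layers from the stiff xylem interface, and with local
  per-element wall energies the tangential confinement of the rigid core
  does not propagate that far before wall yielding relieves it. Radial
  files require the radial expansion of much longer runs (thousands of
  steps, lineages tens of cells long). The corresponding test encodes
  the full directional claim and currently fails at desk scale; the
  epidermis-stiffness control (no ordered shift) behaves as expected.

Other limitations: no T1/T2 topological rearrangements or cell death; no
anisotropic wall materials or microtubule feedback; diffusion is
concentration-based and amount-conserving with a no-flux outer boundary;
hormone pathways (auxin, cytokinin, brassinosteroid) are outside scope.
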