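"""Post-hoc analyses of finished simulations.

Covers the standard read-outs of the radial-growth simulations:

* radial binning of cells and normalized per-bin chemical profiles,
* per-bin division-rate maps over a trailing time window,
* lineage "radiality" — the coefficient of determination (R^2) of a
  straight-line fit through a lineage's cell centroids, a proxy for the
  ratio of periclinal (radial-file) to anticlinal divisions,
* distribution of lineage R^2 over fixed intervals and nonparametric
  comparison of stiffness regimes (Kruskal-Wallis omnibus, Dunn
  post-hoc with Holm adjustment, bootstrap medians),
* per-type morphometrics (cell counts, areas, major-axis lengths).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mesh import TissueMesh, polygon_second_moments

__all__ = [
    "R2_INTERVALS",
    "tissue_center",
    "assign_bins",
    "cells_table",
    "bin_profiles",
    "lineage_records",
    "lineage_radiality",
    "radiality_distribution",
    "compare_regimes",
    "dunn_test",
    "morphometrics",
    "LineageRecord",
    "RegimeComparison",
]

#: Half-open partition of [0, 1] used for lineage R^2 histograms
#: (R^2 = 0 is assigned to the first interval).
R2_INTERVALS = ((0.0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.0))


# ---------------------------------------------------------------------------
# Radial binning
# ---------------------------------------------------------------------------

def tissue_center(tissue: TissueMesh) -> tuple[float, float]:
    """Tissue center: unweighted mean of the cell centroids."""
    cents = [tissue.centroid(c) for c in tissue.cells.values()]
    if not cents:
        raise ValueError("empty tissue")
    arr = np.asarray(cents)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def assign_bins(tissue: TissueMesh, n_bins: int) -> dict[int, int]:
    """Sort cells into equal-width distance bins from the tissue center.

    Bin edges are half-open ``[lo, hi)`` on ``[0, max distance]`` with
    the last bin closed, so every cell lands in exactly one bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    cx, cy = tissue_center(tissue)
    dist = {cid: math.hypot(x - cx, y - cy)
            for cid, (x, y) in ((c.id, tissue.centroid(c))
                                for c in tissue.cells.values())}
    dmax = max(dist.values())
    if dmax == 0.0:
        return {cid: n_bins - 1 for cid in dist}
    out = {}
    for cid, d in dist.items():
        b = int(d / dmax * n_bins)
        out[cid] = min(b, n_bins - 1)
    return out


def cells_table(tissue: TissueMesh, n_bins: int = 7) -> pd.DataFrame:
    """Per-cell table: id, type, centroid, area, radial distance, bin,
    and every chemical concentration."""
    cx, cy = tissue_center(tissue)
    bins = assign_bins(tissue, n_bins)
    rows = []
    for cell in tissue.cells.values():
        x, y = tissue.centroid(cell)
        row = {
            "cell_id": cell.id,
            "cell_type": cell.cell_type,
            "x": x, "y": y,
            "area": tissue.cell_area(cell),
            "distance": math.hypot(x - cx, y - cy),
            "bin": bins[cell.id],
            "lineage_id": cell.lineage_id,
        }
        for name, c in cell.chemicals.items():
            row[name] = c
        rows.append(row)
    return pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)


def bin_profiles(snapshots: list[TissueMesh], n_bins: int = 7,
                 chemicals: tuple[str, ...] | None = None,
                 division_window: int = 100) -> pd.DataFrame:
    """Normalized radial chemical profiles averaged across simulations.

    Per simulation, each chemical's per-bin mean concentration is first
    expressed as a percentage of that chemical's maximum bin value, then
    averaged across simulations; the min/max envelope across simulations
    is retained.  The division rate per bin counts the division events
    of the trailing ``division_window`` steps divided by the bin's cell
    count, normalized the same way.  Bins without cells are missing and
    excluded from the per-chemical maximum.
    """
    if not snapshots:
        raise ValueError("need at least one snapshot")
    if chemicals is None:
        names = set()
        for t in snapshots:
            for c in t.cells.values():
                names.update(c.chemicals)
        chemicals = tuple(sorted(names))
    quantities = list(chemicals) + ["division_rate"]
    # per-sim normalized profiles: sim x quantity -> array of length n_bins
    prof = np.full((len(snapshots), len(quantities), n_bins), np.nan)
    counts = np.zeros((len(snapshots), n_bins))
    for s, tissue in enumerate(snapshots):
        bins = assign_bins(tissue, n_bins)
        per_bin: dict[int, list] = {b: [] for b in range(n_bins)}
        for cell in tissue.cells.values():
            per_bin[bins[cell.id]].append(cell)
        # trailing-window division events mapped to the bin of the parent
        cx, cy = tissue_center(tissue)
        dmax = max(math.hypot(x - cx, y - cy)
                   for x, y in (tissue.centroid(c)
                                for c in tissue.cells.values()))
        div_counts = np.zeros(n_bins)
        for ev in tissue.division_log:
            if ev.step >= tissue.step - division_window:
                d = math.hypot(ev.parent_centroid[0] - cx,
                               ev.parent_centroid[1] - cy)
                b = min(int(d / dmax * n_bins), n_bins - 1) if dmax else 0
                div_counts[b] += 1
        raw = np.full((len(quantities), n_bins), np.nan)
        for b in range(n_bins):
            cells = per_bin[b]
            counts[s, b] = len(cells)
            if not cells:
                continue
            for q, name in enumerate(chemicals):
                raw[q, b] = float(np.mean([c.conc(name) for c in cells]))
            raw[len(chemicals), b] = div_counts[b] / len(cells)
        for q in range(len(quantities)):
            mx = np.nanmax(raw[q]) if np.any(np.isfinite(raw[q])) else np.nan
            prof[s, q] = (100.0 * raw[q] / mx) if mx and mx > 0 else raw[q] * 0.0
    rows = []
    for q, name in enumerate(quantities):
        for b in range(n_bins):
            vals = prof[:, q, b]
            vals = vals[np.isfinite(vals)]
            rows.append({
                "quantity": name,
                "bin": b,
                "mean_pct": float(np.mean(vals)) if len(vals) else np.nan,
                "min_pct": float(np.min(vals)) if len(vals) else np.nan,
                "max_pct": float(np.max(vals)) if len(vals) else np.nan,
                "mean_cell_count": float(counts[:, b].mean()),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Lineage radiality
# ---------------------------------------------------------------------------

@dataclass
class LineageRecord:
    """A founder cell's lineage: its members at analysis time and the
    division events that produced them."""

    founder_id: int
    member_ids: list[int] = field(default_factory=list)
    member_centroids: list[tuple[float, float]] = field(default_factory=list)
    events: list = field(default_factory=list)

    @property
    def r_squared(self) -> float | None:
        pts = np.asarray(self.member_centroids)
        uniq = np.unique(pts, axis=0) if len(pts) else pts
        if len(uniq) < 3:
            return None
        return lineage_radiality(uniq)


def lineage_records(tissue: TissueMesh) -> list[LineageRecord]:
    """Group the tissue's cells by lineage and attach division events."""
    recs: dict[int, LineageRecord] = {}
    for cell in tissue.cells.values():
        rec = recs.setdefault(cell.lineage_id, LineageRecord(cell.lineage_id))
        rec.member_ids.append(cell.id)
        rec.member_centroids.append(tissue.centroid(cell))
    for ev in tissue.division_log:
        if ev.lineage_id in recs:
            recs[ev.lineage_id].events.append(ev)
    return [recs[k] for k in sorted(recs)]


def lineage_radiality(points: np.ndarray) -> float:
    """R^2 of a straight-line fit through the points (>= 3 distinct).

    Computed as the squared Pearson correlation between the x and y
    coordinates, which equals the OLS coefficient of determination and
    is symmetric in the two axes.  A lineage with zero variance in one
    coordinate is a perfectly straight (axis-aligned) file: R^2 = 1.
    """
    pts = np.asarray(points, dtype=float)
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 3:
        raise ValueError("lineage radiality needs >= 3 distinct centroids")
    sx = pts[:, 0].std()
    sy = pts[:, 1].std()
    if sx == 0.0 or sy == 0.0:
        return 1.0
    r = np.corrcoef(pts[:, 0], pts[:, 1])[0, 1]
    return float(r * r)


def radiality_distribution(r_squared: list[float]) -> np.ndarray:
    """Fractions of R^2 values in the four standard intervals.

    Intervals partition [0, 1] half-open from the left (R^2 = 0 counts
    into the first one); the fractions sum to one.
    """
    vals = [r for r in r_squared if r is not None]
    if not vals:
        raise ValueError("no defined R^2 values")
    frac = np.zeros(len(R2_INTERVALS))
    for r in vals:
        for i, (lo, hi) in enumerate(R2_INTERVALS):
            if (r == 0.0 and i == 0) or lo < r <= hi:
                frac[i] += 1
                break
    return frac / len(vals)


# ---------------------------------------------------------------------------
# Regime comparison
# ---------------------------------------------------------------------------

def dunn_test(groups: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Dunn's post-hoc test on mean ranks with tie correction.

    ``groups`` maps label -> 1-d sample.  P-values are Holm-adjusted.
    """
    labels = list(groups)
    data = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    sizes = [len(groups[g]) for g in labels]
    n = len(data)
    ranks = stats.rankdata(data)
    # tie correction term
    _, tie_counts = np.unique(data, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n - 1))
    mean_ranks = {}
    start = 0
    for g, sz in zip(labels, sizes):
        mean_ranks[g] = ranks[start:start + sz].mean()
        start += sz
    rows = []
    for (ga, na), (gb, nb) in itertools.combinations(zip(labels, sizes), 2):
        se = math.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        if se == 0.0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[ga] - mean_ranks[gb]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": ga, "group_b": gb, "z": z, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        from statsmodels.stats.multitest import multipletests
        df["p_adj"] = multipletests(df["p"], method="holm")[1]
        df["significant"] = df["p_adj"] < alpha
    return df


def _letter_display(labels: list, nondiff_pairs: set) -> dict:
    """Compact letter display: groups sharing a letter do not differ."""
    letters: dict = {g: "" for g in labels}
    assigned: list[set] = []
    for g in labels:
        placed = False
        for s in assigned:
            if all(frozenset((g, h)) in nondiff_pairs for h in s):
                s.add(g)
                placed = True
        if not placed:
            assigned.append({g})
    for i, s in enumerate(assigned):
        ch = chr(ord("a") + i)
        for g in s:
            letters[g] += ch
    return {g: "".join(sorted(v)) for g, v in letters.items()}


@dataclass
class RegimeComparison:
    interval: tuple[float, float]
    kw_statistic: float
    kw_p: float
    dunn: pd.DataFrame | None
    letters: dict
    bootstrap_medians: dict
    subsample_size: int


def compare_regimes(per_regime_fractions: dict, rng: np.random.Generator,
                    alpha: float = 0.05,
                    n_boot: int = 1000) -> list[RegimeComparison]:
    """Compare stiffness regimes interval by interval.

    ``per_regime_fractions`` maps regime label -> array of shape
    (n_runs, 4): per-run fractions of lineages in each R^2 interval.
    Runs are subsampled (seeded) to the smallest regime size so all
    regimes contribute equally; per interval a Kruskal-Wallis omnibus is
    computed, Dunn's post-hoc only when the omnibus is significant, and
    bootstrap medians with percentile 95% CIs are attached.
    """
    labels = list(per_regime_fractions)
    if len(labels) < 2:
        raise ValueError("need at least two regimes")
    arrs = {g: np.asarray(per_regime_fractions[g], dtype=float)
            for g in labels}
    for g, a in arrs.items():
        if a.ndim != 2 or a.shape[1] != len(R2_INTERVALS) or a.shape[0] < 2:
            raise ValueError(f"regime {g!r}: expected (n_runs >= 2, 4) array")
    n_sub = min(a.shape[0] for a in arrs.values())
    sub = {g: a[rng.choice(a.shape[0], n_sub, replace=False)]
           for g, a in arrs.items()}
    out = []
    for i, interval in enumerate(R2_INTERVALS):
        samples = {g: sub[g][:, i] for g in labels}
        flat = np.concatenate(list(samples.values()))
        if np.all(flat == flat[0]):
            kw_stat, kw_p = 0.0, 1.0
        else:
            kw_stat, kw_p = stats.kruskal(*samples.values())
        dunn = None
        nondiff = {frozenset(p) for p in itertools.combinations(labels, 2)}
        if kw_p < alpha:
            dunn = dunn_test(samples, alpha=alpha)
            nondiff = {frozenset((r.group_a, r.group_b))
                       for r in dunn.itertuples() if not r.significant}
        letters = _letter_display(labels, nondiff)
        boots = {}
        for g in labels:
            bs = rng.choice(samples[g], (n_boot, n_sub), replace=True)
            med = np.median(bs, axis=1)
            boots[g] = {
                "median": float(np.median(samples[g])),
                "boot_median": float(np.mean(med)),
                "ci_low": float(np.percentile(med, 2.5)),
                "ci_high": float(np.percentile(med, 97.5)),
            }
        out.append(RegimeComparison(interval, float(kw_stat), float(kw_p),
                                    dunn, letters, boots, n_sub))
    return out


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

def morphometrics(tissue: TissueMesh) -> pd.DataFrame:
    """Per-type cell count, area and major-axis length summaries.

    The major-axis length of a cell is ``4 * sqrt(lambda_max)`` of its
    area covariance matrix — the major diameter of the ellipse with the
    same second moments.
    """
    rows = []
    for cell in tissue.cells.values():
        cov = polygon_second_moments(tissue.ring_coords(cell))
        evals = np.linalg.eigvalsh(cov)
        rows.append({
            "cell_type": cell.cell_type,
            "area": tissue.cell_area(cell),
            "major_axis_length": 4.0 * math.sqrt(max(evals[1], 0.0)),
            "minor_axis_length": 4.0 * math.sqrt(max(evals[0], 0.0)),
        })
    df = pd.DataFrame(rows)
    return (df.groupby("cell_type")
              .agg(count=("area", "size"),
                   mean_area=("area", "mean"),
                   median_area=("area", "median"),
                   mean_major_axis=("major_axis_length", "mean"),
                   median_major_axis=("major_axis_length", "median"))
              .reset_index())
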