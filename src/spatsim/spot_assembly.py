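"""Spot assembly: from single-cell layouts to spot-level SRT data.

Cells placed on a canvas are aggregated into capture spots whose spacing
is set by a target average number of cells per spot ``n`` and whose
arrangement mimics the mainstream platforms: a square grid (ST-style), a
hexagonal lattice (Visium-style), or random centers (Slide-seq-style).
Spot expression is the exact sum of member-cell expression and each
spot's ground-truth cell-type composition is recorded, so deconvolution
and resolution-enhancement methods can be scored against truth.

Also provided: merging a high-resolution square grid into a coarser one,
splitting 3-D data into 2-D slices along an axis, and targeted gene-panel
selection (random / highly variable / marker genes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import ExpressionDataset, SpatialAssignment

#: Platform presets: arrangement and the target average cells per spot,
#: matching the realized averages of simulated Slide-seq, Visium, and ST data.
PLATFORM_PRESETS: dict[str, tuple[str, float]] = {
    "slide-seq": ("random", 2.34),
    "visium": ("hexagonal", 10.5),
    "st": ("square", 34.01),
}


@dataclass
class LatticeSpec:
    """Spot arrangement (``random`` | ``hexagonal`` | ``square``), the target
    average number of cells per spot, and the canvas bounds."""

    arrangement: str = "square"
    target_cells_per_spot: float = 10.0
    bounds: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arrangement not in ("random", "hexagonal", "square"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.target_cells_per_spot <= 0:
            raise ValueError("target_cells_per_spot must be positive")


@dataclass
class SpotDataset:
    """Spot coordinates, summed expression, ground-truth composition, and
    per-spot member cell ids."""

    spot_coords: np.ndarray
    spot_expr: np.ndarray
    composition: np.ndarray
    composition_labels: list[str]
    members: list[list[str]]
    gene_names: list[str]
    member_populations: list[list[str]] = field(default_factory=list)

    @property
    def n_spots(self) -> int:
        return self.spot_coords.shape[0]

    def mean_cells_per_spot(self) -> float:
        return float(np.mean([len(m) for m in self.members]))


def generate_spot_lattice(spec: LatticeSpec, cell_density: float) -> np.ndarray:
    """Spot centers over the canvas for a given cell density.

    Square: axis-aligned grid with spacing ``s = sqrt(n / density)``.
    Hexagonal: offset rows with equal per-spot catchment area ``n / density``
    (interior spots have six equidistant neighbors).
    Random: uniform centers, one per ``n / density`` of canvas area.
    """
    if cell_density <= 0:
        raise ValueError("cell_density must be positive")
    x0, x1, y0, y1 = spec.bounds
    area_per_spot = spec.target_cells_per_spot / cell_density
    if spec.arrangement == "square":
        # tile the canvas exactly with the integer tile count closest to the
        # ideal spacing sqrt(n / density)
        s = math.sqrt(area_per_spot)
        mx = max(1, round((x1 - x0) / s))
        my = max(1, round((y1 - y0) / s))
        xs = x0 + ((np.arange(mx) + 0.5) / mx) * (x1 - x0)
        ys = y0 + ((np.arange(my) + 0.5) / my) * (y1 - y0)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel()], axis=1)
    if spec.arrangement == "hexagonal":
        # center spacing h so each hexagonal catchment has the target area
        h = math.sqrt(2.0 * area_per_spot / math.sqrt(3.0))
        row_h = h * math.sqrt(3.0) / 2.0
        centers = []
        row = 0
        y = y0 + row_h / 2
        while y < y1:
            offset = (h / 2) if (row % 2) else 0.0
            x = x0 + h / 2 + offset
            while x < x1:
                centers.append((x, y))
                x += h
            y += row_h
            row += 1
        return np.asarray(centers)
    # random
    n_spots = max(1, int(round((x1 - x0) * (y1 - y0) / area_per_spot)))
    rng = np.random.default_rng(spec.seed)
    pts = rng.random((n_spots, 2))
    pts[:, 0] = x0 + pts[:, 0] * (x1 - x0)
    pts[:, 1] = y0 + pts[:, 1] * (y1 - y0)
    return pts


def bin_cells_to_spots(
    assign: SpatialAssignment,
    expr: ExpressionDataset,
    lattice: np.ndarray,
    spec: LatticeSpec,
) -> SpotDataset:
    """Attach each cell to its catchment spot and aggregate.

    Square/hexagonal arrangements use tile membership (for hexagons the tile
    is the Voronoi cell of the center, i.e. nearest center); random uses
    nearest center. Spot expression is the exact sum of member rows;
    composition rows are member population proportions; empty spots are
    dropped. Boundary ties go to the lower-index tile.
    """
    if assign.cell_ids != expr.cell_ids:
        raise ValueError("assignment and expression cell ids are misaligned")
    coords = assign.coordinates[:, :2]
    if spec.arrangement == "square":
        x0, _, y0, _ = spec.bounds
        xs = np.unique(lattice[:, 0])
        ys = np.unique(lattice[:, 1])
        sx = xs[1] - xs[0] if xs.size > 1 else 1.0
        sy = ys[1] - ys[0] if ys.size > 1 else 1.0
        ix = np.clip(np.floor((coords[:, 0] - x0) / sx).astype(int), 0, xs.size - 1)
        iy = np.clip(np.floor((coords[:, 1] - y0) / sy).astype(int), 0, ys.size - 1)
        spot_of_cell = ix * ys.size + iy
    else:  # hexagonal tiles == Voronoi cells of the centers; random: nearest
        d2 = (
            (coords[:, 0, None] - lattice[None, :, 0]) ** 2
            + (coords[:, 1, None] - lattice[None, :, 1]) ** 2
        )
        spot_of_cell = np.argmin(d2, axis=1)

    pop_labels = sorted(set(assign.population))
    pop_index = {p: i for i, p in enumerate(pop_labels)}
    pops = np.asarray([pop_index[p] for p in assign.population])

    keep, coords_out, exprs, comps, members, member_pops = [], [], [], [], [], []
    for spot in range(lattice.shape[0]):
        idx = np.flatnonzero(spot_of_cell == spot)
        if idx.size == 0:
            continue
        keep.append(spot)
        coords_out.append(lattice[spot])
        exprs.append(expr.matrix[idx].sum(axis=0))
        comp = np.bincount(pops[idx], minlength=len(pop_labels)).astype(float)
        comps.append(comp / comp.sum())
        members.append([assign.cell_ids[i] for i in idx])
        member_pops.append([assign.population[i] for i in idx])
    return SpotDataset(
        spot_coords=np.asarray(coords_out),
        spot_expr=np.asarray(exprs),
        composition=np.asarray(comps),
        composition_labels=pop_labels,
        members=members,
        gene_names=list(expr.gene_names),
        member_populations=member_pops,
    )


def build_low_res_from_high(spots_high: SpotDataset, factor: int) -> SpotDataset:
    """Merge non-overlapping ``factor x factor`` blocks of a square-grid spot
    dataset into coarser spots; expression sums exactly and composition is
    re-derived from the pooled member cells."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return spots_high
    xs = np.unique(spots_high.spot_coords[:, 0])
    ys = np.unique(spots_high.spot_coords[:, 1])
    if xs.size * ys.size != spots_high.n_spots:
        raise ValueError("high-resolution spots must lie on a full square grid")
    ix = np.searchsorted(xs, spots_high.spot_coords[:, 0])
    iy = np.searchsorted(ys, spots_high.spot_coords[:, 1])
    bx, by = ix // factor, iy // factor
    block = bx * (math.ceil(ys.size / factor)) + by

    pop_labels = spots_high.composition_labels
    pop_index = {p: i for i, p in enumerate(pop_labels)}
    coords_out, exprs, comps, members, member_pops = [], [], [], [], []
    for b in np.unique(block):
        idx = np.flatnonzero(block == b)
        coords_out.append(spots_high.spot_coords[idx].mean(axis=0))
        exprs.append(spots_high.spot_expr[idx].sum(axis=0))
        pooled_ids = [cid for i in idx for cid in spots_high.members[i]]
        pooled_pops = [p for i in idx for p in spots_high.member_populations[i]]
        comp = np.zeros(len(pop_labels))
        for p in pooled_pops:
            comp[pop_index[p]] += 1
        comps.append(comp / comp.sum())
        members.append(pooled_ids)
        member_pops.append(pooled_pops)
    return SpotDataset(
        spot_coords=np.asarray(coords_out),
        spot_expr=np.asarray(exprs),
        composition=np.asarray(comps),
        composition_labels=list(pop_labels),
        members=members,
        gene_names=list(spots_high.gene_names),
        member_populations=member_pops,
    )


def split_3d(
    assign3d: SpatialAssignment, axis: str, k: int
) -> list[SpatialAssignment]:
    """Partition a 3-D assignment into ``k`` equal-width slices along one axis.

    Each returned slice is 2-D over the two remaining axes; every cell lands
    in exactly one slice (the last bin is right-inclusive).
    """
    if assign3d.ndim != 3:
        raise ValueError("split_3d needs 3-D coordinates")
    ax = {"x": 0, "y": 1, "z": 2}.get(axis)
    if ax is None:
        raise ValueError("axis must be 'x', 'y' or 'z'")
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = assign3d.coordinates[:, ax]
    lo, hi = float(vals.min()), float(vals.max())
    if k > 1 and hi == lo:
        raise ValueError("cannot split: no coordinate spread along the axis")
    edges = np.linspace(lo, hi, k + 1)
    bins = np.clip(np.digitize(vals, edges[1:-1], right=False), 0, k - 1)
    keep_axes = [i for i in range(3) if i != ax]
    slices = []
    for s in range(k):
        idx = np.flatnonzero(bins == s)
        slices.append(
            SpatialAssignment(
                coordinates=assign3d.coordinates[np.ix_(idx, keep_axes)],
                population=[assign3d.population[i] for i in idx],
                cell_ids=[assign3d.cell_ids[i] for i in idx],
            )
        )
    return slices


def select_gene_panel(
    expr: ExpressionDataset, mode: str, count: int, seed: int = 0
) -> list[str]:
    """Pick a targeted gene panel.

    ``random``: uniform sample without replacement. ``hvg``: top genes by
    cross-cell variance. ``marker``: genes ranked per population by
    one-vs-rest mean difference of (log-scale) expression, taken round-robin
    across populations until ``count`` genes are collected.
    """
    if count > expr.n_genes:
        raise ValueError(f"count {count} exceeds gene count {expr.n_genes}")
    if mode == "random":
        rng = np.random.default_rng(seed)
        idx = rng.choice(expr.n_genes, size=count, replace=False)
        return [expr.gene_names[i] for i in sorted(idx)]
    if mode == "hvg":
        var = expr.matrix.var(axis=0, ddof=1)
        order = np.argsort(-var, kind="stable")
        return [expr.gene_names[i] for i in order[:count]]
    if mode == "marker":
        pops = np.asarray(expr.population)
        labels = sorted(set(expr.population))
        rankings = []
        for pop in labels:
            mask = pops == pop
            lfc = expr.matrix[mask].mean(axis=0) - expr.matrix[~mask].mean(axis=0)
            rankings.append(list(np.argsort(-lfc, kind="stable")))
        chosen: list[int] = []
        seen: set[int] = set()
        cursor = [0] * len(labels)
        while len(chosen) < count:
            progressed = False
            for pi in range(len(labels)):
                if len(chosen) >= count:
                    break
                while cursor[pi] < len(rankings[pi]):
                    g = rankings[pi][cursor[pi]]
                    cursor[pi] += 1
                    if g not in seen:
                        seen.add(g)
                        chosen.append(g)
                        progressed = True
                        break
            if not progressed:
                break
        return [expr.gene_names[i] for i in chosen]
    raise ValueError(f"unknown mode {mode!r}")


def marker_logfc(expr: ExpressionDataset, population: str) -> np.ndarray:
    """One-vs-rest mean difference of expression for one population (the
    ranking statistic behind marker panels)."""
    pops = np.asarray(expr.population)
    mask = pops == population
    return expr.matrix[mask].mean(axis=0) - expr.matrix[~mask].mean(axis=0)
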