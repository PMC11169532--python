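"""Reference-free spatial pattern synthesis.

Two families of patterns are generated without any spatial reference:

Random patterns
    The unit square (or cube) is divided into a regular grid and a
    Gaussian random field V ~ MVN(0, Sigma) is drawn over the grid
    centers, with squared-exponential covariance
    ``Sigma_ij = exp(-(D_ij / delta)^2)`` built from the Euclidean
    distance matrix D. A larger autocorrelation length ``delta`` yields
    more connected patterns. Each patterned population claims its
    proportional share of the still-unclaimed grids, taking those ranked
    highest by a fresh field draw, and its cells are placed uniformly
    inside the claimed grids; remaining populations spread uniformly over
    leftover grids. A clarity parameter ``lambda`` in [0, 1] then blurs
    the result by randomly swapping the coordinates of a ``1 - lambda``
    fraction of cells.

Customized patterns
    Geometric basis patterns — unstructured mixtures, elliptical
    clusters, single/double rings, and stripe-shaped vessels — decide
    position membership through rotated-frame inequalities; members get
    the pattern's population (minus a user-set infiltration fraction),
    non-members the background. Basis patterns compose in painter's
    order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .core_io import ExpressionDataset, SpatialAssignment


# ---------------------------------------------------------------------------
# Gaussian random field over a grid
# ---------------------------------------------------------------------------


@dataclass
class RandomPatternConfig:
    """Settings for :func:`allocate_random_patterns`.

    ``grid_n`` grids per axis; ``delta`` the autocorrelation length of the
    field, in grid units (distance between adjacent grid centers = 1);
    ``lam`` the clarity in [0, 1] (1 = crisp, 0 = fully shuffled);
    ``patterned_populations`` the labels that receive a contiguous
    territory, in processing order.
    """

    grid_n: int = 20
    delta: float = 2.0
    lam: float = 1.0
    patterned_populations: list[str] = field(default_factory=list)
    seed: int = 0
    ndim: int = 2

    def __post_init__(self) -> None:
        if self.grid_n < 2:
            raise ValueError("grid_n must be >= 2")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if self.ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")


@dataclass
class GridField:
    """One field value per grid cell, with the grid-center coordinates."""

    values: np.ndarray
    grid_coords: np.ndarray


def grid_centers(grid_n: int, ndim: int = 2) -> np.ndarray:
    """Centers of a ``grid_n``-per-axis regular grid on the unit square/cube."""
    axis = (np.arange(grid_n) + 0.5) / grid_n
    mesh = np.meshgrid(*([axis] * ndim), indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def build_covariance(grid_coords: np.ndarray, delta: float) -> np.ndarray:
    """Squared-exponential covariance exp(-(D/delta)^2) over grid centers."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    D = cdist(grid_coords, grid_coords)
    return np.exp(-((D / delta) ** 2))


def sample_field(
    Sigma: np.ndarray, seed: int, grid_coords: np.ndarray | None = None
) -> GridField:
    """Draw V ~ MVN(0, Sigma) via a jittered Cholesky factor (seeded)."""
    Sigma = np.asarray(Sigma, dtype=float)
    n = Sigma.shape[0]
    jitter = 1e-8
    for _ in range(6):
        try:
            L = np.linalg.cholesky(Sigma + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            jitter *= 10
    else:
        raise np.linalg.LinAlgError("covariance not factorizable after jitter")
    rng = np.random.default_rng(seed)
    v = L @ rng.standard_normal(n)
    if grid_coords is None:
        grid_coords = np.zeros((n, 0))
    return GridField(values=v, grid_coords=np.asarray(grid_coords))


def apply_fuzziness(
    assign: SpatialAssignment, lam: float, seed: int
) -> SpatialAssignment:
    """Blur a pattern by swapping coordinates of a ``1 - lam`` fraction of cells.

    Exactly ``round((1 - lam) * N)`` cells participate; they are paired
    uniformly at random and each pair exchanges coordinates (an odd
    participant is dropped). Population labels are untouched and the
    coordinate multiset is preserved.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    n = assign.n_cells
    k = int(round((1.0 - lam) * n))
    coords = assign.coordinates.copy()
    if k >= 2:
        rng = np.random.default_rng(seed)
        participants = rng.choice(n, size=k, replace=False)
        participants = rng.permutation(participants)
        if k % 2 == 1:
            participants = participants[:-1]
        half = len(participants) // 2
        a, b = participants[:half], participants[half:]
        coords[a], coords[b] = coords[b].copy(), coords[a].copy()
    return SpatialAssignment(
        coordinates=coords,
        population=list(assign.population),
        cell_ids=list(assign.cell_ids),
    )


def allocate_random_patterns(
    ds: ExpressionDataset, cfg: RandomPatternConfig
) -> SpatialAssignment:
    """Give each cell a position in the unit square (or cube) such that the
    patterned populations occupy spatially contiguous grid territories.

    Per patterned population p (in declared order): a fresh field is drawn,
    the still-unclaimed grids are ranked by field value, and the top
    ``round(q_p * total grids)`` of them are claimed, where q_p is p's
    proportion among the cells. Cells of p are placed uniformly inside the
    claimed grids. Unpatterned populations spread uniformly over leftover
    grids. Finally the lambda fuzziness step runs.
    """
    labels = np.asarray(ds.population)
    unknown = set(cfg.patterned_populations) - set(labels)
    if unknown:
        raise KeyError(f"patterned populations not in dataset: {sorted(unknown)}")
    n_cells = ds.n_cells
    centers = grid_centers(cfg.grid_n, cfg.ndim)
    n_grids = centers.shape[0]
    # the field's covariance is built on grid-unit coordinates (adjacent
    # centers at distance 1), the scale on which delta is expressed
    Sigma = build_covariance(centers * cfg.grid_n, cfg.delta)

    unclaimed = np.ones(n_grids, dtype=bool)
    grid_of_pop: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(cfg.seed)
    for i, pop in enumerate(cfg.patterned_populations):
        q = float((labels == pop).sum()) / n_cells
        want = max(1, int(round(q * n_grids)))
        avail = np.flatnonzero(unclaimed)
        if want > avail.size:
            raise ValueError(
                f"population {pop!r} needs {want} grids but only "
                f"{avail.size} remain unclaimed"
            )
        fld = sample_field(Sigma, seed=cfg.seed + 1 + i, grid_coords=centers)
        order = avail[np.argsort(-fld.values[avail], kind="stable")]
        claimed = order[:want]
        grid_of_pop[pop] = claimed
        unclaimed[claimed] = False

    leftover = np.flatnonzero(unclaimed)
    coords = np.empty((n_cells, cfg.ndim))
    width = 1.0 / cfg.grid_n
    for pop in sorted(set(ds.population)):
        idx = np.flatnonzero(labels == pop)
        pool = grid_of_pop.get(pop, leftover)
        if pool.size == 0:
            raise ValueError(f"no grids left for population {pop!r}")
        g = rng.choice(pool, size=idx.size, replace=True)
        coords[idx] = centers[g] - width / 2 + rng.random((idx.size, cfg.ndim)) * width

    assign = SpatialAssignment(
        coordinates=coords, population=list(ds.population), cell_ids=list(ds.cell_ids)
    )
    return apply_fuzziness(assign, cfg.lam, seed=cfg.seed + 10_007)


# ---------------------------------------------------------------------------
# Customized geometric basis patterns
# ---------------------------------------------------------------------------


@dataclass
class PatternSpec:
    """Declarative description of one basis pattern.

    kind
        ``mixed`` | ``cluster`` | ``ring`` | ``vessel``.
    population
        Label assigned to member positions (for ``mixed``, the labels and
        their proportions go in ``mixed_proportions``).
    center, axes, theta
        Ellipse parameters for ``cluster``/``ring``: center (x0, y0),
        semi-axes (a, b), rotation theta in radians.
    width, width2
        Ring widths: single ring uses ``width``; a double ring adds a second
        annulus of width ``width2`` outside the first. For ``vessel``,
        ``width`` is the stripe width d.
    endpoints
        The vessel's two center endpoints ((x1, y1), (x2, y2)).
    symmetric
        Vessels only: if True, the stripe is centered on the endpoint
        segment instead of using the offset reference point of the
        projection equations (which places it on one side).
    infiltration
        List of (population, proportion) pairs: that fraction of member
        positions is relabeled to the infiltrating population.
    ring_population2
        Label of the second ring of a double ring (defaults to
        ``population``).
    inner_population
        Cluster enclosed by a ring (``None`` leaves the inner disc to the
        background).
    """

    kind: str
    population: str = ""
    center: tuple[float, float] = (0.5, 0.5)
    axes: tuple[float, float] = (0.2, 0.2)
    theta: float = 0.0
    width: float = 0.1
    width2: float | None = None
    endpoints: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.5), (1.0, 0.5))
    symmetric: bool = False
    infiltration: list[tuple[str, float]] = field(default_factory=list)
    mixed_proportions: list[tuple[str, float]] = field(default_factory=list)
    ring_population2: str | None = None
    inner_population: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mixed", "cluster", "ring", "vessel"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.kind in ("cluster", "ring") and min(self.axes) <= 0:
            raise ValueError("ellipse axes must be positive")
        if self.kind in ("ring", "vessel") and self.width <= 0:
            raise ValueError("width must be positive")
        if self.kind == "vessel" and tuple(self.endpoints[0]) == tuple(self.endpoints[1]):
            raise ValueError("vessel endpoints must be distinct")
        total_inf = sum(p for _, p in self.infiltration)
        if any(p <= 0 for _, p in self.infiltration) or total_inf >= 1:
            raise ValueError("infiltration proportions must be positive and sum < 1")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "population": self.population,
            "center": list(self.center), "axes": list(self.axes),
            "theta": self.theta, "width": self.width, "width2": self.width2,
            "endpoints": [list(self.endpoints[0]), list(self.endpoints[1])],
            "symmetric": self.symmetric,
            "infiltration": [list(t) for t in self.infiltration],
            "mixed_proportions": [list(t) for t in self.mixed_proportions],
            "ring_population2": self.ring_population2,
            "inner_population": self.inner_population,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatternSpec":
        d = dict(d)
        for key in ("center", "axes"):
            if key in d:
                d[key] = tuple(d[key])
        if "endpoints" in d:
            d["endpoints"] = (tuple(d["endpoints"][0]), tuple(d["endpoints"][1]))
        for key in ("infiltration", "mixed_proportions"):
            if key in d:
                d[key] = [(str(a), float(b)) for a, b in d[key]]
        return cls(**d)


def _rotate(pts: np.ndarray, center: tuple[float, float], theta: float) -> np.ndarray:
    """Rotated-frame coordinates: translate to the center, rotate by -theta."""
    dx = pts[:, 0] - center[0]
    dy = pts[:, 1] - center[1]
    c, s = math.cos(theta), math.sin(theta)
    return np.stack([dx * c + dy * s, -dx * s + dy * c], axis=1)


def _ellipse_value(pts: np.ndarray, spec: PatternSpec, grow: float = 0.0) -> np.ndarray:
    r = _rotate(pts, spec.center, spec.theta)
    a, b = spec.axes[0] + grow, spec.axes[1] + grow
    return (r[:, 0] / a) ** 2 + (r[:, 1] / b) ** 2


def point_in_ellipse(pt, spec: PatternSpec) -> bool:
    """Strict interior test of the rotated ellipse: value < 1."""
    return bool(_ellipse_value(np.atleast_2d(np.asarray(pt, float)), spec)[0] < 1.0)


def point_in_stripe(pt, spec: PatternSpec) -> bool:
    """Stripe membership via projections onto the direction and perpendicular
    vectors: inside iff 0 <= u <= l and |v| <= d/2.

    By default the projections are taken from the offset reference point
    (x1 + d*p/2, y1 + d*p/2) where p is the unit perpendicular, which places
    the stripe on one side of the endpoint segment; ``spec.symmetric``
    recenters it on the segment.
    """
    return bool(_stripe_mask(np.atleast_2d(np.asarray(pt, float)), spec)[0])


def _stripe_mask(pts: np.ndarray, spec: PatternSpec) -> np.ndarray:
    (x1, y1), (x2, y2) = spec.endpoints
    l = math.hypot(x2 - x1, y2 - y1)
    if l == 0:
        raise ValueError("zero-length stripe")
    d = spec.width
    px, py = -(y2 - y1) / l, (x2 - x1) / l
    if spec.symmetric:
        rx, ry = x1, y1
    else:
        rx, ry = x1 + d * px / 2.0, y1 + d * py / 2.0
    ux, uy = (x2 - x1) / l, (y2 - y1) / l
    u = (pts[:, 0] - rx) * ux + (pts[:, 1] - ry) * uy
    v = -(pts[:, 0] - rx) * uy + (pts[:, 1] - ry) * ux
    return (u >= 0) & (u <= l) & (np.abs(v) <= d / 2.0)


def _ring_masks(pts: np.ndarray, spec: PatternSpec):
    """(inner disc, first ring, second ring) membership masks."""
    v0 = _ellipse_value(pts, spec)
    v1 = _ellipse_value(pts, spec, grow=spec.width)
    inner = v0 < 1.0
    ring1 = (v0 > 1.0) & (v1 < 1.0)
    if spec.width2 is not None:
        v2 = _ellipse_value(pts, spec, grow=spec.width + spec.width2)
        ring2 = (v1 > 1.0) & (v2 < 1.0)
    else:
        ring2 = np.zeros(len(pts), dtype=bool)
    return inner, ring1, ring2


def _membership_labels(
    pts: np.ndarray, spec: PatternSpec, background: str, rng: np.random.Generator
) -> np.ndarray:
    """Position labels under one basis pattern (before composition)."""
    n = pts.shape[0]
    labels = np.array([background] * n, dtype=object)
    if spec.kind == "mixed":
        props = spec.mixed_proportions or [(spec.population, 1.0)]
        total = sum(p for _, p in props)
        if total > 1.0 + 1e-9:
            raise ValueError("mixed proportions sum must be <= 1")
        perm = rng.permutation(n)
        start = 0
        for pop, prop in props:
            take = int(round(prop * n))
            labels[perm[start : start + take]] = pop
            start += take
        return labels
    if spec.kind == "cluster":
        member = _ellipse_value(pts, spec) < 1.0
    elif spec.kind == "ring":
        inner, ring1, ring2 = _ring_masks(pts, spec)
        labels[ring1] = spec.population
        if spec.width2 is not None:
            labels[ring2] = spec.ring_population2 or spec.population
        if spec.inner_population is not None:
            labels[inner] = spec.inner_population
        member = ring1
        _infiltrate(labels, member, spec, rng)
        return labels
    elif spec.kind == "vessel":
        member = _stripe_mask(pts, spec)
    else:  # pragma: no cover
        raise ValueError(spec.kind)
    labels[member] = spec.population
    _infiltrate(labels, member, spec, rng)
    return labels


def _infiltrate(
    labels: np.ndarray, member: np.ndarray, spec: PatternSpec,
    rng: np.random.Generator,
) -> None:
    """Relabel a random fraction of member positions to infiltrating
    populations (i.i.d. per position)."""
    if not spec.infiltration:
        return
    idx = np.flatnonzero(member)
    if idx.size == 0:
        return
    u = rng.random(idx.size)
    lo = 0.0
    for pop, prop in spec.infiltration:
        sel = (u >= lo) & (u < lo + prop)
        labels[idx[sel]] = pop
        lo += prop


def generate_basis_pattern(
    n_cells_or_ds: "int | ExpressionDataset",
    spec: PatternSpec,
    background: str,
    seed: int = 0,
) -> SpatialAssignment:
    """Scatter positions uniformly over the unit square and label them by one
    basis pattern's geometry.

    Accepts either a cell count or an :class:`ExpressionDataset` (its size
    and ids are used). The returned assignment's population labels come from
    the pattern, not from the dataset: pattern synthesis decides the layout
    first, and expression is paired per label downstream.
    """
    return combine_patterns([spec], n_cells_or_ds, background, seed=seed)


def combine_patterns(
    specs: list[PatternSpec],
    n_cells_or_ds: "int | ExpressionDataset",
    background: str,
    seed: int = 0,
) -> SpatialAssignment:
    """Compose basis patterns in painter's order over one set of uniform
    positions: later specs overwrite earlier labels where their geometry
    claims a position."""
    if not specs:
        raise ValueError("need at least one pattern spec")
    if isinstance(n_cells_or_ds, ExpressionDataset):
        n = n_cells_or_ds.n_cells
        cell_ids = list(n_cells_or_ds.cell_ids)
    else:
        n = int(n_cells_or_ds)
        cell_ids = [f"cell_{i}" for i in range(n)]
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 2))
    labels = np.array([background] * n, dtype=object)
    for spec in specs:
        new = _membership_labels(pts, spec, background="__bg__", rng=rng)
        claimed = new != "__bg__"
        labels[claimed] = new[claimed]
    return SpatialAssignment(
        coordinates=pts, population=[str(x) for x in labels], cell_ids=cell_ids
    )
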