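"""Reference-based spatial pattern simulation.

Generated cells are mapped onto the coordinates of an annotated spatial
reference, one population (reference group) at a time. For each group the
same number of cells as reference positions is generated, a cost matrix of
squared Euclidean expression distances is built, and the exact optimal
transport problem

    gamma = argmin <gamma, M>_F   s.t.  gamma 1 = a,  gamma^T 1 = b,  gamma >= 0

is solved with uniform marginals a = b = 1/n. Positions are then assigned
their maximum-likelihood cell by greedily extracting the largest remaining
plan entry, which yields a deterministic bijection.

The mapping is computed purely from expression distance; reference
coordinates enter only as the output locations, never the cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist

from .core_io import ExpressionDataset, SpatialAssignment, SpatialReference
from .expression_vae import TrainedModel, generate_cells

_MARGINAL_TOL = 1e-8


@dataclass
class TransportPlan:
    """An optimal transport plan gamma with its objective <gamma, M>_F."""

    gamma: np.ndarray
    objective: float


def cost_matrix(gen_expr: np.ndarray, ref_expr: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance between every generated cell and every
    reference position, on identically ordered genes."""
    gen_expr = np.atleast_2d(np.asarray(gen_expr, dtype=float))
    ref_expr = np.atleast_2d(np.asarray(ref_expr, dtype=float))
    if gen_expr.shape[1] != ref_expr.shape[1]:
        raise ValueError(
            f"gene mismatch: {gen_expr.shape[1]} vs {ref_expr.shape[1]} columns"
        )
    return cdist(gen_expr, ref_expr, metric="sqeuclidean")


def solve_ot(M: np.ndarray, a: np.ndarray, b: np.ndarray) -> TransportPlan:
    """Exact solution of the transport LP.

    Square problems with uniform marginals reduce to an assignment problem
    (a permutation matrix scaled by 1/n is an optimal vertex of the Birkhoff
    polytope); general marginals go through the HiGHS LP solver.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n, m = M.shape
    if a.shape[0] != n or b.shape[0] != m:
        raise ValueError("marginal lengths must match cost matrix shape")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("marginals must be non-negative")
    if abs(a.sum() - b.sum()) > 1e-6 * max(a.sum(), b.sum(), 1.0):
        raise ValueError(f"infeasible marginals: sum(a)={a.sum()} != sum(b)={b.sum()}")

    uniform = (
        n == m
        and np.allclose(a, a.sum() / n, atol=1e-12)
        and np.allclose(b, b.sum() / n, atol=1e-12)
    )
    if uniform:
        rows, cols = linear_sum_assignment(M)
        gamma = np.zeros_like(M)
        gamma[rows, cols] = a.sum() / n
    else:
        gamma = _solve_ot_lp(M, a, b)
    return TransportPlan(gamma=gamma, objective=float(np.sum(gamma * M)))


def _solve_ot_lp(M: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy import sparse

    n, m = M.shape
    # row-sum constraints then column-sum constraints over vec(gamma)
    row_eq = sparse.kron(sparse.eye(n), np.ones((1, m)))
    col_eq = sparse.kron(np.ones((1, n)), sparse.eye(m))
    A_eq = sparse.vstack([row_eq, col_eq]).tocsr()
    res = linprog(
        M.ravel(), A_eq=A_eq, b_eq=np.concatenate([a, b]),
        bounds=(0, None), method="highs",
    )
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return res.x.reshape(n, m)


def check_marginals(plan: TransportPlan, a: np.ndarray, b: np.ndarray) -> float:
    """Max-norm violation of the plan's marginal constraints."""
    g = plan.gamma
    return float(
        max(
            np.abs(g.sum(axis=1) - np.asarray(a)).max(),
            np.abs(g.sum(axis=0) - np.asarray(b)).max(),
        )
    )


def assign_positions(plan: TransportPlan) -> np.ndarray:
    """Deterministic bijection position -> generated cell from a square plan.

    Repeatedly takes the largest remaining entry of gamma, fixes that
    (cell, position) pair, and deletes its row and column; ties break toward
    the lowest (row, column) index. Returns ``mapping`` with
    ``mapping[position] = cell index``.
    """
    g = np.asarray(plan.gamma, dtype=float)
    n, m = g.shape
    if n != m:
        raise ValueError(f"plan must be square, got {g.shape}")
    work = g.copy()
    mapping = np.full(n, -1, dtype=int)
    for _ in range(n):
        # argmax of the flattened array honors lowest-(row, col) tie-break
        flat = np.argmax(work)
        i, j = divmod(int(flat), m)
        mapping[j] = i
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    return mapping


def simulate_reference_based(
    model: TrainedModel,
    ref: SpatialReference,
    seed: int = 0,
    generated: ExpressionDataset | None = None,
) -> tuple[ExpressionDataset, SpatialAssignment]:
    """Generate cells per reference group and map them to reference positions.

    For every group g with m_g positions, m_g cells of population g are
    generated (or taken from ``generated``, which must then carry exactly
    m_g cells labeled g), the expression cost is built on the shared gene
    set, the uniform-marginal transport problem is solved, and positions
    receive their maximum-likelihood cell. Groups are processed in
    lexicographic order and the result concatenated.
    """
    groups = ref.groups()
    ref_genes = list(ref.gene_names)
    model_genes = list(model.gene_names) if generated is None else list(generated.gene_names)
    if ref_genes:
        shared = sorted(set(ref_genes) & set(model_genes))
        if len(shared) < min(10, len(model_genes)):
            raise ValueError(
                f"only {len(shared)} genes shared between model and reference"
            )
    else:  # reference without gene names: positional match
        shared = None

    grp = np.asarray(ref.group)
    mats, ids, pops, coords = [], [], [], []
    for gi, g in enumerate(groups):
        pos_idx = np.flatnonzero(grp == g)
        m_g = pos_idx.size
        if generated is None:
            if g not in model.latent_summaries:
                raise KeyError(f"reference group {g!r} unknown to the model")
            gen = generate_cells(model, g, m_g, seed=seed + gi)
        else:
            gen = generated.subset_population(g)
            if gen.n_cells != m_g:
                raise ValueError(
                    f"group {g!r}: {gen.n_cells} generated cells for {m_g} positions"
                )
        if shared is not None:
            gcols = [model_genes.index(x) for x in shared]
            rcols = [ref_genes.index(x) for x in shared]
            M = cost_matrix(gen.matrix[:, gcols], ref.expression[pos_idx][:, rcols])
        else:
            M = cost_matrix(gen.matrix, ref.expression[pos_idx])
        u = np.full(m_g, 1.0 / m_g)
        plan = solve_ot(M, u, u)
        mapping = assign_positions(plan)
        mats.append(gen.matrix[mapping])
        ids.extend(gen.cell_ids[i] for i in mapping)
        pops.extend([g] * m_g)
        coords.append(ref.coordinates[pos_idx])

    expr = ExpressionDataset(
        matrix=np.vstack(mats),
        gene_names=model_genes,
        cell_ids=ids,
        population=pops,
    )
    assign = SpatialAssignment(
        coordinates=np.vstack(coords), population=pops, cell_ids=ids
    )
    return expr, assign
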