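"""Ground-truth evaluation metric suite.

Simulation-fidelity metrics on per-gene expression vectors (Pearson
correlation, mean absolute error, and a regression-smoothed Pearson
correlation PCC_GBM), composition/imputation metrics (PCC, Spearman rank
correlation, RMSE, Jensen-Shannon divergence, and the rank-aggregated
accuracy score AS), clustering agreement metrics computed from the
contingency table (ARI, NMI, homogeneity, Fowlkes-Mallows), and Moran's I
spatial autocorrelation with row-standardized k-nearest-neighbor weights.

All formulas are implemented from first principles on NumPy arrays;
undefined cases (constant vectors for correlations, constant fields for
Moran's I) return NaN rather than an arbitrary number, so callers decide
exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata


def _as_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 2:
        raise ValueError("vectors must have length >= 2")
    return x, y


def pearson(x, y) -> float:
    """Pearson correlation; NaN if either vector is constant."""
    x, y = _as_pair(x, y)
    dx, dy = x - x.mean(), y - y.mean()
    denom = math.sqrt(float(dx @ dx)) * math.sqrt(float(dy @ dy))
    if denom == 0.0:
        return float("nan")
    return float((dx @ dy) / denom)


def spearman(x, y) -> float:
    """Spearman rank correlation as Pearson of mid-ranks (tie-safe; equals
    the classical 1 - 6*sum(d^2)/(n(n^2-1)) shortcut when tie-free)."""
    x, y = _as_pair(x, y)
    return pearson(rankdata(x), rankdata(y))


def mae(x, y) -> float:
    x, y = _as_pair(x, y)
    return float(np.abs(x - y).mean())


def rmse(x, y) -> float:
    x, y = _as_pair(x, y)
    return float(math.sqrt(np.mean((x - y) ** 2)))


def js_divergence(p, q, base: float | None = None) -> float:
    """Jensen-Shannon divergence between two proportion vectors.

    Both vectors are renormalized to sum 1; the 0*log(0/.) convention is 0.
    Natural log by default (bounded by ln 2); pass ``base`` to change it.
    """
    p, q = _as_pair(p, q)
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("proportion vectors must be non-negative")
    sp, sq = p.sum(), q.sum()
    if sp == 0 or sq == 0:
        raise ValueError("zero-sum vector: JS undefined")
    p, q = p / sp, q / sq
    m = 0.5 * (p + q)

    def _kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))

    js = 0.5 * _kl(p, m) + 0.5 * _kl(q, m)
    if base is not None:
        js /= math.log(base)
    return js


def gene_vector_metrics(x, y) -> tuple[float, float]:
    """(PCC, MAE) between ground-truth and predicted per-gene expression
    vectors across positions. PCC is NaN for constant vectors."""
    return pearson(x, y), mae(x, y)


def compare_compositions(x, y) -> tuple[float, float, float, float]:
    """(PCC, SRCC, RMSE, JS) between a ground-truth and a predicted
    proportion vector."""
    return pearson(x, y), spearman(x, y), rmse(x, y), js_divergence(x, y)


@dataclass
class MethodScores:
    """Per-method PCC, SRCC, RMSE and JS values for rank aggregation."""

    pcc: dict[str, float]
    srcc: dict[str, float]
    rmse: dict[str, float]
    js: dict[str, float]


def accuracy_score(scores: MethodScores) -> dict[str, float]:
    """Rank-aggregated accuracy score AS per method.

    Per metric, methods are ranked best-to-worst (higher is better for
    PCC/SRCC, lower for RMSE/JS); rank r among m methods is normalized to
    (m - r + 1) / m so the best method scores 1; AS is the mean of the four
    normalized ranks. Ties get mid-ranks.
    """
    methods = sorted(scores.pcc)
    for attr in ("srcc", "rmse", "js"):
        if sorted(getattr(scores, attr)) != methods:
            raise ValueError(f"metric {attr!r} missing for some method")
    m = len(methods)
    out = {meth: 0.0 for meth in methods}
    for attr, higher_better in (
        ("pcc", True), ("srcc", True), ("rmse", False), ("js", False),
    ):
        vals = np.array([getattr(scores, attr)[meth] for meth in methods])
        ranks = rankdata(-vals if higher_better else vals)  # 1 = best
        for meth, r in zip(methods, ranks):
            out[meth] += (m - r + 1) / m / 4.0
    return out


def pcc_gbm(
    coords_real: np.ndarray,
    expr_real: np.ndarray,
    coords_sim: np.ndarray,
    expr_sim: np.ndarray,
    regressor_factory=None,
    seed: int = 0,
) -> float:
    """Regression-smoothed fidelity of one gene's spatial expression.

    Two coordinate-to-expression regressors (gradient-boosted trees by
    default: depth 3, 100 rounds, seeded) are fitted on the real and the
    simulated data separately; both predict at the simulated data's
    coordinates and the Pearson correlation of the two prediction vectors is
    returned. Smoothing makes the comparison robust when real and simulated
    cells do not share positions.
    """
    if regressor_factory is None:
        from sklearn.ensemble import GradientBoostingRegressor

        def regressor_factory():
            return GradientBoostingRegressor(
                max_depth=3, n_estimators=100, random_state=seed
            )

    model_real = regressor_factory()
    model_real.fit(np.asarray(coords_real), np.asarray(expr_real, dtype=float).ravel())
    model_sim = regressor_factory()
    model_sim.fit(np.asarray(coords_sim), np.asarray(expr_sim, dtype=float).ravel())
    pred_real = model_real.predict(np.asarray(coords_sim))
    pred_sim = model_sim.predict(np.asarray(coords_sim))
    return pearson(pred_real, pred_sim)


# ---------------------------------------------------------------------------
# Clustering agreement
# ---------------------------------------------------------------------------


def _contingency(truth, predicted):
    truth = [str(t) for t in truth]
    predicted = [str(p) for p in predicted]
    if len(truth) != len(predicted):
        raise ValueError("labelings must have equal length")
    if len(truth) < 2:
        raise ValueError("need at least two items")
    classes = sorted(set(truth))
    clusters = sorted(set(predicted))
    table = np.zeros((len(classes), len(clusters)), dtype=np.int64)
    ci = {c: i for i, c in enumerate(classes)}
    ki = {k: j for j, k in enumerate(clusters)}
    for t, p in zip(truth, predicted):
        table[ci[t], ki[p]] += 1
    return table


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * (x - 1) / 2.0


def compare_labelings(truth, predicted) -> tuple[float, float, float, float]:
    """(ARI, NMI, HS, FMI) from the contingency table of two labelings.

    ARI is the Hubert-Arabie adjusted Rand index; NMI normalizes mutual
    information by the arithmetic mean of the two label entropies; HS is the
    homogeneity score 1 - H(C|K)/H(C); FMI is sqrt(precision * recall) over
    co-membership pairs with precision = TP/(TP+FP), recall = TP/(TP+FN).
    """
    table = _contingency(truth, predicted)
    n = table.sum()
    a = table.sum(axis=1)  # class sizes
    b = table.sum(axis=0)  # cluster sizes

    # --- ARI (pair counting)
    sum_ij = _comb2(table).sum()
    sum_a, sum_b = _comb2(a).sum(), _comb2(b).sum()
    total = _comb2(np.array([n]))[0]
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    ari = 1.0 if max_index == expected else (sum_ij - expected) / (max_index - expected)

    # --- entropies and mutual information (natural log)
    def _entropy(counts: np.ndarray) -> float:
        p = counts[counts > 0] / n
        return float(-(p * np.log(p)).sum())

    h_c, h_k = _entropy(a), _entropy(b)
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij > 0:
                mi += (nij / n) * math.log(n * nij / (a[i] * b[j]))
    denom = 0.5 * (h_c + h_k)
    nmi = 1.0 if denom == 0 else mi / denom

    # --- homogeneity: 1 - H(C|K) / H(C)
    h_c_given_k = 0.0
    for j in range(table.shape[1]):
        for i in range(table.shape[0]):
            nij = table[i, j]
            if nij > 0:
                h_c_given_k -= (nij / n) * math.log(nij / b[j])
    hs = 1.0 if h_c == 0 else 1.0 - h_c_given_k / h_c

    # --- Fowlkes-Mallows over co-membership pairs
    tp = sum_ij
    fp = sum_b - sum_ij  # same cluster, different class
    fn = sum_a - sum_ij  # same class, different cluster
    if tp == 0:
        fmi = 0.0
    else:
        fmi = math.sqrt((tp / (tp + fp)) * (tp / (tp + fn)))
    return float(ari), float(nmi), float(hs), float(fmi)


# ---------------------------------------------------------------------------
# Spatial autocorrelation
# ---------------------------------------------------------------------------


def morans_i(
    values,
    coords,
    k_neighbors: int = 6,
    weights: np.ndarray | None = None,
) -> float:
    """Moran's I with row-standardized k-nearest-neighbor weights.

    Positive for spatially clustered fields; expectation -1/(N-1) under a
    random permutation null. A constant field makes the statistic undefined
    and returns NaN. A precomputed (unstandardized) weight matrix may be
    passed instead of the kNN construction.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 positions")
    dev = x - x.mean()
    denom = float(dev @ dev)
    if denom == 0.0:
        return float("nan")
    if weights is None:
        coords = np.asarray(coords, dtype=float)
        k = min(k_neighbors, n - 1)
        tree = cKDTree(coords)
        _, nbrs = tree.query(coords, k=k + 1)
        W = np.zeros((n, n))
        for i in range(n):
            for j in nbrs[i][1:]:
                W[i, j] = 1.0
    else:
        W = np.asarray(weights, dtype=float).copy()
    row_sums = W.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    W = W / row_sums
    s0 = W.sum()
    return float((n / s0) * (dev @ W @ dev) / denom)


def morans_i_per_population(
    assign, k_neighbors: int = 6
) -> dict[str, float]:
    """Moran's I of each population's indicator field over all positions."""
    pops = sorted(set(assign.population))
    labels = np.asarray(assign.population)
    out = {}
    for pop in pops:
        indicator = (labels == pop).astype(float)
        out[pop] = morans_i(indicator, assign.coordinates, k_neighbors=k_neighbors)
    return out
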