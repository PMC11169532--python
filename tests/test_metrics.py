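import itertools
import math

import numpy as np
import pytest
from scipy import stats

import spatsim as ss
from spatsim.metrics import (
    mae,
    morans_i_per_population,
    pearson,
    rmse,
    spearman,
)


# ---------------------------------------------------------------------------
# from-scratch summation oracles, coded independently of the implementation
# ---------------------------------------------------------------------------


def oracle_pcc(x, y):
    n = len(x)
    xb, yb = sum(x) / n, sum(y) / n
    num = sum((x[i] - xb) * (y[i] - yb) for i in range(n))
    den = math.sqrt(sum((v - xb) ** 2 for v in x)) * math.sqrt(
        sum((v - yb) ** 2 for v in y)
    )
    return num / den


def oracle_mae(x, y):
    return sum(abs(a - b) for a, b in zip(x, y)) / len(x)


def oracle_rmse(x, y):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)) / len(x))


def oracle_js(p, q):
    p = [v / sum(p) for v in p]
    q = [v / sum(q) for v in q]
    m = [(a + b) / 2 for a, b in zip(p, q)]

    def kl(a, b):
        return sum(ai * math.log(ai / bi) for ai, bi in zip(a, b) if ai > 0)

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


class TestGeneVectorMetrics:
    def test_perfect_agreement(self):
        pcc, err = ss.gene_vector_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (pcc, err) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_perfect_anticorrelation(self):
        pcc, _ = ss.gene_vector_metrics([1, 2, 3], [3, 2, 1])
        assert pcc == pytest.approx(-1.0)

    def test_matches_formula_oracle(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 5.0, 4.0]
        pcc, err = ss.gene_vector_metrics(x, y)
        assert pcc == pytest.approx(oracle_pcc(x, y), abs=1e-12)
        assert err == pytest.approx(oracle_mae(x, y), abs=1e-12)

    def test_constant_vector_flagged_nan(self):
        pcc, _ = ss.gene_vector_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(pcc)


class TestCompositions:
    def test_identical_vectors(self):
        pcc, srcc, r, js = ss.compare_compositions([0.5, 0.3, 0.2], [0.5, 0.3, 0.2])
        assert pcc == pytest.approx(1.0)
        assert srcc == pytest.approx(1.0)
        assert r == pytest.approx(0.0)
        assert js == pytest.approx(0.0)

    def test_disjoint_support_extremes(self):
        _, _, r, js = ss.compare_compositions([1.0, 0.0], [0.0, 1.0])
        assert r == pytest.approx(1.0)
        assert js == pytest.approx(math.log(2.0), abs=1e-12)

    def test_matches_formula_oracles(self):
        x, y = [0.5, 0.3, 0.2], [0.2, 0.3, 0.5]
        pcc, srcc, r, js = ss.compare_compositions(x, y)
        assert pcc == pytest.approx(oracle_pcc(x, y), abs=1e-12)
        assert r == pytest.approx(oracle_rmse(x, y), abs=1e-12)
        assert js == pytest.approx(oracle_js(x, y), abs=1e-12)
        # tie-free ranks: classical shortcut applies
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
        n = 3
        assert srcc == pytest.approx(1 - 6 * d2 / (n * (n**2 - 1)), abs=1e-12)

    def test_zero_sum_rejected_for_js(self):
        with pytest.raises(ValueError):
            ss.js_divergence([0.0, 0.0], [0.5, 0.5])

    def test_js_properties(self, rng):
        for _ in range(20):
            p = rng.random(5)
            q = rng.random(5)
            js = ss.js_divergence(p, q)
            assert 0 <= js <= math.log(2) + 1e-12
            assert js == pytest.approx(ss.js_divergence(q, p), abs=1e-12)
        assert ss.js_divergence(p, 3.0 * p) == pytest.approx(0.0, abs=1e-12)


class TestAccuracyScore:
    def _scores(self, table):
        methods = list(table)
        return ss.MethodScores(
            pcc={m: table[m][0] for m in methods},
            srcc={m: table[m][1] for m in methods},
            rmse={m: table[m][2] for m in methods},
            js={m: table[m][3] for m in methods},
        )

    def test_best_everywhere_scores_one(self):
        table = {f"m{i}": (0.5 - 0.01 * i, 0.5 - 0.01 * i, 0.1 + 0.01 * i, 0.1 + 0.01 * i)
                 for i in range(8)}
        out = ss.accuracy_score(self._scores(table))
        assert out["m0"] == pytest.approx(1.0)

    def test_single_method_scores_one(self):
        out = ss.accuracy_score(self._scores({"only": (0.9, 0.8, 0.1, 0.05)}))
        assert out["only"] == pytest.approx(1.0)

    @pytest.mark.parametrize("m", [2, 3, 4, 5])
    def test_worst_everywhere_scores_inverse_m(self, m):
        table = {f"m{i}": (1.0 - 0.1 * i, 1.0 - 0.1 * i, 0.1 * i, 0.1 * i)
                 for i in range(m)}
        out = ss.accuracy_score(self._scores(table))
        assert out[f"m{m-1}"] == pytest.approx(1.0 / m)

    def test_invariant_to_monotone_rescaling(self, rng):
        vals = {f"m{i}": tuple(rng.random(4)) for i in range(5)}
        base = ss.accuracy_score(self._scores(vals))
        rescaled = {k: (math.exp(v[0]), v[1], v[2] ** 3, v[3]) for k, v in vals.items()}
        out = ss.accuracy_score(self._scores(rescaled))
        for k in vals:
            assert out[k] == pytest.approx(base[k], abs=1e-12)


# ---------------------------------------------------------------------------
# clustering agreement
# ---------------------------------------------------------------------------


def oracle_pair_counting(truth, pred):
    """Brute-force over all item pairs."""
    n = len(truth)
    tp = fp = fn = tn = 0
    for i, j in itertools.combinations(range(n), 2):
        same_t = truth[i] == truth[j]
        same_p = pred[i] == pred[j]
        if same_t and same_p:
            tp += 1
        elif not same_t and same_p:
            fp += 1
        elif same_t and not same_p:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


class TestLabelings:
    def test_identical_up_to_relabeling(self):
        truth = ["A", "A", "B", "B", "C"]
        pred = ["x", "x", "y", "y", "z"]
        assert ss.compare_labelings(truth, pred) == pytest.approx((1, 1, 1, 1))

    def test_single_cluster_homogeneity_zero(self):
        ari, nmi, hs, fmi = ss.compare_labelings(["A", "A", "B", "B"], [1, 1, 1, 1])
        assert hs == pytest.approx(0.0)

    def test_matches_pair_counting_and_sklearn(self):
        truth = ["A", "A", "B", "B"]
        pred = ["1", "1", "1", "2"]
        ari, nmi, hs, fmi = ss.compare_labelings(truth, pred)
        tp, fp, fn, tn = oracle_pair_counting(truth, pred)
        assert fmi == pytest.approx(
            math.sqrt(tp / (tp + fp) * tp / (tp + fn)), abs=1e-12
        )
        from sklearn import metrics as skm

        assert ari == pytest.approx(skm.adjusted_rand_score(truth, pred), abs=1e-12)
        assert nmi == pytest.approx(
            skm.normalized_mutual_info_score(truth, pred), abs=1e-12
        )
        assert hs == pytest.approx(skm.homogeneity_score(truth, pred), abs=1e-12)
        assert fmi == pytest.approx(skm.fowlkes_mallows_score(truth, pred), abs=1e-12)

    def test_ari_invariant_to_label_permutation(self, rng):
        truth = list(rng.integers(0, 3, 30))
        pred = list(rng.integers(0, 4, 30))
        ari1 = ss.compare_labelings(truth, pred)[0]
        remap = {0: "d", 1: "c", 2: "b", 3: "a"}
        ari2 = ss.compare_labelings(truth, [remap[p] for p in pred])[0]
        assert ari1 == pytest.approx(ari2, abs=1e-12)

    def test_homogeneity_asymmetric(self):
        truth = ["A", "A", "B", "B"]
        pred = ["1", "2", "3", "4"]
        hs_fwd = ss.compare_labelings(truth, pred)[2]
        hs_rev = ss.compare_labelings(pred, truth)[2]
        assert hs_fwd != hs_rev


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------


class TestMoransI:
    def test_constant_field_flagged(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        assert math.isnan(ss.morans_i([2, 2, 2, 2], coords, k_neighbors=2))

    def test_checkerboard_rook_neighbors(self):
        # 2x2 checkerboard with rook weights: hand evaluation gives I = -1
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        values = [1.0, 0.0, 0.0, 1.0]
        W = np.array([
            [0, 1, 1, 0],
            [1, 0, 0, 1],
            [1, 0, 0, 1],
            [0, 1, 1, 0],
        ], float)
        assert ss.morans_i(values, coords, weights=W) == pytest.approx(-1.0)

    def test_permutation_null_mean(self, rng):
        n = 30
        coords = rng.random((n, 2))
        values = rng.random(n)
        draws = []
        for _ in range(1000):
            draws.append(ss.morans_i(rng.permutation(values), coords, k_neighbors=4))
        draws = np.asarray(draws)
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - (-1 / (n - 1))) < 3 * se

    def test_per_population_wrapper(self, rng):
        assign = ss.SpatialAssignment(
            coordinates=rng.random((30, 2)),
            population=["a"] * 15 + ["b"] * 15,
            cell_ids=[f"c{i}" for i in range(30)],
        )
        out = morans_i_per_population(assign)
        assert set(out) == {"a", "b"}


class TestPccGbm:
    def _smooth_field(self, coords):
        return np.sin(3 * coords[:, 0]) + np.cos(2 * coords[:, 1])

    def test_identical_data_gives_one(self, rng):
        coords = rng.random((150, 2))
        expr = self._smooth_field(coords)
        val = ss.pcc_gbm(coords, expr, coords, expr, seed=0)
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_noise_vs_signal_uncorrelated(self, rng):
        coords = rng.random((150, 2))
        real = self._smooth_field(coords)
        vals = [
            ss.pcc_gbm(coords, real, coords, rng.standard_normal(150), seed=s)
            for s in range(5)
        ]
        assert np.mean(np.abs(vals)) < 0.2

    def test_signal_plus_small_noise_high(self, rng):
        coords = rng.random((150, 2))
        real = self._smooth_field(coords)
        sd = real.std()
        vals = [
            ss.pcc_gbm(coords, real, coords, real + 0.1 * sd * rng.standard_normal(150), seed=s)
            for s in range(5)
        ]
        assert min(vals) > 0.9
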