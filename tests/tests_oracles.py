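"""From-scratch summation oracles shared by the test modules.

Deliberately written with plain Python loops, independent of the vectorized
implementations they check.
"""

import math


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
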