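"""Independent straight-line oracles used only by the test suite.

Everything here is written with plain Python loops from the textbook
definitions, deliberately sharing no code with the package.
"""

import math


def oracle_interval_transform(values, lo, hi):
    vmin, vmax = min(values), max(values)
    if all(lo <= v <= hi for v in values):
        return [1.0] * len(values)
    m = max(lo - vmin, vmax - hi)
    out = []
    for v in values:
        if v < lo:
            out.append(1 - (lo - v) / m)
        elif v > hi:
            out.append(1 - (v - hi) / m)
        else:
            out.append(1.0)
    return out


def oracle_topsis(rows, directions, weights, normalization="vector", intervals=None):
    """Full TOPSIS by hand: returns (d_plus, d_minus, closeness, ranks).

    ``rows`` is a list of alternatives (lists of floats); ``intervals``
    optionally maps column index -> (lo, hi) for interval columns.
    """
    n = len(rows)
    m = len(rows[0])
    cols = [[rows[i][j] for i in range(n)] for j in range(m)]
    directions = list(directions)

    if intervals:
        for j, (lo, hi) in intervals.items():
            cols[j] = oracle_interval_transform(cols[j], lo, hi)
            directions[j] = "benefit"

    total_w = sum(weights)
    w = [x / total_w for x in weights]

    normed = []
    for j in range(m):
        col = cols[j]
        if normalization == "vector":
            norm = math.sqrt(sum(x * x for x in col))
            normed.append([x / norm for x in col])
        else:  # minmax
            lo, hi = min(col), max(col)
            if directions[j] == "cost":
                normed.append([(hi - x) / (hi - lo) for x in col])
                directions[j] = "benefit"
            else:
                normed.append([(x - lo) / (hi - lo) for x in col])

    weighted = [[normed[j][i] * w[j] for j in range(m)] for i in range(n)]

    pos, neg = [], []
    for j in range(m):
        col = [weighted[i][j] for i in range(n)]
        if directions[j] == "cost":
            pos.append(min(col))
            neg.append(max(col))
        else:
            pos.append(max(col))
            neg.append(min(col))

    d_plus, d_minus, closeness = [], [], []
    for i in range(n):
        dp = math.sqrt(sum((weighted[i][j] - pos[j]) ** 2 for j in range(m)))
        dm = math.sqrt(sum((weighted[i][j] - neg[j]) ** 2 for j in range(m)))
        d_plus.append(dp)
        d_minus.append(dm)
        closeness.append(dm / (dp + dm))

    order = sorted(range(n), key=lambda i: (-closeness[i], i))
    ranks = [0] * n
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return d_plus, d_minus, closeness, ranks


def oracle_entropy_weights(rows, directions):
    """Entropy weights from direction-aware min-max scaled columns."""
    n = len(rows)
    m = len(rows[0])
    e = []
    for j in range(m):
        col = [rows[i][j] for i in range(n)]
        lo, hi = min(col), max(col)
        if hi == lo:
            e.append(1.0)
            continue
        if directions[j] == "cost":
            r = [(hi - x) / (hi - lo) for x in col]
        else:
            r = [(x - lo) / (hi - lo) for x in col]
        total = sum(r)
        p = [x / total for x in r]
        ent = -sum(x * math.log(x) for x in p if x > 0) / math.log(n)
        e.append(ent)
    d = [1 - x for x in e]
    return [x / sum(d) for x in d]


def oracle_welch_t(a, b):
    """Two-sided Welch t-test p-value from the textbook formulas."""
    import statistics
    from scipy.stats import t as t_dist  # distribution function only

    na, nb = len(a), len(b)
    ma, mb = statistics.fmean(a), statistics.fmean(b)
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * t_dist.sf(abs(t), df)
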