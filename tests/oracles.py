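"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from definitions (enumeration,
closed forms, direct counting) and shares no code path with the package
implementation it checks.
"""

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Integer matrices with fixed marginals; exhaustive H2 extrema
# ---------------------------------------------------------------------------

def enumerate_matrices(row_sums, col_sums):
    """Yield every non-negative integer matrix with the given marginals."""
    row_sums = list(row_sums)
    col_sums = list(col_sums)
    n_rows = len(row_sums)

    def rows(remaining_cols, i):
        if i == n_rows - 1:
            if all(v >= 0 for v in remaining_cols) and sum(remaining_cols) == row_sums[i]:
                yield (tuple(remaining_cols),)
            return
        for row in compositions(row_sums[i], remaining_cols):
            rest = [c - r for c, r in zip(remaining_cols, row)]
            for tail in rows(rest, i + 1):
                yield (tuple(row),) + tail

    def compositions(total, caps):
        if len(caps) == 1:
            if 0 <= total <= caps[0]:
                yield (total,)
            return
        for first in range(min(total, caps[0]) + 1):
            for rest in compositions(total - first, caps[1:]):
                yield (first,) + rest

    yield from rows(col_sums, 0)


def h2_of(matrix) -> float:
    cells = [v for row in matrix for v in row if v > 0]
    m = sum(cells)
    return math.log(m) - sum(v * math.log(v) for v in cells) / m


def h2_extrema_exhaustive(row_sums, col_sums):
    """Exact (H2min, H2max) by enumerating every matrix with the marginals."""
    values = [h2_of(mat) for mat in enumerate_matrices(row_sums, col_sums)]
    return min(values), max(values)


# ---------------------------------------------------------------------------
# Exhaustive Barber-modularity maximum over all set partitions
# ---------------------------------------------------------------------------

def set_partitions(items):
    """All set partitions of a list (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [block + [first]] + partition[i + 1:]
        yield partition + [[first]]


def barber_q_of(counts, row_modules, col_modules) -> float:
    counts = np.asarray(counts, dtype=float)
    m = counts.sum()
    k = counts.sum(axis=1)
    d = counts.sum(axis=0)
    q = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            if row_modules[i] == col_modules[j]:
                q += (counts[i, j] - k[i] * d[j] / m) / m
    return q


def max_modularity_exhaustive(counts) -> float:
    """Maximum Barber Q over every set partition of all species."""
    counts = np.asarray(counts)
    n_i, n_j = counts.shape
    nodes = list(range(n_i + n_j))
    best = -np.inf
    for partition in set_partitions(nodes):
        labels = {}
        for mod_id, block in enumerate(partition):
            for node in block:
                labels[node] = mod_id
        r = [labels[i] for i in range(n_i)]
        c = [labels[n_i + j] for j in range(n_j)]
        best = max(best, barber_q_of(counts, r, c))
    return best


# ---------------------------------------------------------------------------
# Hoeffding's D oracles
# ---------------------------------------------------------------------------

def hoeffding_kernel_oracle(x, y) -> float:
    """U-statistic form: mean of the 5-tuple kernel over all ordered
    distinct 5-tuples, scaled by 30.  Exact for untied data."""
    x = list(x)
    y = list(y)
    n = len(x)

    def c(a, b):
        return 1.0 if a < b else (0.5 if a == b else 0.0)

    total = 0.0
    for i, j, k, l, mm in itertools.permutations(range(n), 5):
        t1 = c(x[j], x[i]) * c(y[j], y[i]) * c(x[k], x[i]) * c(y[k], y[i])
        t2 = c(x[j], x[i]) * c(y[j], y[i]) * c(x[k], x[i]) * c(y[l], y[i])
        t3 = c(x[j], x[i]) * c(x[k], x[i]) * c(y[l], y[i]) * c(y[mm], y[i])
        total += t1 - 2.0 * t2 + t3
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return 30.0 * total / denom


def hoeffding_direct_count(x, y) -> float:
    """Midrank-convention statistic computed with plain per-point loops
    (no numpy, no rankdata) — independent coding of the tie handling."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    r = []
    s = []
    q = []
    for i in range(n):
        below_x = sum(1.0 for j in range(n) if x[j] < x[i])
        ties_x = sum(1.0 for j in range(n) if x[j] == x[i])
        r.append(below_x + (ties_x + 1.0) / 2.0)
        below_y = sum(1.0 for j in range(n) if y[j] < y[i])
        ties_y = sum(1.0 for j in range(n) if y[j] == y[i])
        s.append(below_y + (ties_y + 1.0) / 2.0)
        qi = 1.0
        for j in range(n):
            if j == i:
                continue
            if x[j] < x[i] and y[j] < y[i]:
                qi += 1.0
            elif x[j] == x[i] and y[j] == y[i]:
                qi += 0.25
            elif (x[j] == x[i] and y[j] < y[i]) or (x[j] < x[i] and y[j] == y[i]):
                qi += 0.5
        q.append(qi)
    d1 = sum((qi - 1) * (qi - 2) for qi in q)
    d2 = sum((ri - 1) * (ri - 2) * (si - 1) * (si - 2) for ri, si in zip(r, s))
    d3 = sum((ri - 2) * (si - 2) * (qi - 1) for ri, si, qi in zip(r, s, q))
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return 30.0 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3) / denom


# ---------------------------------------------------------------------------
# Closed-form simple/quadratic OLS
# ---------------------------------------------------------------------------

def ols_stats(x, y, degree):
    """(F, r2, p) for polynomial OLS from the textbook matrix formulas."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    z = (x - x.mean()) / 100.0
    design = np.column_stack([np.ones(n)] + [z ** p for p in range(1, degree + 1)])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    rss = float(((y - fitted) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    df_model = degree
    df_resid = n - degree - 1
    r2 = 1.0 - rss / tss
    f = (tss - rss) / df_model / (rss / df_resid)
    p = float(stats.f.sf(f, df_model, df_resid))
    return f, r2, p
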