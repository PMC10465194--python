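"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive — explicit loops, closed forms and
exhaustive enumeration — and shares no code with the package internals it
checks.
"""

import itertools
import math

import numpy as np
from scipy import stats


def midranks(x):
    x = list(x)
    out = []
    for v in x:
        less = sum(1 for u in x if u < v)
        equal = sum(1 for u in x if u == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return num / den


def spearman_lag1_brute(a, b):
    """Rank-then-Pearson on (a_t, b_{t-1}) pairs with a t-approximation p."""
    x = list(a[1:])
    y = list(b[:-1])
    if len(set(x)) == 1 or len(set(y)) == 1:
        return float("nan"), float("nan")
    rho = pearson(midranks(x), midranks(y))
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    return rho, 2 * stats.t.sf(abs(t), df=n - 2)


def holm_brute(pvals):
    """Step-down formula: adj_(i) = max_{j<=i} min(1, (m-j+1) p_(j))."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj_sorted = []
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * pvals[idx]))
        adj_sorted.append(running)
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = adj_sorted[rank]
    return out


def modularity_brute(nodes, edges, assignment):
    m = len(edges)
    modules = set(assignment[n] for n in nodes)
    q = 0.0
    for c in modules:
        lc = sum(1 for u, v in edges if assignment[u] == c and assignment[v] == c)
        dc = sum(
            sum(1 for e in edges if n in e) for n in nodes if assignment[n] == c
        )
        q += lc / m - (dc / (2 * m)) ** 2
    return q


def set_partitions(items):
    """All set partitions of a list (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_partition_exhaustive(nodes, edges):
    """Maximum-modularity partition by full enumeration (small graphs)."""
    best_q, best = -np.inf, None
    for part in set_partitions(list(nodes)):
        assignment = {}
        for label, block in enumerate(part):
            for n in block:
                assignment[n] = label
        q = modularity_brute(nodes, edges, assignment)
        if q > best_q:
            best_q, best = q, assignment
    return best_q, best


def mann_kendall_brute(x):
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            s += int(x[j] > x[i]) - int(x[j] < x[i])
    ties = {}
    for v in x:
        ties[v] = ties.get(v, 0) + 1
    tie_term = sum(t * (t - 1) * (2 * t + 5) for t in ties.values())
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if var_s == 0:
        return s, var_s, 0.0, 1.0
    if s > 0:
        z = (s - 1) / math.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / math.sqrt(var_s)
    else:
        z = 0.0
    return s, var_s, z, 2 * stats.norm.sf(abs(z))


def sen_brute(x):
    slopes = []
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            slopes.append((x[j] - x[i]) / (j - i))
    return float(np.median(slopes))


def sma_aic_brute(x, max_order):
    """Grid of the one-step-ahead SMA AICs; returns (best order, aics)."""
    n = len(x)
    aics = {}
    for k in range(1, max_order + 1):
        sse = 0.0
        for t in range(k, n):
            pred = sum(x[t - k:t]) / k
            sse += (x[t] - pred) ** 2
        n_e = n - k
        aics[k] = -math.inf if sse == 0 else n_e * math.log(sse / n_e) + 4.0
    best = min(sorted(aics), key=lambda k: aics[k])
    return best, aics


def complete_linkage_two_blocks(nmi_within, nmi_between, sizes=(3, 2)):
    """Expected cluster count for a two-block similarity at cut 0.5."""
    # farthest-neighbour distance between the two blocks is 1 - nmi_between;
    # within blocks it is 1 - nmi_within
    return 2 if (1 - nmi_within) <= 0.5 < (1 - nmi_between) else None
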