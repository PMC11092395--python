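"""Brute-force reference implementations used to verify the statistics.

Everything here is deliberately naive — direct formulas, exhaustive
enumeration — and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def welch_oracle(x, y):
    """Textbook Welch t, Welch-Satterthwaite df and two-sided p."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx = sum((xi - x.mean()) ** 2 for xi in x) / (nx - 1)
    vy = sum((yi - y.mean()) ** 2 for yi in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, df, p


def bh_oracle(p):
    """Step-up Benjamini-Hochberg by the definition: sort, scale by m/rank,
    enforce monotonicity from the largest p down, cap at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return np.minimum(adj, 1.0)


def auc_oracle(pos, neg):
    """AUC by enumerating all positive/negative pairs; ties count 1/2."""
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))


def rank_sum_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments
    of the pooled (tie-free) sample."""
    x, y = list(x), list(y)
    pooled = x + y
    nx = len(x)

    def u_of(group_x):
        return sum(1.0 for a in group_x for b in pooled if b not in group_x and a > b)

    u_obs = sum(1.0 for a in x for b in y if a > b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), nx):
        gx = [pooled[i] for i in idx]
        gy = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(1.0 for a in gx for b in gy if a > b))
    us = np.asarray(us)
    p = 2.0 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return u_obs, min(p, 1.0)


def fisher_oracle(table):
    """Two-sided Fisher exact p by hypergeometric enumeration: sum the
    probabilities of all tables with the same margins whose probability
    does not exceed the observed one (with a relative tolerance)."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def logp(aa):
        return (
            math.lgamma(r1 + 1) - math.lgamma(aa + 1) - math.lgamma(r1 - aa + 1)
            + math.lgamma(n - r1 + 1) - math.lgamma(c1 - aa + 1)
            - math.lgamma(n - r1 - (c1 - aa) + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    lp_obs = logp(a)
    total = 0.0
    for aa in range(lo, hi + 1):
        lp = logp(aa)
        if lp <= lp_obs + 1e-7:
            total += math.exp(lp)
    return min(total, 1.0)


def bootstrap_auc_variance(pos, neg, n_boot, rng):
    """Nonparametric bootstrap variance of the midrank AUC."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        gt = (bp[:, None] > bn[None, :]).mean()
        eq = (bp[:, None] == bn[None, :]).mean()
        aucs[i] = gt + 0.5 * eq
    return float(np.var(aucs, ddof=1))
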