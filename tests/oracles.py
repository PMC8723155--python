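"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the code paths they verify: valid-pair counting
works directly off the scipy linkage matrix's size column, the Fisher p is a
direct hypergeometric enumeration, the Welch statistic is the closed form,
and the log-rank statistic is a hand-rolled observed/expected/variance
accumulation over pooled event times.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def count_valid_pairs_from_linkage(Z: np.ndarray, min_size: int) -> int:
    """Count splits whose two child clusters both have >= min_size members,
    reading child sizes straight from the linkage matrix."""
    n = Z.shape[0] + 1

    def size(child):
        child = int(child)
        return 1 if child < n else int(Z[child - n, 3])

    return sum(
        1 for a, b, _, _ in Z if min(size(a), size(b)) >= min_size
    )


def fisher_2x2_p(table) -> float:
    """Two-sided Fisher p for a 2x2 table by hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    rv = stats.hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    ks = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    probs = rv.pmf(ks)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())

def welch_t(x, y):
    """Closed-form Welch t, Welch-Satterthwaite df and two-sided p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def logrank_chi2(times_a, events_a, times_b, events_b) -> float:
    """Log-rank chi-square by accumulating O-E and V over pooled event times."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = int((ta >= t).sum())
        n_b = int((tb >= t).sum())
        d_a = int(((ta == t) & (ea == 1)).sum())
        d_b = int(((tb == t) & (eb == 1)).sum())
        n = n_a + n_b
        d = d_a + d_b
        if n < 2 or d == 0:
            continue
        e_a = d * n_a / n
        v = d * (n_a / n) * (n_b / n) * (n - d) / (n - 1) if n > 1 else 0.0
        o_minus_e += d_a - e_a
        var += v
    return o_minus_e**2 / var if var > 0 else 0.0


def random_tree(rng, n, n_features=5, linkage="ward"):
    """A random scipy linkage over n Gaussian samples."""
    X = rng.standard_normal((n, n_features))
    return hierarchy.linkage(pdist(X), method=linkage), X
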