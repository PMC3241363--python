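"""Independent reference implementations used to check the package.

These are deliberately written from first principles (textbook
formulas, naive loops) and never call into :mod:`metadx`.
"""

import math

import numpy as np
from scipy import stats


def pls1_one_component(X, y):
    """One-component PLS1 (NIPALS, single response) from the textbook recipe.

    X column-centered, y centered. Returns (w, t, p, c).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = X.T @ y
    w = w / math.sqrt(float(w @ w))
    t = X @ w
    p = X.T @ t / float(t @ t)
    c = float(t @ y / (t @ t))
    return w, t, p, c


def pooled_ttest(a, b):
    """Two-sample pooled-variance t statistic and two-sided p, by hand."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va = float(np.sum((a - a.mean()) ** 2)) / (na - 1)
    vb = float(np.sum((b - b.mean()) ** 2)) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def zscores_vs_reference(X, ref_rows):
    """Z-scores against a reference subset, naive per-column loop."""
    X = np.asarray(X, dtype=float)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ref = X[ref_rows, j]
        m = ref.mean()
        s = ref.std(ddof=1)
        out[:, j] = (X[:, j] - m) / s
    return out
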