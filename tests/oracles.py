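"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its definition by a different
route than the package (regex window enumeration, rank definitions, hand
step-down loops) so that implementation and check cannot share a bug.
"""

import re

import numpy as np


def nonwear_oracle(counts, zero_run_min=60, allowance_max_epochs=2,
                   allowance_cpm_max=100):
    """Enumerate nonwear windows with a regex over a symbol string.

    z = zero count, a = count in (0, allowance], x = above the allowance.  A
    nonwear window is a maximal match of ``z+(a{1,k}z+)*`` of total length >=
    the zero-run minimum; every minute inside it is nonwear.
    """
    sym = "".join(
        "z" if c == 0 else ("a" if c <= allowance_cpm_max else "x") for c in counts
    )
    pat = re.compile("z+(?:a{1,%d}z+)*" % allowance_max_epochs)
    nonwear = np.zeros(len(sym), dtype=bool)
    for m in pat.finditer(sym):
        if m.end() - m.start() >= zero_run_min:
            nonwear[m.start():m.end()] = True
    return nonwear


def midranks(v):
    """Average ranks (1-based) computed from the definition: for each value,
    the mean of the sorted positions it occupies."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    positions = np.arange(1, len(v) + 1, dtype=float)
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j < len(v) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = positions[i:j].mean()
        i = j
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation of midranks, straight from the definition."""
    return float(np.corrcoef(midranks(x), midranks(y))[0, 1])


def holm_oracle(pvalues, alpha=0.05):
    """Hand application of the sequential step-down rule."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject


def ccc_oracle(x, y):
    """CCC via the squared-difference identity 1 - E[(x-y)^2]/(sx^2+sy^2+(dx)^2),
    with 1/n moments throughout."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    msd = np.mean((x - y) ** 2)
    denom = x.var() + y.var() + (x.mean() - y.mean()) ** 2
    return float(1.0 - msd / denom)
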