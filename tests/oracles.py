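"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths of the package: percentiles by direct
rank arithmetic on a sorted copy, TFCE by per-threshold breadth-first
connected-component search, OLS by the textbook closed forms.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np


def percentile_width_oracle(values, lo=5.0, hi=95.0):
    """95th minus 5th percentile via explicit linear rank interpolation."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size

    def pct(q):
        pos = (q / 100.0) * (n - 1)
        i = int(np.floor(pos))
        frac = pos - i
        if i + 1 < n:
            return v[i] * (1 - frac) + v[i + 1] * frac
        return v[i]

    return pct(hi) - pct(lo)


def _neighbours(connectivity):
    offs = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        manh = sum(abs(x) for x in d)
        if connectivity == 6 and manh > 1:
            continue
        if connectivity == 18 and manh > 2:
            continue
        offs.append(d)
    return offs


def tfce_oracle(tmap, mask, H=2.0, E=0.5, dh=None, n_steps=100, connectivity=26):
    """Naive TFCE: per-threshold BFS component labelling, signed maps."""
    tmap = np.asarray(tmap, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(tmap)
    offs = _neighbours(connectivity)
    shape = tmap.shape
    for sign in (1.0, -1.0):
        f = np.where(mask, np.clip(sign * tmap, 0, None), 0.0)
        hmax = f.max()
        if hmax <= 0:
            continue
        step = dh if dh is not None else hmax / n_steps
        h = step
        while h <= hmax * (1 + 1e-12):
            supra = f >= h
            seen = np.zeros(shape, dtype=bool)
            for start in zip(*np.nonzero(supra)):
                if seen[start]:
                    continue
                comp = []
                q = deque([start])
                seen[start] = True
                while q:
                    v = q.popleft()
                    comp.append(v)
                    for d in offs:
                        w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                        if all(0 <= w[i] < shape[i] for i in range(3)) and supra[w] and not seen[w]:
                            seen[w] = True
                            q.append(w)
                contrib = len(comp) ** E * h**H * step
                for v in comp:
                    out[v] += sign * contrib
            h += step
    return out


def simple_regression_t(x, y):
    """Closed-form t statistic of the slope in y = a + b x + noise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xc = x - x.mean()
    b = (xc @ y) / (xc @ xc)
    a = y.mean() - b * x.mean()
    resid = y - a - b * x
    s2 = (resid @ resid) / (n - 2)
    se = np.sqrt(s2 / (xc @ xc))
    return b / se


def bh_adjust_oracle(pvals):
    """Benjamini-Hochberg step-up adjusted p-values by hand."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * n / rank_from_top)
        adj[idx] = running
    return adj
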