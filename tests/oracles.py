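"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: flood fill by
explicit BFS (vs labelled connected components), the Welch t closed form
(vs scipy's test), and full rank-assignment enumeration of the
Mann-Whitney U null (vs scipy's exact method).
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import t as t_dist


def flood_fill_count(mask: np.ndarray) -> int:
    """Count 8-connected components of a boolean mask by BFS."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    h, w = mask.shape
    count = 0
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            count += 1
            stack = [(sy, sx)]
            seen[sy, sx] = True
            while stack:
                y, x = stack.pop()
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and \
                                mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
    return count


def welch_t_closed_form(a, b) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p from first principles:
    t = (x̄ − ȳ) / sqrt(sx²/nx + sy²/ny) with Welch–Satterthwaite df."""
    x = np.asarray(a, float)
    y = np.asarray(b, float)
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = vx / nx + vy / ny
    t = (np.mean(x) - np.mean(y)) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(p)


def mann_whitney_exact_enumeration(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating every assignment of
    the pooled ranks to group a (no ties assumed)."""
    x = np.asarray(a, float)
    y = np.asarray(b, float)
    m, n = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1  # 1-based, no ties
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    total = comb(m + n, m)
    count_le = 0
    count_ge = 0
    for idx in combinations(range(m + n), m):
        u = sum(ranks[list(idx)]) - m * (m + 1) / 2
        if u <= u_obs:
            count_le += 1
        if u >= u_obs:
            count_ge += 1
    p = 2.0 * min(count_le, count_ge) / total
    return min(p, 1.0)
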