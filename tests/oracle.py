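"""Independent brute-force checkers used as test oracles.

These re-derive expected results by direct enumeration, sharing no logic
with the implementation paths they validate.
"""

from __future__ import annotations

import math
from itertools import combinations

from rlmscan.sse_matrix import HELIX, STRAND, helix_side_sign

_RANK = {"helix-IV": 0, "strand-IV": 1, "loop-IV": 2}


def brute_force_rlm(matrix, sses, structure=None):
    """Enumerate every SSE tuple and check the motif clauses one by one.

    Returns the deduplicated set of frames as tuples
    (I, II, III, IV-or-None, V, variant) of SSE indices.
    """
    found = []
    n = len(sses)
    for i1, i3, i5 in combinations(range(n), 3):
        if not (sses[i1].kind == STRAND and sses[i3].kind == STRAND and sses[i5].kind == STRAND):
            continue
        if min(len(sses[i1]), len(sses[i3]), len(sses[i5])) < 3:
            continue
        if matrix.code(i1, i3) != "P" or matrix.code(i1, i5) != "P":
            continue
        # II: the first helix after I, and it must precede III and touch I
        helices_after = [k for k in range(i1 + 1, n) if sses[k].kind == HELIX]
        if not helices_after:
            continue
        i2 = helices_after[0]
        if not (i2 < i3 and matrix.code(i1, i2) in ("C", "T")):
            continue
        sheet = [sses[i1], sses[i3], sses[i5]]
        side = helix_side_sign(sses[i2], sheet)
        between = [k for k in range(i3 + 1, i5)]
        for i4 in between:
            e4 = sses[i4]
            if e4.kind == HELIX:
                touches = matrix.code(i4, i1) in ("C", "T") or matrix.code(i4, i5) in ("C", "T")
                if touches and helix_side_sign(e4, sheet) == -side:
                    found.append((i1, i2, i3, i4, i5, "helix-IV"))
            elif e4.kind == STRAND:
                found.append((i1, i2, i3, i4, i5, "strand-IV"))
        if not between:
            ok = True
            if structure is not None:
                a, b = sses[i3], sses[i5]
                chain = structure.chain(a.chain_id)
                loop = [r for r in chain.polymer() if a.end < r.number < b.start]
                ok = len(loop) >= 2
            if ok:
                found.append((i1, i2, i3, None, i5, "loop-IV"))
    best = {}
    for frame in found:
        key = (frame[0], frame[1], frame[2], frame[4])
        rank = (_RANK[frame[5]], -1 if frame[3] is None else frame[3])
        if key not in best or rank < best[key][0]:
            best[key] = (rank, frame)
    return {frame for _, frame in best.values()}


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lg = math.lgamma

    def lpmf(k: int) -> float:
        return (
            lg(r1 + 1) - lg(k + 1) - lg(r1 - k + 1)
            + lg(r2 + 1) - lg(c1 - k + 1) - lg(r2 - c1 + k + 1)
            - (lg(n + 1) - lg(c1 + 1) - lg(n - c1 + 1))
        )

    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    p_obs = lpmf(a)
    total = 0.0
    for k in range(kmin, kmax + 1):
        lp = lpmf(k)
        if lp <= p_obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)


def ks_two_sample(x, y):
    """Two-sample KS statistic and asymptotic two-sided p, from scratch.

    D = sup |F_x - F_y| over the pooled sample; p from the Kolmogorov
    distribution survival function Q(lambda) = 2 sum_k (-1)^(k-1) exp(-2 k^2
    lambda^2) evaluated at lambda = D * sqrt(n m / (n + m)).
    """
    import numpy as np

    x = np.sort(np.asarray(x, float))
    y = np.sort(np.asarray(y, float))
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    fx = np.searchsorted(x, pooled, side="right") / n
    fy = np.searchsorted(y, pooled, side="right") / m
    d = float(np.abs(fx - fy).max())
    lam = d * math.sqrt(n * m / (n + m))
    if lam == 0.0:
        return d, 1.0
    total = 0.0
    for k in range(1, 101):
        total += (-1) ** (k - 1) * math.exp(-2.0 * k * k * lam * lam)
    return d, max(0.0, min(1.0, 2.0 * total))


def match_frames(matches):
    """Implementation matches -> comparable frame tuples."""
    out = set()
    for m in matches:
        iv = m.elements["IV"]
        out.add(
            (
                m.elements["I"].index,
                m.elements["II"].index,
                m.elements["III"].index,
                None if iv is None else iv.index,
                m.elements["V"].index,
                m.variant,
            )
        )
    return out
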