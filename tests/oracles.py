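"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: set arithmetic for
Sorensen-Dice, exhaustive pair enumeration for per-ASV sharing, an LP
over unimodal CDFs for the dip, and direct coordinate geometry for
dispersion distances.
"""

import itertools

import numpy as np
from scipy.optimize import linprog


def dice_matrix_sets(table):
    """Sorensen-Dice dissimilarities via explicit set operations."""
    ids = list(table.index)
    present = {s: {a for a in table.columns if table.loc[s, a] > 0} for s in ids}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = len(present[ids[i]] & present[ids[j]])
            b = len(present[ids[i]] - present[ids[j]])
            c = len(present[ids[j]] - present[ids[i]])
            d = 1.0 - 2.0 * a / (2.0 * a + b + c)
            out[i, j] = out[j, i] = d
    return out


def sharing_by_enumeration(table, populations, asv):
    """(s_within, s_between, n_within, n_between) by listing every pair."""
    ids = list(table.index)
    pres = (table[asv] > 0).to_dict()
    w_scores, b_scores = [], []
    for s1, s2 in itertools.combinations(ids, 2):
        p1, p2 = pres[s1], pres[s2]
        if not (p1 or p2):
            continue
        score = 1.0 if (p1 and p2) else 0.0
        if populations[s1] == populations[s2]:
            w_scores.append(score)
        else:
            b_scores.append(score)
    s_w = float(np.mean(w_scores)) if w_scores else np.nan
    s_b = float(np.mean(b_scores)) if b_scores else np.nan
    return s_w, s_b, len(w_scores), len(b_scores)


def dip_lp(values):
    """Dip via LP: smallest sup-norm band admitting a unimodal CDF.

    For each candidate mode (each distinct value in turn) fit a monotone
    CDF with convex-left / concave-right slope constraints inside the band
    [F_j - e, F_{j-1} + e], minimising e; the dip is the minimum over
    modes.
    """
    v = np.sort(np.asarray(values, float))
    n = v.size
    x, counts = np.unique(v, return_counts=True)
    k = x.size
    if k == 1:
        return 0.0
    f_hi = np.cumsum(counts) / n
    f_lo = np.concatenate([[0.0], f_hi[:-1]])
    best = np.inf
    for j in range(k):
        nv = k + 1
        c = np.zeros(nv)
        c[-1] = 1.0
        A, b = [], []
        for i in range(k):
            row = np.zeros(nv); row[i] = 1.0; row[-1] = -1.0
            A.append(row); b.append(f_lo[i])            # g_i <= F_{i-1} + e
            row = np.zeros(nv); row[i] = -1.0; row[-1] = -1.0
            A.append(row); b.append(-f_hi[i])           # g_i >= F_i - e
        for i in range(k - 1):
            row = np.zeros(nv); row[i] = 1.0; row[i + 1] = -1.0
            A.append(row); b.append(0.0)                # monotone
        for i in range(1, k - 1):
            dx1 = x[i] - x[i - 1]
            dx2 = x[i + 1] - x[i]
            row = np.zeros(nv)
            row[i - 1] = -1.0 / dx1
            row[i] = 1.0 / dx1 + 1.0 / dx2
            row[i + 1] = -1.0 / dx2
            if i + 1 <= j:        # fully left of the mode: convex
                A.append(row); b.append(0.0)
            elif i - 1 >= j:      # fully right: concave
                A.append(-row); b.append(0.0)
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(0.0, 1.0)] * k + [(0.0, None)], method="highs")
        assert res.success, res.message
        best = min(best, res.fun)
    return float(best)


def centroid_distances_2d(points, labels):
    """Distances to group centroids computed directly in the plane."""
    points = np.asarray(points, float)
    labels = np.asarray(labels)
    out = np.empty(len(points))
    for g in np.unique(labels):
        mask = labels == g
        c = points[mask].mean(axis=0)
        out[mask] = np.linalg.norm(points[mask] - c, axis=1)
    return out
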