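"""Independent brute-force reference implementations.

Deliberately written as plain Python loops over bands, sharing no code
with the package, so that agreement with the vectorized implementations
is a meaningful check.
"""

import numpy as np


def nearest_index(axis_values, wavenumber):
    return int(np.argmin([abs(v - wavenumber) for v in axis_values]))


def o_peak_height(spectrum, axis_values, center, half_window=6.0):
    best = None
    for v, a in zip(axis_values, spectrum):
        if center - half_window - 1e-9 <= v <= center + half_window + 1e-9:
            best = a if best is None else max(best, a)
    return best


def o_band_area(spectrum, axis_values, left, right):
    i0 = nearest_index(axis_values, left)
    i1 = nearest_index(axis_values, right)
    v0, v1 = axis_values[i0], axis_values[i1]
    y0, y1 = spectrum[i0], spectrum[i1]
    area = 0.0
    for i in range(i0, i1):
        va, vb = axis_values[i], axis_values[i + 1]
        ya = spectrum[i] - (y0 + (y1 - y0) * (va - v0) / (v1 - v0))
        yb = spectrum[i + 1] - (y0 + (y1 - y0) * (vb - v0) / (v1 - v0))
        area += 0.5 * (ya + yb) * (vb - va)
    return area


def o_center_of_gravity(spectrum, axis_values, left, right,
                        weight_left=None, weight_right=None):
    wl = left if weight_left is None else weight_left
    wr = right if weight_right is None else weight_right
    i0 = nearest_index(axis_values, left)
    i1 = nearest_index(axis_values, right)
    j0 = nearest_index(axis_values, wl)
    j1 = nearest_index(axis_values, wr)
    v0, v1 = axis_values[i0], axis_values[i1]
    y0, y1 = spectrum[i0], spectrum[i1]
    num = den = 0.0
    for i in range(j0, j1 + 1):
        base = y0 + (y1 - y0) * (axis_values[i] - v0) / (v1 - v0)
        w = max(spectrum[i] - base, 0.0)
        num += w * axis_values[i]
        den += w
    if den <= 1e-6:
        return float("nan")
    return num / den


def o_rank_auc(pos, neg):
    """AUC as the tie-aware pairwise-comparison count / (n1 * n0)."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def o_roc_points(scores, labels):
    """Exhaustive threshold enumeration: one (pfa, pd) per distinct score,
    predicting positive at score >= threshold, plus the (0, 0) origin."""
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    points = [(0.0, 0.0)]
    for t in sorted(set(scores), reverse=True):
        tp = sum(1 for s, l in zip(scores, labels) if l and s >= t)
        fp = sum(1 for s, l in zip(scores, labels) if not l and s >= t)
        points.append((fp / n_neg, tp / n_pos))
    return points
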