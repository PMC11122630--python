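"""Independent scalar-loop oracles used to verify losses and metrics.

Everything here is deliberately naive — explicit Python loops over
elements, all-pairs distance computations — so that it shares no code
path with the vectorised implementations it checks.
"""

import math

import numpy as np


def dice_loss_loop(probs, target_onehot, eps=1e-5):
    """Soft Dice loss by explicit per-class scalar sums."""
    probs = np.asarray(probs, dtype=float)
    target = np.asarray(target_onehot, dtype=float)
    if probs.ndim == 3:
        probs, target = probs[None], target[None]
    n, c = probs.shape[:2]
    scores = []
    for k in range(c):
        inter = p_sum = t_sum = 0.0
        for i in range(n):
            for v, t in zip(probs[i, k].ravel(), target[i, k].ravel()):
                inter += v * t
                p_sum += v
                t_sum += t
        scores.append((2.0 * inter + eps) / (p_sum + t_sum + eps))
    return 1.0 - sum(scores) / len(scores)


def ce_loss_loop(probs, target):
    probs = np.asarray(probs, dtype=float)
    target = np.asarray(target)
    if probs.ndim == 3:
        probs, target = probs[None], target[None]
    total, count = 0.0, 0
    n = probs.shape[0]
    for i in range(n):
        for r in range(probs.shape[2]):
            for cc in range(probs.shape[3]):
                total += -math.log(probs[i, target[i, r, cc], r, cc] + 1e-12)
                count += 1
    return total / count


def mse_loop(a, b):
    a, b = np.asarray(a, dtype=float).ravel(), np.asarray(b, dtype=float).ravel()
    return sum((x - y) ** 2 for x, y in zip(a, b)) / a.size


def argmax_onehot_loop(probs):
    """Per-pixel argmax one-hot, ties to the lowest class index."""
    probs = np.asarray(probs, dtype=float)
    single = probs.ndim == 3
    if single:
        probs = probs[None]
    out = np.zeros_like(probs)
    n, c, h, w = probs.shape
    for i in range(n):
        for r in range(h):
            for cc in range(w):
                best, best_v = 0, probs[i, 0, r, cc]
                for k in range(1, c):
                    if probs[i, k, r, cc] > best_v:
                        best, best_v = k, probs[i, k, r, cc]
                out[i, best, r, cc] = 1.0
    return out[0] if single else out


def surface_points_loop(mask):
    """Foreground pixels with a 4-neighbour outside the mask (border = background)."""
    mask = np.asarray(mask).astype(bool)
    pts = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                    pts.append((r, c))
                    break
    return pts


def _nearest(p, points, spacing):
    sy, sx = spacing
    return min(math.hypot((p[0] - q[0]) * sy, (p[1] - q[1]) * sx) for q in points)


def surface_distances_loop(pred, true, spacing=(1.0, 1.0)):
    """All-pairs directed nearest-neighbour surface distances, both ways."""
    sp = surface_points_loop(pred)
    st = surface_points_loop(true)
    d_pt = [_nearest(p, st, spacing) for p in sp]
    d_tp = [_nearest(q, sp, spacing) for q in st]
    return d_pt, d_tp


def hd95_loop(pred, true, spacing=(1.0, 1.0)):
    d_pt, d_tp = surface_distances_loop(pred, true, spacing)
    return float(np.percentile(np.asarray(d_pt + d_tp), 95))


def asd_loop(pred, true, spacing=(1.0, 1.0)):
    d_pt, d_tp = surface_distances_loop(pred, true, spacing)
    return (sum(d_pt) + sum(d_tp)) / (len(d_pt) + len(d_tp))


def dsc_counts_loop(pred, true):
    tp = fp = fn = 0
    for p, t in zip(np.asarray(pred).astype(bool).ravel(),
                    np.asarray(true).astype(bool).ravel()):
        tp += p and t
        fp += p and not t
        fn += t and not p
    return 2.0 * tp / (fn + 2.0 * tp + fp)
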