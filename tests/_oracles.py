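"""Independent brute-force oracles used by the oracle-equivalence tests.

Each function recomputes an operation by direct summation / scanning loops,
deliberately sharing no code with the package implementation.
"""

import numpy as np


def conv3x3_loops(x, kernels, bias):
    """Direct-summation same-padding 3x3 cross-correlation."""
    n, c, h, w = x.shape
    o = kernels.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((n, o, h, w), dtype=np.float64)
    for ni in range(n):
        for oi in range(o):
            for i in range(h):
                for j in range(w):
                    acc = 0.0
                    for ci in range(c):
                        for di in range(3):
                            for dj in range(3):
                                acc += xp[ni, ci, i + di, j + dj] * kernels[oi, ci, di, dj]
                    out[ni, oi, i, j] = acc + bias[oi]
    return out


def maxpool_loops(x):
    """Per-window scan: pooled values and flat argmax indices (row-major ties)."""
    n, c, h, w = x.shape
    ho, wo = h // 2, w // 2
    vals = np.zeros((n, c, ho, wo), dtype=x.dtype)
    idx = np.zeros((n, c, ho, wo), dtype=np.int64)
    for ni in range(n):
        for ci in range(c):
            for i in range(ho):
                for j in range(wo):
                    best = -np.inf
                    besti = -1
                    for di in range(2):
                        for dj in range(2):
                            v = x[ni, ci, 2 * i + di, 2 * j + dj]
                            if v > best:
                                best = v
                                besti = (2 * i + di) * w + (2 * j + dj)
                    vals[ni, ci, i, j] = best
                    idx[ni, ci, i, j] = besti
    return vals, idx


def unpool_loops(vals, idx, out_shape):
    """Write each pooled value at its stored flat index; zeros elsewhere."""
    n, c, h, w = out_shape
    out = np.zeros((n, c, h * w), dtype=vals.dtype)
    for ni in range(n):
        for ci in range(c):
            for v, i in zip(vals[ni, ci].ravel(), idx[ni, ci].ravel()):
                out[ni, ci, i] = v
    return out.reshape(out_shape)


def batchnorm_loops(x, gamma, beta, eps):
    """Per-channel mean/variance recomputed directly over (batch, H, W)."""
    n, c, h, w = x.shape
    out = np.zeros_like(x, dtype=np.float64)
    for ci in range(c):
        vals = x[:, ci].ravel()
        mu = vals.sum() / vals.size
        var = ((vals - mu) ** 2).sum() / vals.size
        out[:, ci] = gamma[ci] * (x[:, ci] - mu) / np.sqrt(var + eps) + beta[ci]
    return out


def confusion_loops(pred, truth, k=4):
    cm = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(truth.ravel(), pred.ravel()):
        cm[int(t), int(p)] += 1
    return cm


def mse_loops(a, b):
    m, n = a.shape
    acc = 0.0
    for i in range(m):
        for j in range(n):
            acc += (float(a[i, j]) - float(b[i, j])) ** 2
    return acc / (m * n)


def wce_loops(probs, truth, w, floor=1e-12):
    n, _, h, wd = probs.shape
    acc = 0.0
    for ni in range(n):
        for i in range(h):
            for j in range(wd):
                y = int(truth[ni, i, j])
                acc -= w[y] * np.log(max(probs[ni, y, i, j], floor))
    return acc / (n * h * wd)


def boundary_loops(mask):
    """Mask pixels with a 4-neighbour outside the mask (image border = outside)."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not mask[ni, nj]:
                    out[i, j] = True
                    break
    return out


def bf_score_loops(pred, truth, tol):
    """Exhaustive nearest-boundary-distance boundary F1."""
    bp = boundary_loops(pred)
    bt = boundary_loops(truth)
    p_pts = np.argwhere(bp)
    t_pts = np.argwhere(bt)
    if len(p_pts) == 0 and len(t_pts) == 0:
        return 1.0
    if len(p_pts) == 0 or len(t_pts) == 0:
        return 0.0

    def frac_within(src, dst):
        hits = 0
        for s in src:
            dmin = min(np.hypot(*(s - d)) for d in dst)
            if dmin <= tol:
                hits += 1
        return hits / len(src)

    precision = frac_within(p_pts, t_pts)
    recall = frac_within(t_pts, p_pts)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
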