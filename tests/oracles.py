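"""Independent brute-force and long-hand oracles used across the suite.

Everything here is deliberately naive and shares no code with the package:
hull rasterisation by exhaustive half-plane search over pixel-corner
pairs, one-way ANOVA and Pearson r spelled out from their defining sums,
and breakpoint search by a dense scan with per-candidate least squares.
"""

import numpy as np


def brute_hull_fill(mask: np.ndarray) -> np.ndarray:
    """Rasterised convex hull by exhaustive supporting-half-plane search.

    Pixels are unit squares; the hull is taken over all pixel corners.  A
    pair of corner points defines a supporting edge when every corner lies
    on one side; a grid cell belongs to the filled hull when its centre is
    not strictly outside any supporting half-plane.  O(n^3) in the corner
    count — only for small masks.
    """
    rows, cols = np.nonzero(mask)
    corners = sorted(
        {
            (r + dr, c + dc)
            for r, c in zip(rows.tolist(), cols.tolist())
            for dr in (-0.5, 0.5)
            for dc in (-0.5, 0.5)
        }
    )
    P = np.array(corners, dtype=float)
    normals, offsets = [], []
    for i in range(len(P)):
        for j in range(len(P)):
            if i == j:
                continue
            d = P[j] - P[i]
            n = np.array([-d[1], d[0]])
            s = (P - P[i]) @ n
            if np.all(s <= 1e-9):
                normals.append(n)
                offsets.append(n @ P[i])
    N = np.array(normals)
    b = np.array(offsets)
    rr, cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    centres = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    inside = (centres @ N.T - b <= 1e-9).all(axis=1)
    return inside.reshape(mask.shape)


def longhand_pearson(x, y):
    """Pearson r as the explicit covariance / variance quotient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


def longhand_anova(groups):
    """One-way ANOVA F from the defining sums of squares."""
    values = [np.asarray(v, float) for v in groups]
    allv = np.concatenate(values)
    grand = allv.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in values)
    dfb = len(values) - 1
    dfe = len(allv) - len(values)
    return float((ssb / dfb) / (ssw / dfe))


def bruteforce_breakpoint_sse(days, values, n_candidates=10_000):
    """Minimum SSE of the continuous two-phase fit over a dense scan.

    Each candidate breakpoint gets its own least-squares solve on the
    basis (1, t - x, max(t - x, 0)); nothing is shared with the package's
    profiled fitter.
    """
    t = np.asarray(days, float)
    y = np.asarray(values, float)
    best = np.inf
    for x in np.linspace(t[1], t[-2], n_candidates):
        u = t - x
        A = np.stack([np.ones_like(t), u, np.maximum(u, 0.0)], axis=1)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        r = y - A @ coef
        best = min(best, float(r @ r))
    return best


def flood_fill_components(mask: np.ndarray):
    """8-connected component sizes by explicit BFS flood fill."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    sizes = []
    H, W = mask.shape
    for r0 in range(H):
        for c0 in range(W):
            if mask[r0, c0] and not seen[r0, c0]:
                stack, size = [(r0, c0)], 0
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                sizes.append(size)
    return sorted(sizes)
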