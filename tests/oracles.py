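"""Independent brute-force reference implementations used to validate the
vectorized feature code.  Everything here is written as plain loops over
pixels/pairs/runs, deliberately sharing no code with the package."""

from __future__ import annotations

import math

import numpy as np


def glcm_bruteforce(levels, mask, offset, ng):
    """Symmetric co-occurrence probabilities by explicit pair enumeration."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    counts = np.zeros((ng, ng))
    for p in zip(*np.nonzero(mask)):
        q = tuple(pi + oi for pi, oi in zip(p, offset))
        if all(0 <= qi < s for qi, s in zip(q, mask.shape)) and mask[q]:
            counts[levels[p], levels[q]] += 1
            counts[levels[q], levels[p]] += 1
    total = counts.sum()
    return counts / total if total else counts


def haralick_bruteforce(p):
    """The 11 statistics from raw definition sums over the matrix."""
    ng = p.shape[0]
    out = {}
    out["asm"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    out["contrast"] = sum(
        (i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mx = sum(i * px[i] for i in range(ng))
    my = sum(j * py[j] for j in range(ng))
    vx = sum((i - mx) ** 2 * px[i] for i in range(ng))
    vy = sum((j - my) ** 2 * py[j] for j in range(ng))
    if vx > 0 and vy > 0:
        out["correlation"] = (
            sum(i * j * p[i, j] for i in range(ng) for j in range(ng)) - mx * my
        ) / math.sqrt(vx * vy)
    else:
        out["correlation"] = 0.0
    out["variance"] = sum(
        (i - mx) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    out["idm"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    psum = np.zeros(2 * ng - 1)
    pdiff = np.zeros(ng)
    for i in range(ng):
        for j in range(ng):
            psum[i + j] += p[i, j]
            pdiff[abs(i - j)] += p[i, j]
    out["sum_average"] = sum(k * psum[k] for k in range(2 * ng - 1))
    out["sum_variance"] = sum(
        (k - out["sum_average"]) ** 2 * psum[k] for k in range(2 * ng - 1)
    )
    ent = lambda q: -sum(v * math.log(v) for v in q if v > 0)
    out["sum_entropy"] = ent(psum)
    out["entropy"] = ent(p.ravel())
    dmean = sum(k * pdiff[k] for k in range(ng))
    out["diff_variance"] = sum((k - dmean) ** 2 * pdiff[k] for k in range(ng))
    out["diff_entropy"] = ent(pdiff)
    return out


def rlm_bruteforce(levels, mask, offset, ng):
    """Run-length counts by walking every line in the offset direction."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    runs = {}  # (level, length) -> count
    for p in zip(*np.nonzero(mask)):
        prev = tuple(pi - oi for pi, oi in zip(p, offset))
        starts = not (
            all(0 <= qi < s for qi, s in zip(prev, mask.shape))
            and mask[prev]
            and levels[prev] == levels[p]
        )
        if not starts:
            continue
        length = 1
        cur = p
        while True:
            nxt = tuple(ci + oi for ci, oi in zip(cur, offset))
            if (
                all(0 <= qi < s for qi, s in zip(nxt, mask.shape))
                and mask[nxt]
                and levels[nxt] == levels[p]
            ):
                length += 1
                cur = nxt
            else:
                break
        runs[(int(levels[p]), length)] = runs.get((int(levels[p]), length), 0) + 1
    if not runs:
        return np.zeros((ng, 1), dtype=int)
    max_len = max(l for _, l in runs)
    counts = np.zeros((ng, max_len), dtype=int)
    for (g, l), c in runs.items():
        counts[g, l - 1] = c
    return counts


SOBEL_Y = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float)
SOBEL_X = SOBEL_Y.T


def sobel_magnitude_bruteforce(image, mask):
    """|G| by direct 3x3 convolution at pixels whose 3x3 neighborhood is
    fully in-mask (matching the eroded-mask contract)."""
    img = np.asarray(image, float)
    mask = np.asarray(mask, bool)
    h, w = img.shape
    out = {}
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            if not mask[r - 1 : r + 2, c - 1 : c + 2].all():
                continue
            patch = img[r - 1 : r + 2, c - 1 : c + 2]
            gy = (patch * SOBEL_Y).sum()
            gx = (patch * SOBEL_X).sum()
            out[(r, c)] = math.hypot(gx, gy)
    return out


def hog_bruteforce(image, mask, n_bins=8, tol=1e-12):
    img = np.asarray(image, float)
    mask = np.asarray(mask, bool)
    h, w = img.shape
    hist = np.zeros(n_bins)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            if not mask[r - 1 : r + 2, c - 1 : c + 2].all():
                continue
            patch = img[r - 1 : r + 2, c - 1 : c + 2]
            gy = (patch * SOBEL_Y).sum()
            gx = (patch * SOBEL_X).sum()
            mag = math.hypot(gx, gy)
            if mag <= tol:
                continue
            ang = math.degrees(math.atan2(gy, gx)) % 360.0
            hist[min(int(ang // (360.0 / n_bins)), n_bins - 1)] += mag
    s = hist.sum()
    return hist / s if s else np.full(n_bins, 1.0 / n_bins)


def haar_level_bruteforce(arr):
    """One Haar analysis level by explicit 2x2 averaging/differencing with
    the orthonormal 1/sqrt(2) filters (edge-padded to even size)."""
    a = np.asarray(arr, float)
    h, w = a.shape
    if h % 2:
        a = np.vstack([a, a[-1:]])
    if w % 2:
        a = np.hstack([a, a[:, -1:]])
    h, w = a.shape
    ll = np.zeros((h // 2, w // 2))
    lh = np.zeros_like(ll)
    hl = np.zeros_like(ll)
    hh = np.zeros_like(ll)
    for r in range(0, h, 2):
        for c in range(0, w, 2):
            blk = a[r : r + 2, c : c + 2]
            ll[r // 2, c // 2] = blk.sum() / 2.0
            # high-pass along columns (x): left minus right
            lh[r // 2, c // 2] = (blk[:, 0].sum() - blk[:, 1].sum()) / 2.0
            # high-pass along rows (y): top minus bottom
            hl[r // 2, c // 2] = (blk[0, :].sum() - blk[1, :].sum()) / 2.0
            hh[r // 2, c // 2] = (blk[0, 0] - blk[0, 1] - blk[1, 0] + blk[1, 1]) / 2.0
    return ll, lh, hl, hh


def percentile_nearest_rank(values, p):
    """Smallest value whose empirical CDF reaches p percent."""
    v = sorted(values)
    rank = math.ceil(p / 100.0 * len(v))
    return v[max(rank, 1) - 1]


def ccc_moments_bruteforce(x, y):
    """Lin's coefficient from explicit population moment sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    vx = sum((xi - mx) ** 2 for xi in x) / n
    vy = sum((yi - my) ** 2 for yi in y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    return 2 * cov / (vx + vy + (mx - my) ** 2)


def quantize_bruteforce(image, mask, ng):
    """Per-pixel min-max quantization formula."""
    img = np.asarray(image, float)
    mask = np.asarray(mask, bool)
    vals = img[mask]
    lo, hi = vals.min(), vals.max()
    out = np.full(img.shape, -1, dtype=int)
    for p in zip(*np.nonzero(mask)):
        q = int(ng * (img[p] - lo) / (hi - lo))
        out[p] = min(q, ng - 1)
    return out


def ar_ols_bruteforce(image, mask):
    """Normal-equation solution of the causal AR fit."""
    img = np.asarray(image, float)
    mask = np.asarray(mask, bool)
    mu = img[mask].mean()
    cen = img - mu
    offs = ((0, -1), (-1, -1), (-1, 0), (-1, 1))
    rows_x, rows_y = [], []
    h, w = img.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            ok = True
            xs = []
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w and mask[rr, cc]):
                    ok = False
                    break
                xs.append(cen[rr, cc])
            if ok:
                rows_x.append(xs)
                rows_y.append(cen[r, c])
    x = np.array(rows_x)
    y = np.array(rows_y)
    theta = np.linalg.solve(x.T @ x, x.T @ y)
    resid = y - x @ theta
    return theta, float(resid.std())
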