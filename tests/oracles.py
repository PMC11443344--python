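"""Independent brute-force oracles used to validate the feature extractors.

Everything here is written as plain loops / closed forms, deliberately sharing
no code path with the package implementation.
"""

import colorsys

import numpy as np

GLCM_OFFSETS = {0.0: (0, 1), 45.0: (1, 1), 90.0: (1, 0), 135.0: (1, -1)}


def pixel_moments(gray, mask):
    """(mean, sd, cbrt third moment, smoothness) by direct pixel sums."""
    vals = [float(v) for v, m in zip(np.asarray(gray).ravel(),
                                     np.asarray(mask).ravel()) if m]
    n = len(vals)
    e = sum(vals) / n
    var = sum((v - e) ** 2 for v in vals) / n
    third = sum((v - e) ** 3 for v in vals) / n
    sd = var ** 0.5
    skew = np.cbrt(third)
    smooth = 1 - 1 / (1 + (sd / 255.0) ** 2)
    return e, sd, skew, smooth


def sobel_magnitude_loops(gray):
    """3x3 Sobel magnitude with symmetric (reflect) padding, by loops."""
    g = np.pad(np.asarray(gray, dtype=float), 1, mode="symmetric")
    h, w = np.asarray(gray).shape
    kx = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]
    ky = [[-1, -2, -1], [0, 0, 0], [1, 2, 1]]
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            gx = gy = 0.0
            for dr in range(3):
                for dc in range(3):
                    gx += kx[dr][dc] * g[r + dr, c + dc]
                    gy += ky[dr][dc] * g[r + dr, c + dc]
            out[r, c] = (gx**2 + gy**2) ** 0.5
    return out


def ggcm_counts(gray, mask, ng, ns):
    """Gray-gradient joint counts by explicit enumeration (levels 1-indexed)."""
    gray = np.asarray(gray)
    mag = sobel_magnitude_loops(gray)
    gmax = max(mag[r, c] for r, c in zip(*np.nonzero(mask)))
    counts = {}
    for r, c in zip(*np.nonzero(mask)):
        i = 1 + (int(gray[r, c]) * ng) // 256
        if gmax > 0:
            j = min(1 + int(mag[r, c] / gmax * ns), ns)
        else:
            j = 1
        counts[(i, j)] = counts.get((i, j), 0) + 1
    return counts


def ggcm_features_direct(counts, ng, ns, t):
    """The six GGCM features by direct summation over a counts dict."""
    h = np.zeros((ng + 1, ns + 1))
    for (i, j), v in counts.items():
        h[i, j] = v
    tot = h.sum()
    t1 = sum(h[i, j] for i in range(1, ng + 1) for j in range(1, t + 1)) / tot
    t2 = sum(j**2 * h[i, j] for i in range(1, ng + 1)
             for j in range(t + 1, ns + 1)) / tot
    t3 = sum(sum(h[i, j] for j in range(1, ns + 1)) ** 2
             for i in range(1, ng + 1)) / tot
    t4 = sum(sum(h[i, j] for i in range(1, ng + 1)) ** 2
             for j in range(1, ns + 1)) / tot
    pj = [sum(h[i, j] for i in range(1, ng + 1)) / tot for j in range(ns + 1)]
    mu = sum(j * pj[j] for j in range(1, ns + 1))
    sd = sum((j - mu) ** 2 * pj[j] for j in range(1, ns + 1)) ** 0.5
    return t1, t2, t3, t4, mu, sd


def glcm_matrix(gray, mask, levels, distance, angle_deg):
    """Symmetric masked co-occurrence by pair enumeration, normalized."""
    gray = np.asarray(gray)
    dr, dc = GLCM_OFFSETS[angle_deg]
    dr, dc = dr * distance, dc * distance
    h, w = gray.shape
    q = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                i = (int(gray[r, c]) * levels) // 256
                j = (int(gray[r2, c2]) * levels) // 256
                q[i, j] += 1
                q[j, i] += 1
    return q / q.sum()


def glcm_features_direct(q):
    """(ASM, ENT, INE, COR) by direct summation over one normalized matrix."""
    levels = q.shape[0]
    asm = sum(q[i, j] ** 2 for i in range(levels) for j in range(levels))
    ent = -sum(q[i, j] * np.log(q[i, j]) for i in range(levels)
               for j in range(levels) if q[i, j] > 0)
    ine = sum((i - j) ** 2 * q[i, j] for i in range(levels) for j in range(levels))
    px = q.sum(axis=1)
    py = q.sum(axis=0)
    mx = sum(i * px[i] for i in range(levels))
    my = sum(j * py[j] for j in range(levels))
    sx = sum((i - mx) ** 2 * px[i] for i in range(levels)) ** 0.5
    sy = sum((j - my) ** 2 * py[j] for j in range(levels)) ** 0.5
    cor = 0.0 if sx * sy == 0 else (
        sum(i * j * q[i, j] for i in range(levels) for j in range(levels)) - mx * my
    ) / (sx * sy)
    return asm, ent, ine, cor


def average_ranks(x):
    """Average (midrank) ranking, 1-based, by sorting and tie-group averaging."""
    order = sorted(range(len(x)), key=lambda k: x[k])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_via_ranks(x, y):
    """Pearson correlation of average ranks (tie-corrected Spearman)."""
    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    return float(np.corrcoef(rx, ry)[0, 1])


def hsv_means(rgb01, mask):
    """Per-channel HSV means over the mask via colorsys (per pixel)."""
    vals = [colorsys.rgb_to_hsv(*rgb01[r, c])
            for r, c in zip(*np.nonzero(mask))]
    return np.mean(vals, axis=0)


def lab_means(rgb01, mask):
    """Per-channel CIELAB (D65) means over the mask, textbook conversion."""
    def inv_gamma(u):
        return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4

    m = [[0.412453, 0.357580, 0.180423],
         [0.212671, 0.715160, 0.072169],
         [0.019334, 0.119193, 0.950227]]
    white = (0.95047, 1.0, 1.08883)

    def f(t):
        return np.cbrt(t) if t > (6 / 29) ** 3 else t / (3 * (6 / 29) ** 2) + 4 / 29

    out = []
    for r, c in zip(*np.nonzero(mask)):
        lin = [inv_gamma(float(u)) for u in rgb01[r, c]]
        xyz = [sum(m[i][k] * lin[k] for k in range(3)) for i in range(3)]
        fx, fy, fz = (f(xyz[i] / white[i]) for i in range(3))
        out.append((116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)))
    return np.mean(out, axis=0)
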