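"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately use plain loops and exhaustive search, never the package's
own vectorized code paths.
"""

import numpy as np


def oracle_moments(values):
    """Direct loop evaluation of the four printed color-moment formulas."""
    n = len(values)
    mu = sum(values) / n
    m2 = sum((v - mu) ** 2 for v in values) / n
    m3 = sum((v - mu) ** 3 for v in values) / n
    m4 = sum((v - mu) ** 4 for v in values) / n
    skew = np.sign(m3) * abs(m3) ** (1 / 3)
    return mu, m2**0.5, skew, m4**0.25 - 3.0


def oracle_glcm(gray, mask, d, theta, levels):
    """Pair enumeration with symmetric accumulation."""
    offs = {0: (0, d), 45: (-d, d), 90: (-d, 0), 135: (-d, -d)}[theta]
    q = (gray.astype(int) * levels) // 256
    h, w = gray.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + offs[0], c + offs[1]
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[q[r, c], q[r2, c2]] += 1
                counts[q[r2, c2], q[r, c]] += 1
    return counts / counts.sum()


def oracle_texture(f):
    """Double-loop evaluation of the seven texture statistics."""
    n = f.shape[0]
    hom = con = dis = ent = ene = auto = 0.0
    for i in range(n):
        for j in range(n):
            p = f[i, j]
            hom += p / (1 + (i - j) ** 2)
            con += (i - j) ** 2 * p
            dis += abs(i - j) * p
            if p > 0:
                ent -= p * np.log10(p)
            ene += p * p
            auto += i * j * p
    pi = f.sum(axis=1)
    mu = sum(i * pi[i] for i in range(n))
    sd = sum((i - mu) ** 2 * pi[i] for i in range(n)) ** 0.5
    if sd > 0:
        cor = sum(
            (i - mu) * (j - mu) * f[i, j] for i in range(n) for j in range(n)
        ) / sd**2
    else:
        cor = 1.0
    return hom, con, dis, ent, ene, cor, auto


def brute_force_otsu(gray):
    """Exhaustive search over all 255 splits for the between-class maximizer."""
    g = gray.ravel().astype(float)
    best_t, best_v = 0, -1.0
    for t in range(255):
        lo = g[g <= t]
        hi = g[g > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        v = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-9:
            best_v, best_t = v, t
    return best_t
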