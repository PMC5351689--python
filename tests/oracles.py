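"""Independent brute-force oracles for the texture and ROC machinery.

Everything here is written as plain enumeration (explicit Python loops,
flood fills, all-pairs counting) so it shares no code path with the
package implementation it checks.
"""

from itertools import product

import numpy as np


def glcm_oracle(levels, ng, offsets, symmetric=True):
    """Co-occurrence matrix by explicit enumeration of all voxel pairs."""
    levels = np.asarray(levels)
    counts = np.zeros((ng, ng), dtype=float)
    for idx in product(*[range(s) for s in levels.shape]):
        a = levels[idx]
        if a == 0:
            continue
        for off in offsets:
            nbr = tuple(i + o for i, o in zip(idx, off))
            if any(k < 0 or k >= s for k, s in zip(nbr, levels.shape)):
                continue
            b = levels[nbr]
            if b == 0:
                continue
            counts[a - 1, b - 1] += 1
            if symmetric:
                counts[b - 1, a - 1] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def glcm_features_oracle(p):
    """Second-order features by direct double loops."""
    ng = p.shape[0]
    entropy = homogeneity = contrast = 0.0
    mu_i = mu_j = 0.0
    for i in range(ng):
        for j in range(ng):
            q = p[i, j]
            if q > 0:
                entropy -= q * np.log2(q)
            homogeneity += q / (1 + abs(i - j))
            contrast += (i - j) ** 2 * q
            mu_i += (i + 1) * q
            mu_j += (j + 1) * q
    var_i = var_j = num = 0.0
    for i in range(ng):
        for j in range(ng):
            q = p[i, j]
            var_i += (i + 1 - mu_i) ** 2 * q
            var_j += (j + 1 - mu_j) ** 2 * q
            num += (i + 1 - mu_i) * (j + 1 - mu_j) * q
    corr = num / np.sqrt(var_i * var_j) if var_i > 0 and var_j > 0 else 0.0
    return dict(entropy=entropy, homogeneity=homogeneity, correlation=corr, contrast=contrast)


def glszm_oracle(levels, ng):
    """Size-zone matrix via breadth-first flood fill, full connectivity."""
    levels = np.asarray(levels)
    ndim = levels.ndim
    nbrs = [off for off in product((-1, 0, 1), repeat=ndim) if any(off)]
    visited = np.zeros(levels.shape, dtype=bool)
    zones = []  # (level, size)
    for idx in product(*[range(s) for s in levels.shape]):
        if levels[idx] == 0 or visited[idx]:
            continue
        lv = levels[idx]
        queue = [idx]
        visited[idx] = True
        size = 0
        while queue:
            cur = queue.pop()
            size += 1
            for off in nbrs:
                nbr = tuple(i + o for i, o in zip(cur, off))
                if any(k < 0 or k >= s for k, s in zip(nbr, levels.shape)):
                    continue
                if not visited[nbr] and levels[nbr] == lv:
                    visited[nbr] = True
                    queue.append(nbr)
        zones.append((int(lv), size))
    smax = max(s for _, s in zones)
    Z = np.zeros((ng, smax), dtype=float)
    for lv, s in zones:
        Z[lv - 1, s - 1] += 1
    return Z


def glszm_features_oracle(Z):
    """Higher-order features by direct double sums."""
    nz = Z.sum()
    sze = size_var = glu = 0.0
    for j in range(Z.shape[0]):
        for s in range(Z.shape[1]):
            sze += Z[j, s] / (s + 1) ** 2
    for s in range(Z.shape[1]):
        size_var += Z[:, s].sum() ** 2
    for j in range(Z.shape[0]):
        glu += Z[j, :].sum() ** 2
    return dict(
        short_zone_emphasis=sze / nz,
        size_variation=size_var / nz,
        grey_level_uniformity=glu / nz,
        intensity_variation=glu / nz,
    )


def auc_oracle(values, labels):
    """AUC by all-pairs counting (ties count one half)."""
    pos = [v for v, l in zip(values, labels) if l == 1]
    neg = [v for v, l in zip(values, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def youden_oracle(values, labels, direction):
    """Best (J, cutoff, sens, spec) by exhaustive midpoint search."""
    uniq = np.unique(values)
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    pos = np.asarray([v for v, l in zip(values, labels) if l == 1])
    neg = np.asarray([v for v, l in zip(values, labels) if l == 0])
    best = None
    for c in cuts:
        if direction == ">":
            sens = (pos > c).mean()
            spec = (neg <= c).mean()
        else:
            sens = (pos <= c).mean()
            spec = (neg > c).mean()
        j = sens + spec - 1.0
        if best is None or (j, spec) > (best[0], best[3]):
            best = (j, c, sens, spec)
    return best


def km_no_censoring_oracle(times):
    """Empirical survivor function at each distinct time (no censoring)."""
    times = np.asarray(times, dtype=float)
    ts = np.unique(times)
    return ts, np.array([(times > t).mean() for t in ts])
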