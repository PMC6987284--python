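"""Independent brute-force oracles, written from the definitions alone.

These deliberately share no code with the package: texture statistics are
computed by explicit pair/run enumeration with Python loops, and the AUC by
counting concordant/tied case pairs.
"""

import numpy as np


def glcm_bruteforce(levels, mask, direction, n_levels):
    """Symmetric normalised co-occurrence matrix by explicit pair loops."""
    shape = mask.shape
    counts = np.zeros((n_levels, n_levels), dtype=float)
    dz, dy, dx = direction
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                z2, y2, x2 = z + dz, y + dy, x + dx
                if (0 <= z2 < shape[0] and 0 <= y2 < shape[1]
                        and 0 <= x2 < shape[2] and mask[z2, y2, x2]):
                    i, j = levels[z, y, x] - 1, levels[z2, y2, x2] - 1
                    counts[i, j] += 1
                    counts[j, i] += 1
    total = counts.sum()
    return None if total == 0 else counts / total


def glcm_stats_bruteforce(levels, mask, direction, n_levels):
    p = glcm_bruteforce(levels, mask, direction, n_levels)
    if p is None:
        return None
    energy = entropy = idm = inertia = shade = prom = 0.0
    mu_x = mu_y = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            mu_x += (i + 1) * p[i, j]
            mu_y += (j + 1) * p[i, j]
    for i in range(n_levels):
        for j in range(n_levels):
            v = p[i, j]
            energy += v * v
            if v > 0:
                entropy -= v * np.log2(v)
            idm += v / (1.0 + (i - j) ** 2)
            inertia += (i - j) ** 2 * v
            s = (i + 1) + (j + 1) - mu_x - mu_y
            shade += s ** 3 * v
            prom += s ** 4 * v
    return {"Energy": energy, "Entropy": entropy,
            "InverseDifferenceMoment": idm, "Inertia": inertia,
            "ClusterShade": shade, "ClusterProminence": prom}


def glrlm_bruteforce(levels, mask, direction, n_levels):
    """Run counts {(grey, length): count} by walking every maximal run."""
    shape = mask.shape
    dz, dy, dx = direction
    runs = {}
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                pz, py, px = z - dz, y - dy, x - dx
                if (0 <= pz < shape[0] and 0 <= py < shape[1]
                        and 0 <= px < shape[2] and mask[pz, py, px]
                        and levels[pz, py, px] == levels[z, y, x]):
                    continue          # not a run start
                g = int(levels[z, y, x])
                length = 1
                nz, ny, nx = z + dz, y + dy, x + dx
                while (0 <= nz < shape[0] and 0 <= ny < shape[1]
                       and 0 <= nx < shape[2] and mask[nz, ny, nx]
                       and levels[nz, ny, nx] == g):
                    length += 1
                    nz, ny, nx = nz + dz, ny + dy, nx + dx
                runs[(g, length)] = runs.get((g, length), 0) + 1
    return runs or None


def glrlm_stats_bruteforce(levels, mask, direction, n_levels):
    runs = glrlm_bruteforce(levels, mask, direction, n_levels)
    if runs is None:
        return None
    nr = sum(runs.values())
    out = {name: 0.0 for name in
           ("ShortRunEmphasis", "LongRunEmphasis", "LowGreyLevelRunEmphasis",
            "HighGreyLevelRunEmphasis", "ShortRunLowGreyLevelEmphasis",
            "ShortRunHighGreyLevelEmphasis", "LongRunLowGreyLevelEmphasis",
            "LongRunHighGreyLevelEmphasis")}
    for (g, length), c in runs.items():
        out["ShortRunEmphasis"] += c / length ** 2
        out["LongRunEmphasis"] += c * length ** 2
        out["LowGreyLevelRunEmphasis"] += c / g ** 2
        out["HighGreyLevelRunEmphasis"] += c * g ** 2
        out["ShortRunLowGreyLevelEmphasis"] += c / (g ** 2 * length ** 2)
        out["ShortRunHighGreyLevelEmphasis"] += c * g ** 2 / length ** 2
        out["LongRunLowGreyLevelEmphasis"] += c * length ** 2 / g ** 2
        out["LongRunHighGreyLevelEmphasis"] += c * g ** 2 * length ** 2
    out = {k: v / nr for k, v in out.items()}
    by_grey, by_len = {}, {}
    for (g, length), c in runs.items():
        by_grey[g] = by_grey.get(g, 0) + c
        by_len[length] = by_len.get(length, 0) + c
    out["GreyLevelNonUniformity"] = sum(v ** 2 for v in by_grey.values()) / nr
    out["RunLengthNonUniformity"] = sum(v ** 2 for v in by_len.values()) / nr
    return out


def auc_rank_bruteforce(scores, labels):
    """Tie-corrected rank AUC: (concordant + ties/2) / (n_pos * n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
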