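"""Independent brute-force radiomics oracle.

Everything here is computed with explicit Python loops straight from the
textbook definitions — no shared code with the package's vectorized
implementation — so it can serve as an independent cross-check for the
texture matrices (exact integer counts) and the full 93-feature vector.
Only suitable for tiny ROIs.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

OFFSETS_13 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
]
NEIGHBORS_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def naive_discretize(values, mask, width):
    lev = np.zeros(values.shape, dtype=int)
    inroi = [tuple(p) for p in np.argwhere(mask)]
    lo = math.floor(min(values[p] for p in inroi) / width)
    for p in inroi:
        lev[p] = math.floor(values[p] / width) - lo + 1
    return lev


def _inside(shape, p):
    return all(0 <= p[i] < shape[i] for i in range(3))


def naive_glcm_counts(lev, offset, ng):
    """Symmetric co-occurrence counts for one direction."""
    counts = np.zeros((ng, ng), dtype=int)
    for p in np.argwhere(lev > 0):
        q = tuple(p[i] + offset[i] for i in range(3))
        if _inside(lev.shape, q) and lev[q] > 0:
            counts[lev[tuple(p)] - 1, lev[q] - 1] += 1
            counts[lev[q] - 1, lev[tuple(p)] - 1] += 1
    return counts


def naive_glrlm_counts(lev, offset, ng, max_len):
    """Run-length counts for one direction, by walking every run."""
    counts = np.zeros((ng, max_len), dtype=int)
    for p in np.argwhere(lev > 0):
        p = tuple(p)
        prev = tuple(p[i] - offset[i] for i in range(3))
        if _inside(lev.shape, prev) and lev[prev] == lev[p]:
            continue  # not a run start
        length = 1
        q = tuple(p[i] + offset[i] for i in range(3))
        while _inside(lev.shape, q) and lev[q] == lev[p]:
            length += 1
            q = tuple(q[i] + offset[i] for i in range(3))
        counts[lev[p] - 1, length - 1] += 1
    return counts


def naive_glszm_zones(lev, ng):
    """(level, size) of every 26-connected equal-level zone, via BFS."""
    seen = np.zeros(lev.shape, dtype=bool)
    zones = []
    for p in np.argwhere(lev > 0):
        p = tuple(p)
        if seen[p]:
            continue
        g = lev[p]
        size = 0
        queue = deque([p])
        seen[p] = True
        while queue:
            q = queue.popleft()
            size += 1
            for off in NEIGHBORS_26:
                r = tuple(q[i] + off[i] for i in range(3))
                if _inside(lev.shape, r) and not seen[r] and lev[r] == g:
                    seen[r] = True
                    queue.append(r)
        zones.append((int(g), size))
    return zones


def naive_gldm_counts(lev, ng, alpha=0):
    """Dependence counts: column j = (number of dependent neighbors) + 1."""
    deps = []
    for p in np.argwhere(lev > 0):
        p = tuple(p)
        d = 0
        for off in NEIGHBORS_26:
            q = tuple(p[i] + off[i] for i in range(3))
            if _inside(lev.shape, q) and lev[q] > 0 and abs(int(lev[q]) - int(lev[p])) <= alpha:
                d += 1
        deps.append((int(lev[p]), d))
    nd = max(d for _, d in deps) + 1
    counts = np.zeros((ng, nd), dtype=int)
    for g, d in deps:
        counts[g - 1, d] += 1
    return counts


def naive_ngtdm(lev, ng):
    """(n_i, p_i, s_i) rows; voxels without in-ROI neighbors are excluded."""
    n = np.zeros(ng)
    s = np.zeros(ng)
    nvp = 0
    for p in np.argwhere(lev > 0):
        p = tuple(p)
        nbr = []
        for off in NEIGHBORS_26:
            q = tuple(p[i] + off[i] for i in range(3))
            if _inside(lev.shape, q) and lev[q] > 0:
                nbr.append(int(lev[q]))
        if not nbr:
            continue
        nvp += 1
        g = int(lev[p])
        n[g - 1] += 1
        s[g - 1] += abs(g - sum(nbr) / len(nbr))
    p_i = n / nvp if nvp else n
    return n, p_i, s, nvp


# ---------------------------------------------------------------------------
# naive feature formulas (explicit loops over matrix entries)


def naive_firstorder(values, mask, lev, spacing):
    x = sorted(float(values[tuple(p)]) for p in np.argwhere(mask))
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    p10, p25, p50, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 50, 75, 90))
    core = [v for v in x if p10 <= v <= p90]
    cmean = sum(core) / len(core)
    hist = {}
    for p in np.argwhere(mask):
        hist[int(lev[tuple(p)])] = hist.get(int(lev[tuple(p)]), 0) + 1
    probs = [c / n for c in hist.values()]
    vol = spacing[0] * spacing[1] * spacing[2]
    return {
        "Energy": sum(v**2 for v in x),
        "TotalEnergy": vol * sum(v**2 for v in x),
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "Minimum": x[0],
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": x[-1],
        "Mean": mean,
        "Median": p50,
        "InterquartileRange": p75 - p25,
        "Range": x[-1] - x[0],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(v - cmean) for v in core) / len(core),
        "RootMeanSquared": math.sqrt(sum(v**2 for v in x) / n),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": sum(p**2 for p in probs),
    }


def naive_glcm_features_one(counts):
    ng = counts.shape[0]
    total = counts.sum()
    p = counts / total
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    ux = sum((i + 1) * px[i] for i in range(ng))
    uy = sum((j + 1) * py[j] for j in range(ng))
    sigx = math.sqrt(sum((i + 1 - ux) ** 2 * px[i] for i in range(ng)))
    sigy = math.sqrt(sum((j + 1 - uy) ** 2 * py[j] for j in range(ng)))
    pxy_sum = {}
    pxy_diff = {}
    for i in range(ng):
        for j in range(ng):
            pxy_sum[i + j + 2] = pxy_sum.get(i + j + 2, 0.0) + p[i, j]
            pxy_diff[abs(i - j)] = pxy_diff.get(abs(i - j), 0.0) + p[i, j]
    da = sum(k * v for k, v in pxy_diff.items())
    eps = np.spacing(1.0)
    hx = -sum(v * math.log2(v) for v in px if v > 0)
    hy = -sum(v * math.log2(v) for v in py if v > 0)
    hxy = -sum(p[i, j] * math.log2(p[i, j]) for i in range(ng) for j in range(ng) if p[i, j] > 0)
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * py[j] + eps) for i in range(ng) for j in range(ng)
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0
    )
    if sigx * sigy > 0:
        corr = (
            sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng)) - ux * uy
        ) / (sigx * sigy)
    else:
        corr = 1.0
    occupied = [i for i in range(ng) if px[i] > 0]
    if len(occupied) > 1:
        m = len(occupied)
        q = np.zeros((m, m))
        for a, i in enumerate(occupied):
            for b, j in enumerate(occupied):
                q[a, b] = sum(
                    p[i, k] * p[j, k] / (px[i] * py[k]) for k in occupied if py[k] > 0
                )
        eig = sorted(np.linalg.eigvals(q).real)
        mcc = math.sqrt(max(eig[-2], 0.0))
    else:
        mcc = 1.0
    return {
        "Autocorrelation": sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng)),
        "ClusterProminence": sum(
            (i + j + 2 - ux - uy) ** 4 * p[i, j] for i in range(ng) for j in range(ng)
        ),
        "ClusterShade": sum(
            (i + j + 2 - ux - uy) ** 3 * p[i, j] for i in range(ng) for j in range(ng)
        ),
        "ClusterTendency": sum(
            (i + j + 2 - ux - uy) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
        ),
        "Contrast": sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * math.log2(v) for v in pxy_diff.values() if v > 0),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in pxy_diff.items()),
        "Id": sum(p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)),
        "Idm": sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)),
        "Idmn": sum(
            p[i, j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)
        ),
        "Idn": sum(
            p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
        ),
        "Imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2 * (hxy2 - hxy)))),
        "InverseVariance": sum(v / k**2 for k, v in pxy_diff.items() if k > 0),
        "JointAverage": ux,
        "JointEnergy": sum(p[i, j] ** 2 for i in range(ng) for j in range(ng)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": p.max(),
        "SumAverage": sum(k * v for k, v in pxy_sum.items()),
        "SumEntropy": -sum(v * math.log2(v) for v in pxy_sum.values() if v > 0),
        "SumSquares": sum(
            (i + 1 - ux) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
        ),
    }


def _naive_sizezone_style(counts, n_total):
    """The shared run/zone/dependence formula family, loop form."""
    ng, nj = counts.shape
    ns = counts.sum()
    p = counts / ns
    pg = [sum(p[i, j] for j in range(nj)) for i in range(ng)]
    pj = [sum(p[i, j] for i in range(ng)) for j in range(nj)]
    mu_i = sum((i + 1) * pg[i] for i in range(ng))
    mu_j = sum((j + 1) * pj[j] for j in range(nj))
    return {
        "small": sum(p[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(nj)),
        "large": sum(p[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(nj)),
        "gln": sum(sum(counts[i]) ** 2 for i in range(ng)) / ns,
        "glnn": sum(sum(counts[i]) ** 2 for i in range(ng)) / ns**2,
        "sn": sum(sum(counts[:, j]) ** 2 for j in range(nj)) / ns,
        "snn": sum(sum(counts[:, j]) ** 2 for j in range(nj)) / ns**2,
        "percentage": ns / n_total,
        "gl_variance": sum(pg[i] * (i + 1 - mu_i) ** 2 for i in range(ng)),
        "size_variance": sum(pj[j] * (j + 1 - mu_j) ** 2 for j in range(nj)),
        "entropy": -sum(
            p[i, j] * math.log2(p[i, j])
            for i in range(ng)
            for j in range(nj)
            if p[i, j] > 0
        ),
        "low_gl": sum(p[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(nj)),
        "high_gl": sum(p[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(nj)),
        "small_low": sum(
            p[i, j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(nj)
        ),
        "small_high": sum(
            p[i, j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(nj)
        ),
        "large_low": sum(
            p[i, j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(nj)
        ),
        "large_high": sum(
            p[i, j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(nj)
        ),
    }


def naive_ngtdm_features(n, p_i, s, nvp):
    ng = len(p_i)
    on = [i for i in range(ng) if p_i[i] > 0]
    ngp = len(on)
    coarse_den = sum(p_i[i] * s[i] for i in range(ng))
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(p_i[i] * p_i[j] * (i - j) ** 2 for i in range(ng) for j in range(ng))
            / (ngp * (ngp - 1))
            * sum(s)
            / nvp
        )
        busy_den = sum(
            abs((i + 1) * p_i[i] - (j + 1) * p_i[j]) for i in on for j in on
        )
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        complexity = (
            sum(
                abs(i - j) * (p_i[i] * s[i] + p_i[j] * s[j]) / (p_i[i] + p_i[j])
                for i in on
                for j in on
            )
            / nvp
        )
        s_sum = sum(s)
        strength = (
            sum((p_i[i] + p_i[j]) * (i - j) ** 2 for i in on for j in on) / s_sum
            if s_sum > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


_GLRLM_KEYS = {
    "ShortRunEmphasis": "small", "LongRunEmphasis": "large",
    "GrayLevelNonUniformity": "gln", "GrayLevelNonUniformityNormalized": "glnn",
    "RunLengthNonUniformity": "sn", "RunLengthNonUniformityNormalized": "snn",
    "RunPercentage": "percentage", "GrayLevelVariance": "gl_variance",
    "RunVariance": "size_variance", "RunEntropy": "entropy",
    "LowGrayLevelRunEmphasis": "low_gl", "HighGrayLevelRunEmphasis": "high_gl",
    "ShortRunLowGrayLevelEmphasis": "small_low",
    "ShortRunHighGrayLevelEmphasis": "small_high",
    "LongRunLowGrayLevelEmphasis": "large_low",
    "LongRunHighGrayLevelEmphasis": "large_high",
}
_GLSZM_KEYS = {
    "SmallAreaEmphasis": "small", "LargeAreaEmphasis": "large",
    "GrayLevelNonUniformity": "gln", "GrayLevelNonUniformityNormalized": "glnn",
    "SizeZoneNonUniformity": "sn", "SizeZoneNonUniformityNormalized": "snn",
    "ZonePercentage": "percentage", "GrayLevelVariance": "gl_variance",
    "ZoneVariance": "size_variance", "ZoneEntropy": "entropy",
    "LowGrayLevelZoneEmphasis": "low_gl", "HighGrayLevelZoneEmphasis": "high_gl",
    "SmallAreaLowGrayLevelEmphasis": "small_low",
    "SmallAreaHighGrayLevelEmphasis": "small_high",
    "LargeAreaLowGrayLevelEmphasis": "large_low",
    "LargeAreaHighGrayLevelEmphasis": "large_high",
}
_GLDM_KEYS = {
    "SmallDependenceEmphasis": "small", "LargeDependenceEmphasis": "large",
    "GrayLevelNonUniformity": "gln", "DependenceNonUniformity": "sn",
    "DependenceNonUniformityNormalized": "snn", "GrayLevelVariance": "gl_variance",
    "DependenceVariance": "size_variance", "DependenceEntropy": "entropy",
    "LowGrayLevelEmphasis": "low_gl", "HighGrayLevelEmphasis": "high_gl",
    "SmallDependenceLowGrayLevelEmphasis": "small_low",
    "SmallDependenceHighGrayLevelEmphasis": "small_high",
    "LargeDependenceLowGrayLevelEmphasis": "large_low",
    "LargeDependenceHighGrayLevelEmphasis": "large_high",
}


def naive_extract_all(values, mask, bin_width, spacing=(1.0, 1.0, 1.0)):
    """Full 93-feature vector by brute force (no resampling)."""
    lev = naive_discretize(values, mask, bin_width)
    ng = int(lev.max())
    n_vox = int((lev > 0).sum())
    out = {}
    for k, v in naive_firstorder(values, mask, lev, spacing).items():
        out[f"firstorder_{k}"] = v

    per_dir = []
    for off in OFFSETS_13:
        counts = naive_glcm_counts(lev, off, ng)
        if counts.sum() > 0:
            per_dir.append(naive_glcm_features_one(counts))
    for k in per_dir[0]:
        out[f"glcm_{k}"] = sum(d[k] for d in per_dir) / len(per_dir)

    gldm = _naive_sizezone_style(naive_gldm_counts(lev, ng), n_vox)
    for name, key in _GLDM_KEYS.items():
        out[f"gldm_{name}"] = gldm[key]

    max_len = max(lev.shape) * 2
    per_dir_rl = []
    for off in OFFSETS_13:
        counts = naive_glrlm_counts(lev, off, ng, max_len)
        if counts.sum() > 0:
            per_dir_rl.append(_naive_sizezone_style(counts, n_vox))
    for name, key in _GLRLM_KEYS.items():
        out[f"glrlm_{name}"] = sum(d[key] for d in per_dir_rl) / len(per_dir_rl)

    zones = naive_glszm_zones(lev, ng)
    max_size = max(s for _, s in zones)
    zcounts = np.zeros((ng, max_size), dtype=int)
    for g, s in zones:
        zcounts[g - 1, s - 1] += 1
    glszm = _naive_sizezone_style(zcounts, n_vox)
    for name, key in _GLSZM_KEYS.items():
        out[f"glszm_{name}"] = glszm[key]

    for k, v in naive_ngtdm_features(*naive_ngtdm(lev, ng)).items():
        out[f"ngtdm_{k}"] = v
    return out
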