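"""First-order and 3D texture-matrix radiomics features (93 total).

The feature set is the classic fixed-bin-width radiomics battery: 18
first-order statistics plus five gray-level texture-matrix families computed
in 3D — co-occurrence (GLCM, 24), dependence (GLDM, 14), run length
(GLRLM, 16), size zone (GLSZM, 16) and neighboring gray-tone difference
(NGTDM, 5).  Conventions follow the widely used open-source radiomics
toolkits:

* distance 1, all 13 unique 3D direction vectors;
* GLCM and GLRLM: one matrix per direction, features computed per direction
  and averaged over directions (directions without voxel pairs are dropped);
* GLSZM (26-connected zones), GLDM (dependence within a 26-neighborhood,
  |level difference| <= alpha, default 0) and NGTDM: a single aggregated
  matrix;
* intensity features use the raw HU values; entropy/uniformity and all
  texture features use the fixed-bin-width discretization (default 50 HU).

Degenerate ROIs (uniform level) take the standard conventions: entropy 0,
uniformity 1, GLCM correlation and MCC 1, so every feature stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ExtractionError
from .image_io import DiscretizedROI, ROIMask, VoxelGrid, discretize, resample_isotropic

__all__ = [
    "DIRECTIONS",
    "FEATURE_NAMES",
    "TextureMatrix",
    "first_order_features",
    "build_glcm",
    "build_glrlm",
    "build_glszm",
    "build_gldm",
    "build_ngtdm",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "extract_all",
]

_EPS = np.spacing(1.0)

#: The 13 unique 3D offsets (one per opposite pair of the 26-neighborhood).
DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
)

_NEIGHBORS_26 = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
)


@dataclass
class TextureMatrix:
    """A gray-level texture matrix.

    For GLCM/GLRLM ``matrix`` is a stack of per-direction count matrices
    (directions first); for GLSZM/GLDM/NGTDM it is a single 2D matrix.
    ``meta`` carries the normalization constants (in-ROI voxel count, ...).
    """

    family: str
    matrix: np.ndarray
    meta: dict = field(default_factory=dict)


def _shift(arr: np.ndarray, offset: tuple[int, int, int], fill=0) -> np.ndarray:
    """Shift so that out[p] = arr[p + offset], filling vacated borders."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for o, n in zip(offset, arr.shape):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _require_roi(levels: np.ndarray) -> None:
    if not (levels > 0).any():
        raise ExtractionError("empty ROI")


# ---------------------------------------------------------------------------
# first order


def first_order_features(
    grid: VoxelGrid, mask: ROIMask, discretized: DiscretizedROI
) -> dict[str, float]:
    """The 18 first-order statistics of the in-ROI intensity distribution.

    Energy/TotalEnergy/RMS and the moments use raw HU; Entropy and
    Uniformity use the fixed-bin-width histogram of ``discretized``.
    Variance, skewness and kurtosis are population moments, and kurtosis is
    not excess-corrected (a Gaussian scores ~3).
    """
    roi = mask.values
    if not roi.any():
        raise ExtractionError("empty ROI")
    x = grid.values[roi].astype(np.float64)
    n = x.size
    voxel_volume = float(np.prod(grid.spacing))
    mean = x.mean()
    diff = x - mean
    m2 = np.mean(diff**2)
    m3 = np.mean(diff**3)
    m4 = np.mean(diff**4)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    core = x[(x >= p10) & (x <= p90)]
    counts = np.bincount(discretized.roi_levels)[1:]
    p = counts[counts > 0] / n
    return {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(voxel_volume * np.sum(x**2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(diff))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(core - core.mean()))),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Variance": float(m2),
        "Uniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# GLCM


def build_glcm(discretized: DiscretizedROI, distance: int = 1) -> TextureMatrix:
    """Per-direction symmetric co-occurrence count matrices (13 x Ng x Ng)."""
    lev = discretized.levels
    _require_roi(lev)
    ng = discretized.Ng
    stack = np.zeros((len(DIRECTIONS), ng, ng), dtype=np.int64)
    for d, off in enumerate(DIRECTIONS):
        offset = tuple(distance * o for o in off)
        nb = _shift(lev, offset)
        both = (lev > 0) & (nb > 0)
        if not both.any():
            continue
        i = lev[both] - 1
        j = nb[both] - 1
        np.add.at(stack[d], (i, j), 1)
        np.add.at(stack[d], (j, i), 1)
    return TextureMatrix("GLCM", stack, {"distance": distance})


def glcm_features(tm: TextureMatrix) -> dict[str, float]:
    """24 co-occurrence features, averaged over non-empty directions."""
    stack = tm.matrix
    ng = stack.shape[1]
    i_idx = np.arange(1, ng + 1, dtype=np.float64)
    ii = i_idx[:, None] * np.ones((1, ng))
    jj = ii.T
    per_dir: list[dict[str, float]] = []
    for counts in stack:
        tot = counts.sum()
        if tot == 0:
            continue
        p = counts / tot
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        ux = float(np.sum(i_idx * px))
        uy = float(np.sum(i_idx * py))
        sigx = float(np.sqrt(np.sum((i_idx - ux) ** 2 * px)))
        sigy = float(np.sqrt(np.sum((i_idx - uy) ** 2 * py)))
        # diagonal sums: p_{x+y}(k), k = 2..2Ng ; p_{x-y}(k), k = 0..Ng-1
        kxy = np.zeros(2 * ng - 1)
        kdiff = np.zeros(ng)
        for a in range(ng):
            for b in range(ng):
                kxy[a + b] += p[a, b]
                kdiff[abs(a - b)] += p[a, b]
        ks = np.arange(2, 2 * ng + 1, dtype=np.float64)
        kd = np.arange(ng, dtype=np.float64)
        diff_avg = float(np.sum(kd * kdiff))
        hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
        hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))
        hxy = float(-np.sum(p[p > 0] * np.log2(p[p > 0])))
        pxy = px[:, None] * py[None, :]
        hxy1 = float(-np.sum(p * np.log2(pxy + _EPS)))
        hxy2 = float(-np.sum(pxy[pxy > 0] * np.log2(pxy[pxy > 0])))
        denom = max(hx, hy)
        imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
        imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
        if sigx * sigy > 0:
            corr = (float(np.sum(ii * jj * p)) - ux * uy) / (sigx * sigy)
        else:
            corr = 1.0
        # MCC via the Q matrix restricted to occupied levels
        nz = px > 0
        if nz.sum() > 1:
            psub = p[np.ix_(nz, nz)]
            # Q[a,b] = sum_k p(a,k) p(b,k) / (px(a) py(k))
            q = (psub / px[nz][:, None]) @ (psub / py[nz][None, :]).T
            eig = np.sort(np.linalg.eigvals(q).real)
            mcc = float(np.sqrt(max(eig[-2], 0.0)))
        else:
            mcc = 1.0
        inv_var_mask = kd > 0
        per_dir.append(
            {
                "Autocorrelation": float(np.sum(ii * jj * p)),
                "ClusterProminence": float(np.sum((ii + jj - ux - uy) ** 4 * p)),
                "ClusterShade": float(np.sum((ii + jj - ux - uy) ** 3 * p)),
                "ClusterTendency": float(np.sum((ii + jj - ux - uy) ** 2 * p)),
                "Contrast": float(np.sum((ii - jj) ** 2 * p)),
                "Correlation": corr,
                "DifferenceAverage": diff_avg,
                "DifferenceEntropy": float(
                    -np.sum(kdiff[kdiff > 0] * np.log2(kdiff[kdiff > 0]))
                ),
                "DifferenceVariance": float(np.sum((kd - diff_avg) ** 2 * kdiff)),
                "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
                "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
                "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
                "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
                "Imc1": imc1,
                "Imc2": imc2,
                "InverseVariance": float(
                    np.sum(kdiff[inv_var_mask] / kd[inv_var_mask] ** 2)
                ),
                "JointAverage": ux,
                "JointEnergy": float(np.sum(p**2)),
                "JointEntropy": hxy,
                "MCC": mcc,
                "MaximumProbability": float(p.max()),
                "SumAverage": float(np.sum(ks * kxy)),
                "SumEntropy": float(-np.sum(kxy[kxy > 0] * np.log2(kxy[kxy > 0]))),
                "SumSquares": float(np.sum((ii - ux) ** 2 * p)),
            }
        )
    if not per_dir:
        # no voxel pair in any direction (e.g. single-voxel ROI)
        base = {k: 0.0 for k in _GLCM_NAMES}
        base.update({"Correlation": 1.0, "MCC": 1.0, "MaximumProbability": 1.0,
                     "JointEnergy": 1.0, "Id": 1.0, "Idm": 1.0, "Idmn": 1.0,
                     "Idn": 1.0, "JointAverage": 1.0, "SumAverage": 2.0,
                     "Autocorrelation": 1.0})
        return base
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM


def build_glrlm(discretized: DiscretizedROI) -> TextureMatrix:
    """Per-direction run-length count matrices (13 x Ng x Lmax)."""
    lev = discretized.levels
    _require_roi(lev)
    ng = discretized.Ng
    inroi = lev > 0
    lmax = int(np.ceil(np.sqrt(np.sum(np.square(lev.shape))))) + 1
    stack = np.zeros((len(DIRECTIONS), ng, lmax), dtype=np.int64)
    max_extent = max(lev.shape)
    for d, off in enumerate(DIRECTIONS):
        nb = _shift(lev, off)
        same = inroi & (nb == lev) & (nb > 0)
        # run length by backwards propagation along the direction
        runlen = np.ones_like(lev)
        for _ in range(max_extent):
            nxt = 1 + np.where(same, _shift(runlen, off), 0)
            if np.array_equal(nxt, runlen):
                break
            runlen = nxt
        prev_same = _shift(same, tuple(-o for o in off), fill=False)
        start = inroi & ~prev_same
        np.add.at(stack[d], (lev[start] - 1, runlen[start] - 1), 1)
    used = stack.sum(axis=(0, 1)) > 0
    lmax_used = int(np.max(np.nonzero(used)[0])) + 1 if used.any() else 1
    return TextureMatrix(
        "GLRLM", stack[:, :, :lmax_used], {"Np": int(inroi.sum())}
    )


def _run_zone_features(P: np.ndarray, n_total: float, prefix: dict[str, str]) -> dict:
    """Shared formulas for run-length/size-zone/dependence style matrices.

    ``P`` is a 2D count matrix (gray level x size), ``n_total`` the voxel
    count (for the percentage feature).  Returns the generic quantities;
    callers rename to family conventions via ``prefix`` mapping.
    """
    ns = P.sum()
    p = P / ns
    ng, nj = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, nj + 1, dtype=np.float64)[None, :]
    pg = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.sum(np.arange(1, ng + 1) * pg))
    mu_j = float(np.sum(np.arange(1, nj + 1) * pj))
    nz = p > 0
    out = {
        "small": float(np.sum(p / j**2)),
        "large": float(np.sum(p * j**2)),
        "gln": float(np.sum(P.sum(axis=1) ** 2) / ns),
        "glnn": float(np.sum(P.sum(axis=1) ** 2) / ns**2),
        "sn": float(np.sum(P.sum(axis=0) ** 2) / ns),
        "snn": float(np.sum(P.sum(axis=0) ** 2) / ns**2),
        "percentage": float(ns / n_total),
        "gl_variance": float(np.sum(pg * (np.arange(1, ng + 1) - mu_i) ** 2)),
        "size_variance": float(np.sum(pj * (np.arange(1, nj + 1) - mu_j) ** 2)),
        "entropy": float(-np.sum(p[nz] * np.log2(p[nz]))),
        "low_gl": float(np.sum(p / i**2)),
        "high_gl": float(np.sum(p * i**2)),
        "small_low": float(np.sum(p / (i**2 * j**2))),
        "small_high": float(np.sum(p * i**2 / j**2)),
        "large_low": float(np.sum(p * j**2 / i**2)),
        "large_high": float(np.sum(p * i**2 * j**2)),
    }
    return {name: out[key] for name, key in prefix.items()}


_GLRLM_MAP = {
    "ShortRunEmphasis": "small",
    "LongRunEmphasis": "large",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "RunLengthNonUniformity": "sn",
    "RunLengthNonUniformityNormalized": "snn",
    "RunPercentage": "percentage",
    "GrayLevelVariance": "gl_variance",
    "RunVariance": "size_variance",
    "RunEntropy": "entropy",
    "LowGrayLevelRunEmphasis": "low_gl",
    "HighGrayLevelRunEmphasis": "high_gl",
    "ShortRunLowGrayLevelEmphasis": "small_low",
    "ShortRunHighGrayLevelEmphasis": "small_high",
    "LongRunLowGrayLevelEmphasis": "large_low",
    "LongRunHighGrayLevelEmphasis": "large_high",
}


def glrlm_features(tm: TextureMatrix) -> dict[str, float]:
    """16 run-length features, averaged over directions."""
    np_total = tm.meta["Np"]
    per_dir = [
        _run_zone_features(P, np_total, _GLRLM_MAP)
        for P in tm.matrix
        if P.sum() > 0
    ]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in _GLRLM_MAP}


# ---------------------------------------------------------------------------
# GLSZM


def build_glszm(discretized: DiscretizedROI) -> TextureMatrix:
    """Size-zone count matrix: 26-connected zones of equal gray level."""
    lev = discretized.levels
    _require_roi(lev)
    ng = discretized.Ng
    structure = np.ones((3, 3, 3), dtype=int)
    zones: list[tuple[int, int]] = []
    max_size = 1
    for g in range(1, ng + 1):
        labeled, nlab = ndimage.label(lev == g, structure=structure)
        if nlab == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            zones.append((g, int(s)))
            max_size = max(max_size, int(s))
    P = np.zeros((ng, max_size), dtype=np.int64)
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return TextureMatrix("GLSZM", P, {"Np": int((lev > 0).sum())})


_GLSZM_MAP = {
    "SmallAreaEmphasis": "small",
    "LargeAreaEmphasis": "large",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "SizeZoneNonUniformity": "sn",
    "SizeZoneNonUniformityNormalized": "snn",
    "ZonePercentage": "percentage",
    "GrayLevelVariance": "gl_variance",
    "ZoneVariance": "size_variance",
    "ZoneEntropy": "entropy",
    "LowGrayLevelZoneEmphasis": "low_gl",
    "HighGrayLevelZoneEmphasis": "high_gl",
    "SmallAreaLowGrayLevelEmphasis": "small_low",
    "SmallAreaHighGrayLevelEmphasis": "small_high",
    "LargeAreaLowGrayLevelEmphasis": "large_low",
    "LargeAreaHighGrayLevelEmphasis": "large_high",
}


def glszm_features(tm: TextureMatrix) -> dict[str, float]:
    return _run_zone_features(tm.matrix, tm.meta["Np"], _GLSZM_MAP)


# ---------------------------------------------------------------------------
# GLDM


def build_gldm(
    discretized: DiscretizedROI, alpha: int = 0, distance: int = 1
) -> TextureMatrix:
    """Dependence matrix: counts of (level, 1 + #dependent 26-neighbors).

    A neighbor is dependent when it lies in the ROI and its level differs by
    at most ``alpha``.  Column index j = dependence + 1, so j >= 1.
    """
    lev = discretized.levels
    _require_roi(lev)
    ng = discretized.Ng
    inroi = lev > 0
    dep = np.zeros(lev.shape, dtype=np.int64)
    for off in _NEIGHBORS_26:
        offset = tuple(distance * o for o in off)
        nb = _shift(lev, offset)
        dep += (inroi & (nb > 0) & (np.abs(nb - lev) <= alpha)).astype(np.int64)
    nd = int(dep[inroi].max()) + 1
    P = np.zeros((ng, nd), dtype=np.int64)
    np.add.at(P, (lev[inroi] - 1, dep[inroi]), 1)
    return TextureMatrix("GLDM", P, {"Np": int(inroi.sum())})


_GLDM_MAP = {
    "SmallDependenceEmphasis": "small",
    "LargeDependenceEmphasis": "large",
    "GrayLevelNonUniformity": "gln",
    "DependenceNonUniformity": "sn",
    "DependenceNonUniformityNormalized": "snn",
    "GrayLevelVariance": "gl_variance",
    "DependenceVariance": "size_variance",
    "DependenceEntropy": "entropy",
    "LowGrayLevelEmphasis": "low_gl",
    "HighGrayLevelEmphasis": "high_gl",
    "SmallDependenceLowGrayLevelEmphasis": "small_low",
    "SmallDependenceHighGrayLevelEmphasis": "small_high",
    "LargeDependenceLowGrayLevelEmphasis": "large_low",
    "LargeDependenceHighGrayLevelEmphasis": "large_high",
}


def gldm_features(tm: TextureMatrix) -> dict[str, float]:
    return _run_zone_features(tm.matrix, tm.meta["Np"], _GLDM_MAP)


# ---------------------------------------------------------------------------
# NGTDM


def build_ngtdm(discretized: DiscretizedROI, distance: int = 1) -> TextureMatrix:
    """Neighborhood gray-tone difference vector.

    Row i holds (n_i, p_i, s_i): count and fraction of valid voxels with
    level i, and the summed absolute difference between i and the mean level
    of each such voxel's in-ROI 26-neighborhood.  Voxels with no in-ROI
    neighbor are excluded.
    """
    lev = discretized.levels
    _require_roi(lev)
    ng = discretized.Ng
    inroi = lev > 0
    nbr_sum = np.zeros(lev.shape, dtype=np.float64)
    nbr_cnt = np.zeros(lev.shape, dtype=np.int64)
    for off in _NEIGHBORS_26:
        offset = tuple(distance * o for o in off)
        nb = _shift(lev, offset)
        ok = nb > 0
        nbr_sum += np.where(ok, nb, 0)
        nbr_cnt += ok.astype(np.int64)
    valid = inroi & (nbr_cnt > 0)
    nvp = int(valid.sum())
    with np.errstate(invalid="ignore"):
        mean_nb = np.where(valid, nbr_sum / np.maximum(nbr_cnt, 1), 0.0)
    diffs = np.abs(lev - mean_nb)
    mat = np.zeros((ng, 3), dtype=np.float64)
    for g in range(1, ng + 1):
        sel = valid & (lev == g)
        mat[g - 1, 0] = sel.sum()
        mat[g - 1, 2] = diffs[sel].sum()
    mat[:, 1] = mat[:, 0] / nvp if nvp else 0.0
    return TextureMatrix("NGTDM", mat, {"Nvp": nvp})


def ngtdm_features(tm: TextureMatrix) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity, strength."""
    n_i = tm.matrix[:, 0]
    p_i = tm.matrix[:, 1]
    s_i = tm.matrix[:, 2]
    nvp = tm.meta["Nvp"]
    ng = len(p_i)
    i = np.arange(1, ng + 1, dtype=np.float64)
    ngp = int((p_i > 0).sum())
    coarse_den = float(np.sum(p_i * s_i))
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6
    if ngp > 1:
        pij = p_i[:, None] * p_i[None, :]
        dij2 = (i[:, None] - i[None, :]) ** 2
        contrast = (
            float(np.sum(pij * dij2)) / (ngp * (ngp - 1)) * float(np.sum(s_i)) / nvp
        )
        ip = i * p_i
        busy_den = float(
            np.sum(np.abs(ip[:, None] - ip[None, :])[np.ix_(p_i > 0, p_i > 0)])
        )
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        on = p_i > 0
        absdiff = np.abs(i[:, None] - i[None, :])
        num = (
            absdiff
            * (p_i[:, None] * s_i[:, None] + p_i[None, :] * s_i[None, :])
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(
                (p_i[:, None] + p_i[None, :]) > 0,
                num / (p_i[:, None] + p_i[None, :]),
                0.0,
            )
        complexity = float(frac[np.ix_(on, on)].sum()) / nvp
        s_sum = float(np.sum(s_i))
        strength = (
            float(np.sum((p_i[:, None] + p_i[None, :])[np.ix_(on, on)]
                         * dij2[np.ix_(on, on)])) / s_sum
            if s_sum > 0
            else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# assembly

_FIRSTORDER_NAMES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
]
_GLCM_NAMES = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
]

#: The 93 feature names in canonical order: 18 first-order, 24 GLCM, 14 GLDM,
#: 16 GLRLM, 16 GLSZM, 5 NGTDM.
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"firstorder_{n}" for n in _FIRSTORDER_NAMES]
    + [f"glcm_{n}" for n in _GLCM_NAMES]
    + [f"gldm_{n}" for n in _GLDM_MAP]
    + [f"glrlm_{n}" for n in _GLRLM_MAP]
    + [f"glszm_{n}" for n in _GLSZM_MAP]
    + [f"ngtdm_{n}" for n in ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]]
)


def _crop_to_roi(grid: VoxelGrid, mask: ROIMask, pad: int = 1):
    """Crop both arrays to the ROI bounding box (+1 voxel pad) for speed."""
    idx = np.nonzero(mask.values)
    slices = tuple(
        slice(max(int(a.min()) - pad, 0), min(int(a.max()) + pad + 1, n))
        for a, n in zip(idx, mask.values.shape)
    )
    g = VoxelGrid(grid.values[slices], grid.spacing, grid.origin)
    m = ROIMask(mask.values[slices], mask.spacing, mask.origin)
    return g, m


def extract_all(
    grid: VoxelGrid,
    mask: ROIMask,
    bin_width: float = 50.0,
    target: float | None = 1.0,
    sample_id: str | None = None,
) -> dict[str, float]:
    """Full 93-feature vector: resample -> discretize -> all six families.

    ``target=None`` skips isotropic resampling (features from the native
    acquisition grid).  Deterministic; raises :class:`ExtractionError` if the
    ROI is empty (possibly after resampling).
    """
    if target is not None:
        grid, mask = resample_isotropic(grid, mask, target)
    if not mask.values.any():
        raise ExtractionError(
            f"ROI empty after preprocessing (sample {sample_id or 'unknown'})"
        )
    grid, mask = _crop_to_roi(grid, mask)
    disc = discretize(grid, mask, bin_width)
    out: dict[str, float] = {}
    for name, val in first_order_features(grid, mask, disc).items():
        out[f"firstorder_{name}"] = val
    for name, val in glcm_features(build_glcm(disc)).items():
        out[f"glcm_{name}"] = val
    for name, val in gldm_features(build_gldm(disc)).items():
        out[f"gldm_{name}"] = val
    for name, val in glrlm_features(build_glrlm(disc)).items():
        out[f"glrlm_{name}"] = val
    for name, val in glszm_features(build_glszm(disc)).items():
        out[f"glszm_{name}"] = val
    for name, val in ngtdm_features(build_ngtdm(disc)).items():
        out[f"ngtdm_{name}"] = val
    return {name: out[name] for name in FEATURE_NAMES}
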