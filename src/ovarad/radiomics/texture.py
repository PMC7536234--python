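"""Grey-level texture matrices (co-occurrence, run-length, size-zone,
distance-zone) and their scalar features over a masked, discretized ROI.

All builders operate on a :class:`~ovarad.imaging_io.DiscretizedRoi` whose
levels lie in 1..Ng on the mask and 0 outside; pixels outside the mask never
pair, run or zone with inside pixels. Feature definitions follow the common
standardized texture-feature formulary (IBSI-style): matrices are symmetric
(GLCM), direction-resolved (GLRLM) or connectivity-based (GLSZM/GLDZM), and
degenerate cases (no valid pair) fall back to fixed values so feature
vectors stay rectangular.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..imaging_io import OUTSIDE, DiscretizedRoi

__all__ = [
    "DIRECTIONS",
    "cooccurrence_matrix",
    "glcm_features",
    "glcm_feature_block",
    "run_length_matrix",
    "glrlm_features",
    "size_zone_matrix",
    "glszm_features",
    "distance_zone_features",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDZM_NAMES",
]

#: direction label -> unit offset (row, col)
DIRECTIONS = {
    "0": (0, 1),
    "45": (-1, 1),
    "90": (-1, 0),
    "135": (-1, -1),
}

_EPS = np.finfo(float).tiny


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------------------
# GLCM


def cooccurrence_matrix(
    roi: DiscretizedRoi, offset: tuple[int, int], distance: int = 1
) -> np.ndarray:
    """Symmetric grey-level co-occurrence counts for one offset.

    Pairs are counted only where both pixels lie inside the mask; the
    matrix is symmetrized by also counting the reversed offset. Returns an
    Ng x Ng float array of raw counts (not normalized).
    """
    lv = roi.levels
    ng = roi.n_levels
    dr, dc = offset[0] * distance, offset[1] * distance
    h, w = lv.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = lv[r0s:r0e, c0s:c0e]
    b = lv[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    sel = (a != OUTSIDE) & (b != OUTSIDE)
    p = np.zeros((ng, ng))
    if sel.any():
        np.add.at(p, (a[sel] - 1, b[sel] - 1), 1.0)
        p += p.T.copy()
    return p


GLCM_NAMES = (
    "joint.max",
    "joint.avg",
    "joint.var",
    "joint.entr",
    "diff.avg",
    "diff.var",
    "diff.entr",
    "sum.avg",
    "sum.var",
    "sum.entr",
    "energy",
    "contrast",
    "dissimilarity",
    "inv.diff",
    "inv.diff.norm",
    "inv.diff.mom",
    "inv.diff.mom.norm",
    "inv.var",
    "corr",
    "auto.corr",
    "clust.tend",
    "clust.shade",
    "clust.prom",
    "info.corr.1",
    "info.corr.2",
)


def glcm_features(counts: np.ndarray) -> dict[str, float]:
    """The 25 co-occurrence features from a (symmetric) count matrix.

    With no valid pixel pair the fallbacks are energy = 1 and 0 elsewhere.
    """
    total = counts.sum()
    if total <= 0:
        out = {k: 0.0 for k in GLCM_NAMES}
        out["energy"] = 1.0
        return out
    p = counts / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # symmetric: px == py
    mu = float((ii * p).sum())
    var = float(((ii - mu) ** 2 * p).sum())

    d = np.abs(ii - jj)
    s = ii + jj
    # diagonal/cross-diagonal probabilities
    pdiff = np.bincount(d.ravel(), weights=p.ravel(), minlength=ng)
    psum = np.bincount(s.ravel(), weights=p.ravel(), minlength=2 * ng + 1)
    kd = np.arange(pdiff.size)
    ks = np.arange(psum.size)
    diff_avg = float((kd * pdiff).sum())
    sum_avg = float((ks * psum).sum())

    hxy = _entropy(p.ravel())
    pxy = np.outer(px, px)
    hxy1 = float(-(p[pxy > 0] * np.log2(pxy[pxy > 0])).sum()) if (pxy > 0).any() else 0.0
    hxy2 = _entropy(pxy.ravel())
    hx = _entropy(px)

    corr = 0.0
    if var > 0:
        corr = float(((ii - mu) * (jj - mu) * p).sum() / var)

    off = d > 0
    out = {
        "joint.max": float(p.max()),
        "joint.avg": mu,
        "joint.var": var,
        "joint.entr": hxy,
        "diff.avg": diff_avg,
        "diff.var": float(((kd - diff_avg) ** 2 * pdiff).sum()),
        "diff.entr": _entropy(pdiff),
        "sum.avg": sum_avg,
        "sum.var": float(((ks - sum_avg) ** 2 * psum).sum()),
        "sum.entr": _entropy(psum),
        "energy": float((p**2).sum()),
        "contrast": float((d**2 * p).sum()),
        "dissimilarity": float((d * p).sum()),
        "inv.diff": float((p / (1.0 + d)).sum()),
        "inv.diff.norm": float((p / (1.0 + d / ng)).sum()),
        "inv.diff.mom": float((p / (1.0 + d**2)).sum()),
        "inv.diff.mom.norm": float((p / (1.0 + (d / ng) ** 2)).sum()),
        "inv.var": float((p[off] / d[off] ** 2).sum()),
        "corr": corr,
        "auto.corr": float((ii * jj * p).sum()),
        "clust.tend": float(((s - 2 * mu) ** 2 * p).sum()),
        "clust.shade": float(((s - 2 * mu) ** 3 * p).sum()),
        "clust.prom": float(((s - 2 * mu) ** 4 * p).sum()),
        "info.corr.1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "info.corr.2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
    }
    return out


def glcm_feature_block(
    roi: DiscretizedRoi, distance: int = 1, variant: str = "avg"
) -> dict[str, float]:
    """Features over the 4 in-plane directions for one distance.

    ``variant="avg"`` computes features per direction and averages them;
    ``variant="merged"`` pools the directional matrices into one matrix
    first (for single-frame input this is also the 2.5D-merged variant).
    """
    mats = [cooccurrence_matrix(roi, off, distance) for off in DIRECTIONS.values()]
    if variant == "merged":
        return glcm_features(np.sum(mats, axis=0))
    if variant != "avg":
        raise ValueError(f"unknown GLCM variant {variant!r}")
    per_dir = [glcm_features(m) for m in mats]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM


def _direction_lines(lv: np.ndarray, direction: str):
    """1D scan lines of the level image along one of the four directions."""
    if direction == "0":
        return [lv[r] for r in range(lv.shape[0])]
    if direction == "90":
        return [lv[:, c] for c in range(lv.shape[1])]
    if direction == "135":  # offset (-1,-1): main diagonals
        h, w = lv.shape
        return [np.diagonal(lv, k) for k in range(-h + 1, w)]
    if direction == "45":  # offset (-1,+1): anti-diagonals
        f = np.fliplr(lv)
        h, w = f.shape
        return [np.diagonal(f, k) for k in range(-h + 1, w)]
    raise ValueError(f"unknown direction {direction!r}")


def run_length_matrix(roi: DiscretizedRoi, direction: str) -> np.ndarray:
    """Counts of maximal constant-level runs by (grey level, run length).

    Returns an Ng x Lmax integer array; column j-1 holds runs of length j.
    Background (outside-mask) pixels break runs.
    """
    lv = roi.levels
    ng = roi.n_levels
    lines = _direction_lines(lv, direction)
    # concatenate with 0 sentinels so runs never cross line boundaries
    flat = np.concatenate([np.concatenate([ln, [OUTSIDE]]) for ln in lines])
    # run-length encode
    change = np.flatnonzero(np.diff(flat) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [flat.size]])
    vals = flat[starts]
    lens = ends - starts
    keep = vals != OUTSIDE
    vals, lens = vals[keep], lens[keep]
    lmax = int(lens.max()) if lens.size else 1
    r = np.zeros((ng, lmax))
    if vals.size:
        np.add.at(r, (vals - 1, lens - 1), 1.0)
    return r


GLRLM_NAMES = (
    "sre",
    "lre",
    "lgre",
    "hgre",
    "srlge",
    "srhge",
    "lrlge",
    "lrhge",
    "glnu",
    "glnu.norm",
    "rlnu",
    "rlnu.norm",
    "r.perc",
    "gl.var",
    "rl.var",
    "rl.entr",
)


def _ngldm_style_features(mat: np.ndarray, n_pixels: int, prefix: tuple[str, ...]):
    """Shared emphasis/non-uniformity feature formulary for GLRLM/GLSZM.

    ``mat`` counts by (grey level i, size j); features are named by
    ``prefix`` = the 16 names in the family's ordering.
    """
    ns = mat.sum()
    if ns <= 0:
        return {k: 0.0 for k in prefix}
    ng, jmax = mat.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, jmax + 1)[None, :]
    gi = mat.sum(axis=1)  # per grey level
    rj = mat.sum(axis=0)  # per size
    p = mat / ns
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    jv = np.arange(1, jmax + 1)
    iv = np.arange(1, ng + 1)
    return {
        prefix[0]: float((rj / jv**2).sum() / ns),
        prefix[1]: float((rj * jv**2).sum() / ns),
        prefix[2]: float((gi / iv**2).sum() / ns),
        prefix[3]: float((gi * iv**2).sum() / ns),
        prefix[4]: float((mat / (i**2 * j**2)).sum() / ns),
        prefix[5]: float((mat * i**2 / j**2).sum() / ns),
        prefix[6]: float((mat * j**2 / i**2).sum() / ns),
        prefix[7]: float((mat * i**2 * j**2).sum() / ns),
        prefix[8]: float((gi**2).sum() / ns),
        prefix[9]: float((gi**2).sum() / ns**2),
        prefix[10]: float((rj**2).sum() / ns),
        prefix[11]: float((rj**2).sum() / ns**2),
        prefix[12]: float(ns / n_pixels),
        prefix[13]: float(((i - mu_i) ** 2 * p).sum()),
        prefix[14]: float(((j - mu_j) ** 2 * p).sum()),
        prefix[15]: _entropy(p.ravel()),
    }


def glrlm_features(roi: DiscretizedRoi, direction: str) -> dict[str, float]:
    """The 16 run-length features for one direction."""
    mat = run_length_matrix(roi, direction)
    return _ngldm_style_features(mat, int(roi.mask.sum()), GLRLM_NAMES)


# ---------------------------------------------------------------------------
# GLSZM


def size_zone_matrix(roi: DiscretizedRoi) -> np.ndarray:
    """Counts of 4-connected constant-level zones by (grey level, size)."""
    lv = roi.levels
    ng = roi.n_levels
    sizes_by_level: list[tuple[int, np.ndarray]] = []
    zmax = 1
    for g in range(1, ng + 1):
        lab, ncomp = ndimage.label(lv == g)
        if ncomp == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zmax = max(zmax, int(sizes.max()))
        sizes_by_level.append((g, sizes))
    s = np.zeros((ng, zmax))
    for g, sizes in sizes_by_level:
        np.add.at(s, (np.full(sizes.size, g - 1), sizes - 1), 1.0)
    return s


GLSZM_NAMES = (
    "sze",
    "lze",
    "lgze",
    "hgze",
    "szlge",
    "szhge",
    "lzlge",
    "lzhge",
    "glnu",
    "glnu.norm",
    "zsnu",
    "zsnu.norm",
    "z.perc",
    "gl.var",
    "zs.var",
    "z.entr",
)


def glszm_features(roi: DiscretizedRoi) -> dict[str, float]:
    """The 16 size-zone features (direction-free, 4-connectivity)."""
    mat = size_zone_matrix(roi)
    return _ngldm_style_features(mat, int(roi.mask.sum()), GLSZM_NAMES)


# ---------------------------------------------------------------------------
# GLDZM (reduced: 3 summary features)

GLDZM_NAMES = ("sde", "lde", "d.entr")


def distance_zone_features(roi: DiscretizedRoi) -> dict[str, float]:
    """Distance-zone summaries: small/large distance emphasis and entropy.

    Zone distance is the city-block distance of a zone to the ROI border
    (border pixels have distance 1; the image edge counts as border),
    minimized over the zone's pixels. Probabilities are per zone, jointly
    over (grey level, distance).
    """
    lv = roi.levels
    mask = roi.mask
    padded = np.pad(mask, 1)
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")[1:-1, 1:-1]
    counts: dict[tuple[int, int], int] = {}
    for g in range(1, roi.n_levels + 1):
        lab, ncomp = ndimage.label(lv == g)
        if ncomp == 0:
            continue
        zone_d = ndimage.minimum(dist, labels=lab, index=np.arange(1, ncomp + 1))
        for dz in np.atleast_1d(zone_d):
            key = (g, int(dz))
            counts[key] = counts.get(key, 0) + 1
    nz = sum(counts.values())
    if nz == 0:
        return {k: 0.0 for k in GLDZM_NAMES}
    p = np.array(list(counts.values()), dtype=float) / nz
    d = np.array([k[1] for k in counts], dtype=float)
    return {
        "sde": float((p / d**2).sum()),
        "lde": float((p * d**2).sum()),
        "d.entr": _entropy(p),
    }
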