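"""First-order (histogram) statistics of the normalized ROI intensities."""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..imaging_io import NormalizedRoi, discretize

__all__ = ["FIRSTORDER_NAMES", "first_order_features"]

FIRSTORDER_NAMES = (
    "mean",
    "var",
    "skew",
    "kurt",
    "median",
    "min",
    "max",
    "range",
    "p10",
    "p90",
    "iqr",
    "mad",
    "rmad",
    "medad",
    "cov",
    "qcod",
    "energy",
    "rms",
    "entropy",
    "uniformity",
)


def first_order_features(roi: NormalizedRoi, n_levels: int = 32) -> dict[str, float]:
    """The 20 first-order features of the normalized grey-level histogram.

    Computed on the [0, 255]-rescaled masked pixels; entropy and uniformity
    use the same ``n_levels``-bin discretization as the texture features.
    Degenerate (constant) ROIs get skewness = kurtosis = CoV = 0.
    """
    v = roi.masked_values.astype(np.float64)
    n = v.size
    if n < 16:
        raise ValueError(f"need >= 16 masked pixels, got {n}")
    mean = float(v.mean())
    var = float(v.var())
    p10, p25, p75, p90 = np.percentile(v, [10, 25, 75, 90])
    med = float(np.median(v))
    # robust MAD: mean absolute deviation of the 10-90 percentile core
    core = v[(v >= p10) & (v <= p90)]
    rmad = float(np.abs(core - core.mean()).mean()) if core.size else 0.0

    lv = discretize(roi, n_levels).levels[roi.mask]
    ph = np.bincount(lv, minlength=n_levels + 1)[1:] / n
    pz = ph[ph > 0]

    return {
        "mean": mean,
        "var": var,
        "skew": float(stats.skew(v)) if var > 0 else 0.0,
        "kurt": float(stats.kurtosis(v)) if var > 0 else 0.0,  # excess
        "median": med,
        "min": float(v.min()),
        "max": float(v.max()),
        "range": float(v.max() - v.min()),
        "p10": float(p10),
        "p90": float(p90),
        "iqr": float(p75 - p25),
        "mad": float(np.abs(v - mean).mean()),
        "rmad": rmad,
        "medad": float(np.abs(v - med).mean()),
        "cov": float(np.sqrt(var) / mean) if mean != 0 else 0.0,
        "qcod": float((p75 - p25) / (p75 + p25)) if (p75 + p25) != 0 else 0.0,
        "energy": float((v**2).sum()),
        "rms": float(np.sqrt((v**2).mean())),
        "entropy": float(-(pz * np.log2(pz)).sum()),
        "uniformity": float((ph**2).sum()),
    }
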