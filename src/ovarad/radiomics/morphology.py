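"""Morphological (shape) features of the ROI mask in physical units.

Lengths are reported in millimetres and areas in mm^2. Per-axis pixel
spacing scales areas exactly; length-type descriptors (perimeter, axis
lengths, Feret diameter) assume near-isotropic spacing and use the mean of
the row/col spacing — the synthetic scanners are isotropic, so this is
exact there.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from ..imaging_io import RoiMask, UltrasoundFrame

__all__ = ["MORPHOLOGY_NAMES", "morphological_features"]

MORPHOLOGY_NAMES = (
    "surface",
    "perimeter",
    "major",
    "minor",
    "ecc",
    "elongation",
    "circularity",
    "compactness",
    "convex.area",
    "solidity",
    "extent",
    "feret.max",
    "eq.diam",
    "com.shift",
)


def morphological_features(
    roi: RoiMask, spacing: tuple[float, float], frame: UltrasoundFrame | None = None
) -> dict[str, float]:
    """The 14 shape features of a binary ROI.

    ``frame`` supplies the intensities for the centre-of-mass shift (the
    distance between the intensity-weighted and geometric centroids); when
    omitted that feature is 0.
    """
    m = roi.mask.astype(np.uint8)
    sr, sc = float(spacing[0]), float(spacing[1])
    s_len = 0.5 * (sr + sc)
    props = measure.regionprops(m)[0]

    area = props.area * sr * sc
    perim = props.perimeter * s_len
    major = props.axis_major_length * s_len
    minor = props.axis_minor_length * s_len

    com_shift = 0.0
    if frame is not None:
        w = frame.pixels.astype(np.float64) * roi.mask
        if w.sum() > 0:
            rr, cc = np.nonzero(roi.mask)
            geo = np.array([rr.mean(), cc.mean()])
            wts = frame.pixels[rr, cc].astype(np.float64)
            com = np.array([np.average(rr, weights=wts), np.average(cc, weights=wts)])
            com_shift = float(np.hypot((com[0] - geo[0]) * sr, (com[1] - geo[1]) * sc))

    return {
        "surface": float(area),
        "perimeter": float(perim),
        "major": float(major),
        "minor": float(minor),
        "ecc": float(props.eccentricity),
        "elongation": float(minor / major) if major > 0 else 1.0,
        "circularity": float(4 * np.pi * area / perim**2) if perim > 0 else 0.0,
        "compactness": float(area / perim**2) if perim > 0 else 0.0,
        "convex.area": float(props.area_convex * sr * sc),
        "solidity": float(props.solidity),
        "extent": float(props.extent),
        "feret.max": float(props.feret_diameter_max * s_len),
        "eq.diam": float(2.0 * np.sqrt(area / np.pi)),
        "com.shift": com_shift,
    }
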