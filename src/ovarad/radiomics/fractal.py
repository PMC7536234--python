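"""Box-counting fractal dimension of thresholded ROI intensity sets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..imaging_io import NormalizedRoi

__all__ = ["FractalEstimate", "box_count_fd", "DEFAULT_THRESHOLDS"]

#: the 15 default binarization thresholds, as fractions of 255
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(1, 16) * 0.05, 2))


@dataclass(frozen=True)
class FractalEstimate:
    """Box-counting fit for one threshold.

    ``fd`` is minus the least-squares slope of log N(s) on log s over
    dyadic box sizes; ``degenerate`` flags fits with fewer than two usable
    scales (fd falls back to 0 there).
    """

    threshold: float
    box_sizes: tuple[int, ...]
    box_counts: tuple[int, ...]
    fd: float
    degenerate: bool = False


def _box_counts(binary: np.ndarray, sizes) -> list[int]:
    counts = []
    h, w = binary.shape
    for s in sizes:
        ph, pw = (-h) % s, (-w) % s
        b = np.pad(binary, ((0, ph), (0, pw)))
        occ = b.reshape(b.shape[0] // s, s, b.shape[1] // s, s).any(axis=(1, 3))
        counts.append(int(occ.sum()))
    return counts


def box_count_fd(roi: NormalizedRoi, threshold: float) -> FractalEstimate:
    """Estimate the box-counting dimension of {v' >= threshold*255}.

    The binary set is restricted to the mask and cropped to the mask's
    bounding box; box sizes are the powers of 2 up to the larger
    bounding-box side, with grids anchored at the bounding-box origin.
    An empty binary set yields fd = 0.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    binary = (roi.values >= threshold * 255.0) & roi.mask
    rr, cc = np.nonzero(roi.mask)
    binary = binary[rr.min() : rr.max() + 1, cc.min() : cc.max() + 1]
    if not binary.any():
        return FractalEstimate(threshold, (), (), 0.0, degenerate=True)
    max_dim = max(binary.shape)
    sizes = [1]
    while sizes[-1] * 2 <= max_dim:
        sizes.append(sizes[-1] * 2)
    counts = _box_counts(binary, sizes)
    if len(sizes) < 2:
        return FractalEstimate(threshold, tuple(sizes), tuple(counts), 0.0, True)
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return FractalEstimate(threshold, tuple(sizes), tuple(counts), float(-slope))
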