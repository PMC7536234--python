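"""Whole-catalog feature extraction for single images and cohorts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..imaging_io import (
    NormalizedRoi,
    RoiMask,
    UltrasoundFrame,
    discretize,
    normalize_roi,
    read_dicom_pair,
)
from .catalog import (
    FeatureCatalog,
    default_catalog,
    glcm_variant_prefix,
    glrlm_direction_suffix,
)
from .firstorder import first_order_features
from .fractal import DEFAULT_THRESHOLDS, box_count_fd
from .morphology import morphological_features
from .texture import (
    distance_zone_features,
    glcm_feature_block,
    glrlm_features,
    glszm_features,
)

__all__ = ["ExtractionConfig", "extract_all", "extract_table"]

META_COLUMNS = ["image_id", "patient_id", "machine", "label"]


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable knobs of the extraction pipeline.

    ``n_levels`` is the grey-level bin count shared by all texture
    matrices and the histogram entropy/uniformity features.
    """

    n_levels: int = 32
    glcm_distances: tuple[int, ...] = (1, 2)
    fractal_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def catalog(self) -> FeatureCatalog:
        return default_catalog(self.glcm_distances, self.fractal_thresholds)


def extract_all(
    frame: UltrasoundFrame,
    mask: RoiMask,
    config: ExtractionConfig | None = None,
) -> pd.Series:
    """Compute the full feature vector for one image/mask pair.

    Pipeline: rescale masked pixels to [0, 255] -> discretize to
    ``n_levels`` grey levels -> first-order, morphology, texture and
    fractal families. Returns a Series indexed exactly by the catalog
    names, every entry finite.
    """
    config = config or ExtractionConfig()
    roi: NormalizedRoi = normalize_roi(frame, mask)
    disc = discretize(roi, config.n_levels)

    values: dict[str, float] = {}
    for k, v in first_order_features(roi, config.n_levels).items():
        values[f"F_stat.{k}"] = v
    morph = morphological_features(mask, frame.pixel_spacing, frame)
    for k, v in morph.items():
        name = {"major": "L_major", "minor": "L_minor"}.get(k, f"F_morph.{k}")
        values[name] = v
    for d in config.glcm_distances:
        for variant in ("avg", "merged"):
            pre = glcm_variant_prefix(d, variant)
            for k, v in glcm_feature_block(disc, d, variant).items():
                values[f"{pre}{k}"] = v
    for direction in ("0", "45", "90", "135"):
        suf = glrlm_direction_suffix(direction)
        for k, v in glrlm_features(disc, direction).items():
            values[f"F_rlm.{k}{suf}"] = v
    for k, v in glszm_features(disc).items():
        values[f"F_szm.{k}"] = v
    for k, v in distance_zone_features(disc).items():
        values[f"F_dzm.{k}"] = v
    for t in config.fractal_thresholds:
        values[f"FD_{t:.3f}"] = box_count_fd(roi, t).fd

    cat = config.catalog()
    vec = pd.Series(values).reindex(cat.names)
    if vec.isna().any():
        missing = list(vec.index[vec.isna()])
        raise RuntimeError(f"extraction produced no value for: {missing}")
    if not np.all(np.isfinite(vec.to_numpy())):
        bad = list(vec.index[~np.isfinite(vec.to_numpy())])
        raise RuntimeError(f"non-finite feature values: {bad}")
    return vec


def extract_table(
    manifest: pd.DataFrame, config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Extract features for every manifest row (reads the DICOM pairs).

    Returns a feature table with metadata columns image_id, patient_id,
    machine, label followed by the catalog features, one row per image.
    """
    config = config or ExtractionConfig()
    rows = []
    for rec in manifest.itertuples(index=False):
        frame, mask = read_dicom_pair(rec.path_image, rec.path_mask)
        vec = extract_all(frame, mask, config)
        meta = pd.Series(
            {
                "image_id": rec.image_id,
                "patient_id": rec.patient_id,
                "machine": rec.machine,
                "label": rec.label,
            }
        )
        rows.append(pd.concat([meta, vec]))
    return pd.DataFrame(rows).reset_index(drop=True)


def extract_table_from_arrays(
    items, config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Like :func:`extract_table` but over in-memory (frame, mask, record)
    triples, e.g. straight from :func:`ovarad.synthdata.generate_cohort`."""
    config = config or ExtractionConfig()
    rows = []
    for frame, mask, record in items:
        vec = extract_all(frame, mask, config)
        meta = pd.Series({k: record[k] for k in META_COLUMNS})
        rows.append(pd.concat([meta, vec]))
    return pd.DataFrame(rows).reset_index(drop=True)
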