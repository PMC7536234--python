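"""The default 232-descriptor feature catalog.

Family composition: 20 first-order statistics, 14 morphology, 183 texture
(25 co-occurrence features x {distance 1, 2} x {directional average,
merged} = 100; 16 run-length features x 4 directions = 64; 16 size-zone;
3 distance-zone) and 15 box-counting fractal dimensions at thresholds
0.05..0.75. The catalog is an ordered registry: extraction returns exactly
these names in this order, and alternative compositions can be registered
by constructing a custom :class:`FeatureCatalog`.

Naming: co-occurrence features are ``F_cm.<name>`` for the canonical
distance-1 directional average, with ``2.5Dmerged`` and ``d2`` tags for the
other variants; run-length features are ``F_rlm.<name>`` for the 0-degree
direction with ``.45``/``.90``/``.135`` suffixes otherwise; size-zone,
distance-zone, first-order and morphology use ``F_szm.``, ``F_dzm.``,
``F_stat.`` and ``F_morph.`` prefixes (the axis lengths keep their
conventional ``L_major``/``L_minor`` labels); fractal dimensions are
``FD_<threshold>``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .firstorder import FIRSTORDER_NAMES
from .fractal import DEFAULT_THRESHOLDS
from .morphology import MORPHOLOGY_NAMES
from .texture import GLCM_NAMES, GLDZM_NAMES, GLRLM_NAMES, GLSZM_NAMES

__all__ = ["FeatureDescriptor", "FeatureCatalog", "default_catalog"]

FAMILIES = ("first_order", "morphology", "texture", "fractal")


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    family: str
    variant: str = ""


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered, name-unique registry of feature descriptors."""

    descriptors: tuple[FeatureDescriptor, ...]

    def __post_init__(self):
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def family(self, family: str) -> list[str]:
        return [d.name for d in self.descriptors if d.family == family]

    def family_counts(self) -> dict[str, int]:
        return {f: len(self.family(f)) for f in FAMILIES}

    def __len__(self) -> int:
        return len(self.descriptors)


def glcm_variant_prefix(distance: int, variant: str) -> str:
    tag = "F_cm."
    if variant == "merged":
        tag += "2.5Dmerged."
    if distance != 1:
        tag += f"d{distance}."
    return tag


def glrlm_direction_suffix(direction: str) -> str:
    return "" if direction == "0" else f".{direction}"


def default_catalog(
    glcm_distances=(1, 2), fractal_thresholds=DEFAULT_THRESHOLDS
) -> FeatureCatalog:
    """Build the default 232-feature catalog."""
    desc: list[FeatureDescriptor] = []
    for n in FIRSTORDER_NAMES:
        desc.append(FeatureDescriptor(f"F_stat.{n}", "first_order"))
    for n in MORPHOLOGY_NAMES:
        name = {"major": "L_major", "minor": "L_minor"}.get(n, f"F_morph.{n}")
        desc.append(FeatureDescriptor(name, "morphology"))
    for d in glcm_distances:
        for variant in ("avg", "merged"):
            pre = glcm_variant_prefix(d, variant)
            for n in GLCM_NAMES:
                desc.append(FeatureDescriptor(f"{pre}{n}", "texture", f"d{d}.{variant}"))
    for direction in ("0", "45", "90", "135"):
        suf = glrlm_direction_suffix(direction)
        for n in GLRLM_NAMES:
            desc.append(FeatureDescriptor(f"F_rlm.{n}{suf}", "texture", f"dir{direction}"))
    for n in GLSZM_NAMES:
        desc.append(FeatureDescriptor(f"F_szm.{n}", "texture"))
    for n in GLDZM_NAMES:
        desc.append(FeatureDescriptor(f"F_dzm.{n}", "texture"))
    for t in fractal_thresholds:
        desc.append(FeatureDescriptor(f"FD_{t:.3f}", "fractal"))
    return FeatureCatalog(tuple(desc))
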