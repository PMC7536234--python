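"""Synthetic ultrasound phantom cohorts with a plantable texture effect.

The generator emulates the kind of data the pipeline is meant for: speckled
elliptical ovary regions on 2D greyscale frames, one to four images per
patient (one per ovary side x scan plane), four scanner profiles with mild
monotone intensity differences, roughly one carrier patient in three, and a
class effect planted as extra small bright spots — i.e. the carrier class
has more short runs / small clusters of high grey-level intensity, which is
the texture signature the downstream screen and classifiers should recover.

The model is deliberately the simplest texture-bearing surrogate of B-mode
speckle: a smooth echogenicity map multiplied by spatially correlated
Rayleigh noise, quantized to 8 bits. It makes no claim of acoustic realism
(no beamforming, attenuation or point-spread physics).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_io import RoiMask, UltrasoundFrame, write_dicom_pair

__all__ = [
    "PhantomSpec",
    "MachineProfile",
    "CohortSpec",
    "GroundTruth",
    "DEFAULT_MACHINES",
    "make_phantom",
    "make_cohort",
    "generate_cohort",
    "apply_machine_transform",
]

CARRIER = "carrier"
WILD_TYPE = "wild-type"

_SLOTS = [
    ("left", "longitudinal"),
    ("left", "coronal"),
    ("right", "longitudinal"),
    ("right", "coronal"),
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture parameters of one synthetic ovary phantom.

    Attributes
    ----------
    image_size : int
        Square frame side, pixels.
    pixel_spacing : float
        Native mm/pixel before any machine profile overrides it.
    ellipse_axes : ((amin, amax), (bmin, bmax))
        Sampling ranges of the semi-major / semi-minor axis, millimetres.
    echogenicity_base : float
        Mean background grey of the ovary parenchyma (0-255 scale).
    shading_amplitude : float
        Standard deviation of the smooth large-scale shading field, grey
        levels.
    speckle_scale : float
        Rayleigh scale of the multiplicative speckle; the default
        sqrt(2/pi) gives the speckle field unit mean.
    follicle_count : (int, int)
        Range of dark circular inclusions (class-independent nuisance).
    follicle_radius_mm : (float, float)
        Follicle radius range, millimetres.
    spot_rate : float
        Expected bright spots per 100 ROI pixels (baseline class).
    spot_boost : float
        Additive grey increment of a bright spot (baseline class). Applied
        after the speckle multiplication, so with the default magnitude
        spots saturate towards 255 and read as crisp 1-2 pixel bright
        foci — short runs of high grey level — rather than diffuse lifts.
    spot_size : (int, int)
        Spot diameter range, pixels.
    """

    image_size: int = 160
    pixel_spacing: float = 0.25
    ellipse_axes: tuple[tuple[float, float], tuple[float, float]] = (
        (10.0, 15.0),
        (6.0, 10.0),
    )
    echogenicity_base: float = 95.0
    shading_amplitude: float = 8.0
    speckle_scale: float = float(np.sqrt(2.0 / np.pi))
    follicle_count: tuple[int, int] = (0, 3)
    follicle_radius_mm: tuple[float, float] = (1.0, 2.5)
    spot_rate: float = 0.8
    spot_boost: float = 200.0
    spot_size: tuple[int, int] = (1, 2)

    def __post_init__(self):
        if self.spot_rate < 0 or self.spot_boost < 0:
            raise ValueError("spot_rate and spot_boost must be >= 0")
        if self.speckle_scale <= 0:
            raise ValueError("speckle_scale must be > 0")


@dataclass(frozen=True)
class MachineProfile:
    """Monotone intensity response + pixel spacing of one scanner.

    output = clip(gain * 255 * (input/255)^gamma + noise_floor, 0, 255);
    gamma, gain > 0 keep the transform strictly monotone.
    """

    name: str
    gamma: float = 1.0
    gain: float = 1.0
    noise_floor: float = 0.0
    pixel_spacing: float = 0.25

    def __post_init__(self):
        if self.gamma <= 0 or self.gain <= 0:
            raise ValueError("gamma and gain must be > 0")


#: Four scanner profiles standing in for the four clinical machines. The
#: magnitudes are deliberately mild: images of one patient share a machine,
#: so strong systematic machine shifts would correlate same-patient feature
#: values and distort the per-image null distribution the screening stage
#: relies on.
DEFAULT_MACHINES = (
    MachineProfile("voluson", gamma=1.00, gain=1.00, noise_floor=0.0, pixel_spacing=0.250),
    MachineProfile("toshiba", gamma=0.96, gain=0.98, noise_floor=2.0, pixel_spacing=0.260),
    MachineProfile("samsung", gamma=1.04, gain=1.02, noise_floor=1.0, pixel_spacing=0.240),
    MachineProfile("esaote", gamma=0.98, gain=1.03, noise_floor=1.5, pixel_spacing=0.255),
)


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for a whole synthetic cohort.

    ``effect_size`` scales the carrier-class spot planting: carriers get
    spot_rate*(1+effect_size) spots of boost spot_boost*(1+effect_size);
    effect_size = 0 makes the two class-conditional laws identical.
    """

    n_patients: int = 100
    carrier_prevalence: float = 1.0 / 3.0
    images_per_patient: tuple[int, int] = (1, 4)
    machine_mix: tuple[float, ...] = (0.40, 0.21, 0.24, 0.15)
    effect_size: float = 0.0
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    machines: tuple[MachineProfile, ...] = DEFAULT_MACHINES

    def __post_init__(self):
        if not 0.0 <= self.carrier_prevalence <= 1.0:
            raise ValueError("carrier_prevalence must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if len(self.machine_mix) != len(self.machines):
            raise ValueError("machine_mix length must match machines")
        if abs(sum(self.machine_mix) - 1.0) > 1e-9:
            raise ValueError("machine_mix must sum to 1")


@dataclass(frozen=True)
class GroundTruth:
    """Per-image record of the class and the realized planted effect."""

    patient_id: str
    label: str  # CARRIER or WILD_TYPE
    n_spots: int
    spot_boost: float


def apply_machine_transform(
    frame: UltrasoundFrame, machine: MachineProfile
) -> UltrasoundFrame:
    """Apply a scanner's monotone grey-level response to a frame."""
    v = np.clip(frame.pixels, 0.0, 255.0)
    out = machine.gain * 255.0 * (v / 255.0) ** machine.gamma + machine.noise_floor
    np.clip(out, 0.0, 255.0, out=out)
    return UltrasoundFrame(
        pixels=out,
        pixel_spacing=(machine.pixel_spacing, machine.pixel_spacing),
        machine=machine.name,
        patient_id=frame.patient_id,
        side=frame.side,
        plane=frame.plane,
    )


def _render_ellipse(shape, center, axes_px, theta):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dc * ct + dr * st
    w = -dc * st + dr * ct
    return (u / axes_px[0]) ** 2 + (w / axes_px[1]) ** 2 <= 1.0


def make_phantom(
    spec: PhantomSpec,
    machine: MachineProfile,
    is_carrier: bool,
    effect_size: float,
    rng: np.random.Generator,
) -> tuple[UltrasoundFrame, RoiMask, GroundTruth]:
    """Render one speckled ovary phantom with its ROI mask.

    The ROI mask is the rendered ellipse minus any follicles (dark
    inclusions are excluded from the delineation). The class enters only
    through the bright-spot parameters, so with ``effect_size == 0`` the
    carrier and wild-type laws coincide draw for draw.
    """
    n = spec.image_size
    spacing = machine.pixel_spacing
    (amin, amax), (bmin, bmax) = spec.ellipse_axes
    a_px = rng.uniform(amin, amax) / spacing
    b_px = rng.uniform(bmin, bmax) / spacing
    if max(a_px, b_px) > n / 2 - 3:
        raise ValueError(
            f"ellipse semi-axis {max(a_px, b_px):.1f}px does not fit in a "
            f"{n}px frame at {spacing} mm/px"
        )
    theta = rng.uniform(0.0, np.pi)
    jitter = n / 16
    center = (n / 2 + rng.uniform(-jitter, jitter), n / 2 + rng.uniform(-jitter, jitter))
    ellipse = _render_ellipse((n, n), center, (a_px, b_px), theta)

    # smooth echogenicity map: base level + large-scale shading
    shading = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (n, n)), sigma=n / 10)
    sd = shading.std()
    if sd > 0:
        shading *= spec.shading_amplitude / sd
    echo = np.full((n, n), 0.35 * spec.echogenicity_base)  # dimmer surroundings
    echo[ellipse] = spec.echogenicity_base
    echo += shading

    # follicles: dark, strictly interior, removed from the ROI mask
    follicles = np.zeros((n, n), dtype=bool)
    n_fol = int(rng.integers(spec.follicle_count[0], spec.follicle_count[1] + 1))
    mask = ellipse.copy()
    for _ in range(n_fol):
        r_f = rng.uniform(*spec.follicle_radius_mm) / spacing
        # keep centers well inside so the mask stays 4-connected
        frac = rng.uniform(0.0, 0.55)
        ang = rng.uniform(0.0, 2 * np.pi)
        u, w = frac * a_px * np.cos(ang), frac * b_px * np.sin(ang)
        ct, st = np.cos(theta), np.sin(theta)
        fc = (center[0] + u * st + w * ct, center[1] + u * ct - w * st)
        disc = _render_ellipse((n, n), fc, (r_f, r_f), 0.0)
        cand = mask & ~disc
        lab, ncomp = ndimage.label(cand)
        if ncomp == 1:  # reject placements that would fragment the ROI
            mask = cand
            follicles |= disc & ellipse
    echo[follicles] *= 0.35

    # multiplicative speckle with a small correlation length (grain)
    ray = rng.rayleigh(scale=spec.speckle_scale, size=(n, n))
    ray = ndimage.gaussian_filter(ray, sigma=0.7)
    img = echo * ray

    # planted class effect: small bright spots, added after the speckle so
    # they stay crisp (short high-grey runs) instead of diffusing
    factor = 1.0 + (effect_size if is_carrier else 0.0)
    boost = spec.spot_boost * factor
    roi_px = np.argwhere(mask)
    lam = spec.spot_rate * factor * mask.sum() / 100.0
    n_spots = int(rng.poisson(lam)) if lam > 0 else 0
    if n_spots > 0 and len(roi_px) > 0:
        idx = rng.integers(0, len(roi_px), size=n_spots)
        for r0, c0 in roi_px[idx]:
            d = int(rng.integers(spec.spot_size[0], spec.spot_size[1] + 1))
            rad = max(d / 2.0, 0.5)
            disc = _render_ellipse((n, n), (r0, c0), (rad, rad), 0.0)
            img[disc & mask] += boost

    img = np.clip(img, 0.0, 255.0)

    frame = UltrasoundFrame(pixels=img, pixel_spacing=(spacing, spacing))
    frame = apply_machine_transform(frame, machine)
    frame = frame.with_tags(
        pixels=np.round(frame.pixels),  # 8-bit quantization
    )
    truth = GroundTruth(
        patient_id="",
        label=CARRIER if is_carrier else WILD_TYPE,
        n_spots=n_spots,
        spot_boost=boost,
    )
    return frame, RoiMask(mask=mask), truth


def generate_cohort(cohort: CohortSpec):
    """Yield ``(frame, mask, truth, record)`` for each image of a cohort.

    Patients are assigned a machine by ``machine_mix``, a label by
    ``carrier_prevalence``, and 1-4 images drawn as distinct
    (side, plane) slots. All randomness flows from ``cohort.seed``.
    """
    rng = np.random.default_rng(cohort.seed)
    mix = np.asarray(cohort.machine_mix)
    lo, hi = cohort.images_per_patient
    for p in range(cohort.n_patients):
        pid = f"P{p:04d}"
        machine = cohort.machines[int(rng.choice(len(mix), p=mix))]
        is_carrier = bool(rng.random() < cohort.carrier_prevalence)
        n_img = int(rng.integers(lo, hi + 1))
        slots = [_SLOTS[i] for i in rng.choice(len(_SLOTS), size=n_img, replace=False)]
        for side, plane in slots:
            frame, mask, truth = make_phantom(
                cohort.phantom, machine, is_carrier, cohort.effect_size, rng
            )
            frame = frame.with_tags(patient_id=pid, side=side, plane=plane)
            truth = GroundTruth(
                patient_id=pid,
                label=truth.label,
                n_spots=truth.n_spots,
                spot_boost=truth.spot_boost,
            )
            record = {
                "image_id": f"{pid}_{side}_{plane}",
                "machine": machine.name,
                "patient_id": pid,
                "side": side,
                "plane": plane,
                "label": truth.label,
            }
            yield frame, mask, truth, record


def make_cohort(cohort: CohortSpec, out_dir: str) -> pd.DataFrame:
    """Write a cohort to disk as DICOM pairs plus a manifest CSV.

    Layout: ``<machine>/<patient>/<side>/<plane>/{original.dcm, mask.dcm}``.
    Returns the manifest (also written to ``<out_dir>/manifest.csv``) with
    columns image_id, path_image, path_mask, machine, patient_id, side,
    plane, label. Identical specs (including seed) produce byte-identical
    files.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for frame, mask, truth, record in generate_cohort(cohort):
        leaf = os.path.join(
            out_dir, record["machine"], record["patient_id"], record["side"], record["plane"]
        )
        path_image = os.path.join(leaf, "original.dcm")
        path_mask = os.path.join(leaf, "mask.dcm")
        write_dicom_pair(frame, mask, path_image, path_mask)
        rows.append({**record, "path_image": path_image, "path_mask": path_mask})
    manifest = pd.DataFrame(rows)[
        ["image_id", "path_image", "path_mask", "machine", "patient_id", "side", "plane", "label"]
    ]
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
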