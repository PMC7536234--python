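import numpy as np
import pandas as pd
import pytest

from ovarad.imaging_io import DiscretizedRoi, RoiMask, UltrasoundFrame
from ovarad.radiomics import extract_table_from_arrays
from ovarad.synthdata import CohortSpec, DEFAULT_MACHINES, PhantomSpec, generate_cohort


def grid_roi(levels, n_levels=None):
    """DiscretizedRoi from a small hand grid (0 = outside the mask)."""
    lv = np.asarray(levels, dtype=np.int64)
    ng = int(n_levels or max(2, lv.max()))
    return DiscretizedRoi(levels=lv, n_levels=ng)


@pytest.fixture(scope="session")
def phantom_pair():
    """One default phantom frame/mask pair (wild-type, no effect)."""
    from ovarad.synthdata import make_phantom

    rng = np.random.default_rng(11)
    frame, mask, _ = make_phantom(PhantomSpec(), DEFAULT_MACHINES[0], False, 0.0, rng)
    return frame, mask


def synthetic_feature_table(
    n_patients=75,
    images_per_patient=2,
    n_noise=20,
    shift=2.0,
    prevalence=1.0 / 3.0,
    patient_sd=0.5,
    seed=0,
):
    """Feature-level cohort: one planted feature among Gaussian noise.

    The planted column shifts by ``shift`` (in noise-SD units) for carrier
    patients; every column carries a per-patient random intercept so images
    of one patient are correlated, as in real repeated imaging.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        carrier = rng.random() < prevalence
        intercepts = rng.normal(0.0, patient_sd, size=n_noise + 1)
        for i in range(images_per_patient):
            x = rng.normal(0.0, 1.0, size=n_noise + 1) + intercepts
            if carrier:
                x[0] += shift
            rows.append(
                {
                    "image_id": f"P{p:03d}_{i}",
                    "patient_id": f"P{p:03d}",
                    "machine": "sim",
                    "label": "carrier" if carrier else "wild-type",
                    **{f"noise_{k:02d}": x[k + 1] for k in range(n_noise)},
                    "planted": x[0],
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def effect_cohort_table():
    """Extracted feature table of a planted-effect cohort (effect_size 2).

    Shared by the recovery and invariant checks; 60 patients keeps the
    extraction under a minute while leaving ~15 carrier patients.
    """
    spec = CohortSpec(n_patients=60, effect_size=2.0, seed=202)
    items = ((f, m, rec) for f, m, _, rec in generate_cohort(spec))
    return extract_table_from_arrays(items)


@pytest.fixture(scope="session")
def feature_names(effect_cohort_table):
    from ovarad.radiomics import META_COLUMNS

    return [c for c in effect_cohort_table.columns if c not in META_COLUMNS]
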