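"""Redundancy pruning and univariate outcome screening of radiomics features.

Radiomics features are heavily inter-correlated, so the feature space is
first reduced by iteratively removing one member of every pair whose
absolute Pearson correlation exceeds a threshold (default 0.9). The
survivors are tested one at a time against the binary outcome with the
two-sample Wilcoxon-Mann-Whitney rank-sum test, and the number of
significant results is reported next to the count expected from type-I
error alone (m * alpha) — the screen deliberately applies no
multiple-testing correction, reporting the expected false-positive count
instead (a Benjamini-Hochberg adjustment is available but off by default).

Tests are performed per image; multiple images per patient share a label,
which makes the per-image tests optimistic about independence. The
reports carry this caveat, mirroring how the screen is meant to be read:
as a ranking device, not confirmatory inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreeningConfig",
    "ScreeningReport",
    "correlation_prune",
    "wilcoxon_screen",
    "type1_report",
    "screen_table",
    "permutation_size_check",
]

POSITIVE_LABEL = "carrier"


@dataclass(frozen=True)
class ScreeningConfig:
    """Knobs of the screening stage.

    exact_limit: largest per-group size at which the Wilcoxon p-value is
    computed by exact enumeration (ties force the normal approximation).
    """

    r_threshold: float = 0.9
    alpha: float = 0.05
    exact_limit: int = 25
    bh_adjust: bool = False

    def __post_init__(self):
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class ScreeningReport:
    """Outcome of pruning + univariate screening on one dataset."""

    dataset: str
    retained: tuple[str, ...]
    p_values: pd.Series
    significant: tuple[str, ...]
    alpha: float

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_significant(self) -> int:
        return len(self.significant)

    @property
    def expected_type1(self) -> float:
        return self.n_retained * self.alpha

    @property
    def percent_significant(self) -> float:
        if self.n_retained == 0:
            return 0.0
        return 100.0 * self.n_significant / self.n_retained

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.retained),
                "p_value": [self.p_values[f] for f in self.retained],
                "significant": [f in set(self.significant) for f in self.retained],
            }
        )


def correlation_prune(features: pd.DataFrame, r_threshold: float = 0.9) -> list[str]:
    """Drop all but one feature from every highly correlated group.

    Iteratively finds the pair with the largest |Pearson r| above the
    threshold and drops the member with the larger mean absolute
    correlation against all remaining features (ties drop the
    later-ordered column). Zero-variance columns are removed up front.
    Returns the retained column names in the original order; the result is
    idempotent and guarantees all retained pairwise |r| <= threshold.
    """
    if len(features) < 3:
        raise ValueError(f"need >= 3 rows to estimate correlations, got {len(features)}")
    variances = features.var(axis=0, ddof=0)
    cols = [c for c in features.columns if variances[c] > 0]
    corr = features[cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    order = {c: k for k, c in enumerate(cols)}
    alive = list(range(len(cols)))
    while alive:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() <= r_threshold:
            break
        i_s, j_s = np.unravel_index(np.argmax(sub), sub.shape)
        i, j = alive[i_s], alive[j_s]
        mean_i = sub[i_s].sum() / (len(alive) - 1)
        mean_j = sub[j_s].sum() / (len(alive) - 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:  # tie: drop the later-ordered name
            drop = max(i, j, key=lambda k: order[cols[k]])
        alive.remove(drop)
    kept = {cols[k] for k in alive}
    return [c for c in features.columns if c in kept]


def _wilcoxon_p(x: np.ndarray, y: np.ndarray, exact_limit: int) -> float:
    """Two-sided rank-sum p; exact when small and tie-free, else normal
    approximation with tie and continuity correction."""
    tie_free = np.unique(np.concatenate([x, y])).size == x.size + y.size
    if tie_free and max(x.size, y.size) <= exact_limit:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=True
        ).pvalue
    )


def wilcoxon_screen(
    features: pd.DataFrame, labels: pd.Series, config: ScreeningConfig | None = None
) -> pd.Series:
    """Per-feature two-sided Wilcoxon-Mann-Whitney p-values.

    ``labels`` is boolean (or the ``carrier`` string label) per row.
    """
    config = config or ScreeningConfig()
    y = np.asarray(labels == POSITIVE_LABEL if labels.dtype == object else labels, bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present for screening")
    xs = features.to_numpy(dtype=float)
    out = {}
    for k, col in enumerate(features.columns):
        out[col] = _wilcoxon_p(xs[y, k], xs[~y, k], config.exact_limit)
    return pd.Series(out, name="p_value")


def type1_report(p_values: pd.Series, alpha: float = 0.05, bh_adjust: bool = False):
    """Significant set and the expected chance count m * alpha.

    Returns (significant feature names, expected count, percent of tested).
    """
    p = p_values
    if bh_adjust:
        adj = stats.false_discovery_control(p.to_numpy(), method="bh")
        sig = list(p.index[adj < alpha])
    else:
        sig = list(p.index[p.to_numpy() < alpha])
    m = len(p)
    expected = m * alpha
    percent = 100.0 * len(sig) / m if m else 0.0
    return sig, expected, percent


def permutation_size_check(
    features: pd.DataFrame,
    patient_ids: pd.Series,
    n_permutations: int = 50,
    prevalence: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Empirical size of the per-feature Wilcoxon screen under the null.

    Draws an initial random patient-level label assignment at the given
    prevalence, then re-screens every feature under ``n_permutations``
    permutations of that patient-label vector (labels stay constant within
    a patient, as the outcome is a patient property). Returns the pooled
    fraction of (feature, permutation) tests significant at ``alpha`` and
    the per-permutation rejection fractions, whose spread estimates the
    Monte-Carlo error of the pooled rate.
    """
    rng = np.random.default_rng(seed)
    patients = np.asarray(pd.unique(patient_ids))
    base = rng.random(len(patients)) < prevalence
    if base.all() or not base.any():  # resample a degenerate assignment
        base = np.arange(len(patients)) < max(1, int(prevalence * len(patients)))
    idx = pd.Series(np.arange(len(patients)), index=patients)
    rates = []
    config = ScreeningConfig(alpha=alpha)
    for _ in range(n_permutations):
        perm = rng.permutation(base)
        labels = pd.Series(perm[idx[patient_ids].to_numpy()])
        p = wilcoxon_screen(features, labels, config)
        rates.append(float((p.to_numpy() < alpha).mean()))
    rates = np.asarray(rates)
    return float(rates.mean()), rates


def screen_table(
    table: pd.DataFrame,
    feature_names: list[str],
    config: ScreeningConfig | None = None,
    dataset: str = "All",
) -> ScreeningReport:
    """Full screen of one feature table: prune, test, report."""
    config = config or ScreeningConfig()
    retained = correlation_prune(table[feature_names], config.r_threshold)
    p = wilcoxon_screen(table[retained], table["label"], config)
    sig, _, _ = type1_report(p, config.alpha, config.bh_adjust)
    return ScreeningReport(
        dataset=dataset,
        retained=tuple(retained),
        p_values=p,
        significant=tuple(f for f in retained if f in set(sig)),
        alpha=config.alpha,
    )
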