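"""Experiment runner: simulate -> extract -> screen -> split -> train -> report.

Ties the pipeline stages together over the full dataset and, optionally,
one sub-dataset per scanner, producing a report bundle with the screening
summary (retained / significant counts per dataset), the significant
p-value table, and one metric row per (dataset, strategy). Every number in
the bundle is regenerable from the configuration and the global seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import modeling
from .modeling import GaConfig, SplitSpec
from .radiomics import ExtractionConfig, extract_table, extract_table_from_arrays
from .screening import ScreeningConfig, ScreeningReport, screen_table
from .synthdata import CohortSpec, generate_cohort, make_cohort
from .imaging_io import read_manifest

__all__ = [
    "ExperimentConfig",
    "ReportBundle",
    "run_experiment",
    "summarize_screening",
    "plot_strategy_metrics",
]

log = logging.getLogger("ovarad")

STRATEGY_FITTERS = {
    "A": lambda tr, te, pool, seed, cfg: modeling.fit_strategy_A(tr, te, pool, seed),
    "B": lambda tr, te, pool, seed, cfg: modeling.fit_strategy_B(tr, te, pool, seed),
    "C": lambda tr, te, pool, seed, cfg: modeling.fit_strategy_C(
        tr, te, pool, grid=cfg.xgb_grid, folds=cfg.cv_folds, seed=seed
    ),
    "D": lambda tr, te, pool, seed, cfg: modeling.fit_strategy_D(
        tr, te, pool, config=cfg.ga, seed=seed
    ),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment end to end."""

    cohort: CohortSpec | None = None
    manifest_path: str | None = None
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    strategies: tuple[str, ...] = ("A", "B", "C", "D")
    per_machine: bool = True
    min_patients_per_class: int = 4
    xgb_grid: dict | None = None
    ga: GaConfig = field(default_factory=GaConfig)
    cv_folds: int = 5
    seed: int = 0
    out_dir: str | None = None
    write_dicom: bool = False

    def __post_init__(self):
        if self.cohort is None and self.manifest_path is None:
            raise ValueError("config needs either a cohort spec or a manifest path")
        unknown = set(self.strategies) - set(STRATEGY_FITTERS)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")


@dataclass
class ReportBundle:
    """All tables an experiment produces, plus run metadata."""

    screening_summary: pd.DataFrame
    significant_features: pd.DataFrame
    strategy_metrics: pd.DataFrame
    screening_reports: dict[str, ScreeningReport]
    metadata: dict

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.screening_summary.to_csv(
            os.path.join(out_dir, "screening_summary.csv"), index=False
        )
        self.significant_features.to_csv(
            os.path.join(out_dir, "significant_features.csv"), index=False
        )
        self.strategy_metrics.to_csv(
            os.path.join(out_dir, "strategy_metrics.csv"), index=False
        )
        with open(os.path.join(out_dir, "run_metadata.json"), "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


def summarize_screening(reports: dict[str, ScreeningReport]) -> pd.DataFrame:
    """One row per dataset: retained count, significant count and percent.

    Percentages are reported to one decimal.
    """
    rows = []
    for name, rep in reports.items():
        rows.append(
            {
                "dataset": name,
                "n_retained": rep.n_retained,
                "n_significant": rep.n_significant,
                "percent_significant": round(rep.percent_significant, 1),
                "expected_type1": rep.expected_type1,
            }
        )
    return pd.DataFrame(rows)


def plot_strategy_metrics(metrics: pd.DataFrame, path: str | None = None):
    """Grouped bar chart of the six per-strategy metrics, one panel per
    dataset. Returns the matplotlib figure (saved to ``path`` if given)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = [
        "train_accuracy",
        "test_accuracy",
        "test_specificity",
        "test_sensitivity",
        "test_npv",
        "test_ppv",
    ]
    datasets = list(dict.fromkeys(metrics["dataset"]))
    fig, axes = plt.subplots(
        len(datasets), 1, figsize=(8, 2.6 * len(datasets)), squeeze=False
    )
    for ax, ds in zip(axes[:, 0], datasets):
        sub = metrics[metrics["dataset"] == ds].set_index("strategy")
        x = np.arange(len(cols))
        width = 0.8 / max(len(sub), 1)
        for k, (strat, row) in enumerate(sub[cols].iterrows()):
            ax.bar(x + k * width, row.to_numpy(), width, label=strat)
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels([c.replace("_", "\n") for c in cols], fontsize=8)
        ax.set_ylim(0, 1.05)
        ax.set_title(ds)
        ax.legend(fontsize=8, ncol=len(sub))
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig


def _acquire_table(config: ExperimentConfig) -> pd.DataFrame:
    if config.manifest_path is not None:
        manifest = read_manifest(config.manifest_path)
        log.info("extract: %d manifest rows", len(manifest))
        return extract_table(manifest, config.extraction)
    if config.write_dicom:
        if not config.out_dir:
            raise ValueError("write_dicom requires out_dir")
        manifest = make_cohort(config.cohort, os.path.join(config.out_dir, "cohort"))
        log.info("simulate: wrote %d DICOM pairs", len(manifest))
        return extract_table(manifest, config.extraction)
    items = (
        (frame, mask, record)
        for frame, mask, _, record in generate_cohort(config.cohort)
    )
    return extract_table_from_arrays(items, config.extraction)


def run_experiment(config: ExperimentConfig) -> ReportBundle:
    """Execute the full pipeline and assemble the report bundle.

    Stages: simulate (or load) -> extract -> screen -> split -> train the
    requested strategies -> evaluate on held-out patients; repeated for
    each scanner's sub-dataset when ``per_machine`` is on. Sub-datasets
    with fewer than ``min_patients_per_class`` patients in either class
    are screened but not modeled.
    """
    stage = "simulate/extract"
    try:
        table = _acquire_table(config)
        feature_names = config.extraction.catalog().names
        log.info("extract: %d images x %d features", len(table), len(feature_names))

        datasets = {"All": table}
        if config.per_machine:
            for m, sub in table.groupby("machine", sort=True):
                datasets[str(m)] = sub.reset_index(drop=True)

        stage = "screen"
        reports: dict[str, ScreeningReport] = {}
        for name, sub in datasets.items():
            reports[name] = screen_table(sub, feature_names, config.screening, name)
            log.info(
                "screen[%s]: retained %d, significant %d",
                name,
                reports[name].n_retained,
                reports[name].n_significant,
            )

        stage = "train"
        metric_rows = []
        selections = {}
        for name, sub in datasets.items():
            counts = sub.drop_duplicates("patient_id")["label"].value_counts()
            if len(counts) < 2 or counts.min() < config.min_patients_per_class:
                log.info("train[%s]: skipped (too few patients per class)", name)
                continue
            train_ids, test_ids = modeling.split_patients(sub, replace(
                config.split, seed=config.seed
            ))
            tr = sub[sub["patient_id"].isin(train_ids)].reset_index(drop=True)
            te = sub[sub["patient_id"].isin(test_ids)].reset_index(drop=True)
            pool = list(reports[name].retained)
            for s in config.strategies:
                res = STRATEGY_FITTERS[s](tr, te, pool, config.seed, config)
                metric_rows.append(res.metrics_row(name))
                selections[f"{name}/{s}"] = {
                    "selected": list(res.selected),
                    "descriptor": res.descriptor,
                    "cutoff": res.cutoff,
                }
                log.info(
                    "train[%s/%s]: test accuracy %.3f kappa %.3f",
                    name,
                    s,
                    res.test_metrics["accuracy"],
                    res.test_metrics["kappa"],
                )
    except Exception:
        log.exception("experiment failed at stage %r", stage)
        raise

    sig_rows = []
    for name, rep in reports.items():
        for f in rep.significant:
            sig_rows.append({"dataset": name, "feature": f, "p_value": rep.p_values[f]})
    bundle = ReportBundle(
        screening_summary=summarize_screening(reports),
        significant_features=pd.DataFrame(
            sig_rows, columns=["dataset", "feature", "p_value"]
        ).sort_values(["dataset", "p_value"], ignore_index=True),
        strategy_metrics=pd.DataFrame(metric_rows),
        screening_reports=reports,
        metadata={
            "seed": config.seed,
            "strategies": list(config.strategies),
            "n_images": int(len(table)),
            "selections": selections,
            "config": repr(config),
        },
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
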