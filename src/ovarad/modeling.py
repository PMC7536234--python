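"""Four classification strategies for carrier-status prediction.

All strategies work on a feature table with one row per image but split the
data per patient (no patient contributes images to both sides), because the
outcome is a property of the patient and per-image splitting would leak.
The positive class is ``carrier`` throughout, and classification uses the
rule "score >= cutoff => carrier".

Strategies:

* **A** — logistic regression with a forward feature-selection wrapper;
* **B** — RBF-kernel support vector machine with the same wrapper;
* **C** — gradient-boosted trees with an exhaustive hyperparameter grid
  scored by patient-grouped 5-fold cross-validation error;
* **D** — a small genetic algorithm searching over pipeline genomes
  (preprocessor x model family x hyperparameters), fitness = the same
  grouped 5-fold CV error.

The wrapper used by A and B adds one feature at a time: at each step every
remaining candidate is fitted together with the held set, the training ROC
is computed, the Youden-optimal cutoff picked, and the candidate whose
training confusion matrix has the highest Cohen's kappa is kept; the loop
stops as soon as no candidate strictly increases kappa. Kappa (rather than
accuracy) scores the confusion matrices because the classes are imbalanced
— chance-corrected agreement makes results comparable across datasets with
different prevalence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import VarianceThreshold
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .screening import POSITIVE_LABEL

__all__ = [
    "SplitSpec",
    "RocCurve",
    "ConfusionMatrix",
    "KappaResult",
    "SelectionTrace",
    "StrategyResult",
    "GaConfig",
    "split_patients",
    "roc_youden",
    "cohen_kappa",
    "confusion",
    "metrics_from_confusion",
    "forward_select",
    "fit_strategy_A",
    "fit_strategy_B",
    "fit_strategy_C",
    "fit_strategy_D",
    "feature_gain",
    "DEFAULT_XGB_GRID",
]


# ---------------------------------------------------------------------------
# basic statistics


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class KappaResult:
    po: float
    pe: float
    kappa: float


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true, bool)
    y_pred = np.asarray(y_pred, bool)
    return ConfusionMatrix(
        tp=int((y_true & y_pred).sum()),
        fp=int((~y_true & y_pred).sum()),
        tn=int((~y_true & ~y_pred).sum()),
        fn=int((y_true & ~y_pred).sum()),
    )


def cohen_kappa(cm: ConfusionMatrix) -> KappaResult:
    """Chance-corrected agreement of a confusion matrix.

    po = (tp+tn)/n; pe = [(tp+fn)(tp+fp) + (fp+tn)(fn+tn)] / n^2;
    kappa = (po - pe)/(1 - pe), defined as 0 when pe = 1.
    """
    n = cm.n
    if n <= 0:
        raise ValueError("empty confusion matrix")
    po = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.fp + cm.tn) * (cm.fn + cm.tn)) / n**2
    kappa = 0.0 if pe >= 1.0 else (po - pe) / (1.0 - pe)
    return KappaResult(po=po, pe=pe, kappa=kappa)


def metrics_from_confusion(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, Se, Sp, PPV, NPV and kappa at a fixed operating point."""
    n = cm.n
    se = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    sp = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else 0.0
    ppv = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else 0.0
    npv = cm.tn / (cm.tn + cm.fn) if cm.tn + cm.fn else 0.0
    return {
        "accuracy": (cm.tp + cm.tn) / n,
        "sensitivity": se,
        "specificity": sp,
        "ppv": ppv,
        "npv": npv,
        "kappa": cohen_kappa(cm).kappa,
    }


@dataclass(frozen=True)
class RocCurve:
    """ROC points (threshold, Se, Sp, J) under "score >= threshold"."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    @property
    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def roc_youden(scores: np.ndarray, y: np.ndarray) -> tuple[RocCurve, float]:
    """ROC over all candidate cutoffs and the Youden-optimal one.

    Candidate thresholds are the sorted unique scores plus +inf (predict
    nothing positive); the optimum maximizes J = Se + Sp - 1, ties broken
    by the lowest threshold.
    """
    scores = np.asarray(scores, float)
    y = np.asarray(y, bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present to build a ROC curve")
    thr = np.concatenate([np.unique(scores), [np.inf]])
    pos = scores[y]
    neg = scores[~y]
    se = np.array([(pos >= t).mean() for t in thr])
    sp = np.array([(neg < t).mean() for t in thr])
    curve = RocCurve(thresholds=thr, sensitivity=se, specificity=sp)
    j = curve.youden
    best = int(np.argmax(j))  # argmax returns the first (lowest threshold) max
    return curve, float(thr[best])


# ---------------------------------------------------------------------------
# splitting


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.75
    seed: int = 0
    stratify_by_label: bool = True


def split_patients(table: pd.DataFrame, spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Partition patients (not images) into train and test id lists.

    Stratified by patient label by default; the train fraction applies to
    the patient count of each stratum, rounded to nearest. Raises if any
    class has fewer than 2 patients.
    """
    pat = table[["patient_id", "label"]].drop_duplicates()
    if pat["patient_id"].duplicated().any():
        bad = pat[pat["patient_id"].duplicated()]["patient_id"].tolist()
        raise ValueError(f"patients with inconsistent labels: {bad}")
    rng = np.random.default_rng(spec.seed)
    strata = (
        [g for _, g in pat.groupby("label", sort=True)]
        if spec.stratify_by_label
        else [pat]
    )
    train: list[str] = []
    test: list[str] = []
    for g in strata:
        ids = g["patient_id"].tolist()
        if len(ids) < 2:
            raise ValueError(
                f"class {g['label'].iloc[0]!r} has {len(ids)} patient(s); need >= 2"
            )
        perm = rng.permutation(len(ids))
        n_train = int(round(spec.train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[k] for k in perm[:n_train])
        test.extend(ids[k] for k in perm[n_train:])
    return sorted(train), sorted(test)


def _rows_for(table: pd.DataFrame, patient_ids) -> pd.DataFrame:
    return table[table["patient_id"].isin(set(patient_ids))]


def _y(table: pd.DataFrame) -> np.ndarray:
    return (table["label"] == POSITIVE_LABEL).to_numpy()


# ---------------------------------------------------------------------------
# forward selection (strategies A and B)


@dataclass(frozen=True)
class SelectionTrace:
    """Ordered (feature, training kappa) pairs; kappa strictly increases."""

    steps: tuple[tuple[str, float], ...]

    @property
    def features(self) -> list[str]:
        return [f for f, _ in self.steps]

    @property
    def kappas(self) -> list[float]:
        return [k for _, k in self.steps]


def _make_model(family: str, seed: int = 0):
    if family == "logistic":
        est = LogisticRegression(C=np.inf, max_iter=5000)  # unpenalized ML fit
    elif family == "svm_rbf":
        est = SVC(C=1.0, kernel="rbf", gamma="scale")
    else:
        raise ValueError(f"unknown model family {family!r}")
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def _scores(pipe: Pipeline, X: np.ndarray) -> np.ndarray:
    model = pipe.named_steps["model"]
    if hasattr(model, "predict_proba"):
        return pipe.predict_proba(X)[:, 1]
    return pipe.decision_function(X)


def forward_select(
    model_family: str,
    train: pd.DataFrame,
    feature_pool: list[str],
    seed: int = 0,
) -> tuple[Pipeline, SelectionTrace, float]:
    """Kappa-driven forward feature selection on the training split.

    At step n every candidate feature is added in turn to the held set,
    one model per candidate is fitted on the training images, the
    Youden-optimal cutoff is read off the training ROC, and the candidate
    with the highest Cohen's kappa of the resulting training confusion
    matrix wins (ties go to the earlier feature in pool order). Iteration
    stops when no candidate strictly increases kappa. Returns the model
    refitted on the final set, the selection trace and the final cutoff.
    """
    if not feature_pool:
        raise ValueError("empty feature pool")
    y = _y(train)
    held: list[str] = []
    best_kappa = -np.inf
    trace: list[tuple[str, float]] = []
    final_cutoff = 0.0
    while True:
        candidates = [f for f in feature_pool if f not in held]
        if not candidates:
            break
        step_best = None  # (kappa, feature, cutoff)
        for f in candidates:
            X = train[held + [f]].to_numpy(float)
            pipe = _make_model(model_family, seed)
            pipe.fit(X, y)
            s = _scores(pipe, X)
            _, cutoff = roc_youden(s, y)
            kap = cohen_kappa(confusion(y, s >= cutoff)).kappa
            if step_best is None or kap > step_best[0]:
                step_best = (kap, f, cutoff)
        kap, f, cutoff = step_best
        if kap <= best_kappa:
            break
        held.append(f)
        best_kappa = kap
        final_cutoff = cutoff
        trace.append((f, kap))
    model = _make_model(model_family, seed)
    model.fit(train[held].to_numpy(float), y)
    return model, SelectionTrace(tuple(trace)), final_cutoff


# ---------------------------------------------------------------------------
# strategy results


@dataclass(frozen=True)
class StrategyResult:
    strategy: str
    selected: tuple[str, ...]
    descriptor: str
    cutoff: float
    train_metrics: dict[str, float]
    test_metrics: dict[str, float]
    trace: SelectionTrace | None = None
    model: object = field(default=None, repr=False, compare=False)
    fitness_history: tuple[float, ...] = ()

    def metrics_row(self, dataset: str = "All") -> dict:
        row = {"dataset": dataset, "strategy": self.strategy}
        row["train_accuracy"] = self.train_metrics["accuracy"]
        for k, v in self.test_metrics.items():
            row[f"test_{k}"] = v
        return row


def _evaluate(model, features, cutoff, train, test) -> tuple[dict, dict]:
    out = []
    for part in (train, test):
        X = part[features].to_numpy(float)
        y = _y(part)
        s = _scores(model, X) if isinstance(model, Pipeline) else model.predict_proba(X)[:, 1]
        out.append(metrics_from_confusion(confusion(y, s >= cutoff)))
    return out[0], out[1]


def fit_strategy_A(train, test, feature_pool, seed=0) -> StrategyResult:
    """Logistic regression + kappa/Youden forward selection."""
    model, trace, cutoff = forward_select("logistic", train, feature_pool, seed)
    tr, te = _evaluate(model, trace.features, cutoff, train, test)
    return StrategyResult(
        "A", tuple(trace.features), "logistic", cutoff, tr, te, trace, model
    )


def fit_strategy_B(train, test, feature_pool, seed=0) -> StrategyResult:
    """RBF-kernel SVM + kappa/Youden forward selection."""
    model, trace, cutoff = forward_select("svm_rbf", train, feature_pool, seed)
    tr, te = _evaluate(model, trace.features, cutoff, train, test)
    return StrategyResult(
        "B", tuple(trace.features), "svm_rbf", cutoff, tr, te, trace, model
    )


# ---------------------------------------------------------------------------
# strategy C: boosted trees with grid search

DEFAULT_XGB_GRID = {
    "max_depth": (2, 3, 4),
    "learning_rate": (0.05, 0.1, 0.3),
    "n_estimators": (50, 100, 200),
    "subsample": (0.7, 1.0),
}


def _xgb(params: dict, seed: int) -> XGBClassifier:
    return XGBClassifier(
        **params,
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
        tree_method="hist",
        verbosity=0,
    )


def _grouped_cv_error(estimator, X, y, groups, folds, seed) -> float:
    """Misclassification rate under patient-grouped k-fold CV."""
    uniq = np.unique(groups)
    k = min(folds, len(uniq))
    if k < 2:
        raise ValueError("need >= 2 patient groups for cross-validation")
    cv = GroupKFold(n_splits=k)
    err = 0
    for tr_idx, va_idx in cv.split(X, y, groups):
        if len(np.unique(y[tr_idx])) < 2:
            err += int(len(va_idx))  # degenerate fold: count as all wrong
            continue
        est = clone(estimator)
        est.fit(X[tr_idx], y[tr_idx])
        err += int((est.predict(X[va_idx]) != y[va_idx]).sum())
    return err / len(y)


def fit_strategy_C(
    train,
    test,
    feature_pool,
    grid: dict | None = None,
    folds: int = 5,
    seed: int = 0,
) -> StrategyResult:
    """Gradient-boosted trees with exhaustive grid search.

    Every configuration in the Cartesian product of ``grid`` is scored by
    patient-grouped ``folds``-fold CV misclassification error on the
    training split; the argmin (first in grid order on ties) is refitted
    on the full training set. The operating cutoff is the Youden optimum
    of the training ROC.
    """
    grid = grid or DEFAULT_XGB_GRID
    keys = list(grid)
    combos = list(itertools.product(*(grid[k] for k in keys)))
    if not combos:
        raise ValueError("empty hyperparameter grid")
    X = train[feature_pool].to_numpy(float)
    y = _y(train)
    groups = train["patient_id"].to_numpy()
    best = None  # (error, index, params)
    for idx, combo in enumerate(combos):
        params = dict(zip(keys, combo))
        err = _grouped_cv_error(_xgb(params, seed), X, y, groups, folds, seed)
        if best is None or err < best[0]:
            best = (err, idx, params)
    model = _xgb(best[2], seed)
    model.fit(X, y)
    _, cutoff = roc_youden(model.predict_proba(X)[:, 1], y)
    tr, te = _evaluate(model, feature_pool, cutoff, train, test)
    return StrategyResult(
        "C",
        tuple(feature_pool),
        f"xgboost{best[2]}",
        cutoff,
        tr,
        te,
        None,
        model,
    )


def feature_gain(result: StrategyResult) -> list[tuple[str, float]]:
    """Total split gain per feature of a fitted strategy-C model, descending.

    Features the booster never split on get gain 0.
    """
    model = result.model
    if model is None or not isinstance(model, XGBClassifier):
        raise ValueError("feature_gain needs a fitted boosted-tree StrategyResult")
    booster = model.get_booster()
    booster.feature_names = list(result.selected)
    raw = booster.get_score(importance_type="total_gain")
    gains = [(f, float(raw.get(f, 0.0))) for f in result.selected]
    return sorted(gains, key=lambda t: (-t[1], result.selected.index(t[0])))


# ---------------------------------------------------------------------------
# strategy D: genetic pipeline search


@dataclass(frozen=True)
class GaConfig:
    population: int = 24
    generations: int = 8
    tournament: int = 3
    crossover_rate: float = 0.7
    mutation_rate: float = 0.25
    folds: int = 5

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")


_GA_MODELS = ("logistic", "svm_rbf", "xgboost", "random_forest")
_GA_PREPROCS = ("none", "variance_filter")


def _sample_hyperparams(model: str, rng: np.random.Generator) -> dict:
    if model == "logistic":
        return {"C": float(10 ** rng.uniform(-2, 2))}
    if model == "svm_rbf":
        return {
            "C": float(10 ** rng.uniform(-1, 2)),
            "gamma": float(10 ** rng.uniform(-3, 0)),
        }
    if model == "xgboost":
        return {
            "max_depth": int(rng.integers(2, 6)),
            "learning_rate": float(10 ** rng.uniform(-1.5, -0.5)),
            "n_estimators": int(rng.choice([50, 100, 200])),
            "subsample": float(rng.uniform(0.6, 1.0)),
        }
    return {
        "n_estimators": int(rng.choice([50, 100, 200])),
        "max_depth": int(rng.choice([3, 5, 8, 0])),  # 0 -> unlimited
        "max_features": float(rng.choice([0.3, 0.5, 1.0])),
    }


def _genome_pipeline(genome: dict, seed: int) -> Pipeline:
    steps = []
    if genome["preproc"] == "variance_filter":
        steps.append(("filter", VarianceThreshold(1e-8)))
    hp = genome["params"]
    m = genome["model"]
    if m == "logistic":
        est = LogisticRegression(C=hp["C"], max_iter=5000)
        steps.append(("scale", StandardScaler()))
    elif m == "svm_rbf":
        est = SVC(C=hp["C"], gamma=hp["gamma"])
        steps.append(("scale", StandardScaler()))
    elif m == "xgboost":
        est = _xgb(hp, seed)
    else:
        est = RandomForestClassifier(
            n_estimators=hp["n_estimators"],
            max_depth=hp["max_depth"] or None,
            max_features=hp["max_features"],
            random_state=seed,
            n_jobs=1,
        )
    steps.append(("model", est))
    return Pipeline(steps)


def _random_genome(rng: np.random.Generator) -> dict:
    model = str(rng.choice(_GA_MODELS))
    return {
        "preproc": str(rng.choice(_GA_PREPROCS)),
        "model": model,
        "params": _sample_hyperparams(model, rng),
    }


def _crossover(a: dict, b: dict, rng: np.random.Generator) -> dict:
    child = dict(a)
    if rng.random() < 0.5:
        child["preproc"] = b["preproc"]
    if rng.random() < 0.5:  # model and params travel together
        child["model"], child["params"] = b["model"], dict(b["params"])
    else:
        child["params"] = dict(a["params"])
    return child


def _mutate(genome: dict, rate: float, rng: np.random.Generator) -> dict:
    g = {**genome, "params": dict(genome["params"])}
    if rng.random() < rate:
        g["preproc"] = str(rng.choice(_GA_PREPROCS))
    if rng.random() < rate:
        model = str(rng.choice(_GA_MODELS))
        g["model"], g["params"] = model, _sample_hyperparams(model, rng)
    elif rng.random() < rate:  # re-sample hyperparameters in place
        g["params"] = _sample_hyperparams(g["model"], rng)
    return g


def _genome_key(genome: dict) -> str:
    items = ",".join(f"{k}={genome['params'][k]!r}" for k in sorted(genome["params"]))
    return f"{genome['preproc']}|{genome['model']}|{items}"


def fit_strategy_D(
    train,
    test,
    feature_pool,
    config: GaConfig | None = None,
    seed: int = 0,
) -> StrategyResult:
    """Genetic search over preprocessing/model/hyperparameter genomes.

    Tournament selection + uniform crossover + mutation with elitism;
    fitness is the patient-grouped 5-fold CV misclassification error on
    the training split. The best genome is refitted on the whole training
    set; the cutoff is the Youden optimum of its training scores. The
    search is a deliberately small pipeline optimizer in the spirit of
    automated-ML systems, sized for desk-scale experiments.
    """
    config = config or GaConfig()
    rng = np.random.default_rng(seed)
    X = train[feature_pool].to_numpy(float)
    y = _y(train)
    groups = train["patient_id"].to_numpy()
    cache: dict[str, float] = {}

    def fitness(genome: dict) -> float:
        key = _genome_key(genome)
        if key not in cache:
            pipe = _genome_pipeline(genome, seed)
            cache[key] = _grouped_cv_error(pipe, X, y, groups, config.folds, seed)
        return cache[key]

    pop = [_random_genome(rng) for _ in range(config.population)]
    fits = [fitness(g) for g in pop]
    history = [min(fits)]
    for _ in range(config.generations):
        order = int(np.argmin(fits))
        nxt = [pop[order]]  # elitism: best genome survives unchanged
        while len(nxt) < config.population:
            idx = rng.integers(0, len(pop), size=config.tournament)
            pa = pop[min(idx, key=lambda k: fits[k])]
            idx = rng.integers(0, len(pop), size=config.tournament)
            pb = pop[min(idx, key=lambda k: fits[k])]
            child = _crossover(pa, pb, rng) if rng.random() < config.crossover_rate else dict(pa, params=dict(pa["params"]))
            nxt.append(_mutate(child, config.mutation_rate, rng))
        pop = nxt
        fits = [fitness(g) for g in pop]
        history.append(min(min(fits), history[-1]))

    best = pop[int(np.argmin(fits))]
    model = _genome_pipeline(best, seed)
    model.fit(X, y)
    s = _scores(model, X)
    _, cutoff = roc_youden(s, y)
    tr, te = _evaluate(model, feature_pool, cutoff, train, test)
    return StrategyResult(
        "D",
        tuple(feature_pool),
        _genome_key(best),
        cutoff,
        tr,
        te,
        None,
        model,
        tuple(history),
    )
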