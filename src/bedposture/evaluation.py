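"""Posture-classifier evaluation: LOPO cross-validation with incremental learning.

The protocol measures how well a three-class posture classifier (left-side
lying / supine / right-side lying) generalises to an unseen person, and how
much a small amount of that person's own data ("incremental learning")
improves it:

* leave-one-participant-out (LOPO): each participant in turn is held out
  for testing while the others train the model;
* the held-out participant's windows are split 30:70 (class-stratified)
  into a calibration pool and a fixed test set, so the test set is identical
  across incremental levels;
* at level ``c`` in {0, 10, 20, 30}% a stratified ``c/0.30`` fraction of the
  pool is added to the training data before fitting.

Eight classifier families are supported (AdaBoost, gradient boosting,
LightGBM, logistic regression, two multilayer perceptrons, SVM, XGBoost).
The statsmodels-style entry point is :class:`PostureExperiment`, whose
``fit`` returns an :class:`ExperimentResults` carrying per-fold accuracies,
macro-F1 scores and confusion matrices, a ``summary()`` table, and the
model-comparison statistics (Shapiro-Wilk, Levene, Friedman, post hoc
Wilcoxon with Bonferroni correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES
from .signal_model import POSTURES, ValidationError

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "make_model",
    "lopo_folds",
    "incremental_split",
    "train_and_score",
    "compare_models",
    "PostureExperiment",
    "ExperimentResults",
]

MODEL_NAMES = ("ADA", "GBC", "LGB", "LR", "MLP_OG", "MLP_SIMPLE", "SVM", "XGB")

#: Pool fraction of the held-out participant's data reserved for calibration.
POOL_FRACTION = 0.30
DEFAULT_C_LEVELS = (0.0, 0.10, 0.20, 0.30)


@dataclass(frozen=True)
class ModelSpec:
    """A named classifier family with optional hyperparameter overrides.

    The two multilayer perceptrons follow fixed fully-connected widths:
    MLP_OG 12->64->100->3 and MLP_SIMPLE 12->12->6->4->3, ReLU hidden
    activations, softmax output, cross-entropy loss, early stopping on a
    10% validation split.
    """

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValidationError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")


def make_model(spec: ModelSpec | str, seed: int = 0):
    """Instantiate the sklearn/LightGBM/XGBoost estimator for a model spec."""
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    hp = dict(spec.hyperparameters)
    name = spec.name
    if name == "ADA":
        return AdaBoostClassifier(random_state=seed, **hp)
    if name == "GBC":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if name == "LGB":
        from lightgbm import LGBMClassifier
        hp.setdefault("verbose", -1)
        return LGBMClassifier(random_state=seed, **hp)
    if name == "XGB":
        from xgboost import XGBClassifier
        hp.setdefault("verbosity", 0)
        return XGBClassifier(random_state=seed, **hp)
    if name == "LR":
        hp.setdefault("max_iter", 2000)
        return make_pipeline(StandardScaler(), LogisticRegression(random_state=seed, **hp))
    if name == "SVM":
        return make_pipeline(StandardScaler(), SVC(random_state=seed, **hp))
    if name in ("MLP_OG", "MLP_SIMPLE"):
        layers = (64, 100) if name == "MLP_OG" else (12, 6, 4)
        hp.setdefault("hidden_layer_sizes", layers)
        hp.setdefault("activation", "relu")
        hp.setdefault("early_stopping", True)
        hp.setdefault("validation_fraction", 0.10)
        hp.setdefault("max_iter", 400)
        return make_pipeline(StandardScaler(), MLPClassifier(random_state=seed, **hp))
    raise ValidationError(f"unknown model {name!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Folds and splits
# ---------------------------------------------------------------------------

def lopo_folds(participant_ids: np.ndarray,
               labelled_mask: np.ndarray | None = None) -> list[tuple[object, np.ndarray, np.ndarray]]:
    """Leave-one-participant-out folds over row indices.

    Returns ``(participant, train_idx, test_idx)`` triples, one per
    participant with at least one labelled window; participants with none
    are excluded with a warning.  Test sets partition the labelled rows.
    """
    participant_ids = np.asarray(participant_ids)
    if labelled_mask is None:
        labelled_mask = np.ones(len(participant_ids), dtype=bool)
    ids = pd.unique(participant_ids)
    if len(ids) < 2:
        raise ValidationError("LOPO needs at least 2 participants")
    folds = []
    for pid in ids:
        test = np.flatnonzero((participant_ids == pid) & labelled_mask)
        train = np.flatnonzero((participant_ids != pid) & labelled_mask)
        if len(test) == 0:
            warnings.warn(f"participant {pid!r} has no labelled windows; excluded from LOPO")
            continue
        folds.append((pid, train, test))
    return folds


def incremental_split(heldout_labels: np.ndarray, c: float, seed: int,
                      pool_fraction: float = POOL_FRACTION,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Split a held-out participant's windows for incremental learning.

    ``pool_fraction`` (30%) of the windows form the calibration pool and the
    remainder the fixed test set — identical across all ``c`` for a given
    seed.  The increment is a class-stratified ``c / pool_fraction`` of the
    pool (empty at c=0, the whole pool at c=pool_fraction).  Returns
    ``(increment_idx, test_idx)`` as positions into the held-out rows.
    """
    heldout_labels = np.asarray(heldout_labels)
    n = len(heldout_labels)
    if n < 10:
        raise ValidationError(f"held-out set of {n} windows too small to split (needs >= 10)")
    if not 0 <= c <= pool_fraction + 1e-12:
        raise ValidationError(
            f"c={c} exceeds the calibration pool fraction {pool_fraction}")
    idx = np.arange(n)
    strat = heldout_labels if np.min(np.unique(heldout_labels, return_counts=True)[1]) >= 2 \
        else None
    pool_idx, test_idx = train_test_split(
        idx, train_size=pool_fraction, random_state=seed, stratify=strat)
    if c <= 0:
        return np.empty(0, dtype=int), np.sort(test_idx)
    frac = c / pool_fraction
    if frac >= 1.0 - 1e-12:
        return np.sort(pool_idx), np.sort(test_idx)
    pool_labels = heldout_labels[pool_idx]
    strat = pool_labels if np.min(np.unique(pool_labels, return_counts=True)[1]) >= 2 else None
    inc_idx, _ = train_test_split(pool_idx, train_size=frac, random_state=seed,
                                  stratify=strat)
    return np.sort(inc_idx), np.sort(test_idx)


# ---------------------------------------------------------------------------
# Training and scoring
# ---------------------------------------------------------------------------

def _score(y_true, y_pred, f1_average: str = "macro") -> dict:
    cm = confusion_matrix(y_true, y_pred, labels=list(POSTURES))
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "f1": float(f1_score(y_true, y_pred, labels=list(POSTURES),
                             average=f1_average, zero_division=0)),
        "confusion": cm,
        "n_test": int(len(y_true)),
    }


def train_and_score(model: ModelSpec | str, X: np.ndarray, y: np.ndarray,
                    folds: list, c_levels=DEFAULT_C_LEVELS, seed: int = 0,
                    f1_average: str = "macro") -> pd.DataFrame:
    """Fit and score one model over all folds and incremental levels.

    Per fold and level: fit on the training participants plus the increment
    drawn from the held-out participant's calibration pool, predict the
    fixed 70% test set, and record accuracy, F1 (macro by default) and the
    3x3 confusion matrix.  Deterministic given ``seed``.  Folds whose
    training data contain a single class are skipped with a warning.
    """
    spec = ModelSpec(model) if isinstance(model, str) else model
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    records = []
    for fold_i, (pid, train_idx, test_idx) in enumerate(folds):
        split_seed = (seed * 1009 + fold_i * 101) % (2 ** 31)
        for c in c_levels:
            inc_c, test_c = incremental_split(y[test_idx], c, split_seed)
            fit_idx = np.concatenate([train_idx, test_idx[inc_c]])
            if len(np.unique(y[fit_idx])) < 2:
                warnings.warn(f"fold {pid!r}: single-class training set; skipped")
                continue
            est = make_model(spec, seed=(seed + fold_i) % (2 ** 31))
            yfit = _encode(y[fit_idx]) if spec.name == "XGB" else y[fit_idx]
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message=".*valid feature names.*")
                est.fit(X[fit_idx], yfit)
                pred = est.predict(X[test_idx[test_c]])
            if spec.name == "XGB":
                pred = _decode(pred)
            rec = _score(y[test_idx[test_c]], pred, f1_average)
            rec.update({"model": spec.name, "c": float(c), "participant": pid,
                        "n_train": int(len(fit_idx))})
            records.append(rec)
    return pd.DataFrame.from_records(records)


def _encode(y):
    lut = {p: i for i, p in enumerate(POSTURES)}
    return np.array([lut[v] for v in y])


def _decode(y):
    arr = np.array(POSTURES, dtype=object)
    return arr[np.asarray(y, dtype=int)]


# ---------------------------------------------------------------------------
# Model comparison statistics
# ---------------------------------------------------------------------------

def compare_models(per_fold: pd.DataFrame, c: float = 0.30, metric: str = "accuracy",
                   alpha: float = 0.05, n_top: int = 3) -> dict:
    """The model-comparison protocol at one incremental level.

    Shapiro-Wilk normality per model, Levene homogeneity across models,
    Friedman rank test across all models (paired by participant), and post
    hoc pairwise Wilcoxon signed-rank tests on the top ``n_top`` models by
    mean, with the Bonferroni-adjusted threshold ``alpha / n_pairs``
    reported alongside raw p-values.  All-identical scores yield a
    ``"no variation"`` report instead of a statistic.
    """
    sub = per_fold[np.isclose(per_fold["c"], c)]
    table = sub.pivot_table(index="participant", columns="model", values=metric)
    models = list(table.columns)
    if len(models) < 3 or len(table) < 3:
        raise ValidationError("comparison needs >= 3 models and >= 3 participants")
    report: dict = {"c": c, "metric": metric, "models": models}

    report["shapiro"] = {}
    for m in models:
        x = table[m].to_numpy()
        if np.ptp(x) == 0:
            report["shapiro"][m] = {"note": "no variation"}
        else:
            st, p = stats.shapiro(x)
            report["shapiro"][m] = {"statistic": float(st), "p": float(p)}
    cols = [table[m].to_numpy() for m in models]
    if all(np.ptp(x) == 0 for x in cols):
        report["levene"] = {"note": "no variation"}
        report["friedman"] = {"note": "no variation"}
    else:
        st, p = stats.levene(*cols)
        report["levene"] = {"statistic": float(st), "p": float(p)}
        try:
            st, p = stats.friedmanchisquare(*cols)
            report["friedman"] = {"statistic": float(st), "p": float(p)}
        except ValueError as err:
            report["friedman"] = {"note": str(err)}

    top = table.mean().sort_values(ascending=False).index[:n_top].tolist()
    pairs = [(a, b) for i, a in enumerate(top) for b in top[i + 1:]]
    threshold = alpha / len(pairs) if pairs else alpha
    posthoc = []
    for a, b in pairs:
        diff = table[a].to_numpy() - table[b].to_numpy()
        if np.all(diff == 0):
            posthoc.append({"pair": (a, b), "note": "no variation"})
            continue
        st, p = stats.wilcoxon(table[a], table[b])
        posthoc.append({"pair": (a, b), "V": float(st), "p": float(p),
                        "significant": bool(p < threshold)})
    report["top_models"] = top
    report["bonferroni_threshold"] = round(threshold, 3)
    report["posthoc_wilcoxon"] = posthoc
    return report


def compare_increments(per_fold: pd.DataFrame, model: str,
                       c_levels=DEFAULT_C_LEVELS, metric: str = "accuracy",
                       alpha: float = 0.05) -> dict:
    """Friedman across incremental levels plus adjacent-level Wilcoxon tests."""
    sub = per_fold[per_fold["model"] == model]
    table = sub.pivot_table(index="participant", columns="c", values=metric)
    cols = [table[c].to_numpy() for c in c_levels]
    report: dict = {"model": model, "metric": metric}
    if all(np.ptp(x) == 0 for x in cols):
        report["friedman"] = {"note": "no variation"}
    else:
        st, p = stats.friedmanchisquare(*cols)
        report["friedman"] = {"statistic": float(st), "p": float(p)}
    pairs = list(zip(c_levels[:-1], c_levels[1:]))
    threshold = alpha / len(pairs)
    posthoc = []
    for a, b in pairs:
        diff = table[b].to_numpy() - table[a].to_numpy()
        if np.all(diff == 0):
            posthoc.append({"pair": (a, b), "note": "no variation"})
            continue
        st, p = stats.wilcoxon(table[a], table[b])
        posthoc.append({"pair": (a, b), "V": float(st), "p": float(p),
                        "significant": bool(p < threshold)})
    report["bonferroni_threshold"] = round(threshold, 3)
    report["posthoc_wilcoxon"] = posthoc
    return report


# ---------------------------------------------------------------------------
# Model/Results façade
# ---------------------------------------------------------------------------

class PostureExperiment:
    """LOPO + incremental-learning experiment over a labelled feature table.

    Parameters
    ----------
    data : DataFrame
        One row per window with the twelve feature columns, a ``posture``
        column over {LEFT, SUPINE, RIGHT} and a ``participant`` column.
        Rows with any missing feature or label are dropped (counted in
        ``n_dropped``).
    models : sequence of str or ModelSpec
        Classifier families to evaluate (default: all eight).
    c_levels : sequence of float
        Incremental levels as fractions (default 0, 0.10, 0.20, 0.30).
    """

    def __init__(self, data: pd.DataFrame, models=MODEL_NAMES,
                 c_levels=DEFAULT_C_LEVELS, f1_average: str = "macro"):
        missing = [c for c in FEATURE_NAMES + ["posture", "participant"]
                   if c not in data.columns]
        if missing:
            raise ValidationError(f"data missing columns {missing}")
        ok = data[FEATURE_NAMES].notna().all(axis=1) & data["posture"].isin(POSTURES)
        self.data = data.loc[ok].reset_index(drop=True)
        self.n_dropped = int((~ok).sum())
        self.models = tuple(ModelSpec(m) if isinstance(m, str) else m for m in models)
        self.c_levels = tuple(float(c) for c in c_levels)
        self.f1_average = f1_average

    @classmethod
    def from_tables(cls, feature_tables: dict, label_map: dict, **kw) -> "PostureExperiment":
        """Build from per-participant feature tables and window-label series.

        ``feature_tables`` maps participant id -> feature DataFrame (as
        produced by :func:`bedposture.features.extract_features`);
        ``label_map`` maps participant id -> per-window posture labels
        aligned with the table rows.
        """
        parts = []
        for pid, tab in feature_tables.items():
            t = tab.copy()
            t["posture"] = np.asarray(label_map[pid], dtype=object)
            t["participant"] = pid
            parts.append(t)
        return cls(pd.concat(parts, ignore_index=True), **kw)

    def fit(self, seed: int = 0) -> "ExperimentResults":
        """Run every model over every fold and level; deterministic per seed."""
        X = self.data[FEATURE_NAMES].to_numpy(dtype=float)
        y = self.data["posture"].to_numpy(dtype=object)
        folds = lopo_folds(self.data["participant"].to_numpy())
        frames = [train_and_score(m, X, y, folds, self.c_levels, seed=seed,
                                  f1_average=self.f1_average)
                  for m in self.models]
        per_fold = pd.concat(frames, ignore_index=True)
        manifest = {
            "seed": seed,
            "c_levels": list(self.c_levels),
            "n_windows": int(len(self.data)),
            "n_dropped": self.n_dropped,
            "f1_average": self.f1_average,
            "models": {m.name: {k: v for k, v in make_model(m, seed).get_params(deep=False).items()
                                if isinstance(v, (int, float, str, bool, tuple, type(None)))}
                       for m in self.models},
        }
        return ExperimentResults(per_fold, manifest)


class ExperimentResults:
    """Per-fold scores with aggregation, comparison statistics and plotting."""

    def __init__(self, per_fold: pd.DataFrame, manifest: dict):
        self.per_fold = per_fold
        self.manifest = manifest

    def aggregate(self) -> pd.DataFrame:
        """Mean and sd of accuracy and F1 per (model, c) across participants."""
        g = self.per_fold.groupby(["model", "c"])
        out = g.agg(accuracy_mean=("accuracy", "mean"), accuracy_sd=("accuracy", "std"),
                    f1_mean=("f1", "mean"), f1_sd=("f1", "std"),
                    n_folds=("participant", "nunique"))
        return out.reset_index()

    def confusion(self, model: str, c: float) -> np.ndarray:
        """Pooled 3x3 confusion matrix for one model and level."""
        sub = self.per_fold[(self.per_fold["model"] == model)
                            & np.isclose(self.per_fold["c"], c)]
        return np.sum(np.stack(sub["confusion"].to_numpy()), axis=0)

    def compare(self, c: float = 0.30, metric: str = "accuracy", **kw) -> dict:
        return compare_models(self.per_fold, c=c, metric=metric, **kw)

    def summary(self) -> str:
        agg = self.aggregate()
        lines = ["Posture classification — LOPO with incremental learning",
                 f"windows={self.manifest['n_windows']}  "
                 f"folds={agg['n_folds'].max()}  seed={self.manifest['seed']}",
                 "",
                 f"{'model':<12}" + "".join(f"c={c:>4.0%}         " for c in
                                            sorted(self.per_fold['c'].unique()))]
        for model in sorted(agg["model"].unique()):
            row = f"{model:<12}"
            for c in sorted(agg["c"].unique()):
                m = agg[(agg["model"] == model) & np.isclose(agg["c"], c)]
                row += f"{m['accuracy_mean'].iloc[0]:6.1%} ± {m['accuracy_sd'].iloc[0]:5.1%}  "
            lines.append(row)
        lines.append("")
        lines.append("cells: mean accuracy ± sd across held-out participants")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        cols = ["model", "c", "participant", "accuracy", "f1", "n_test", "n_train"]
        self.per_fold[cols].to_csv(path, index=False)

    def plot_accuracy(self, ax=None, metric: str = "accuracy"):
        """Mean ± sd per model across incremental levels (matplotlib axes)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        agg = self.aggregate()
        for model, g in agg.groupby("model"):
            ax.errorbar(g["c"] * 100, g[f"{metric}_mean"], yerr=g[f"{metric}_sd"],
                        marker="o", capsize=3, label=model)
        ax.set_xlabel("incremental learning level c (%)")
        ax.set_ylabel(f"mean {metric}")
        ax.legend(fontsize="small")
        return ax
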