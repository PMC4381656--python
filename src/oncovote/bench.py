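"""Cross-validated classifier bench, confusion metrics and ensemble voting.

A registry of classifier families (probabilistic, linear, nearest-
neighbour, rule-like, tree-based, plus trivial baselines) is evaluated
under stratified 10-fold cross-validation with fold assignments shared
across classifiers, so that per-edge out-of-fold votes align and can be
combined by majority voting, family-group voting, or strict (unanimous)
consensus.

Metric conventions
------------------
ACC, SPE, SEN, PPV and MCC follow the usual confusion-matrix definitions.
The reported F1 is the *harmonic mean of specificity and sensitivity*
(not the precision/recall F-measure) — the convention used throughout this
benchmark — and is reported as a fraction in [0, 1].  AUC is the rank-based
area under the ROC curve of each classifier's continuous positive-class
score.  Ratios with a zero denominator are reported as 0 and flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .dataset import LabeledDataset
from .exceptions import StratificationError
from .features import apply_normalizer, fit_normalizer
from .io_data import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

FAMILIES = ("bayes", "functions", "misc", "lazy", "rules", "trees")


# ---------------------------------------------------------------------------
# metrics

@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN counts pooled over cross-validation folds."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(tp=int(np.sum((y_true == 1) & (y_pred == 1))),
                   tn=int(np.sum((y_true == 0) & (y_pred == 0))),
                   fp=int(np.sum((y_true == 0) & (y_pred == 1))),
                   fn=int(np.sum((y_true == 1) & (y_pred == 0))))


@dataclass
class MetricReport:
    acc: float
    spe: float
    sen: float
    f1_paper: float
    mcc: float
    ppv: float
    auc: float | None = None
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = {"acc": self.acc, "spe": self.spe, "sen": self.sen,
             "f1": self.f1_paper, "mcc": self.mcc, "ppv": self.ppv}
        d["auc"] = self.auc if self.auc is not None else float("nan")
        return d


def harmonic_f1(spe: float, sen: float) -> float:
    """Harmonic mean of specificity and sensitivity, 2·SPE·SEN/(SPE+SEN)."""
    if spe + sen == 0:
        return 0.0
    return 2.0 * spe * sen / (spe + sen)


def _safe_ratio(num: float, den: float, name: str, degenerate: list) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts,
                    scores: tuple[Sequence, Sequence] | None = None,
                    ) -> MetricReport:
    """Confusion-matrix metrics plus rank-based AUC when scores are given.

    ``scores`` is an optional ``(y_true, score)`` pair for the AUC.  MCC is
    the standard Matthews coefficient with the square-root denominator.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on empty counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    degenerate: list[str] = []
    acc = (tp + tn) / counts.total
    spe = _safe_ratio(tn, tn + fp, "spe", degenerate)
    sen = _safe_ratio(tp, tp + fn, "sen", degenerate)
    ppv = _safe_ratio(tp, tp + fp, "ppv", degenerate)
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        degenerate.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    auc = None
    if scores is not None:
        y_true, s = scores
        y_true = np.asarray(y_true)
        if len(np.unique(y_true)) < 2:
            degenerate.append("auc")
            auc = 0.0
        else:
            auc = float(roc_auc_score(y_true, np.asarray(s, dtype=float)))
    return MetricReport(acc=acc, spe=spe, sen=sen,
                        f1_paper=harmonic_f1(spe, sen), mcc=mcc, ppv=ppv,
                        auc=auc, degenerate=tuple(degenerate))


# ---------------------------------------------------------------------------
# registry

@dataclass
class ClassifierSpec:
    """A named classifier with its family tag and estimator factory."""

    name: str
    family: str
    factory: Callable[[int], object]
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    def build(self):
        return self.factory(self.seed)


def default_registry(seed: int = 0) -> list[ClassifierSpec]:
    """The stock bench: 13 classifiers, 2–3 per family.

    Families follow the six-way taxonomy (probabilistic "bayes", function
    fitters, miscellaneous, instance-based "lazy", rule inducers, and
    trees); representatives are scikit-learn estimators plus trivial
    baselines (a prior-rate rule and a one-feature stump) in the rules
    family.
    """
    return [
        ClassifierSpec("gaussian_nb", "bayes", lambda s: GaussianNB(), seed),
        ClassifierSpec("bernoulli_nb", "bayes",
                       lambda s: BernoulliNB(binarize=0.5), seed),
        ClassifierSpec("logistic", "functions",
                       lambda s: LogisticRegression(max_iter=2000, random_state=s),
                       seed),
        ClassifierSpec("linear_svm", "functions",
                       lambda s: LinearSVC(random_state=s), seed),
        ClassifierSpec("lda", "misc", lambda s: LinearDiscriminantAnalysis(), seed),
        ClassifierSpec("qda", "misc",
                       lambda s: QuadraticDiscriminantAnalysis(reg_param=0.1), seed),
        ClassifierSpec("knn1", "lazy",
                       lambda s: KNeighborsClassifier(n_neighbors=1), seed),
        ClassifierSpec("knn5", "lazy",
                       lambda s: KNeighborsClassifier(n_neighbors=5), seed),
        ClassifierSpec("zero_rule", "rules",
                       lambda s: DummyClassifier(strategy="prior"), seed),
        ClassifierSpec("one_rule", "rules",
                       lambda s: DecisionTreeClassifier(max_depth=1, random_state=s),
                       seed),
        ClassifierSpec("cart", "trees",
                       lambda s: DecisionTreeClassifier(min_samples_leaf=5,
                                                        random_state=s), seed),
        ClassifierSpec("pruned_tree", "trees",
                       lambda s: DecisionTreeClassifier(max_depth=6,
                                                        min_samples_leaf=10,
                                                        random_state=s), seed),
        ClassifierSpec("random_forest", "trees",
                       lambda s: RandomForestClassifier(n_estimators=100,
                                                        random_state=s), seed),
    ]


#: estimator types available to registry config files
ESTIMATOR_TYPES = {
    "gaussian_nb": lambda p, s: GaussianNB(**p),
    "bernoulli_nb": lambda p, s: BernoulliNB(**p),
    "logistic": lambda p, s: LogisticRegression(random_state=s, **p),
    "linear_svm": lambda p, s: LinearSVC(random_state=s, **p),
    "lda": lambda p, s: LinearDiscriminantAnalysis(**p),
    "qda": lambda p, s: QuadraticDiscriminantAnalysis(**p),
    "knn": lambda p, s: KNeighborsClassifier(**p),
    "dummy": lambda p, s: DummyClassifier(**p),
    "decision_tree": lambda p, s: DecisionTreeClassifier(random_state=s, **p),
    "random_forest": lambda p, s: RandomForestClassifier(random_state=s, **p),
}


def registry_from_config(path, seed: int = 0) -> list[ClassifierSpec]:
    """Load a classifier registry from a YAML or JSON list.

    Each entry needs ``name``, ``family`` and ``estimator`` (one of
    :data:`ESTIMATOR_TYPES`); ``params`` is an optional keyword mapping
    passed to the estimator.
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        entries = yaml.safe_load(fh)  # YAML is a superset of JSON
    if not isinstance(entries, list) or not entries:
        raise ValueError(f"registry config {path} must be a nonempty list")
    specs = []
    for entry in entries:
        try:
            estimator = entry["estimator"]
            factory = ESTIMATOR_TYPES[estimator]
        except KeyError as exc:
            raise ValueError(f"registry entry {entry!r}: unknown or missing "
                             f"estimator type ({exc})") from exc
        params = dict(entry.get("params", {}))
        specs.append(ClassifierSpec(
            name=entry["name"], family=entry["family"],
            factory=lambda s, f=factory, p=params: f(p, s),
            seed=int(entry.get("seed", seed))))
    return specs


def positive_score(estimator, X: np.ndarray) -> np.ndarray:
    """Continuous positive-class score: probability if available, else margin."""
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, list(estimator.classes_).index(1)]
    return estimator.decision_function(X)


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class BenchResult:
    """Everything run_cv produces, with rows aligned to the input dataset.

    ``predictions``/``scores`` are DataFrames (one column per classifier)
    of out-of-fold binary predictions and continuous scores; ``fold_of``
    maps each row to its test fold.
    """

    specs: list[ClassifierSpec]
    y_true: np.ndarray
    predictions: pd.DataFrame
    scores: pd.DataFrame
    counts: dict[str, ConfusionCounts]
    reports: dict[str, MetricReport]
    fold_of: np.ndarray

    def family_of(self, name: str) -> str:
        return next(s.family for s in self.specs if s.name == name)

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for spec in self.specs:
            r = self.reports[spec.name]
            rows.append({"algorithm": spec.name, "family": spec.family,
                         **r.as_dict()})
        frame = pd.DataFrame(rows)
        return frame.sort_values(["f1", "acc", "algorithm"],
                                 ascending=[False, False, True],
                                 ignore_index=True)


def run_cv(ds: LabeledDataset, specs: Iterable[ClassifierSpec] | None = None,
           folds: int = 10, seed: int = 0) -> BenchResult:
    """Stratified k-fold cross-validation of every spec on one dataset.

    Folds are deterministic under ``seed`` and shared across classifiers,
    so per-edge votes align.  Min–max normalization is fitted on each
    training fold and applied (clamped) to its test fold.  Confusion counts
    are pooled over folds.
    """
    specs = list(specs) if specs is not None else default_registry(seed)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = ds.y()
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if min(n_pos, n_neg) < folds:
        raise StratificationError(
            f"cannot stratify {folds} folds with class counts {n_pos}/{n_neg}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    raw = ds.frame
    fold_of = np.full(len(y), -1, dtype=int)
    predictions = {s.name: np.zeros(len(y), dtype=int) for s in specs}
    scores = {s.name: np.zeros(len(y), dtype=float) for s in specs}
    splits = list(skf.split(np.zeros(len(y)), y))
    for fold, (train_idx, test_idx) in enumerate(splits):
        fold_of[test_idx] = fold
        norm = fit_normalizer(raw.iloc[train_idx], clamp=True)
        X_train = apply_normalizer(norm, raw.iloc[train_idx]) \
            .loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        X_test = apply_normalizer(norm, raw.iloc[test_idx]) \
            .loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        y_train = y[train_idx]
        for spec in specs:
            est = spec.build()
            est.fit(X_train, y_train)
            predictions[spec.name][test_idx] = est.predict(X_test).astype(int)
            scores[spec.name][test_idx] = positive_score(est, X_test)
    counts, reports = {}, {}
    for spec in specs:
        c = ConfusionCounts.from_predictions(y, predictions[spec.name])
        counts[spec.name] = c
        reports[spec.name] = compute_metrics(c, scores=(y, scores[spec.name]))
    return BenchResult(specs=specs, y_true=y,
                       predictions=pd.DataFrame(predictions),
                       scores=pd.DataFrame(scores),
                       counts=counts, reports=reports, fold_of=fold_of)


def rank_classifiers(reports: dict[str, MetricReport],
                     key: str = "f1_paper") -> list[str]:
    """Classifier names in descending metric order (ties: acc, then name)."""
    if not reports:
        raise ValueError("no reports to rank")
    valid = {"acc", "spe", "sen", "f1_paper", "mcc", "ppv", "auc"}
    if key not in valid:
        raise KeyError(f"unknown metric {key!r}")

    def sort_key(name: str):
        r = reports[name]
        value = getattr(r, key)
        value = float("-inf") if value is None else value
        return (-value, -r.acc, name)

    return sorted(reports, key=sort_key)


# ---------------------------------------------------------------------------
# voting

def majority_vote(predictions: pd.DataFrame, subset: Sequence[str]) -> np.ndarray:
    """Per-edge majority decision over an odd panel of classifiers."""
    subset = list(subset)
    if len(subset) % 2 == 0:
        raise ValueError("majority voting requires an odd number of classifiers")
    votes = predictions.loc[:, subset].to_numpy(dtype=int)
    return (votes.sum(axis=1) * 2 > len(subset)).astype(int)


def vote_fraction(predictions: pd.DataFrame, subset: Sequence[str]) -> np.ndarray:
    """Fraction of panel members voting positive — the ensemble's score."""
    votes = predictions.loc[:, list(subset)].to_numpy(dtype=int)
    return votes.mean(axis=1)


def top_k_subset(reports: dict[str, MetricReport], k: int,
                 key: str = "f1_paper") -> list[str]:
    names = rank_classifiers(reports, key=key)
    if k > len(names):
        raise ValueError(f"requested top {k} of {len(names)} classifiers")
    return names[:k]


def group_vote(result: BenchResult, family: str, k: int) -> np.ndarray:
    """Majority vote over the top-k members (by F1) of one family."""
    members = [s.name for s in result.specs if s.family == family]
    if len(members) < k:
        raise ValueError(f"family {family!r} has {len(members)} members < k={k}")
    ranked = [n for n in rank_classifiers(result.reports) if n in members]
    return majority_vote(result.predictions, ranked[:k])


def strict_consensus(predictions: pd.DataFrame, subset: Sequence[str]) -> np.ndarray:
    """Positive only where every panel member votes positive."""
    subset = list(subset)
    if not subset:
        raise ValueError("strict consensus needs a nonempty panel")
    votes = predictions.loc[:, subset].to_numpy(dtype=int)
    return (votes.sum(axis=1) == len(subset)).astype(int)


def vote_report(result: BenchResult, subset: Sequence[str]) -> MetricReport:
    """Metrics of a majority-vote panel, with AUC from the vote fraction."""
    pred = majority_vote(result.predictions, subset)
    counts = ConfusionCounts.from_predictions(result.y_true, pred)
    frac = vote_fraction(result.predictions, subset)
    return compute_metrics(counts, scores=(result.y_true, frac))


def voting_report_frame(result: BenchResult,
                        ks: Sequence[int] | None = None) -> pd.DataFrame:
    """Majority-vote metrics for odd top-k panels (Table-2-style report)."""
    n = len(result.specs)
    if ks is None:
        ks = [k for k in range(3, n + 1, 2)]
    rows = []
    for k in ks:
        subset = top_k_subset(result.reports, k)
        r = vote_report(result, subset)
        rows.append({"classifiers": f"TOP: {k}", "k": k, **r.as_dict()})
    return pd.DataFrame(rows).sort_values("f1", ascending=False,
                                          ignore_index=True)


# ---------------------------------------------------------------------------
# per-feature discrimination

def feature_auc(ds: LabeledDataset) -> dict[str, float]:
    """Univariate rank-based AUC of each feature against the positive class."""
    y = ds.y()
    if len(np.unique(y)) < 2:
        raise ValueError("feature_auc needs both classes present")
    return {col: float(roc_auc_score(y, ds.frame[col].to_numpy(dtype=float)))
            for col in FEATURE_COLUMNS}


# ---------------------------------------------------------------------------
# trained panels for downstream protein inference

@dataclass
class TrainedPanel:
    """Classifiers fitted on a full training set, for out-of-sample edges.

    Normalization parameters are fitted once on the training rows and
    applied with clamping to new edges.
    """

    specs: list[ClassifierSpec]
    estimators: dict[str, object] = field(default_factory=dict)
    normalizer: object = None

    @classmethod
    def fit(cls, ds: LabeledDataset,
            specs: Iterable[ClassifierSpec] | None = None,
            seed: int = 0) -> "TrainedPanel":
        specs = list(specs) if specs is not None else default_registry(seed)
        norm = fit_normalizer(ds.frame, clamp=True)
        X = apply_normalizer(norm, ds.frame) \
            .loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        y = ds.y()
        estimators = {}
        for spec in specs:
            est = spec.build()
            est.fit(X, y)
            estimators[spec.name] = est
        return cls(specs=specs, estimators=estimators, normalizer=norm)

    def predict_frame(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Per-classifier binary predictions for raw (unnormalized) rows."""
        X = apply_normalizer(self.normalizer, frame) \
            .loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        return pd.DataFrame({s.name: self.estimators[s.name].predict(X).astype(int)
                             for s in self.specs})

    def vote(self, frame: pd.DataFrame, mode: str = "majority",
             subset: Sequence[str] | None = None) -> np.ndarray:
        names = list(subset) if subset is not None else [s.name for s in self.specs]
        preds = self.predict_frame(frame)
        if mode == "majority":
            return majority_vote(preds, names)
        if mode == "strict":
            return strict_consensus(preds, names)
        raise ValueError(f"unknown vote mode {mode!r}")
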