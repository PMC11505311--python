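"""Cross-validated classifier comparison and Shapley feature attribution.

Five classifier families (logistic regression, RBF support vector machine,
decision tree, random forest, k-nearest neighbours) are evaluated with
stratified 10-fold cross-validation. Features are standardized on the
training folds only. Six metrics are reported per fold: accuracy,
sensitivity, specificity, positive and negative predictive value, and AUC;
the positive class throughout is the first (e.g. DCM / class "A").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSIFIER_NAMES = ("LR", "SVM", "DT", "RF", "KNN")
METRIC_NAMES = ("ACC", "SEN", "SPE", "PPV", "NPV", "AUC")


def make_classifier(name: str, seed: int | None = None):
    """Instantiate one of the five classifier families with fixed defaults."""
    if name == "LR":
        return LogisticRegression(C=1.0, max_iter=2000)
    if name == "SVM":
        return SVC(kernel="rbf", C=1.0, gamma="scale", probability=False)
    if name == "DT":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


@dataclass
class ConfusionCounts:
    """Counts with the positive class mapped to TP."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUC: probability a random positive outscores a random
    negative, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(
    counts: ConfusionCounts,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> dict[str, float]:
    """Six evaluation metrics from confusion counts (+ scores for AUC).

    ACC = (TP+TN)/total, SEN = TP/(TP+FN), SPE = TN/(FP+TN),
    PPV = TP/(TP+FP), NPV = TN/(TN+FN). A ratio with a zero denominator is
    returned as NaN. AUC needs per-instance scores and boolean labels; it
    is NaN when they are not supplied.
    """
    if counts.total <= 0:
        raise ValueError("empty confusion counts")

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    out = {
        "ACC": ratio(counts.tp + counts.tn, counts.total),
        "SEN": ratio(counts.tp, counts.tp + counts.fn),
        "SPE": ratio(counts.tn, counts.fp + counts.tn),
        "PPV": ratio(counts.tp, counts.tp + counts.fp),
        "NPV": ratio(counts.tn, counts.tn + counts.fn),
    }
    out["AUC"] = (
        auc_rank(scores, labels) if scores is not None and labels is not None
        else float("nan")
    )
    return out


def _scores(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, 1]
    return model.decision_function(x)


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    classifier_name: str,
    k: int = 10,
    seed: int = 0,
    positive_label=None,
) -> pd.DataFrame:
    """Stratified k-fold evaluation of one classifier.

    Returns a tidy frame with one row per (fold, metric). Standardization
    parameters come from the training folds only; fold assignment and any
    classifier randomness derive from ``seed``.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if counts.min() < k:
        raise ValueError(f"need >= {k} samples per class, got {counts.min()}")
    if positive_label is None:
        positive_label = classes[0]
    y = labels == positive_label  # True = positive class

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (train, test) in enumerate(skf.split(features, y)):
        scaler = StandardScaler().fit(features[train])
        model = make_classifier(classifier_name, seed=seed)
        model.fit(scaler.transform(features[train]), y[train])
        xt = scaler.transform(features[test])
        pred = model.predict(xt)
        yt = y[test]
        # scores oriented so larger means more positive
        sc = _scores(model, xt)
        if hasattr(model, "predict_proba"):
            pos_col = list(model.classes_).index(True)
            sc = model.predict_proba(xt)[:, pos_col]
        counts_f = ConfusionCounts(
            tp=int(np.sum(pred & yt)),
            tn=int(np.sum(~pred & ~yt)),
            fp=int(np.sum(pred & ~yt)),
            fn=int(np.sum(~pred & yt)),
        )
        metrics = compute_metrics(counts_f, scores=sc, labels=yt)
        rows.extend(
            {"fold": fold, "metric": m, "value": v} for m, v in metrics.items()
        )
    return pd.DataFrame(rows)


@dataclass
class MetricsPanel:
    """Classifier x lead x fold x metric array of evaluation results."""

    values: np.ndarray  # shape (n_classifiers, n_leads, k, n_metrics)
    classifiers: list[str]
    leads: list[str]
    metrics: list[str] = None

    def __post_init__(self):
        if self.metrics is None:
            self.metrics = list(METRIC_NAMES)
        expected = (
            len(self.classifiers),
            len(self.leads),
            self.values.shape[2],
            len(self.metrics),
        )
        if self.values.shape != expected:
            raise ValueError(f"panel shape {self.values.shape} != {expected}")

    def fold_vectors(self, classifier: str, metric: str) -> np.ndarray:
        """(k, n_leads) matrix of one metric across leads, per fold."""
        ci = self.classifiers.index(classifier)
        mi = self.metrics.index(metric)
        return self.values[ci, :, :, mi].T

    def to_tidy(self) -> pd.DataFrame:
        recs = []
        for ci, c in enumerate(self.classifiers):
            for li, l in enumerate(self.leads):
                for f in range(self.values.shape[2]):
                    for mi, m in enumerate(self.metrics):
                        recs.append(
                            {
                                "classifier": c,
                                "lead": l,
                                "fold": f,
                                "metric": m,
                                "value": self.values[ci, li, f, mi],
                            }
                        )
        return pd.DataFrame(recs)

    def best_lead_summary(self, metric: str = "ACC") -> pd.DataFrame:
        """Per classifier: the lead with the best fold-mean of ``metric``."""
        mi = self.metrics.index(metric)
        rows = []
        for ci, c in enumerate(self.classifiers):
            means = self.values[ci, :, :, mi].mean(axis=1)
            sds = self.values[ci, :, :, mi].std(axis=1, ddof=1)
            li = int(np.nanargmax(means))
            rows.append(
                {
                    "classifier": c,
                    "best_lead": self.leads[li],
                    "mean": means[li],
                    "sd": sds[li],
                }
            )
        return pd.DataFrame(rows)


def run_grid(
    feature_frame: pd.DataFrame,
    classifiers: list[str] = list(CLASSIFIER_NAMES),
    k: int = 10,
    seed: int = 0,
    positive_label=None,
) -> MetricsPanel:
    """Evaluate classifiers on every lead of a per-beat feature table.

    ``feature_frame`` must carry a ``lead`` column, a ``label`` column and
    feature columns (everything else); rows are beats. Features from
    multiple modes of the same beat are expected pre-concatenated into one
    row (one row per beat per lead).
    """
    key_cols = {"lead", "label", "record_id", "beat_index", "method", "mode"}
    feat_cols = [c for c in feature_frame.columns if c not in key_cols]
    leads = list(dict.fromkeys(feature_frame["lead"]))
    values = np.full((len(classifiers), len(leads), k, len(METRIC_NAMES)), np.nan)
    for li, lead in enumerate(leads):
        sub = feature_frame[feature_frame["lead"] == lead]
        x = sub[feat_cols].to_numpy(dtype=float)
        y = sub["label"].to_numpy()
        for ci, cname in enumerate(classifiers):
            tidy = cross_validate(
                x, y, cname, k=k, seed=seed, positive_label=positive_label
            )
            pivot = tidy.pivot(index="fold", columns="metric", values="value")
            values[ci, li] = pivot[list(METRIC_NAMES)].to_numpy()
    return MetricsPanel(values=values, classifiers=list(classifiers), leads=leads)


def shapley_attribution(
    model,
    x: np.ndarray,
    background: np.ndarray,
    n_samples: int = 200,
    seed: int = 0,
    score_fn=None,
) -> np.ndarray:
    """Sampling-based Shapley attribution per instance and feature.

    For each instance, marginal contributions of each feature are averaged
    over random feature-subset permutations, with features outside the
    subset replaced by draws from the background set (Strumbelj-Kononenko
    estimator). Attributions sum to score(instance) minus the expected
    background score, up to Monte-Carlo error.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if score_fn is None:
        score_fn = lambda a: _scores(model, a)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    background = np.asarray(background, dtype=float)
    rng = np.random.default_rng(seed)
    n_inst, n_feat = x.shape
    attrib = np.zeros((n_inst, n_feat))
    for _ in range(n_samples):
        perm = rng.permutation(n_feat)
        bg = background[rng.integers(len(background), size=n_inst)]
        current = bg.copy()
        prev_score = score_fn(current)
        for f in perm:
            current[:, f] = x[:, f]
            new_score = score_fn(current)
            attrib[:, f] += new_score - prev_score
            prev_score = new_score
    return attrib / n_samples


def global_importance(attributions: np.ndarray) -> np.ndarray:
    """Mean absolute attribution per feature."""
    return np.mean(np.abs(attributions), axis=0)
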