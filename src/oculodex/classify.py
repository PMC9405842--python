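"""Cross-validated dyslexia screening from oculomotor feature tables.

Three grouping analyses over a seven-painting free-viewing cohort:

* ``per-painting`` — one 92-row dataset per painting (7 models),
* ``groups``      — Op-Art paintings 1–3 pooled (276 rows) vs the
  space-composition paintings 4–7 (368 rows),
* ``combined``    — all seven pooled (644 rows), painting identity unknown
  to the model.

Each dataset is evaluated with stratified 5-fold cross-validation; within
every fold, features are z-scored with *training-fold* statistics only, and
the model is fit at fixed defaults with no hyperparameter tuning
(RBF-kernel SVM: C = 1, gamma = 1/(n_features x mean train variance);
logistic regression: ridge C = 1, tol = 1e-4, max 1000 iterations).
Metrics are reported in percent: accuracy, sensitivity (recall on the
dyslexic, positive class) and specificity (recall on controls).

Subjects contribute one row per painting; in pooled analyses folds split
rows, not subjects, mirroring the stated dataset sizes — an optional
``group_by_subject`` switch exists for leakage sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .recording import CohortManifest

__all__ = [
    "FeatureMatrix",
    "CVReport",
    "SCHEMES",
    "MODELS",
    "assemble",
    "crossvalidate",
    "metrics_percent",
    "mann_whitney",
    "feature_importance",
    "fuse_and_classify",
]

SCHEMES = ("per-painting", "groups", "combined")
MODELS = ("svm_rbf", "logistic")
#: painting partition of the two-group analysis: Op Art vs space composition
GROUP_PARTITION = ((1, 2, 3), (4, 5, 6, 7))


@dataclasses.dataclass
class FeatureMatrix:
    """Aligned features / labels / painting ids for one analysis dataset."""

    X: pd.DataFrame  # rows = recordings, named feature columns
    y: np.ndarray  # 1 dyslexic, 0 control
    painting: np.ndarray
    subject: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.painting) == len(self.subject)):
            raise ValueError("features, labels and painting ids must align")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n(self) -> int:
        return len(self.X)


@dataclasses.dataclass
class CVReport:
    """Per-fold and mean accuracy/sensitivity/specificity, in percent."""

    model: str
    scheme: str
    n: int
    fold_metrics: list[dict[str, float]]
    accuracy: float
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def assemble(
    manifest: CohortManifest,
    features: Mapping[str, Mapping[str, float]],
    scheme: str = "combined",
) -> list[FeatureMatrix]:
    """Build one feature matrix per element of the grouping scheme.

    ``features`` maps each manifest ``path`` to a named feature mapping
    (e.g. the three DGI descriptors, or the 32 saccade summaries).  Painting
    identity is never a feature — it only selects rows.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    missing = [row["path"] for row in manifest if row["path"] not in features]
    if missing:
        raise KeyError(f"no features for recordings: {missing[:5]}")
    df = manifest.table.copy()
    feat = pd.DataFrame([dict(features[p]) for p in df["path"]], index=df.index)

    def _subset(paintings: Sequence[int], name: str) -> FeatureMatrix:
        m = df["painting"].astype(int).isin(paintings)
        return FeatureMatrix(
            X=feat[m].reset_index(drop=True),
            y=df.loc[m, "label"].to_numpy(int),
            painting=df.loc[m, "painting"].to_numpy(int),
            subject=df.loc[m, "subject"].to_numpy(str),
            name=name,
        )

    if scheme == "per-painting":
        return [_subset([p], f"painting-{p}") for p in manifest.paintings]
    if scheme == "groups":
        return [
            _subset(part, f"group-{i + 1}") for i, part in enumerate(GROUP_PARTITION)
        ]
    return [_subset(manifest.paintings, "combined")]


def _make_model(model: str) -> Pipeline:
    if model == "svm_rbf":
        clf = SVC(C=1.0, kernel="rbf", gamma="scale")
    elif model == "logistic":
        clf = LogisticRegression(C=1.0, tol=1e-4, max_iter=1000)
    else:
        raise ValueError(f"model must be one of {MODELS}")
    # scaler inside the pipeline -> z-scoring uses training-fold statistics
    # only; zero-variance features get a unit divisor (sklearn convention)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def metrics_percent(
    truth: np.ndarray, predicted: np.ndarray
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent.

    Sensitivity is recall on the dyslexic (1) class, specificity recall on
    the control (0) class; either is nan when its class is absent from
    ``truth``.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("label vectors must have equal length")
    acc = float((truth == predicted).mean() * 100)
    pos = truth == 1
    neg = truth == 0
    sens = float((predicted[pos] == 1).mean() * 100) if pos.any() else float("nan")
    spec = float((predicted[neg] == 0).mean() * 100) if neg.any() else float("nan")
    return acc, sens, spec


def crossvalidate(
    fm: FeatureMatrix,
    model: str = "svm_rbf",
    seed: int = 42,
    *,
    n_splits: int = 5,
    group_by_subject: bool = False,
) -> CVReport:
    """Stratified 5-fold CV with train-statistic normalization per fold."""
    if fm.n < 10:
        raise ValueError("need at least 10 rows to cross-validate")
    classes, counts = np.unique(fm.y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if counts.min() < n_splits:
        raise ValueError("cannot stratify: a class has fewer rows than folds")
    X = fm.X.to_numpy(float)
    if group_by_subject:
        splitter = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        splits = splitter.split(X, fm.y, groups=fm.subject)
    else:
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        splits = splitter.split(X, fm.y)
    folds = []
    for k, (tr, te) in enumerate(splits):
        pipe = _make_model(model)
        pipe.fit(X[tr], fm.y[tr])
        acc, sens, spec = metrics_percent(fm.y[te], pipe.predict(X[te]))
        folds.append(
            {"fold": k, "n_test": len(te), "accuracy": acc,
             "sensitivity": sens, "specificity": spec}
        )
    return CVReport(
        model=model,
        scheme=fm.name,
        n=fm.n,
        fold_metrics=folds,
        accuracy=float(np.mean([f["accuracy"] for f in folds])),
        sensitivity=float(np.nanmean([f["sensitivity"] for f in folds])),
        specificity=float(np.nanmean([f["specificity"] for f in folds])),
    )


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two-sided Mann–Whitney U with tie-corrected normal approximation.

    Returns ``(U, z, p)`` where U counts pairs won by ``x`` and z is signed
    by the rank tendency of x relative to y (positive when x tends larger).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(x.size * y.size / 2), 0.0, 1.0
    u = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
    n1, n2 = x.size, y.size
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    z = (u - mu) / sigma
    p = float(2 * stats.norm.sf(abs(z)))
    return u, float(z), min(p, 1.0)


def feature_importance(
    fm: FeatureMatrix,
    model: str = "svm_rbf",
    seed: int = 42,
    *,
    n_repeats: int = 10,
) -> dict[str, float]:
    """Permutation importance: mean accuracy drop over shuffles per feature."""
    pipe = _make_model(model)
    X = fm.X.to_numpy(float)
    pipe.fit(X, fm.y)
    result = permutation_importance(
        pipe, X, fm.y, scoring="accuracy", n_repeats=n_repeats, random_state=seed
    )
    return dict(zip(fm.X.columns, result.importances_mean.astype(float)))


def fuse_and_classify(
    manifest: CohortManifest,
    saccade_features: Mapping[str, Mapping[str, float]],
    dgi_features: Mapping[str, Mapping[str, float]],
    seed: int = 42,
    model: str = "svm_rbf",
) -> CVReport:
    """Column-concatenate the two feature sets; CV on the combined cohort."""
    fused = {
        path: {**dict(saccade_features[path]), **dict(dgi_features[path])}
        for path in (row["path"] for row in manifest)
    }
    (fm,) = assemble(manifest, fused, scheme="combined")
    fm.name = "combined+fused"
    return crossvalidate(fm, model=model, seed=seed)
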