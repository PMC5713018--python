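"""Benthic habitat classification and map-quality metrics.

Features are the retrieved per-class abundances plus the bathymetry.
Class separability is screened with the Jeffries–Matusita distance
(JM = 2·(1 − e^{−B}), B the Bhattacharyya distance under Gaussian class
models, saturating at 2 for perfectly separable pairs).  Classification
uses a one-vs-one RBF support vector machine (γ = 0.25, C = 100) on
features standardised by the training statistics.  Map quality is
reported as a ground-truth-column-normalised confusion matrix with
overall accuracy and Cohen's kappa, and a published matrix of that form
can be inverted back to the truth-class proportions it implies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ValidationError

__all__ = ["LabeledRegions", "ConfusionReport", "jm_separability", "regions_from_class_map",
           "train_classify", "confusion_metrics", "reconstruct_truth_proportions"]


@dataclass
class LabeledRegions:
    """Disjoint train/test pixel index sets per class."""

    classes: list[str]
    train: dict[str, np.ndarray]   # class -> (n, 2) array of (row, col)
    test: dict[str, np.ndarray]

    def __post_init__(self):
        for name in self.classes:
            for split in (self.train, self.test):
                if name not in split or len(split[name]) == 0:
                    raise ValidationError(f"class {name!r} empty in train or test")
        seen = set()
        for name in self.classes:
            for r, c in self.train[name]:
                seen.add((int(r), int(c)))
        for name in self.classes:
            for r, c in self.test[name]:
                if (int(r), int(c)) in seen:
                    raise ValidationError("train and test regions overlap")


def regions_from_class_map(class_map: np.ndarray, classes: list[str],
                           n_train: int = 50, n_test: int = 50,
                           seed: int = 0) -> LabeledRegions:
    """Sample disjoint train/test pixel sets per class from a label raster."""
    rng = np.random.default_rng(seed)
    train, test = {}, {}
    for k, name in enumerate(classes):
        px = np.argwhere(class_map == k)
        if len(px) < n_train + n_test:
            raise ValidationError(
                f"class {name!r}: only {len(px)} pixels, need {n_train + n_test}")
        rng.shuffle(px)
        train[name] = px[:n_train]
        test[name] = px[n_train:n_train + n_test]
    return LabeledRegions(classes=list(classes), train=train, test=test)


def _class_samples(features: np.ndarray, pixels: np.ndarray) -> np.ndarray:
    """(n, nfeat) sample matrix from an (nfeat, ny, nx) stack."""
    return features[:, pixels[:, 0], pixels[:, 1]].T


def jm_separability(features: np.ndarray, regions: LabeledRegions,
                    split: str = "train", ridge: float = 1e-6) -> np.ndarray:
    """Pairwise Jeffries–Matusita distances between class distributions."""
    sets = getattr(regions, split)
    stats = {}
    for name in regions.classes:
        X = _class_samples(features, np.asarray(sets[name]))
        if len(X) < 2:
            raise ValidationError(f"class {name!r}: need >= 2 samples")
        C = np.cov(X.T) + ridge * np.eye(X.shape[1])
        sign, logdet = np.linalg.slogdet(C)
        if sign <= 0:
            raise ValidationError(f"class {name!r}: singular covariance")
        stats[name] = (X.mean(axis=0), C, logdet)
    k = len(regions.classes)
    jm = np.zeros((k, k))
    for i in range(k):
        mi, Ci, ldi = stats[regions.classes[i]]
        for j in range(i + 1, k):
            mj, Cj, ldj = stats[regions.classes[j]]
            Cm = 0.5 * (Ci + Cj)
            sign, ldm = np.linalg.slogdet(Cm)
            d = mi - mj
            B = 0.125 * d @ np.linalg.solve(Cm, d) + 0.5 * (ldm - 0.5 * (ldi + ldj))
            jm[i, j] = jm[j, i] = 2.0 * (1.0 - np.exp(-B))
    return jm


def train_classify(features: np.ndarray, regions: LabeledRegions,
                   gamma: float = 0.25, C: float = 100.0,
                   seed: int = 0) -> np.ndarray:
    """Train a one-vs-one RBF SVM on the train regions; label every pixel.

    Features are z-scored using the training statistics before the kernel
    is applied.  Returns an integer class raster indexed into
    ``regions.classes``.
    """
    if len(regions.classes) < 2:
        raise ValidationError("need at least two classes to train")
    X_train, y_train = [], []
    for label, name in enumerate(regions.classes):
        X = _class_samples(features, np.asarray(regions.train[name]))
        X_train.append(X)
        y_train.append(np.full(len(X), label))
    X_train = np.vstack(X_train)
    y_train = np.concatenate(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValidationError("training set covers a single class")
    scaler = StandardScaler().fit(X_train)
    svm = SVC(kernel="rbf", gamma=gamma, C=C, decision_function_shape="ovo",
              random_state=seed)
    svm.fit(scaler.transform(X_train), y_train)
    nfeat, ny, nx = features.shape
    flat = features.reshape(nfeat, -1).T
    valid = np.all(np.isfinite(flat), axis=1)
    labels = np.full(flat.shape[0], -1, int)
    labels[valid] = svm.predict(scaler.transform(flat[valid]))
    return labels.reshape(ny, nx)


@dataclass
class ConfusionReport:
    """Ground-truth-percent confusion matrix with summary statistics."""

    classes: list[str]
    matrix_percent: np.ndarray     # column-normalised to 100 per truth class
    counts: np.ndarray
    row_totals_percent: np.ndarray  # share of all test pixels per predicted class
    overall_accuracy: float         # percent
    kappa: float


def confusion_metrics(pred: np.ndarray, regions: LabeledRegions) -> ConfusionReport:
    """Confusion matrix over the test regions, with OA (%) and kappa."""
    k = len(regions.classes)
    counts = np.zeros((k, k))     # rows: predicted, cols: truth
    for truth, name in enumerate(regions.classes):
        px = np.asarray(regions.test[name])
        if len(px) == 0:
            raise ValidationError(f"empty test class {name!r}")
        labels = pred[px[:, 0], px[:, 1]]
        for lab in labels:
            if lab < 0:
                raise ValidationError("unlabelled pixel in test region")
            counts[lab, truth] += 1
    total = counts.sum()
    col_sums = counts.sum(axis=0)
    matrix_percent = 100.0 * counts / col_sums
    row_totals = 100.0 * counts.sum(axis=1) / total
    po = np.trace(counts) / total
    pe = float(counts.sum(axis=1) @ counts.sum(axis=0)) / total ** 2
    kappa = (po - pe) / (1.0 - pe) if pe < 1 else 1.0
    return ConfusionReport(classes=list(regions.classes),
                           matrix_percent=matrix_percent, counts=counts,
                           row_totals_percent=row_totals,
                           overall_accuracy=100.0 * po, kappa=float(kappa))


@dataclass
class TruthReconstruction:
    proportions_percent: np.ndarray
    implied_oa: float
    residual: float
    consistent: bool


def reconstruct_truth_proportions(matrix_percent: np.ndarray,
                                  row_totals_percent: np.ndarray,
                                  tol: float = 1.0) -> TruthReconstruction:
    """Invert a published column-normalised confusion matrix.

    Given the ground-truth-percent matrix ``M`` (columns sum to ~100) and
    the "% of Total" row shares ``r``, solves ``M·t/100 = r`` for the
    truth-class proportions ``t`` and reports the implied overall accuracy
    ``Σ_j M_jj·t_j/100``.  A residual above ``tol`` (percent) flags the
    published table as internally inconsistent.
    """
    M = np.asarray(matrix_percent, float)
    r = np.asarray(row_totals_percent, float)
    if M.shape[0] != M.shape[1] or M.shape[0] != r.size:
        raise ValidationError("matrix and row totals are not conformable")
    try:
        t = np.linalg.solve(M / 100.0, r)
    except np.linalg.LinAlgError as e:
        raise ValidationError(f"singular reconstruction system: {e}")
    residual = float(np.abs(t.sum() - 100.0))
    implied_oa = float(np.diag(M) @ t / 100.0)
    return TruthReconstruction(proportions_percent=t, implied_oa=implied_oa,
                               residual=residual, consistent=residual <= tol)
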