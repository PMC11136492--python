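"""Multivariate decoding of block amplitudes with permutation inference.

The decoder is a two-class maximum-likelihood Gaussian classifier with a
diagonal covariance pooled across classes (a diagonal linear discriminant,
equivalent to Gaussian naive Bayes with shared per-feature variance and
equal priors).  Features are per-voxel block betas; before decoding,
voxels are restricted to the top 50th percentile of GLM R² and z-scored.
Accuracy is assessed by leave-one-run-out cross-validation, and its
significance by a permutation test in which block labels are shuffled
within each run and the whole cross-validation is repeated (1000 times by
default); observed accuracy above the 95th percentile of the null counts
as significant (one-tailed p < 0.05).

R² selection and z-scoring are computed on the training folds only, so no
information flows from the held-out run into the trained model.  The
permissive whole-session variant can be requested with
``selection_scope="session"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .design import ConditionLabel
from .glm import BetaMatrix

__all__ = [
    "ClassifierModel",
    "DecodingResult",
    "select_top_r2",
    "zscore_features",
    "fit_diag_gaussian",
    "loro_cv",
    "illusion_decoding",
    "path_decoding",
    "permutation_null",
    "illusion_permutation_null",
    "permute_labels_within_runs",
]


@dataclass
class ClassifierModel:
    """Fitted two-class diagonal-Gaussian (pooled variance) classifier."""

    classes: tuple
    class_means: np.ndarray  # 2 x features
    pooled_var: np.ndarray  # features

    def log_ratio(self, X: np.ndarray) -> np.ndarray:
        """Log posterior ratio class0 vs class1 (equal priors).

        For pooled diagonal covariance this reduces to the linear score
        sum_f (mu0 - mu1) * (x - (mu0 + mu1)/2) / var.
        """
        d = self.class_means[0] - self.class_means[1]
        mid = (self.class_means[0] + self.class_means[1]) / 2.0
        return (X - mid) @ (d / self.pooled_var)

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.log_ratio(np.atleast_2d(X))
        out = np.empty(scores.size, dtype=object)
        out[scores >= 0] = self.classes[0]
        out[scores < 0] = self.classes[1]
        return out


@dataclass
class DecodingResult:
    """Cross-validated accuracy with its permutation null distribution."""

    accuracy: float
    null_accuracies: np.ndarray
    threshold_95: float
    p_value: float
    n_exemplars: int = 0

    @property
    def significant(self) -> bool:
        return self.accuracy > self.threshold_95

    def to_json(self, path=None) -> str:
        payload = {
            "accuracy": self.accuracy,
            "threshold_95": self.threshold_95,
            "p_value": self.p_value,
            "significant": bool(self.significant),
            "n_exemplars": int(self.n_exemplars),
            "null_accuracies": np.asarray(self.null_accuracies).tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def select_top_r2(
    betas: BetaMatrix,
    percentile: float = 50.0,
    fit_runs=None,
) -> np.ndarray:
    """Indices of voxels with GLM R² at or above the given percentile.

    ``fit_runs`` restricts the R² computation to a subset of runs (the
    training folds) to avoid leaking test-run fit quality into voxel
    selection.  Voxels exactly at the percentile are retained, so equal R²
    everywhere keeps every voxel.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    r2 = betas.r2(fit_runs)
    cut = np.percentile(r2, percentile)
    idx = np.flatnonzero(r2 >= cut)
    if idx.size < 2:
        raise ValueError("fewer than 2 voxels survive R^2 selection")
    return idx


def zscore_features(train: np.ndarray, test: np.ndarray):
    """Z-score columns of train and test using training mean/SD (ddof=1).

    Features with zero training SD carry no training information and are
    dropped from both sets, with a warning.
    """
    train = np.asarray(train, dtype=float)
    test = np.atleast_2d(np.asarray(test, dtype=float))
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training exemplars to z-score")
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {np.count_nonzero(~keep)} features with zero training SD",
            stacklevel=2,
        )
    return (train[:, keep] - mu[keep]) / sd[keep], (test[:, keep] - mu[keep]) / sd[keep]


def fit_diag_gaussian(train: np.ndarray, labels) -> ClassifierModel:
    """Fit the two-class pooled-diagonal-covariance Gaussian classifier."""
    train = np.asarray(train, dtype=float)
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels), key=str)
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {classes}")
    # elementwise equality (numpy == against a str-enum scalar misfires)
    masks = [np.array([l == c for l in labels]) for c in classes]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("each class needs at least 2 training exemplars")
    means = np.stack([train[m].mean(axis=0) for m in masks])
    # variance pooled across classes: within-class SS / (N - 2)
    ss = sum(((train[m] - means[i]) ** 2).sum(axis=0) for i, m in enumerate(masks))
    pooled = ss / (train.shape[0] - 2)
    if np.any(pooled <= 0):
        raise ValueError("pooled variance must be positive for every feature")
    return ClassifierModel(tuple(classes), means, pooled)


def _pair_mask(condition: np.ndarray, pair) -> np.ndarray:
    return np.isin(condition, np.array(list(pair), dtype=object))


def _loro_accuracy(
    betas: BetaMatrix,
    labels: np.ndarray,
    pair,
    percentile: float,
    selection_scope: str,
) -> float:
    """Leave-one-run-out accuracy for a given label assignment.

    ``labels`` is the full per-block label array (possibly permuted);
    blocks whose label is outside ``pair`` are ignored.
    """
    in_pair = _pair_mask(labels, pair)
    correct = 0
    total = 0
    for run in betas.run_ids:
        test_mask = in_pair & (betas.run_id == run)
        train_mask = in_pair & (betas.run_id != run)
        if not test_mask.any():
            continue
        if len(set(labels[test_mask])) < 2:
            warnings.warn(
                f"run {run!r} is missing one class of {pair}; skipped as test fold",
                stacklevel=2,
            )
            continue
        train_labels = labels[train_mask]
        if len(set(train_labels)) < 2:
            raise ValueError(f"a training fold is missing one class of {pair}")
        fit_runs = None if selection_scope == "session" else [r for r in betas.run_ids if r != run]
        vox = select_top_r2(betas, percentile, fit_runs)
        Xtr = betas.betas[vox][:, train_mask].T
        Xte = betas.betas[vox][:, test_mask].T
        Xtr, Xte = zscore_features(Xtr, Xte)
        model = fit_diag_gaussian(Xtr, train_labels)
        pred = model.predict(Xte)
        correct += int(np.sum(pred == labels[test_mask]))
        total += int(test_mask.sum())
    if total == 0:
        raise ValueError("no test exemplars found for the pair")
    return correct / total


def loro_cv(
    betas: BetaMatrix,
    pair,
    percentile: float = 50.0,
    selection_scope: str = "train",
) -> float:
    """Leave-one-run-out cross-validated accuracy for a condition pair.

    For each run: voxels are selected by training-fold R², features
    z-scored with training statistics, the classifier fit on all other
    runs' blocks, and the held-out run's blocks decoded.  Returns the
    pooled fraction correct over all held-out blocks.
    """
    if len(betas.run_ids) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    return _loro_accuracy(betas, betas.condition, pair, percentile, selection_scope)


def illusion_decoding(betas: BetaMatrix, control: ConditionLabel | None = None, **kw) -> float:
    """Illusion-vs-control accuracy: mean of left-vs-control and
    right-vs-control pairwise decodes."""
    if control is None:
        present = set(betas.condition)
        if ConditionLabel.NO_ILLUSION in present:
            control = ConditionLabel.NO_ILLUSION
        else:
            raise ValueError("no control condition present; pass `control`")
    left = loro_cv(betas, (ConditionLabel.LEFT_ILLUSION, control), **kw)
    right = loro_cv(betas, (ConditionLabel.RIGHT_ILLUSION, control), **kw)
    return (left + right) / 2.0


def path_decoding(betas: BetaMatrix, **kw) -> float:
    """Leftward-vs-rightward illusory drift path accuracy."""
    return loro_cv(
        betas, (ConditionLabel.LEFT_ILLUSION, ConditionLabel.RIGHT_ILLUSION), **kw
    )


def permute_labels_within_runs(
    condition: np.ndarray, run_id: np.ndarray, pair, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle the pair's block labels independently within each run."""
    labels = condition.copy()
    in_pair = _pair_mask(condition, pair)
    for run in np.unique(run_id):
        idx = np.flatnonzero(in_pair & (run_id == run))
        labels[idx] = labels[rng.permutation(idx)]
    return labels


def permutation_null(
    betas: BetaMatrix,
    pair,
    n_perm: int = 1000,
    seed: int = 0,
    percentile: float = 50.0,
    selection_scope: str = "train",
) -> DecodingResult:
    """Permutation test of leave-one-run-out decoding for a pair.

    Block labels are permuted within each run (preserving per-run class
    counts) and the full cross-validation is repeated ``n_perm`` times.
    The accuracy threshold is the null's 95th percentile;
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable 95th percentile", stacklevel=2)
    observed = _loro_accuracy(betas, betas.condition, pair, percentile, selection_scope)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        labels = permute_labels_within_runs(betas.condition, betas.run_id, pair, rng)
        null[i] = _loro_accuracy(betas, labels, pair, percentile, selection_scope)
    threshold = float(np.percentile(null, 95))
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    n_ex = int(_pair_mask(betas.condition, pair).sum())
    return DecodingResult(
        accuracy=float(observed),
        null_accuracies=null,
        threshold_95=threshold,
        p_value=float(p),
        n_exemplars=n_ex,
    )


def illusion_permutation_null(
    betas: BetaMatrix,
    control: ConditionLabel | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    percentile: float = 50.0,
    selection_scope: str = "train",
) -> DecodingResult:
    """Permutation test for the averaged illusion-vs-control accuracy.

    The statistic is the mean of the left-vs-control and right-vs-control
    pairwise accuracies; each permutation shuffles both pairs' labels
    within runs and recomputes the averaged accuracy.
    """
    if control is None:
        present = set(betas.condition)
        if ConditionLabel.NO_ILLUSION in present:
            control = ConditionLabel.NO_ILLUSION
        else:
            raise ValueError("no control condition present; pass `control`")
    pairs = [
        (ConditionLabel.LEFT_ILLUSION, control),
        (ConditionLabel.RIGHT_ILLUSION, control),
    ]

    def stat(labels):
        return np.mean(
            [_loro_accuracy(betas, labels, p, percentile, selection_scope) for p in pairs]
        )

    observed = stat(betas.condition)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        labels = betas.condition.copy()
        for p in pairs:
            labels = permute_labels_within_runs(labels, betas.run_id, p, rng)
        null[i] = stat(labels)
    threshold = float(np.percentile(null, 95))
    pv = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    n_ex = int(
        np.sum([_pair_mask(betas.condition, p).sum() for p in pairs])
    )
    return DecodingResult(
        accuracy=float(observed),
        null_accuracies=null,
        threshold_95=threshold,
        p_value=float(pv),
        n_exemplars=n_ex,
    )
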