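"""Linear SVM classification with leave-one-out cross-validation and
Monte-Carlo permutation inference.

The classifier is a hard-default linear SVM (C = 1) over raw, unscaled
features: the downstream weight-map thresholding uses an absolute-weight
cutoff, which is only meaningful on the original feature scale.  Per-fold
z-scoring (fit on the training fold) is available as a config option.

The permutation p-value is the fraction of label shuffles whose LOO
accuracy meets or exceeds the observed accuracy, reported as ``k/B``; the
identity labeling is not included in the count.  The bias-corrected
``(k+1)/(B+1)`` estimator is reported alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "SvmConfig",
    "PermutationConfig",
    "CVResult",
    "loo_cv",
    "classification_metrics",
    "permutation_pvalue",
]

logger = logging.getLogger(__name__)

# Fast path for the LOO / permutation inner loop: call the libsvm training
# routine directly, skipping the per-call input validation of the SVC
# wrapper (the permutation test refits the identical small problem tens of
# thousands of times).  The solver, and hence every prediction, is the same;
# equivalence with SVC is asserted in the test suite and the SVC path
# remains as fallback.
try:  # pragma: no cover - import guard
    from sklearn.svm import _libsvm as _libsvm_mod

    _libsvm_mod.set_verbosity_wrap(0)
except Exception:  # pragma: no cover
    _libsvm_mod = None


def _libsvm_decision(X_train: np.ndarray, codes: np.ndarray, x_test: np.ndarray,
                     C: float) -> float:
    """Raw libsvm decision value for one held-out sample (linear kernel).

    ``codes`` are class codes {0.0, 1.0}; a positive decision value votes
    for code 0 (libsvm's internal ordering, verified against SVC)."""
    out = _libsvm_mod.fit(X_train, codes, svm_type=0, kernel="linear", C=C)
    support_vectors, sv_coef, intercept = out[1], out[3], out[4]
    w = sv_coef.ravel() @ support_vectors
    return float(x_test @ w + intercept[0])


@dataclass(frozen=True)
class SvmConfig:
    """Linear SVM settings; the kernel is always linear."""

    C: float = 1.0
    scaling: str = "none"  # "none" | "zscore" (fit within training fold)

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.scaling not in ("none", "zscore"):
            raise ValueError(f"unknown scaling mode {self.scaling!r}")


@dataclass(frozen=True)
class PermutationConfig:
    """Monte-Carlo permutation settings; the statistic is LOO accuracy."""

    n_shuffles: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")


@dataclass
class CVResult:
    """Held-out predictions and derived classification metrics.

    All metrics are fractions in [0, 1]; multiply by 100 for the
    percentage form used in reporting.  ``permutation_k`` counts shuffles
    with accuracy >= observed, so ``permutation_p = k/B``.
    """

    predictions: np.ndarray
    labels: np.ndarray
    positive_class: str
    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    n_pos: int
    n_neg: int
    permutation_k: int | None = None
    permutation_B: int | None = None
    permutation_p: float | None = None
    permutation_p_corrected: float | None = None
    permutation_seed: int | None = None

    def as_row(self) -> dict:
        """One flat dict matching the exported results-CSV schema."""
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "k": self.permutation_k,
            "B": self.permutation_B,
            "p": self.permutation_p,
            "p_corrected": self.permutation_p_corrected,
            "seed": self.permutation_seed,
        }


def _fit_predict_one(X_train, codes_train, x_test, config: SvmConfig,
                     use_fast_path: bool) -> int:
    """Fit a linear SVM on one training fold; return the predicted class code.

    Codes are 0/1 in sorted-class order.  An exact-zero decision value (a
    fully symmetric degenerate problem) resolves to code 0, the first class
    in the documented sorted ordering, and is logged.
    """
    if config.scaling == "zscore":
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        X_train = (X_train - mu) / sd
        x_test = (x_test - mu) / sd
    present = np.unique(codes_train)
    if present.size == 1:
        # degenerate fold at tiny n: majority (only) class of the training fold
        logger.warning("degenerate one-class training fold; predicting code %d",
                       int(present[0]))
        return int(present[0])
    if use_fast_path and _libsvm_mod is not None:
        dec = _libsvm_decision(np.ascontiguousarray(X_train, dtype=np.float64),
                               codes_train, x_test, config.C)
        if dec == 0.0:
            logger.warning("tied SVM decision; resolving to the first class")
            return 0
        return 0 if dec > 0 else 1
    clf = SVC(kernel="linear", C=config.C)
    clf.fit(X_train, codes_train)
    return int(clf.predict(x_test[None, :])[0])


def loo_cv(
    features: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    config: SvmConfig | None = None,
    positive_class: str | None = None,
    use_fast_path: bool = True,
) -> CVResult:
    """Leave-one-out cross-validated linear SVM.

    Fold *i* holds out sample *i*, fits on the rest, and records the
    held-out prediction; metrics are computed from the n held-out
    predictions.  With ``scaling='none'`` the procedure is fully
    deterministic.  ``use_fast_path=False`` forces the SVC code path
    (identical solver, slower per fold).
    """
    config = config or SvmConfig()
    X = np.ascontiguousarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels have different sample counts")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 samples per class")
    codes = (y == classes[1]).astype(np.float64)  # classes[0] -> 0, classes[1] -> 1
    n = X.shape[0]
    pred_codes = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        pred_codes[i] = _fit_predict_one(X[mask], codes[mask], X[i], config,
                                         use_fast_path)
        mask[i] = True
    preds = classes[pred_codes]
    if positive_class is None:
        positive_class = str(classes[0])
    m = classification_metrics(preds, y, positive_class)
    return CVResult(
        predictions=preds,
        labels=y,
        positive_class=positive_class,
        **m,
    )


def classification_metrics(
    predictions: Sequence | np.ndarray,
    labels: Sequence | np.ndarray,
    positive_class,
) -> dict:
    """Accuracy, sensitivity, specificity, and balanced accuracy.

    Sensitivity is the recall of the positive class, specificity the recall
    of the negative class, and balanced accuracy their arithmetic mean.
    A zero-denominator metric (no samples of one class) is NaN with a
    warning.
    """
    pred = np.asarray(predictions)
    y = np.asarray(labels)
    if pred.shape != y.shape:
        raise ValueError("predictions and labels must be aligned")
    classes = set(np.unique(y).tolist()) | set(np.unique(pred).tolist())
    if len(classes) > 2:
        raise ValueError(f"expected two classes, got {sorted(map(str, classes))}")
    pos = y == positive_class
    neg = ~pos
    tp = int(np.sum(pred[pos] == positive_class))
    tn = int(np.sum(pred[neg] != positive_class))
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    accuracy = (tp + tn) / y.size
    if n_pos == 0:
        warnings.warn("no positive samples; sensitivity undefined", stacklevel=2)
        sensitivity = float("nan")
    else:
        sensitivity = tp / n_pos
    if n_neg == 0:
        warnings.warn("no negative samples; specificity undefined", stacklevel=2)
        specificity = float("nan")
    else:
        specificity = tn / n_neg
    balanced = (sensitivity + specificity) / 2.0
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "balanced_accuracy": balanced,
        "n_pos": n_pos,
        "n_neg": n_neg,
    }


def permutation_pvalue(
    features: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    svm_config: SvmConfig | None = None,
    perm_config: PermutationConfig | None = None,
    observed: CVResult | None = None,
) -> CVResult:
    """Monte-Carlo permutation test on the LOO accuracy.

    Shuffles are whole-label-vector permutations (class sizes preserved by
    construction), drawn from a seeded generator.  Returns the observed
    :class:`CVResult` with the permutation fields filled in:
    ``p = k/B`` where ``k`` counts shuffles with accuracy >= observed, plus
    the bias-corrected ``(k+1)/(B+1)``.
    """
    svm_config = svm_config or SvmConfig()
    perm_config = perm_config or PermutationConfig()
    y = np.asarray(labels)
    if observed is None:
        observed = loo_cv(features, y, svm_config)
    rng = np.random.default_rng(perm_config.seed)
    B = perm_config.n_shuffles
    k = 0
    for _ in range(B):
        y_perm = rng.permutation(y)
        res = loo_cv(features, y_perm, svm_config,
                     positive_class=observed.positive_class)
        if res.accuracy >= observed.accuracy:
            k += 1
    observed.permutation_k = k
    observed.permutation_B = B
    observed.permutation_p = k / B
    observed.permutation_p_corrected = (k + 1) / (B + 1)
    observed.permutation_seed = perm_config.seed
    return observed
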