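"""Performance and parameter-recovery metrics.

Accuracy is averaged over simulation runs with its (S-1)-denominator
standard deviation. Parameter recovery uses the mean over classes of the
Euclidean distance between true and estimated class means, and the mean
over classes of the Frobenius norm of the covariance differences. For the
three-class lesion problem, collapsing adenoma and serrated adenoma into a
single "malignant" class yields standard binary confusion-matrix metrics.
"""

from __future__ import annotations

import logging
import math

import numpy as np

logger = logging.getLogger(__name__)


def accuracy_mean_sd(per_run: np.ndarray) -> tuple[float, float]:
    """Mean accuracy over runs and its sample (S-1) standard deviation.

    With a single run the SD is undefined and reported as NaN.
    """
    per_run = np.asarray(per_run, dtype=float)
    if per_run.size == 0:
        raise ValueError("no accuracy values supplied")
    mean = float(per_run.mean())
    sd = float(per_run.std(ddof=1)) if per_run.size > 1 else math.nan
    return mean, sd


def mean_param_error(true_means: np.ndarray, est_means: np.ndarray) -> float:
    """Mean over classes of the Euclidean distance ||mu_g - mu_hat_g||.

    The distance is the plain norm, not its square: on well-specified
    simulated data the per-class error is then Rayleigh-distributed with
    mean ~ sqrt(pi / (2 n_g)), matching the reported benchmark scale.
    """
    true_means = np.atleast_2d(np.asarray(true_means, dtype=float))
    est_means = np.atleast_2d(np.asarray(est_means, dtype=float))
    if true_means.shape != est_means.shape:
        raise ValueError(f"shape mismatch: {true_means.shape} vs {est_means.shape}")
    return float(np.linalg.norm(true_means - est_means, axis=1).mean())


def cov_frobenius_error(true_covs: np.ndarray, est_covs: np.ndarray) -> float:
    """Mean over classes of the Frobenius norm ||Sigma_g - Sigma_hat_g||_F."""
    true_covs = np.asarray(true_covs, dtype=float)
    est_covs = np.asarray(est_covs, dtype=float)
    if true_covs.shape != est_covs.shape:
        raise ValueError(f"shape mismatch: {true_covs.shape} vs {est_covs.shape}")
    if true_covs.ndim == 2:
        true_covs, est_covs = true_covs[None], est_covs[None]
    diff = true_covs - est_covs
    return float(np.sqrt((diff ** 2).sum(axis=(1, 2))).mean())


def binary_collapse_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                            positive_classes: set[int] | frozenset[int],
                            ) -> dict[str, float]:
    """Sensitivity, NPV, specificity and precision after collapsing classes.

    Classes in ``positive_classes`` map to positive (e.g. the malignant
    lesion types), the remainder to negative. Ratios with a zero denominator
    are reported as NaN with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted labels differ in length")
    positive_classes = set(int(c) for c in positive_classes)
    observed = set(np.unique(np.concatenate([y_true, y_pred])).tolist())
    unknown = positive_classes - observed
    if not positive_classes:
        raise ValueError("positive_classes must be nonempty")
    if unknown and not positive_classes & observed:
        raise ValueError(f"positive classes {sorted(unknown)} never occur in the labels")

    t_pos = np.isin(y_true, list(positive_classes))
    p_pos = np.isin(y_pred, list(positive_classes))
    tp = int(np.sum(t_pos & p_pos))
    fn = int(np.sum(t_pos & ~p_pos))
    tn = int(np.sum(~t_pos & ~p_pos))
    fp = int(np.sum(~t_pos & p_pos))

    def ratio(num, den, name):
        if den == 0:
            logger.warning("%s has a zero denominator; reported as NaN", name)
            return math.nan
        return num / den

    return {
        "sensitivity": ratio(tp, tp + fn, "sensitivity"),
        "npv": ratio(tn, tn + fn, "NPV"),
        "specificity": ratio(tn, tn + fp, "specificity"),
        "precision": ratio(tp, tp + fp, "precision"),
    }


def agreement_matrix(Y: np.ndarray, y_true: np.ndarray,
                     G: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Annotator-vs-truth agreement heatmap data.

    Returns ``(A, acc)`` where ``A[m, g]`` is the fraction of units with
    true class g+1 that annotator m labeled g+1 (NaN with a warning if the
    class never occurs), and ``acc[m]`` is annotator m's overall accuracy.
    """
    Y = np.asarray(Y, dtype=int)
    y_true = np.asarray(y_true, dtype=int)
    if Y.ndim != 2 or Y.shape[0] != len(y_true):
        raise ValueError("Y must be N x M with one row per unit in y_true")
    N, M = Y.shape
    G = int(G if G is not None else max(Y.max(), y_true.max()))
    A = np.full((M, G), math.nan)
    for g in range(1, G + 1):
        idx = y_true == g
        if not idx.any():
            logger.warning("class %d absent from the ground truth; agreement "
                           "entries reported as NaN", g)
            continue
        A[:, g - 1] = (Y[idx] == g).mean(axis=0)
    acc = (Y == y_true[:, None]).mean(axis=0)
    return A, acc
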