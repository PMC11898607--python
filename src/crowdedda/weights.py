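"""The six annotator-weighting strategies.

Weights live on the M-simplex and control each annotator's contribution to
the stacked parameters. Two strategies use a priori information (PGT scores
against a known-truth subset; EN splits a fixed weight mass across declared
expertise tiers), the rest are data-driven (equal weights; majority-vote
agreement scoring with a deadlock-aware threshold; and two iterative
schemes that alternate scoring against the current ensemble labels with
re-stacking, using hard agreement counts or posterior-probability scores).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .ensemble import WeightVector, ensemble_loglik, ensemble_predict, stack
from .models import ClassifierParams, posterior

logger = logging.getLogger(__name__)

#: Sentinel for "no reference label available" (majority-vote deadlock or
#: below-threshold agreement). Reference rows equal to MISSING award no score.
MISSING: int = -1


def _as_label_matrix(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=int)
    if Y.ndim != 2:
        raise ValueError("annotator labels must be an N x M matrix")
    return Y


def score_against_reference(Y, ref) -> np.ndarray:
    """Integer agreement scores: s_m = #{n : ref_n != MISSING and Y_nm = ref_n}."""
    Y = _as_label_matrix(Y)
    ref = np.asarray(ref, dtype=int)
    if ref.shape != (Y.shape[0],):
        raise ValueError(f"reference has shape {ref.shape}, expected ({Y.shape[0]},)")
    mask = ref != MISSING
    return (Y[mask] == ref[mask, None]).sum(axis=0)


def rescale_scores(s, strategy: str = "user") -> WeightVector:
    """Normalize nonnegative scores to simplex weights, w_m = s_m / sum(s).

    A zero score total carries no information about any annotator, so the
    fallback is equal weights (with a warning) rather than dropping everyone.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("scores must be nonnegative")
    total = s.sum()
    if total == 0:
        logger.warning("all scores are zero; falling back to equal weights")
        return WeightVector(np.full(len(s), 1.0 / len(s)), s=s, strategy=strategy)
    return WeightVector(s / total, s=s, strategy=strategy)


def weights_pgt(Y2, y_true) -> WeightVector:
    """Partial-ground-truth weights: agreement counts on the known-truth subset."""
    Y2 = _as_label_matrix(Y2)
    y_true = np.asarray(y_true, dtype=int)
    if len(y_true) < 1:
        raise ValueError("PGT needs at least one unit with known ground truth")
    return rescale_scores(score_against_reference(Y2, y_true), strategy="PGT")


def weights_en(levels, tier_mass: dict[str, float] | None = None) -> WeightVector:
    """Expertise-tier weights: each tier's mass is split equally within the tier.

    Parameters
    ----------
    levels : sequence of tier labels per annotator, e.g.
        ``["expert", "expert", "novice"]``.
    tier_mass : total weight mass per tier, summing to 1. Default splits
        0.8 to ``"expert"`` and 0.2 to ``"novice"``.
    """
    levels = list(levels)
    if tier_mass is None:
        tier_mass = {"expert": 0.8, "novice": 0.2}
    if abs(sum(tier_mass.values()) - 1.0) > 1e-12:
        raise ValueError("tier masses must sum to 1")
    counts = {t: levels.count(t) for t in tier_mass}
    for tier, mass in tier_mass.items():
        if counts[tier] == 0 and mass > 0:
            raise ValueError(f"tier {tier!r} has positive mass but no annotators")
    unknown = set(levels) - set(tier_mass)
    if unknown:
        raise ValueError(f"annotator tiers {sorted(unknown)} have no declared mass")
    w = np.array([tier_mass[t] / counts[t] for t in levels])
    return WeightVector(w / w.sum(), strategy="EN")


def weights_equal(M: int) -> WeightVector:
    """Equal weights 1/M for all annotators."""
    if M < 1:
        raise ValueError("need at least one annotator")
    return WeightVector(np.full(M, 1.0 / M), strategy="E")


@dataclass
class MajorityLabels:
    """Per-unit majority labels with deadlock/threshold bookkeeping."""

    labels: np.ndarray          # (N,) labels in 1..G, or MISSING
    top_count: np.ndarray       # (N,) votes received by the top class
    tie: np.ndarray             # (N,) True where the top count was tied


def majority_labels(Y, agreement_threshold: float | None = None,
                    G: int | None = None) -> MajorityLabels:
    """Per-unit majority label, MISSING on deadlocks or weak agreement.

    A unit's majority label is the unique class with the most votes. Tied top
    counts are deadlocks (no label can be trusted). With an agreement
    threshold t in (0, 1], the top count must additionally reach
    ``ceil(t * M)`` votes; ``None`` means plain majority (any unique top).
    """
    Y = _as_label_matrix(Y)
    N, M = Y.shape
    G = int(G if G is not None else Y.max())
    if agreement_threshold is None:
        required = 1
    else:
        if not 0 < agreement_threshold <= 1:
            raise ValueError("agreement threshold must be in (0, 1]")
        required = math.ceil(agreement_threshold * M - 1e-9)
    counts = np.stack([(Y == g).sum(axis=1) for g in range(1, G + 1)], axis=1)
    order = np.sort(counts, axis=1)
    top = order[:, -1]
    tie = (counts.shape[1] > 1) & (order[:, -2] == top)
    labels = np.argmax(counts, axis=1) + 1
    labels = np.where(tie | (top < required), MISSING, labels)
    return MajorityLabels(labels=labels, top_count=top, tie=np.asarray(tie))


def weights_mv(Y, agreement_threshold: float | None = None,
               G: int | None = None) -> WeightVector:
    """Majority-vote weights: agreement counts with the per-unit majority labels."""
    mv = majority_labels(Y, agreement_threshold, G=G)
    return rescale_scores(score_against_reference(Y, mv.labels), strategy="MV")


def soft_scores(Y, ref, posteriors: np.ndarray) -> np.ndarray:
    """Posterior-probability scores gated by label agreement (ItAlg2 scoring).

    ``s_m = sum_n z_m[n, ref_n] * 1(Y_nm == ref_n)`` over units with a
    non-MISSING reference, where ``z_m`` is annotator m's base-learner
    posterior matrix. An annotator whose label disagrees with the reference
    earns nothing for that unit regardless of confidence.
    """
    Y = _as_label_matrix(Y)
    ref = np.asarray(ref, dtype=int)
    N, M = Y.shape
    if posteriors.shape[0] != M or posteriors.shape[1] != N:
        raise ValueError("posteriors must have shape (M, N, G)")
    mask = ref != MISSING
    agree = Y[mask] == ref[mask, None]                    # (N', M)
    z_at_ref = posteriors[:, mask, :][:, np.arange(mask.sum()), ref[mask] - 1]  # (M, N')
    return (agree.T * z_at_ref).sum(axis=1)


@dataclass
class IterativeResult:
    """Output of the iterative reweighting loop."""

    weights: WeightVector
    labels: np.ndarray
    n_iterations: int
    converged: bool


def iterative_weights(X, Y, base: list[ClassifierParams], variant: int = 1,
                      max_iter: int = 100,
                      init_threshold: float | None = None) -> IterativeResult:
    """Iterative annotator reweighting (ItAlg1 hard / ItAlg2 soft scores).

    Starting from majority-vote labels, each iteration scores every
    annotator against the current estimated labels, rescales the scores to
    weights, re-stacks the (fixed) base learners and relabels all units by
    the MAP rule; the loop stops when the labels repeat on consecutive
    iterations or the iteration cap is hit. ``max_iter=0`` returns the
    weights scored against the initial majority-vote labels.

    Variant 1 scores hard agreement counts; variant 2 scores the annotator's
    base-learner posterior at the estimated label, gated by agreement.
    Majority-vote deadlocks at initialization resolve to the lowest tied
    class index; if the label sequence cycles without converging, the state
    with the higher ensemble log-likelihood is returned with
    ``converged=False``.
    """
    if variant not in (1, 2):
        raise ValueError("variant must be 1 (hard scores) or 2 (soft scores)")
    if max_iter < 0:
        raise ValueError("max_iter must be >= 0")
    X = np.asarray(X, dtype=float)
    Y = _as_label_matrix(Y)
    N, M = Y.shape
    if len(base) != M:
        raise ValueError(f"{M} annotators but {len(base)} base learners")
    G = base[0].G

    mv = majority_labels(Y, init_threshold, G=G)
    y_hat = mv.labels.copy()
    if np.any(y_hat == MISSING):
        # deadlocked units: lowest class index among the tied top classes
        counts = np.stack([(Y == g).sum(axis=1) for g in range(1, G + 1)], axis=1)
        fallback = np.argmax(counts == counts.max(axis=1, keepdims=True), axis=1) + 1
        y_hat = np.where(y_hat == MISSING, fallback, y_hat)

    posteriors = None
    if variant == 2:
        posteriors = np.stack([posterior(b, X) for b in base])  # (M, N, G)

    def score(ref):
        if variant == 1:
            return score_against_reference(Y, ref)
        return soft_scores(Y, ref, posteriors)

    tag = f"ItAlg{variant}"
    seen: dict[bytes, int] = {y_hat.tobytes(): 0}
    best_state = None

    w = rescale_scores(score(y_hat), strategy=tag)
    for t in range(1, max_iter + 1):
        ens = stack(base, w)
        _, y_new = ensemble_predict(ens, X)
        if np.array_equal(y_new, y_hat):
            return IterativeResult(weights=w, labels=y_hat, n_iterations=t,
                                   converged=True)
        key = y_new.tobytes()
        ll_new = ensemble_loglik(ens, X)
        if best_state is None or ll_new > best_state[0]:
            best_state = (ll_new, w, y_new)
        if key in seen:
            logger.warning("iterative reweighting entered a cycle at iteration %d; "
                           "returning the highest-likelihood state", t)
            _, w_best, y_best = best_state
            return IterativeResult(weights=w_best, labels=y_best,
                                   n_iterations=t, converged=False)
        seen[key] = t
        y_hat = y_new
        w = rescale_scores(score(y_hat), strategy=tag)

    return IterativeResult(weights=w, labels=y_hat, n_iterations=max_iter,
                           converged=False if max_iter > 0 else True)
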