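"""Stacking base learners by convex parameter averaging.

The ensemble classifier's priors, means and covariances are annotator-
weighted averages of the base learners' fitted parameters:

    tau_g  = sum_m w_m tau_mg
    mu_g   = sum_m w_m mu_mg
    Sigma_g = sum_m w_m Sigma_mg

Averaging acts on the realized parameter values, so base learners may carry
heterogeneous covariance model codes; note that even when every base learner
has equal covariances across classes (EEE), the stacked Sigma_g generally
differ across classes -- the all-equality constraint is not re-imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import ClassifierParams, posterior, predict_map


@dataclass
class WeightVector:
    """Annotator weights on the M-simplex plus the raw scores behind them."""

    w: np.ndarray
    s: np.ndarray | None = None
    strategy: str = "user"

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.s is not None:
            self.s = np.asarray(self.s, dtype=float)
        if self.w.ndim != 1 or len(self.w) < 1:
            raise ValueError("weights must be a nonempty 1-D vector")
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {self.w.sum()!r}")

    @property
    def M(self) -> int:
        return len(self.w)


@dataclass
class EnsembleParams:
    """Stacked classifier parameters (duck-compatible with ClassifierParams
    for posterior/MAP prediction)."""

    tau: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    weights: WeightVector
    source_models: list[str] = field(default_factory=list)

    @property
    def G(self) -> int:
        return self.means.shape[0]

    @property
    def p(self) -> int:
        return self.means.shape[1]


def stack(base: list[ClassifierParams], weights: WeightVector) -> EnsembleParams:
    """Convex combination of base-learner parameters under annotator weights.

    All base learners must share the class count G and dimension p. Zero
    weights are allowed: the corresponding learner contributes nothing.
    """
    if not isinstance(weights, WeightVector):
        weights = WeightVector(np.asarray(weights, dtype=float))
    if len(base) != weights.M:
        raise ValueError(f"{len(base)} base learners but {weights.M} weights")
    G, p = base[0].G, base[0].p
    for m, b in enumerate(base):
        if (b.G, b.p) != (G, p):
            raise ValueError(f"base learner {m + 1} has (G={b.G}, p={b.p}); "
                             f"expected (G={G}, p={p})")
    w = weights.w
    tau = np.einsum("m,mg->g", w, np.stack([b.tau for b in base]))
    means = np.einsum("m,mgp->gp", w, np.stack([b.means for b in base]))
    covs = np.einsum("m,mgij->gij", w, np.stack([b.covariances for b in base]))
    return EnsembleParams(tau=tau, means=means, covariances=covs,
                          weights=weights, source_models=[b.model for b in base])


def ensemble_predict(ens: EnsembleParams, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior matrix and MAP labels of the stacked classifier on X."""
    z = posterior(ens, X)
    labels = np.argmax(z, axis=1) + 1
    return z, labels


def ensemble_loglik(ens: EnsembleParams, X: np.ndarray) -> float:
    """Observed-data mixture log-likelihood sum_n log sum_g tau_g phi(x_n; g).

    Used to pick a state when the iterative reweighting cycles without
    converging; not an inferential quantity of the stacking procedure itself.
    """
    from scipy.special import logsumexp

    from .models import _class_log_densities

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    log_dens = _class_log_densities(ens.tau, ens.means, ens.covariances, X)
    return float(logsumexp(log_dens, axis=1).sum())
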