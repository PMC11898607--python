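"""Independent oracles used by the test suite.

These deliberately avoid the library's fitting code paths: the constrained
ML fits are checked against a generic numerical likelihood maximizer over
an explicit volume/shape/orientation parameterization (p=2 only, where the
orientation is a single rotation angle per class), and the pooled-covariance
linear discriminant rule is reproduced from its closed-form linear scores.
"""

import numpy as np
from scipy.optimize import minimize

from crowdedda.models import _class_log_densities


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _build_sigmas(code: str, params: np.ndarray, G: int) -> np.ndarray:
    """Assemble (G,2,2) covariances from a free-parameter vector for `code`."""
    i = 0
    n_lam = G if code[0] == "V" else 1
    lam = np.exp(params[i:i + n_lam]); i += n_lam
    if code[1] == "I":
        A = [np.eye(2)] * G
    else:
        n_a = G if code[1] == "V" else 1
        a = np.exp(params[i:i + n_a]); i += n_a
        A = [np.diag([a[g % n_a], 1.0 / a[g % n_a]]) for g in range(G)]
    if code[2] == "I":
        D = [np.eye(2)] * G
    else:
        n_d = G if code[2] == "V" else 1
        th = params[i:i + n_d]; i += n_d
        D = [_rot(th[g % n_d]) for g in range(G)]
    return np.stack([lam[g % n_lam] * D[g] @ A[g] @ D[g].T for g in range(G)])


def _n_params(code: str, G: int) -> int:
    n = G if code[0] == "V" else 1
    if code[1] != "I":
        n += G if code[1] == "V" else 1
    if code[2] != "I":
        n += G if code[2] == "V" else 1
    return n


def numeric_ml_loglik(code: str, X: np.ndarray, y: np.ndarray,
                      n_restarts: int = 4) -> float:
    """Maximum joint log-likelihood under the model's constraint, found by
    multi-start Nelder-Mead over the explicit parameterization (p must be 2).

    Priors and means are profiled out at their unconstrained ML values,
    which maximize the likelihood irrespective of the covariance constraint.
    """
    assert X.shape[1] == 2, "oracle parameterization is for p=2 toys"
    G = int(y.max())
    n_g = np.array([(y == g).sum() for g in range(1, G + 1)])
    tau = n_g / len(y)
    means = np.stack([X[y == g].mean(axis=0) for g in range(1, G + 1)])

    def neg_loglik(params):
        try:
            sigmas = _build_sigmas(code, params, G)
            log_dens = _class_log_densities(tau, means, sigmas, X)
            return -float(log_dens[np.arange(len(y)), y - 1].sum())
        except np.linalg.LinAlgError:
            return 1e12

    best = np.inf
    for s in range(n_restarts):
        rng = np.random.default_rng(1000 + s)
        x0 = rng.normal(0.0, 0.6, _n_params(code, G))
        res = minimize(neg_loglik, x0, method="Nelder-Mead",
                       options=dict(maxiter=20000, maxfev=20000,
                                    xatol=1e-11, fatol=1e-11))
        best = min(best, res.fun)
    return -best


def lda_scores(X, y, Xnew):
    """Closed-form pooled-covariance linear discriminant scores.

    delta_g(x) = x' S^-1 mu_g - mu_g' S^-1 mu_g / 2 + log tau_g with the ML
    pooled covariance S = W/N; the argmax reproduces the EEE MAP rule.
    """
    G = int(y.max())
    N = len(y)
    n_g = np.array([(y == g).sum() for g in range(1, G + 1)])
    means = np.stack([X[y == g].mean(axis=0) for g in range(1, G + 1)])
    W = sum((X[y == g] - means[g - 1]).T @ (X[y == g] - means[g - 1])
            for g in range(1, G + 1))
    S = W / N
    Sinv = np.linalg.inv(S)
    scores = np.empty((len(Xnew), G))
    for g in range(G):
        mu = means[g]
        scores[:, g] = (Xnew @ Sinv @ mu - 0.5 * mu @ Sinv @ mu
                        + np.log(n_g[g] / N))
    return scores
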