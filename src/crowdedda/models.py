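"""Parsimonious Gaussian discriminant analysis (EDDA base learners).

Each class-conditional density is a multivariate Gaussian whose covariance
is eigendecomposed as ``Sigma_g = lambda_g * D_g @ A_g @ D_g.T`` with volume
``lambda_g > 0``, diagonal shape ``A_g`` (det 1) and orthogonal orientation
``D_g``. Constraining each factor to be equal (E) or variable (V) across
classes -- with diagonal (I) or spherical (II) special cases -- yields the
family of 14 covariance models, from the one-parameter spherical EII up to
the fully unconstrained VVV (quadratic discriminant analysis); EEE is the
classical pooled-covariance linear discriminant analysis.

Estimation is maximum likelihood with known labels. Models whose ML
estimate has a closed form use it; the remaining ones (VEI, VEE, EVE, VVE,
VEV) alternate closed-form updates of volume/shape with, where the
orientation is shared, a majorize-minimize step over the orthogonal group.
Model choice within the family is by BIC.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

#: Canonical order of the 14 covariance model codes (volume, shape, orientation).
MODEL_CODES: tuple[str, ...] = (
    "EII", "VII", "EEI", "VEI", "EVI", "VVI", "EEE",
    "VEE", "EVE", "VVE", "EEV", "VEV", "EVV", "VVV",
)

_ALIASES = {"LDA": "EEE", "QDA": "VVV", "EDDA": "EDDA"}

#: relative tolerance / iteration cap for the iterative ML fits
_ITER_TOL = 1e-8
_ITER_MAX = 200
_EIG_FLOOR = 1e-10


class SingularFitError(np.linalg.LinAlgError):
    """An ML covariance estimate is numerically singular even after the ridge floor."""


def resolve_model(name: str) -> str:
    """Resolve a model name or alias to a canonical code.

    ``LDA`` maps to ``EEE``, ``QDA`` to ``VVV``; ``EDDA`` is returned as-is
    and means "select among all 14 by BIC".
    """
    code = _ALIASES.get(name.upper(), name.upper())
    if code != "EDDA" and code not in MODEL_CODES:
        raise ValueError(f"unknown covariance model {name!r}; expected one of "
                         f"{MODEL_CODES} or aliases LDA/QDA/EDDA")
    return code


def cov_param_count(code: str, G: int, p: int) -> int:
    """Number of free covariance parameters of a model (standard parsimonious table)."""
    full = p * (p + 1) // 2
    counts = {
        "EII": 1,
        "VII": G,
        "EEI": p,
        "VEI": p + G - 1,
        "EVI": 1 + G * (p - 1),
        "VVI": G * p,
        "EEE": full,
        "VEE": full + G - 1,
        "EVE": full + (G - 1) * (p - 1),
        "VVE": full + (G - 1) * p,
        "EEV": G * full - (G - 1) * p,
        "VEV": G * full - (G - 1) * (p - 1),
        "EVV": G * full - (G - 1),
        "VVV": G * full,
    }
    return counts[code]


def n_free_params(code: str, G: int, p: int) -> int:
    """Total free parameters: (G-1) priors + G*p means + covariance parameters."""
    return (G - 1) + G * p + cov_param_count(code, G, p)


@dataclass
class ClassifierParams:
    """Fitted parameters of one Gaussian discriminant classifier.

    Attributes
    ----------
    tau : (G,) class prior probabilities, strictly positive, summing to 1.
    means : (G, p) class mean vectors.
    covariances : (G, p, p) class covariance matrices (symmetric PD).
    model : covariance model code actually fitted.
    loglik : joint log-likelihood of (X, y) at the ML estimate.
    n_free_params : free-parameter count used by BIC.
    bic : 2*loglik - n_free_params*log(N) (larger is better).
    class_counts : (G,) per-class sample sizes.
    """

    tau: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    model: str
    loglik: float
    n_free_params: int
    bic: float
    class_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def G(self) -> int:
        return self.means.shape[0]

    @property
    def p(self) -> int:
        return self.means.shape[1]


def volume_shape_orientation(sigma: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Decompose a PD matrix as ``lambda * D @ A @ D.T``.

    Returns volume ``lambda`` (positive scalar), shape ``A`` (diagonal matrix
    with unit determinant, eigenvalues descending) and orientation ``D``
    (orthogonal). Reconstruction ``lam * D @ A @ D.T`` recovers the input.
    """
    vals, vecs = np.linalg.eigh(sigma)
    vals, vecs = vals[::-1], vecs[:, ::-1]  # descending
    if vals[-1] <= 0:
        raise np.linalg.LinAlgError("matrix is not positive definite")
    lam = float(np.exp(np.mean(np.log(vals))))  # det(Sigma)^(1/p)
    return lam, np.diag(vals / lam), vecs


# ---------------------------------------------------------------------------
# ML covariance estimation per model
# ---------------------------------------------------------------------------

def _det_normalize_diag(d: np.ndarray) -> tuple[np.ndarray, float]:
    """Split a positive vector d into (shape with unit geometric mean, scale)."""
    scale = float(np.exp(np.mean(np.log(d))))
    return d / scale, scale


def _profile_deviance(W: np.ndarray, n_g: np.ndarray, sigmas: np.ndarray) -> float:
    """sum_g [ tr(W_g Sigma_g^-1) + n_g log det Sigma_g ]; the fits minimize this."""
    total = 0.0
    for g in range(len(n_g)):
        sign, logdet = np.linalg.slogdet(sigmas[g])
        total += float(np.trace(np.linalg.solve(sigmas[g], W[g]))) + n_g[g] * logdet
    return total

def _mm_orientation(D0, S_list, Ainv_list, n_iter=50, tol=1e-12):
    """Minimize sum_g tr(D Ainv_g D' S_g) over orthogonal D.

    Majorize-minimize: the objective is a convex quadratic in vec(D); on the
    orthogonal group (where ||D||_F^2 is constant) subtracting the largest
    eigenvalue of the Hessian leaves a concave function, majorized by its
    tangent plane. Each step minimizes a linear functional over the group,
    solved by an SVD (polar projection).
    """
    def objective(D):
        return sum(float(np.trace(D @ np.diag(Ainv) @ D.T @ S))
                   for S, Ainv in zip(S_list, Ainv_list))

    D = D0
    prev = objective(D)
    for _ in range(n_iter):
        F = np.zeros_like(D)
        for S, Ainv in zip(S_list, Ainv_list):
            kappa = float(np.linalg.eigvalsh(S)[-1]) * float(np.max(Ainv))
            F += 2.0 * (S @ D @ np.diag(Ainv) - kappa * D)
        U, _, Vt = np.linalg.svd(F)
        D = -U @ Vt
        cur = objective(D)
        if abs(prev - cur) <= tol * (abs(prev) + 1.0):
            break
        prev = cur
    return D


def _fit_cov(code: str, W: np.ndarray, n_g: np.ndarray, N: int, p: int) -> np.ndarray:
    """ML covariance estimates (G, p, p) for one model given class scatters W_g."""
    G = len(n_g)

    if code == "EEE":
        pooled = W.sum(axis=0) / N
        return np.broadcast_to(pooled, (G, p, p)).copy()

    if code == "VVV":
        return np.stack([W[g] / n_g[g] for g in range(G)])

    if code == "EII":
        lam = float(np.trace(W.sum(axis=0))) / (N * p)
        return np.broadcast_to(lam * np.eye(p), (G, p, p)).copy()

    if code == "VII":
        return np.stack([(np.trace(W[g]) / (n_g[g] * p)) * np.eye(p) for g in range(G)])

    if code == "EEI":
        d = np.diagonal(W.sum(axis=0)) / N
        return np.broadcast_to(np.diag(d), (G, p, p)).copy()

    if code == "VVI":
        return np.stack([np.diag(np.diagonal(W[g]) / n_g[g]) for g in range(G)])

    if code == "EVI":
        # per-class diagonal shape, common volume: closed form
        diags = [np.maximum(np.diagonal(W[g]), 1e-300) for g in range(G)]
        dets = [float(np.exp(np.mean(np.log(d)))) for d in diags]  # det^(1/p)
        lam = sum(dets) / N
        return np.stack([lam * np.diag(d / det) for d, det in zip(diags, dets)])

    if code == "EVV":
        # per-class full shape/orientation, common volume: closed form
        dets = []
        shapes = []
        for g in range(G):
            sign, logdet = np.linalg.slogdet(W[g])
            if sign <= 0:
                raise SingularFitError(f"class scatter singular for model EVV, class {g + 1}")
            det_root = math.exp(logdet / p)
            dets.append(det_root)
            shapes.append(W[g] / det_root)
        lam = sum(dets) / N
        return np.stack([lam * C for C in shapes])

    if code == "EEV":
        # common volume and shape, per-class orientation: closed form via
        # eigendecompositions of the class scatters (eigenvalues descending)
        omegas, vecs = [], []
        for g in range(G):
            vals, V = np.linalg.eigh(W[g])
            omegas.append(vals[::-1])
            vecs.append(V[:, ::-1])
        shared = np.sum(omegas, axis=0) / N
        return np.stack([V @ np.diag(shared) @ V.T for V in vecs])

    if code == "VEI":
        # variable volume, common diagonal shape
        lam = np.array([max(np.trace(W[g]), 1e-300) / (n_g[g] * p) for g in range(G)])
        prev = np.inf
        for _ in range(_ITER_MAX):
            b = np.sum([np.diagonal(W[g]) / lam[g] for g in range(G)], axis=0)
            B, _ = _det_normalize_diag(np.maximum(b, 1e-300))
            lam = np.array([float(np.sum(np.diagonal(W[g]) / B)) / (n_g[g] * p)
                            for g in range(G)])
            sigmas = np.stack([lam[g] * np.diag(B) for g in range(G)])
            cur = _profile_deviance(W, n_g, sigmas)
            if abs(prev - cur) <= _ITER_TOL * (abs(cur) + 1.0):
                break
            prev = cur
        return sigmas

    if code == "VEE":
        # variable volume, common shape and orientation (shared C = D A D')
        lam = np.array([max(np.trace(W[g]), 1e-300) / (n_g[g] * p) for g in range(G)])
        prev = np.inf
        for _ in range(_ITER_MAX):
            Craw = np.sum([W[g] / lam[g] for g in range(G)], axis=0)
            sign, logdet = np.linalg.slogdet(Craw)
            if sign <= 0:
                raise SingularFitError("pooled scatter singular for model VEE")
            C = Craw / math.exp(logdet / p)
            Cinv = np.linalg.inv(C)
            lam = np.array([float(np.trace(Cinv @ W[g])) / (n_g[g] * p) for g in range(G)])
            sigmas = np.stack([lam[g] * C for g in range(G)])
            cur = _profile_deviance(W, n_g, sigmas)
            if abs(prev - cur) <= _ITER_TOL * (abs(cur) + 1.0):
                break
            prev = cur
        return sigmas

    if code == "VEV":
        # variable volume and orientation, common shape; D_g are the
        # eigenvectors of W_g, small fixed point over (lambda_g, A)
        omegas, vecs = [], []
        for g in range(G):
            vals, V = np.linalg.eigh(W[g])
            omegas.append(np.maximum(vals[::-1], 1e-300))
            vecs.append(V[:, ::-1])
        lam = np.array([float(np.sum(omegas[g])) / (n_g[g] * p) for g in range(G)])
        prev = np.inf
        for _ in range(_ITER_MAX):
            a = np.sum([omegas[g] / lam[g] for g in range(G)], axis=0)
            A, _ = _det_normalize_diag(np.maximum(a, 1e-300))
            lam = np.array([float(np.sum(omegas[g] / A)) / (n_g[g] * p) for g in range(G)])
            sigmas = np.stack([lam[g] * vecs[g] @ np.diag(A) @ vecs[g].T
                               for g in range(G)])
            cur = _profile_deviance(W, n_g, sigmas)
            if abs(prev - cur) <= _ITER_TOL * (abs(cur) + 1.0):
                break
            prev = cur
        return sigmas

    if code in ("EVE", "VVE"):
        # common orientation D; shape per class; volume shared (EVE) or not (VVE)
        pooled = W.sum(axis=0)
        _, D = np.linalg.eigh(pooled)
        lam = np.array([max(np.trace(W[g]), 1e-300) / (n_g[g] * p) for g in range(G)])
        prev = np.inf
        sigmas = None
        for _ in range(_ITER_MAX):
            diags = [np.maximum(np.diagonal(D.T @ W[g] @ D), 1e-300) for g in range(G)]
            A = [_det_normalize_diag(d)[0] for d in diags]
            if code == "EVE":
                lam_shared = sum(float(np.sum(diags[g] / A[g])) for g in range(G)) / (N * p)
                lam = np.full(G, lam_shared)
            else:
                lam = np.array([float(np.sum(diags[g] / A[g])) / (n_g[g] * p)
                                for g in range(G)])
            S_list = [W[g] / lam[g] for g in range(G)]
            Ainv_list = [1.0 / A[g] for g in range(G)]
            D = _mm_orientation(D, S_list, Ainv_list)
            sigmas = np.stack([lam[g] * D @ np.diag(A[g]) @ D.T for g in range(G)])
            cur = _profile_deviance(W, n_g, sigmas)
            if abs(prev - cur) <= _ITER_TOL * (abs(cur) + 1.0):
                break
            prev = cur
        return sigmas

    raise ValueError(f"unknown covariance model code {code!r}")


# ---------------------------------------------------------------------------
# Fitting, likelihood, selection, prediction
# ---------------------------------------------------------------------------

def _check_labels(y: np.ndarray, G: int) -> None:
    present = np.unique(y)
    for g in range(1, G + 1):
        if g not in present:
            raise ValueError(f"class {g} has no observations; every class 1..G "
                             f"must appear in the training labels")


def fit_edda(X: np.ndarray, y: np.ndarray, model: str = "EDDA",
             G: int | None = None) -> ClassifierParams:
    """Fit one Gaussian discriminant classifier by maximum likelihood.

    Parameters
    ----------
    X : (N, p) feature matrix.
    y : (N,) integer class labels in 1..G.
    model : covariance model code, an alias (LDA/QDA), or ``"EDDA"`` to
        select among all 14 models by BIC.
    G : number of classes; defaults to ``max(y)``.

    Priors are class frequencies ``n_g/N``, means are class sample means and
    covariances maximize the joint likelihood under the model's constraint
    (ML denominators, i.e. ``n_g``/``N`` rather than ``n_g - 1``).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    N, p = X.shape
    if y.shape != (N,):
        raise ValueError(f"labels have shape {y.shape}, expected ({N},)")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    G = int(G if G is not None else y.max())
    if N < G:
        raise ValueError(f"need at least G={G} observations, got N={N}")
    _check_labels(y, G)

    code = resolve_model(model)
    if code == "EDDA":
        return select_model_bic(X, y, MODEL_CODES, G=G)

    n_g = np.array([int(np.sum(y == g)) for g in range(1, G + 1)])
    tau = n_g / N
    means = np.stack([X[y == g].mean(axis=0) for g in range(1, G + 1)])
    W = np.stack([
        (X[y == g] - means[g - 1]).T @ (X[y == g] - means[g - 1])
        for g in range(1, G + 1)
    ])

    sigmas = _fit_cov(code, W, n_g, N, p)
    sigmas = 0.5 * (sigmas + np.transpose(sigmas, (0, 2, 1)))

    # ridge floor for near-singular estimates (degenerate classes)
    for g in range(G):
        min_eig = float(np.linalg.eigvalsh(sigmas[g])[0])
        if min_eig < _EIG_FLOOR:
            eps = 1e-8 * float(np.trace(sigmas[g])) / p
            sigmas[g] += eps * np.eye(p)
            if float(np.linalg.eigvalsh(sigmas[g])[0]) < _EIG_FLOOR:
                raise SingularFitError(
                    f"singular covariance estimate for model {code}, class {g + 1}")

    params = ClassifierParams(
        tau=tau, means=means, covariances=sigmas, model=code,
        loglik=0.0, n_free_params=n_free_params(code, G, p), bic=0.0,
        class_counts=n_g,
    )
    params.loglik = loglik(params, X, y)
    params.bic = 2.0 * params.loglik - params.n_free_params * math.log(N)
    return params


def loglik(params: ClassifierParams, X: np.ndarray, y: np.ndarray) -> float:
    """Joint log-likelihood sum_n log[ tau_{y_n} phi(x_n; mu_{y_n}, Sigma_{y_n}) ]."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    if X.shape[1] != params.p:
        raise ValueError(f"X has {X.shape[1]} features, model expects {params.p}")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of observations")
    log_dens = _class_log_densities(params.tau, params.means, params.covariances, X)
    return float(log_dens[np.arange(len(y)), y - 1].sum())


def select_model_bic(X: np.ndarray, y: np.ndarray,
                     candidates: list[str] | tuple[str, ...] = MODEL_CODES,
                     G: int | None = None) -> ClassifierParams:
    """Fit every candidate model and return the one maximizing BIC.

    BIC is oriented as ``2*loglik - k*log(N)`` (maximized). Candidates whose
    fit is singular are skipped with a warning. Ties break toward fewer free
    parameters, then canonical model-code order.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    fits: list[ClassifierParams] = []
    for name in candidates:
        code = resolve_model(name)
        if code == "EDDA":
            raise ValueError("'EDDA' is not itself a candidate; pass concrete codes")
        try:
            fits.append(fit_edda(X, y, model=code, G=G))
        except (SingularFitError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"skipping model {code}: {exc}", stacklevel=2)
    if not fits:
        raise SingularFitError("all candidate covariance models failed to fit")
    return min(
        fits,
        key=lambda f: (-f.bic, f.n_free_params, MODEL_CODES.index(f.model)),
    )


def _class_log_densities(tau, means, covariances, X) -> np.ndarray:
    """(N, G) matrix of log[tau_g phi(x_n; mu_g, Sigma_g)]."""
    N, p = X.shape
    G = len(tau)
    out = np.empty((N, G))
    for g in range(G):
        L = np.linalg.cholesky(covariances[g])
        z = solve_triangular(L, (X - means[g]).T, lower=True)
        maha = np.sum(z * z, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diagonal(L)))
        out[:, g] = (math.log(tau[g]) - 0.5 * (p * math.log(2.0 * math.pi)
                                               + logdet + maha))
    return out


def posterior(params, X: np.ndarray) -> np.ndarray:
    """Posterior class-membership probabilities (N, G), rows summing to 1.

    ``z_ng = tau_g phi(x_n) / sum_v tau_v phi(x_n)``, computed on the log
    scale with log-sum-exp stabilization. Accepts any object carrying
    ``tau``, ``means`` and ``covariances`` (fitted classifier or stacked
    ensemble).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    log_dens = _class_log_densities(params.tau, params.means, params.covariances, X)
    return np.exp(log_dens - logsumexp(log_dens, axis=1, keepdims=True))


def predict_map(params, X: np.ndarray) -> np.ndarray:
    """MAP labels (1..G): per-row argmax of the posterior, ties to the lowest class."""
    return np.argmax(posterior(params, X), axis=1) + 1
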