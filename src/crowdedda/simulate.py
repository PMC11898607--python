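"""Synthetic multi-annotator experiments.

Features come from G equiprobable multivariate Gaussians. Scenario 1 uses
fixed means on the diagonal of the plane with identity covariances;
Scenario 2 draws class-wise different positive-definite covariances
(uniform eigenvalues in a range, Haar-random rotation), inducing
heterogeneous correlation patterns across classes.

Annotator noise is Dirichlet-multinomial: for each unit and annotator a
class-probability vector is drawn from a Dirichlet whose concentration is
largest on the unit's true class, then the label is one multinomial draw.
The concentration profile encodes expertise -- experts concentrate more
mass on the truth than novices. Default study conditions: M = 7 annotators
(4 experts, 3 novices), N = 150 units, stratified 100/50 train/test split,
S = 50 repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .ensemble import ensemble_predict, stack
from .metrics import cov_frobenius_error, mean_param_error
from .models import ClassifierParams, fit_edda, predict_map
from .weights import (
    iterative_weights,
    weights_en,
    weights_equal,
    weights_mv,
    weights_pgt,
)

ALL_STRATEGIES = ("PGT", "EN", "E", "MV", "ItAlg1", "ItAlg2")


@dataclass
class ScenarioConfig:
    """Gaussian feature-generating process for one scenario."""

    means: np.ndarray                       # (G, p) true class means
    covariances: np.ndarray                 # (G, p, p) true class covariances
    N: int = 150
    train_size: int = 100

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.shape != (self.G, self.p, self.p):
            raise ValueError("covariances must have shape (G, p, p)")
        for g in range(self.G):
            if np.linalg.eigvalsh(self.covariances[g])[0] <= 0:
                raise ValueError(f"covariance of class {g + 1} is not positive definite")
        if not 0 < self.train_size < self.N:
            raise ValueError("train_size must lie strictly between 0 and N")

    @property
    def G(self) -> int:
        return self.means.shape[0]

    @property
    def p(self) -> int:
        return self.means.shape[1]


@dataclass
class AnnotatorProfile:
    """Dirichlet concentration profile of one annotator.

    ``alpha[g]`` is the length-G concentration vector used when the true
    class is g+1; its g-th entry must be the (strict) maximum, so the true
    class is always the most likely label. Expected probability of the
    correct label is ``alpha_true / sum(alpha)`` (Dirichlet-multinomial mean).
    """

    alpha: np.ndarray                       # (G, G)
    tier: str = "expert"

    def __post_init__(self):
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        G = self.alpha.shape[0]
        if self.alpha.shape != (G, G):
            raise ValueError("alpha must be a G x G matrix (row per true class)")
        if np.any(self.alpha <= 0):
            raise ValueError("Dirichlet concentrations must be positive")
        for g in range(G):
            off = np.delete(self.alpha[g], g)
            if G > 1 and self.alpha[g, g] <= off.max():
                raise ValueError(
                    f"true-class concentration must be the largest (row {g + 1})")


def tiered_profile(G: int, true_alpha: float, other_alpha: float,
                   tier: str) -> AnnotatorProfile:
    """Symmetric profile: concentration ``true_alpha`` on the true class,
    ``other_alpha`` elsewhere, identical for every true class."""
    alpha = np.full((G, G), other_alpha)
    np.fill_diagonal(alpha, true_alpha)
    return AnnotatorProfile(alpha=alpha, tier=tier)


def default_profiles(G: int = 3, n_expert: int = 4, n_novice: int = 3,
                     expert_alpha: tuple[float, float] = (8.0, 1.0),
                     novice_alpha: tuple[float, float] = (3.5, 1.5),
                     ) -> list[AnnotatorProfile]:
    """Study-default annotator panel: 4 experts (mean correct-label
    probability 0.8) and 3 novices (mean approximately 0.54)."""
    return ([tiered_profile(G, *expert_alpha, tier="expert")] * n_expert
            + [tiered_profile(G, *novice_alpha, tier="novice")] * n_novice)


def scenario1(N: int = 150, train_size: int = 100) -> ScenarioConfig:
    """Three equiprobable bivariate Gaussians at (2,2), (0,0), (-2,-2),
    identity covariances."""
    means = np.array([[2.0, 2.0], [0.0, 0.0], [-2.0, -2.0]])
    covs = np.stack([np.eye(2)] * 3)
    return ScenarioConfig(means=means, covariances=covs, N=N, train_size=train_size)


def scenario2(seed: int, N: int = 150, train_size: int = 100,
              eig_range: tuple[float, float] = (0.5, 2.0)) -> ScenarioConfig:
    """Same means as Scenario 1 but class-wise random PD covariances with
    heterogeneous correlations."""
    means = np.array([[2.0, 2.0], [0.0, 0.0], [-2.0, -2.0]])
    covs = gen_random_covariances(3, 2, seed, eig_range=eig_range)
    return ScenarioConfig(means=means, covariances=covs, N=N, train_size=train_size)


def gen_random_covariances(G: int, p: int, seed: int,
                           eig_range: tuple[float, float] = (0.5, 2.0)) -> np.ndarray:
    """G random symmetric PD matrices: eigenvalues uniform in ``eig_range``,
    eigenvectors Haar-distributed (QR of a Gaussian matrix)."""
    lo, hi = eig_range
    if not 0 < lo <= hi:
        raise ValueError("eigenvalue range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    out = np.empty((G, p, p))
    for g in range(G):
        eigs = rng.uniform(lo, hi, size=p)
        Q, R = np.linalg.qr(rng.standard_normal((p, p)))
        Q *= np.sign(np.diagonal(R))
        out[g] = Q @ np.diag(eigs) @ Q.T
        out[g] = 0.5 * (out[g] + out[g].T)
    return out


def gen_features(scenario: ScenarioConfig, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw (X, y_true): equiprobable class labels, Gaussian features."""
    rng = np.random.default_rng(seed)
    G, p, N = scenario.G, scenario.p, scenario.N
    y = rng.integers(1, G + 1, size=N)
    chols = np.stack([np.linalg.cholesky(scenario.covariances[g]) for g in range(G)])
    z = rng.standard_normal((N, p))
    X = scenario.means[y - 1] + np.einsum("nij,nj->ni", chols[y - 1], z)
    return X, y


def gen_noisy_labels(y_true: np.ndarray, profiles: list[AnnotatorProfile],
                     seed: int) -> np.ndarray:
    """Dirichlet-multinomial noisy labels, one column per annotator.

    For each unit n and annotator m: p ~ Dirichlet(alpha_m(y_true_n)), then
    one multinomial draw of the label from p.
    """
    rng = np.random.default_rng(seed)
    y_true = np.asarray(y_true, dtype=int)
    N = len(y_true)
    M = len(profiles)
    G = profiles[0].alpha.shape[0]
    Y = np.empty((N, M), dtype=int)
    u = rng.random((N, M))
    for m, prof in enumerate(profiles):
        probs = np.empty((N, G))
        for g in range(1, G + 1):
            idx = y_true == g
            if idx.any():
                probs[idx] = rng.dirichlet(prof.alpha[g - 1], size=int(idx.sum()))
        cum = np.cumsum(probs, axis=1)
        Y[:, m] = (u[:, m:m + 1] > cum).sum(axis=1) + 1
    return Y


def stratified_split(y: np.ndarray, train_size: int,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified train/test index split (disjoint, exhaustive)."""
    y = np.asarray(y, dtype=int)
    idx = np.arange(len(y))
    train, test = train_test_split(idx, train_size=train_size, stratify=y,
                                   random_state=int(seed) % (2 ** 31))
    return np.sort(train), np.sort(test)


@dataclass
class StudyConfig:
    """Replicated simulation study: scenario, annotator panel, strategies."""

    scenario: ScenarioConfig | str = "scenario1"
    profiles: list[AnnotatorProfile] = field(default_factory=default_profiles)
    S: int = 50
    base_model: str = "LDA"
    strategies: tuple[str, ...] = ALL_STRATEGIES
    pgt_fraction: float = 0.1
    expert_mass: float = 0.8
    mv_threshold: float = 5.0 / 7.0
    max_iter: int = 100
    master_seed: int = 0
    scenario2_cov_seed: int | None = None

    def resolve_scenario(self) -> ScenarioConfig:
        if isinstance(self.scenario, ScenarioConfig):
            return self.scenario
        if self.scenario == "scenario1":
            return scenario1()
        if self.scenario == "scenario2":
            seed = (self.scenario2_cov_seed if self.scenario2_cov_seed is not None
                    else self.master_seed + 777_001)
            return scenario2(seed % (2 ** 31))
        raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class StudyResult:
    """Tidy per-repetition results plus aggregated summary tables."""

    records: pd.DataFrame       # scenario, repetition, model, strategy, metric, value
    config: StudyConfig

    def summary(self) -> pd.DataFrame:
        """Mean (and SD for accuracy) of every metric by model row."""
        agg = (self.records
               .groupby(["model", "metric"])["value"]
               .agg(["mean", "std"])
               .reset_index())
        return agg

    def mean_metric(self, model: str, metric: str) -> float:
        sel = self.records[(self.records["model"] == model)
                           & (self.records["metric"] == metric)]
        return float(sel["value"].mean())


def _rep_seed(master_seed: int, rep: int) -> int:
    # independent, reproducible per-repetition streams below 2^31
    return int(np.random.SeedSequence([master_seed, rep]).generate_state(1)[0] % (2 ** 31))


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full replicated experiment.

    Per repetition: draw features and true labels, draw the M annotators'
    noisy labels, split stratified train/test, fit the ground-truth (GT)
    benchmark on true training labels and one base learner per annotator,
    compute every requested weighting strategy, stack, and record test
    accuracy plus mean and covariance recovery errors against the true
    generative parameters. Identical configs (including the master seed)
    reproduce identical results bit for bit.
    """
    scenario = config.resolve_scenario()
    profiles = config.profiles
    M = len(profiles)
    levels = [p.tier for p in profiles]
    rows: list[dict] = []
    scen_name = (config.scenario if isinstance(config.scenario, str) else "custom")

    for s in range(config.S):
        seed = _rep_seed(config.master_seed, s)
        rng = np.random.default_rng(seed)
        X, y_true = gen_features(scenario, seed=int(rng.integers(2 ** 31)))
        Y = gen_noisy_labels(y_true, profiles, seed=int(rng.integers(2 ** 31)))
        train, test = stratified_split(y_true, scenario.train_size,
                                       seed=int(rng.integers(2 ** 31)))
        Xtr, Xte = X[train], X[test]
        ytr, yte = y_true[train], y_true[test]
        Ytr = Y[train]

        def record(model_row, strategy, acc, mse, frob, weights=None):
            base_info = dict(scenario=scen_name, repetition=s, model=model_row,
                             strategy=strategy, base_model=config.base_model)
            rows.append({**base_info, "metric": "accuracy", "value": acc})
            rows.append({**base_info, "metric": "mse", "value": mse})
            rows.append({**base_info, "metric": "frobenius", "value": frob})
            if weights is not None:
                for m, wm in enumerate(weights.w):
                    rows.append({**base_info, "metric": f"weight_{m + 1}",
                                 "value": float(wm)})

        def evaluate(params):
            acc = float(np.mean(predict_map(params, Xte) == yte))
            mse = mean_param_error(scenario.means, params.means)
            frob = cov_frobenius_error(scenario.covariances, params.covariances)
            return acc, mse, frob

        gt = fit_edda(Xtr, ytr, model=config.base_model, G=scenario.G)
        record("GT", "-", *evaluate(gt))

        base: list[ClassifierParams] = []
        expert_seen = novice_seen = 0
        for m in range(M):
            b = fit_edda(Xtr, Ytr[:, m], model=config.base_model, G=scenario.G)
            base.append(b)
            if levels[m] == "expert":
                expert_seen += 1
                name = f"E{expert_seen}"
            else:
                novice_seen += 1
                name = f"N{novice_seen}"
            record(name, "-", *evaluate(b))

        n2 = max(1, round(config.pgt_fraction * len(train)))
        pgt_idx = rng.choice(len(train), size=n2, replace=False)

        for strat in config.strategies:
            if strat == "PGT":
                w = weights_pgt(Ytr[pgt_idx], ytr[pgt_idx])
            elif strat == "EN":
                w = weights_en(levels, {"expert": config.expert_mass,
                                        "novice": 1.0 - config.expert_mass})
            elif strat == "E":
                w = weights_equal(M)
            elif strat == "MV":
                w = weights_mv(Ytr, config.mv_threshold, G=scenario.G)
            elif strat in ("ItAlg1", "ItAlg2"):
                variant = 1 if strat == "ItAlg1" else 2
                w = iterative_weights(Xtr, Ytr, base, variant=variant,
                                      max_iter=config.max_iter).weights
            else:
                raise ValueError(f"unknown weighting strategy {strat!r}")
            ens = stack(base, w)
            acc = float(np.mean(ensemble_predict(ens, Xte)[1] == yte))
            mse = mean_param_error(scenario.means, ens.means)
            frob = cov_frobenius_error(scenario.covariances, ens.covariances)
            record(strat, strat, acc, mse, frob, weights=w)

    return StudyResult(records=pd.DataFrame(rows), config=config)
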