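"""Simulation-decoupled neural posterior estimation (SD-NPE).

A probabilistic regressor maps one reduced feature vector to a bivariate
normal "per-sample posterior" over the target parameters.  Under a
mean-field (sample-independence) approximation, Bayes' rule combines N
such per-sample posteriors p_i(w) with an approximate prior p_hat(w) into
one posterior over a discretized parameter lattice:

    log p(w | x_1..x_N) = sum_i log p_i(w) - (N - 1) * log p_hat(w) + const

where the prior is approximated by the pixel-wise (Monte Carlo) average
of the per-sample posteriors predicted for all *training* samples.  Once
the regressor is trained, inference needs no further simulation.

The regressor is natural-gradient boosting: each stage fits one
depth-limited regression tree per distribution parameter to the natural
gradient (Fisher-preconditioned gradient) of the negative log-likelihood,
with a per-stage line search and shrinkage.  The covariance is carried in
Cholesky form, so predicted covariances are positive-definite by
construction.  Any regressor emitting mean + SPD covariance can be
slotted in; SD-NPE's arithmetic is regressor-agnostic.

The module also contains the closed-form conjugate Bayesian linear
regression oracle and the validation harness that compares the full
SD-NPE pipeline against it on a lattice (KL divergence).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal
from sklearn.tree import DecisionTreeRegressor

logger = logging.getLogger(__name__)

__all__ = [
    "RegressorSpec",
    "SamplePosterior",
    "ParameterLattice",
    "TURING_LATTICE",
    "NaturalGradientBoostingMVN",
    "train_regressor",
    "predict_sample_posterior",
    "estimate_prior",
    "integrate_posteriors",
    "sdnpe_posterior",
    "generalization_error",
    "hpd_region_contains",
    "analytic_linreg_posterior",
    "run_linreg_validation",
    "lattice_kl",
]

DENSITY_FLOOR = 1e-300
MIN_TRAIN_SAMPLES = 50


@dataclass(frozen=True)
class RegressorSpec:
    """Boosting configuration: Friedman-MSE depth-3 trees, 150 stages, lr 0.087."""

    n_estimators: int = 150
    learning_rate: float = 0.087
    max_depth: int = 3
    criterion: str = "friedman_mse"
    minibatch_frac: float = 1.0


@dataclass
class SamplePosterior:
    """Bivariate normal posterior for one sample: mean + SPD covariance."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(2)
        self.cov = np.asarray(self.cov, dtype=float).reshape(2, 2)
        self.cov = 0.5 * (self.cov + self.cov.T)
        try:
            np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError:
            w, V = np.linalg.eigh(self.cov)
            logger.warning("repairing non-SPD covariance by eigenvalue flooring")
            self.cov = (V * np.maximum(w, 1e-10)) @ V.T

    def logpdf(self, points: np.ndarray) -> np.ndarray:
        return multivariate_normal(self.mean, self.cov, allow_singular=False) \
            .logpdf(points)

    def density_on(self, lattice: "ParameterLattice") -> np.ndarray:
        return np.exp(self.logpdf(lattice.points)).reshape(lattice.shape)


@dataclass(frozen=True)
class ParameterLattice:
    """Regular cell grid over the 2-d parameter plane.

    ``origin`` is the lower corner; cell centers are at
    origin + (i + 1/2) * cell along each axis.  Densities live on cell
    centers; a normalized density satisfies sum(d) * cell_area == 1.
    """

    origin: tuple = (0.55, 0.55)
    n: tuple = (100, 100)
    cell: float = 0.005

    @property
    def shape(self):
        return self.n

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell

    @property
    def axes(self):
        ax0 = self.origin[0] + (np.arange(self.n[0]) + 0.5) * self.cell
        ax1 = self.origin[1] + (np.arange(self.n[1]) + 0.5) * self.cell
        return ax0, ax1

    @property
    def points(self) -> np.ndarray:
        ax0, ax1 = self.axes
        g0, g1 = np.meshgrid(ax0, ax1, indexing="ij")
        return np.column_stack([g0.ravel(), g1.ravel()])

    def normalize(self, density: np.ndarray) -> np.ndarray:
        density = np.asarray(density, dtype=float)
        total = density.sum() * self.cell_area
        if total <= 0:
            raise ValueError("cannot normalize an all-zero lattice density")
        return density / total

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        hi = np.array(self.origin) + np.array(self.n) * self.cell
        return bool(np.all(p >= self.origin) and np.all(p <= hi))

    def interpolate(self, density: np.ndarray, point) -> float:
        """Bilinear interpolation of a cell-center density at a point."""
        if not self.contains(point):
            raise ValueError(f"point {point} outside lattice")
        ax0, ax1 = self.axes
        x, y = float(point[0]), float(point[1])
        i = np.clip(np.searchsorted(ax0, x) - 1, 0, self.n[0] - 2)
        j = np.clip(np.searchsorted(ax1, y) - 1, 0, self.n[1] - 2)
        tx = np.clip((x - ax0[i]) / self.cell, 0.0, 1.0)
        ty = np.clip((y - ax1[j]) / self.cell, 0.0, 1.0)
        d = np.asarray(density)
        return float((1 - tx) * (1 - ty) * d[i, j] + tx * (1 - ty) * d[i + 1, j]
                     + (1 - tx) * ty * d[i, j + 1] + tx * ty * d[i + 1, j + 1])


# The estimation-protocol lattice: 100 x 100 cells of size 0.005 span 0.5
# per axis, centered on the [0.6, 1.0]^2 parameter box.
TURING_LATTICE = ParameterLattice(origin=(0.55, 0.55), n=(100, 100), cell=0.005)


# --- natural-gradient boosting with a bivariate-normal head ---------------

# theta = (mu1, mu2, s1, s2, a) with Cholesky L = [[e^s1, 0], [a, e^s2]]


def _theta_to_moments(theta: np.ndarray):
    mu = theta[:, :2]
    l11 = np.exp(theta[:, 2])
    l22 = np.exp(theta[:, 3])
    a = theta[:, 4]
    cov = np.empty((len(theta), 2, 2))
    cov[:, 0, 0] = l11 ** 2
    cov[:, 0, 1] = cov[:, 1, 0] = l11 * a
    cov[:, 1, 1] = a ** 2 + l22 ** 2
    return mu, cov


def _nll(theta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-sample negative log-likelihood of y under MVN(theta)."""
    mu = theta[:, :2]
    s1, s2, a = theta[:, 2], theta[:, 3], theta[:, 4]
    r = y - mu
    # z = L^{-1} r for lower-triangular L
    z1 = r[:, 0] * np.exp(-s1)
    z2 = (r[:, 1] - a * z1) * np.exp(-s2)
    return 0.5 * (z1 ** 2 + z2 ** 2) + s1 + s2 + math.log(2.0 * math.pi)


def _nll_grad(theta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d NLL / d theta, shape (n, 5)."""
    s1, s2, a = theta[:, 2], theta[:, 3], theta[:, 4]
    r = y - theta[:, :2]
    inv11 = np.exp(-s1)
    inv22 = np.exp(-s2)
    z1 = r[:, 0] * inv11
    z2 = (r[:, 1] - a * z1) * inv22
    # w = L^{-T} z  (gradient wrt mu is -w)
    w2 = z2 * inv22
    w1 = (z1 - a * w2) * inv11
    g = np.empty_like(theta)
    g[:, 0] = -w1
    g[:, 1] = -w2
    g[:, 2] = -np.exp(s1) * w1 * z1 + 1.0
    g[:, 3] = -np.exp(s2) * w2 * z2 + 1.0
    g[:, 4] = -w2 * z1
    return g


def _fisher(theta: np.ndarray) -> np.ndarray:
    """Fisher information of theta, shape (n, 5, 5) (block: mean vs cov params)."""
    n = len(theta)
    s1, s2, a = theta[:, 2], theta[:, 3], theta[:, 4]
    l11 = np.exp(s1)
    l22 = np.exp(s2)
    # Sigma^{-1} from the Cholesky factor
    det = (l11 * l22) ** 2
    sig11 = a ** 2 + l22 ** 2
    inv = np.empty((n, 2, 2))
    inv[:, 0, 0] = sig11 / det
    inv[:, 0, 1] = inv[:, 1, 0] = -(l11 * a) / det
    inv[:, 1, 1] = (l11 ** 2) / det
    I = np.zeros((n, 5, 5))
    I[:, :2, :2] = inv
    # dSigma/dtheta_k as (n, 3, 2, 2) for k in (s1, s2, a)
    dS = np.zeros((n, 3, 2, 2))
    dS[:, 0, 0, 0] = 2.0 * l11 ** 2
    dS[:, 0, 0, 1] = dS[:, 0, 1, 0] = l11 * a
    dS[:, 1, 1, 1] = 2.0 * l22 ** 2
    dS[:, 2, 0, 1] = dS[:, 2, 1, 0] = l11
    dS[:, 2, 1, 1] = 2.0 * a
    M = np.einsum("nij,nkjl->nkil", inv, dS)  # Sigma^{-1} dSigma
    I[:, 2:, 2:] = 0.5 * np.einsum("nkij,nlji->nkl", M, M)
    return I


class NaturalGradientBoostingMVN:
    """Gradient boosting that predicts a full bivariate normal per input."""

    def __init__(self, spec: RegressorSpec = RegressorSpec(), seed: int = 0):
        self.spec = spec
        self.seed = seed
        self.theta0: np.ndarray | None = None
        self.stages: list = []  # (trees, scale) per stage
        self._train_X: np.ndarray | None = None
        self._train_theta: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NaturalGradientBoostingMVN":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if len(X) < MIN_TRAIN_SAMPLES:
            raise ValueError(f"need at least {MIN_TRAIN_SAMPLES} training samples")
        if np.any(y.std(axis=0) == 0):
            raise ValueError("degenerate labels: zero variance in a target column")
        # initial theta: marginal MLE of the label distribution
        mu0 = y.mean(axis=0)
        cov0 = np.cov(y.T) + 1e-12 * np.eye(2)
        L0 = np.linalg.cholesky(cov0)
        self.theta0 = np.array([mu0[0], mu0[1], math.log(L0[0, 0]),
                                math.log(L0[1, 1]), L0[1, 0]])
        theta = np.tile(self.theta0, (len(X), 1))
        rng = np.random.default_rng(self.seed)
        scales = np.array([2.0, 1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125])
        self.stages = []
        for stage in range(self.spec.n_estimators):
            grads = _nll_grad(theta, y)
            nat = np.linalg.solve(_fisher(theta), grads[..., None])[..., 0]
            if self.spec.minibatch_frac < 1.0:
                m = max(int(len(X) * self.spec.minibatch_frac), MIN_TRAIN_SAMPLES)
                sub = rng.choice(len(X), size=min(m, len(X)), replace=False)
            else:
                sub = slice(None)
            trees = []
            preds = np.empty_like(theta)
            # sklearn deprecated the "friedman_mse" alias; splits are identical
            criterion = {"friedman_mse": "squared_error"}.get(self.spec.criterion,
                                                              self.spec.criterion)
            for k in range(5):
                tree = DecisionTreeRegressor(criterion=criterion,
                                             max_depth=self.spec.max_depth,
                                             random_state=stage * 5 + k)
                tree.fit(X[sub], nat[sub, k])
                trees.append(tree)
                preds[:, k] = tree.predict(X)
            # line search on the fitted direction, then shrink
            losses = [np.mean(_nll(theta - s * preds, y)) for s in scales]
            scale = float(scales[int(np.argmin(losses))])
            theta = theta - self.spec.learning_rate * scale * preds
            self.stages.append((trees, scale))
        self._train_X = X
        self._train_theta = theta
        return self

    def predict_theta(self, X: np.ndarray) -> np.ndarray:
        if self.theta0 is None:
            raise ValueError("regressor is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self._train_X is not None and X is self._train_X:
            return self._train_theta.copy()  # exact: final boosted state
        theta = np.tile(self.theta0, (len(X), 1))
        for trees, scale in self.stages:
            for k, tree in enumerate(trees):
                theta[:, k] -= self.spec.learning_rate * scale * tree.predict(X)
        return theta

    def predict_posteriors(self, X: np.ndarray):
        """One :class:`SamplePosterior` per input row."""
        mu, cov = _theta_to_moments(self.predict_theta(X))
        return [SamplePosterior(m, c) for m, c in zip(mu, cov)]


def train_regressor(features: np.ndarray, labels: np.ndarray,
                    spec: RegressorSpec = RegressorSpec(),
                    seed: int = 0) -> NaturalGradientBoostingMVN:
    """Fit the probabilistic boosting regressor (features -> MVN posterior)."""
    return NaturalGradientBoostingMVN(spec, seed=seed).fit(features, labels)


def predict_sample_posterior(regressor, feature: np.ndarray) -> SamplePosterior:
    """Per-sample posterior for a single feature vector."""
    return regressor.predict_posteriors(np.atleast_2d(np.asarray(feature)))[0]


# --- lattice arithmetic ----------------------------------------------------


def _log_density_stack(posteriors, lattice: ParameterLattice) -> np.ndarray:
    pts = lattice.points
    return np.stack([p.logpdf(pts).reshape(lattice.shape) for p in posteriors])


def estimate_prior(regressor, training_features: np.ndarray,
                   lattice: ParameterLattice = TURING_LATTICE,
                   chunk: int = 256) -> np.ndarray:
    """Monte Carlo prior: cell-wise mean of all per-sample training densities.

    Averaged over the full training set by default (chunked for memory);
    returns a normalized lattice density.
    """
    X = np.asarray(training_features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) == 0:
        raise ValueError("prior estimation requires at least one feature")
    pts = lattice.points  # (M, 2)
    acc = np.zeros(len(pts))
    all_theta = regressor.predict_theta(X)
    for start in range(0, len(X), chunk):
        theta = all_theta[start:start + chunk]
        mu, cov = _theta_to_moments(theta)
        inv = np.linalg.inv(cov)  # (B, 2, 2)
        _, logdet = np.linalg.slogdet(cov)
        diff = pts[None, :, :] - mu[:, None, :]  # (B, M, 2)
        quad = np.einsum("bmi,bij,bmj->bm", diff, inv, diff)
        logd = -0.5 * (quad + logdet[:, None]) - math.log(2.0 * math.pi)
        acc += np.exp(logd).sum(axis=0)
    prior = (acc / len(X)).reshape(lattice.shape)
    return lattice.normalize(prior)


def integrate_posteriors(sample_posteriors, prior: np.ndarray,
                         lattice: ParameterLattice = TURING_LATTICE) -> np.ndarray:
    """Combine N per-sample posteriors and the prior on the lattice.

    log p(w) = sum_i log p_i(w) - (N - 1) log prior(w) + const, evaluated
    entirely in the log domain with density flooring, then renormalized.
    """
    if len(sample_posteriors) < 1:
        raise ValueError("need at least one sample posterior")
    logs = _log_density_stack(sample_posteriors, lattice)
    log_prior = np.log(np.maximum(np.asarray(prior, dtype=float), DENSITY_FLOOR))
    n = len(sample_posteriors)
    # cellwise sort before summing: float addition is order-dependent, and
    # the result must not depend on the order the posteriors are supplied
    total = np.sort(logs, axis=0).sum(axis=0) - (n - 1) * log_prior
    total -= total.max()
    dens = np.exp(total)
    if not np.any(dens > 0):
        raise FloatingPointError("integrated posterior vanished everywhere")
    return lattice.normalize(dens)


def sdnpe_posterior(regressor, features: np.ndarray, prior: np.ndarray,
                    lattice: ParameterLattice = TURING_LATTICE) -> np.ndarray:
    """Full second stage: per-sample posteriors for ``features``, integrated."""
    posts = regressor.predict_posteriors(np.atleast_2d(np.asarray(features)))
    return integrate_posteriors(posts, prior, lattice)


def generalization_error(posteriors, true_params,
                         lattice: ParameterLattice = TURING_LATTICE):
    """-(1/N) sum_g log p_g(w*_g): negative mean log density at the truths.

    ``posteriors`` is a list of normalized lattice densities (one per test
    group); the density at each truth is bilinearly interpolated between
    cell centers.
    """
    logs = []
    for dens, w in zip(posteriors, true_params):
        val = lattice.interpolate(np.asarray(dens), w)
        logs.append(math.log(max(val, DENSITY_FLOOR)))
    return -float(np.mean(logs))


def hpd_region_contains(density: np.ndarray, lattice: ParameterLattice,
                        point, mass: float = 0.95) -> bool:
    """True iff ``point`` falls in the highest-density region holding ``mass``."""
    d = np.asarray(density, dtype=float)
    order = np.argsort(d.ravel())[::-1]
    csum = np.cumsum(d.ravel()[order]) * lattice.cell_area
    k = int(np.searchsorted(csum, mass)) + 1
    threshold = d.ravel()[order[min(k - 1, d.size - 1)]]
    return lattice.interpolate(d, point) >= threshold


def lattice_kl(p: np.ndarray, q: np.ndarray, lattice: ParameterLattice) -> float:
    """KL(p || q) between two normalized lattice densities (cell masses)."""
    pm = np.asarray(p, dtype=float).ravel() * lattice.cell_area
    qm = np.maximum(np.asarray(q, dtype=float).ravel() * lattice.cell_area,
                    DENSITY_FLOOR)
    mask = pm > 0
    return float(np.sum(pm[mask] * (np.log(pm[mask]) - np.log(qm[mask]))))


# --- conjugate linear-regression oracle and validation harness ------------


def analytic_linreg_posterior(design: np.ndarray, observations: np.ndarray,
                              noise_sigma: float,
                              prior_mean=None, prior_cov=None) -> SamplePosterior:
    """Exact posterior of regression weights in the normal-normal model.

    y = design @ w + eps, eps ~ N(0, noise_sigma^2).  With ``prior_cov``
    None the prior is flat (requires a non-singular design).
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(observations, dtype=float).reshape(-1)
    d = X.shape[1] if len(y) else (2 if prior_mean is None else len(prior_mean))
    if prior_cov is None:
        prec = np.zeros((d, d))
        pm = np.zeros(d)
    else:
        prec = np.linalg.inv(np.asarray(prior_cov, dtype=float))
        pm = np.zeros(d) if prior_mean is None else np.asarray(prior_mean, float)
    if len(y):
        prec_post = prec + X.T @ X / noise_sigma ** 2
        rhs = prec @ pm + X.T @ y / noise_sigma ** 2
    else:
        prec_post, rhs = prec, prec @ pm
    try:
        cov = np.linalg.inv(prec_post)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular design with an improper prior") from exc
    if prior_cov is None and np.linalg.cond(prec_post) > 1e12:
        raise np.linalg.LinAlgError("singular design with an improper prior")
    return SamplePosterior(cov @ rhs, cov)


LINREG_LATTICE = ParameterLattice(origin=(-1.25, -1.25), n=(100, 100), cell=0.025)
LINREG_NOISE_SIGMA = 0.1
LINREG_PRIOR_STD = 0.5


def _linreg_design_row(x: float, condition: str) -> np.ndarray:
    if condition == "simple":
        return np.array([x, 1.0])  # y = a*x + b
    if condition == "redundant":
        return np.array([x, x])  # y = (a + b)*x: only the sum is identified
    raise ValueError(f"unknown condition: {condition!r}")


def simulate_linreg(condition: str, n: int, rng) -> tuple:
    """Draw (features, labels) for SD-NPE training: feature = (x, y)."""
    w = rng.normal(0.0, LINREG_PRIOR_STD, size=(n, 2))
    x = rng.uniform(-1.0, 1.0, size=n)
    if condition == "simple":
        mean = w[:, 0] * x + w[:, 1]
    else:
        mean = (w[:, 0] + w[:, 1]) * x
    y = mean + rng.normal(0.0, LINREG_NOISE_SIGMA, size=n)
    return np.column_stack([x, y]), w


def run_linreg_validation(condition: str = "simple", train_size: int = 100_000,
                          seed: int = 0, n_obs: int = 20, n_cases: int = 50,
                          spec: RegressorSpec = RegressorSpec(),
                          lattice: ParameterLattice = LINREG_LATTICE,
                          prior_subsample: int | None = None) -> dict:
    """Full SD-NPE pipeline on simulated linear-regression data vs the oracle.

    Each observation (x, y) is one sample fed to the regressor; each test
    case integrates ``n_obs`` per-sample posteriors and is scored by the
    lattice KL divergence from the analytic conjugate posterior.
    """
    rng = np.random.default_rng(seed)
    feats, labels = simulate_linreg(condition, train_size, rng)
    reg = train_regressor(feats, labels, spec=spec, seed=seed)
    prior_feats = feats
    if prior_subsample is not None and prior_subsample < len(feats):
        prior_feats = feats[rng.choice(len(feats), prior_subsample, replace=False)]
    prior = estimate_prior(reg, prior_feats, lattice)
    prior_cov = LINREG_PRIOR_STD ** 2 * np.eye(2)
    kls, cases = [], []
    for case in range(n_cases):
        w_true = rng.normal(0.0, LINREG_PRIOR_STD, size=2)
        x = rng.uniform(-1.0, 1.0, size=n_obs)
        X = np.stack([_linreg_design_row(xi, condition) for xi in x])
        y = X @ w_true + rng.normal(0.0, LINREG_NOISE_SIGMA, size=n_obs)
        analytic = analytic_linreg_posterior(X, y, LINREG_NOISE_SIGMA,
                                             prior_mean=np.zeros(2),
                                             prior_cov=prior_cov)
        analytic_dens = lattice.normalize(analytic.density_on(lattice))
        sdnpe_dens = sdnpe_posterior(reg, np.column_stack([x, y]), prior, lattice)
        kls.append(lattice_kl(analytic_dens, sdnpe_dens, lattice))
        cases.append({"w_true": w_true, "kl": kls[-1],
                      "sdnpe": sdnpe_dens, "analytic": analytic_dens})
    return {"condition": condition, "train_size": train_size,
            "median_kl": float(np.median(kls)), "mean_kl": float(np.mean(kls)),
            "kls": np.array(kls), "cases": cases, "prior": prior}
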