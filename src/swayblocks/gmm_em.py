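"""Two-component Gaussian mixture fitted by EM for quiet/unquiet block clustering.

Normalized block descriptors ``Z_j in R^3`` are modelled as a mixture of
``k = 2`` multivariate Gaussians, the latent components being interpreted as
quiet blocks (QB) and unquiet blocks (UB).  The model is fitted by
expectation-maximization with the classical repeated-random-initialization
scheme (20 restarts by default), keeping the run with the highest final
log-likelihood.  The UB component is designated afterwards as the component
maximizing the weighted likelihood of the mean descriptor of the
faller-derived training blocks; it is the component whose posterior becomes
the block score.

One model is fitted per acquisition condition (eyes open / eyes closed);
descriptors from different conditions are never pooled into one fit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import List, Optional, Tuple

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .cop_data import Condition
from .exceptions import InsufficientDataError, StateError, ValidationError

logger = logging.getLogger(__name__)

#: Ridge added to every covariance update; data are z-normalized so this is
#: six orders of magnitude below the typical index variance.
DEFAULT_REG = 1e-6
DEFAULT_N_INIT = 20
DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-8

_LOG_2PI = np.log(2.0 * np.pi)


@dataclasses.dataclass
class GMMModel:
    """Parameters of the fitted 2-component mixture.

    ``ub_index`` is None until :func:`label_ub_cluster` designates the unquiet
    component.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    ub_index: Optional[int] = None
    condition: Optional[Condition] = None
    train_loglik: Optional[float] = None
    n_train_blocks: Optional[int] = None
    seed: Optional[int] = None
    converged: bool = True
    ll_histories: Optional[List[np.ndarray]] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).reshape(2)
        self.means = np.asarray(self.means, dtype=float).reshape(2, -1)
        d = self.means.shape[1]
        self.covariances = np.asarray(self.covariances, dtype=float).reshape(2, d, d)
        if np.any(self.weights <= 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValidationError("mixture weights must be positive and sum to 1")
        if self.condition is not None:
            self.condition = Condition(self.condition)

    @property
    def qb_index(self) -> int:
        if self.ub_index is None:
            raise StateError("UB component not designated yet")
        return 1 - self.ub_index


@dataclasses.dataclass
class Responsibilities:
    """Posterior component memberships p_{i,j}, one row per data point."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[1] != 2:
            raise ValidationError("responsibilities must have shape (n, 2)")


def gaussian_logpdf(z: np.ndarray, mu: np.ndarray, sigma: np.ndarray):
    """Log density of the multivariate normal N(mu, sigma) at z.

    ``z`` may be a single d-vector or an (n, d) array; returns a scalar or an
    (n,) array accordingly.  ``sigma`` must be symmetric positive-definite.
    """
    z = np.asarray(z, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    single = z.ndim == 1
    Z = np.atleast_2d(z)
    d = mu.size
    chol = np.linalg.cholesky(sigma)
    diff = Z - mu
    sol = solve_triangular(chol, diff.T, lower=True)
    maha = np.einsum("ij,ij->j", sol, sol)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    out = -0.5 * (d * _LOG_2PI + logdet + maha)
    return float(out[0]) if single else out


def _weighted_log_densities(
    Z: np.ndarray, weights: np.ndarray, means: np.ndarray, covariances: np.ndarray
) -> np.ndarray:
    """(n, 2) array of log(pi_i) + log N(Z_j; mu_i, Sigma_i)."""
    cols = [
        np.log(weights[i]) + gaussian_logpdf(Z, means[i], covariances[i])
        for i in range(2)
    ]
    return np.column_stack(cols)


def e_step(model: GMMModel, Z: np.ndarray) -> Responsibilities:
    """Posterior membership of every point, computed in log space.

    ``p_{i,j} proportional to pi_i N(Z_j; mu_i, Sigma_i)``, rows normalized
    after subtracting the row-wise maximum for numerical stability.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    logw = _weighted_log_densities(Z, model.weights, model.means, model.covariances)
    logw -= logw.max(axis=1, keepdims=True)
    p = np.exp(logw)
    p /= p.sum(axis=1, keepdims=True)
    return Responsibilities(p=p)


def m_step(
    Z: np.ndarray,
    resp: Responsibilities,
    reg: float = DEFAULT_REG,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximization step: update weights, means and covariances.

    ``pi_i = mean_j p_{i,j}``; ``mu_i`` and ``Sigma_i`` are the responsibility-
    weighted mean and (biased) covariance, plus a ridge ``reg * I``.  A
    component whose responsibility mass vanishes is re-seeded at a random data
    point (requires ``rng``; raises otherwise).
    """
    Z = np.asarray(Z, dtype=float)
    p = resp.p
    n, d = Z.shape
    nk = p.sum(axis=0)
    weights = nk / n
    means = np.empty((2, d))
    covs = np.empty((2, d, d))
    eye = np.eye(d)
    for i in range(2):
        if nk[i] < 1e-10:
            if rng is None:
                raise ValidationError(f"component {i} received no responsibility mass")
            logger.warning("empty mixture component %d re-seeded at a data point", i)
            means[i] = Z[rng.integers(n)]
            covs[i] = np.cov(Z.T, ddof=0) + reg * eye
            weights[i] = 1.0 / n
            continue
        means[i] = p[:, i] @ Z / nk[i]
        diff = Z - means[i]
        covs[i] = (diff.T * p[:, i]) @ diff / nk[i] + reg * eye
    weights = weights / weights.sum()
    return weights, means, covs


def log_likelihood(model: GMMModel, Z: np.ndarray) -> float:
    """Total log-likelihood sum_j log sum_i pi_i N(Z_j; mu_i, Sigma_i)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    logw = _weighted_log_densities(Z, model.weights, model.means, model.covariances)
    return float(logsumexp(logw, axis=1).sum())


def _component_logpdf_fast(Z, mu, cov, d, eye):
    """1-D log density of one component; the 3x3 solve is done once."""
    chol = np.linalg.cholesky(cov)
    li = solve_triangular(chol, eye, lower=True)
    x = (Z - mu) @ li.T
    maha = np.einsum("ij,ij->i", x, x)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (d * _LOG_2PI + logdet + maha)


def _run_em(
    Z: np.ndarray,
    weights: np.ndarray,
    means: np.ndarray,
    covs: np.ndarray,
    max_iter: int,
    tol: float,
    reg: float,
    rng: np.random.Generator,
):
    """EM iterations from one initialization; returns params, LL history, flag.

    The hot loop works on the two components as flat 1-D arrays and updates
    covariances through weighted second moments, which keeps every operation
    contiguous; results are identical to e_step/m_step up to rounding.
    """
    n, d = Z.shape
    eye = np.eye(d)
    reg_eye = reg * eye
    w0, w1 = float(weights[0]), float(weights[1])
    history = []
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        l0 = np.log(w0) + _component_logpdf_fast(Z, means[0], covs[0], d, eye)
        l1 = np.log(w1) + _component_logpdf_fast(Z, means[1], covs[1], d, eye)
        m = np.maximum(l0, l1)
        e0 = np.exp(l0 - m)
        e1 = np.exp(l1 - m)
        tot = e0 + e1
        ll = float((np.log(tot) + m).sum())
        history.append(ll)
        p1 = e1 / tot
        p0 = 1.0 - p1
        new_means = np.empty_like(means)
        new_covs = np.empty_like(covs)
        nks = []
        for i, p in enumerate((p0, p1)):
            nk = float(p.sum())
            nks.append(nk)
            if nk < 1e-10:
                logger.warning(
                    "empty mixture component %d re-seeded at a data point", i
                )
                new_means[i] = Z[rng.integers(n)]
                new_covs[i] = np.cov(Z.T, ddof=0) + reg_eye
                nks[i] = 1.0
                continue
            mu = p @ Z / nk
            second = (Z.T * p) @ Z / nk
            new_covs[i] = second - np.outer(mu, mu) + reg_eye
            new_means[i] = mu
        means, covs = new_means, new_covs
        w0, w1 = nks[0] / (nks[0] + nks[1]), nks[1] / (nks[0] + nks[1])
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(ll):
            converged = True
            break
        prev_ll = ll
    weights = np.array([w0, w1])
    final_logw = _weighted_log_densities(Z, weights, means, covs)
    history.append(float(logsumexp(final_logw, axis=1).sum()))
    return weights, means, covs, np.array(history), converged


def fit_gmm(
    Z: np.ndarray,
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: Optional[int] = None,
    condition: Optional[Condition] = None,
    reg: float = DEFAULT_REG,
    track_history: bool = False,
) -> GMMModel:
    """Fit the k = 2 mixture by EM with repeated random initialization.

    Each restart initializes the component means at two distinct data points
    drawn uniformly, both covariances at the global data covariance, and equal
    weights.  EM iterates until the relative log-likelihood change drops below
    ``tol`` or ``max_iter`` is reached; the restart with the highest final
    log-likelihood wins.  ``converged`` is False if that best restart hit the
    iteration cap.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n, d = Z.shape
    if n < 10:
        raise InsufficientDataError(f"need at least 10 descriptors to fit, got {n}")
    rng = np.random.default_rng(seed)
    global_cov = np.cov(Z.T, ddof=0) + reg * np.eye(d)
    best = None
    histories = []
    for _ in range(n_init):
        idx = rng.choice(n, size=2, replace=False)
        weights0 = np.array([0.5, 0.5])
        means0 = Z[idx].copy()
        covs0 = np.stack([global_cov.copy(), global_cov.copy()])
        weights, means, covs, history, converged = _run_em(
            Z, weights0, means0, covs0, max_iter, tol, reg, rng
        )
        histories.append(history)
        if best is None or history[-1] > best[3]:
            best = (weights, means, covs, history[-1], converged)
    weights, means, covs, final_ll, converged = best
    if not converged:
        logger.warning("best EM run did not reach tolerance %.1e", tol)
    return GMMModel(
        weights=weights,
        means=means,
        covariances=covs,
        condition=condition,
        train_loglik=final_ll,
        n_train_blocks=n,
        seed=seed,
        converged=converged,
        ll_histories=histories if track_history else None,
    )


def label_ub_cluster(model: GMMModel, faller_train_descriptors: np.ndarray) -> GMMModel:
    """Designate the unquiet-block component.

    The mean ``m`` of the faller-derived training descriptors is evaluated
    under each component's weighted density ``pi_i N(m; mu_i, Sigma_i)``; the
    maximizing component becomes UB.  An (unlikely) exact tie is broken toward
    the component with the larger mean-velocity coordinate of its center.
    """
    F = np.atleast_2d(np.asarray(faller_train_descriptors, dtype=float))
    if F.shape[0] < 1 or F.size == 0:
        raise StateError(
            "no faller-derived training descriptors; cannot designate the UB "
            "component (fall back to the larger-mean-velocity component manually)"
        )
    m = F.mean(axis=0)
    scores = _weighted_log_densities(
        m[None, :], model.weights, model.means, model.covariances
    )[0]
    if abs(scores[0] - scores[1]) <= 1e-12:
        ub = int(np.argmax(model.means[:, 1]))
    else:
        ub = int(np.argmax(scores))
    return dataclasses.replace(model, ub_index=ub)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: GMMModel) -> dict:
    return {
        "condition": None if model.condition is None else model.condition.value,
        "weights": model.weights.tolist(),
        "means": model.means.tolist(),
        "covariances": model.covariances.tolist(),
        "ub_index": model.ub_index,
        "train_loglik": model.train_loglik,
        "n_train_blocks": model.n_train_blocks,
        "seed": model.seed,
        "converged": model.converged,
    }


def model_from_dict(data: dict) -> GMMModel:
    return GMMModel(
        weights=np.array(data["weights"]),
        means=np.array(data["means"]),
        covariances=np.array(data["covariances"]),
        ub_index=data.get("ub_index"),
        condition=data.get("condition"),
        train_loglik=data.get("train_loglik"),
        n_train_blocks=data.get("n_train_blocks"),
        seed=data.get("seed"),
        converged=data.get("converged", True),
    )


def save_model(model: GMMModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh, indent=2)


def load_model(path) -> GMMModel:
    with open(path, encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))
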