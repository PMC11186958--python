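"""Exchange-algorithm updates and adaptive random-walk proposals.

The exchange move avoids the intractable ERGM normalising constant by
simulating an auxiliary network at the proposed parameter; the constant
cancels in the acceptance ratio. Proposals are two-component Gaussian
mixtures whose main component tracks the sample covariance of the chain
and whose scale is tuned toward a 0.234 acceptance rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, LinAlgError

from .ergm import AuxSamplerConfig, simulate_ergm
from .netstats import Graph, StatisticSpec, summary_stats

__all__ = [
    "GaussianPrior",
    "MatrixNormalPrior",
    "ProposalState",
    "log_exchange_ratio",
    "exchange_update",
    "ncp_beta_log_ratio",
    "propose",
    "adapt_step",
    "run_exchange",
]

ACCEPT_TARGET = 0.234
ADAPT_BATCH = 20


class GaussianPrior:
    """Multivariate normal prior with cached Cholesky factorisation."""

    def __init__(self, mean: np.ndarray, covariance: np.ndarray):
        mean = np.atleast_1d(np.asarray(mean, dtype=np.float64))
        covariance = np.atleast_2d(np.asarray(covariance, dtype=np.float64))
        if covariance.shape != (mean.size, mean.size):
            raise ValueError("prior covariance shape does not match mean")
        if not np.allclose(covariance, covariance.T):
            raise ValueError("prior covariance must be symmetric")
        self.mean = mean
        self.covariance = covariance
        try:
            self._cho = cho_factor(covariance, lower=True)
        except LinAlgError as e:
            raise ValueError("prior covariance must be positive definite") from e

    def logpdf_unnorm(self, x: np.ndarray) -> float:
        """Log-density up to an additive constant."""
        r = np.asarray(x, dtype=np.float64) - self.mean
        return float(-0.5 * r @ cho_solve(self._cho, r))


class MatrixNormalPrior:
    """Matrix-normal prior MN(M, U^-1, V) on a q x p coefficient matrix.

    U (row precision) is fixed; V (column scale) is supplied per call
    because in the multilevel model it is the current residual
    covariance.
    """

    def __init__(self, mean: np.ndarray, row_precision: np.ndarray):
        self.mean = np.atleast_2d(np.asarray(mean, dtype=np.float64))
        self.row_precision = np.atleast_2d(np.asarray(row_precision, dtype=np.float64))
        q = self.mean.shape[0]
        if self.row_precision.shape != (q, q):
            raise ValueError("row precision must be q x q")

    def logpdf_unnorm(self, B: np.ndarray, col_scale: np.ndarray) -> float:
        """-0.5 tr(V^-1 (B-M)' U (B-M)), up to a constant in B."""
        R = np.atleast_2d(B) - self.mean
        cho = cho_factor(np.atleast_2d(col_scale), lower=True)
        inner = R.T @ self.row_precision @ R
        return float(-0.5 * np.trace(cho_solve(cho, inner)))


@dataclass
class ProposalState:
    """Adaptive random-walk proposal for a d-dimensional block.

    The proposal is the symmetric mixture
    (1-gamma) N(x, 2.38^2 delta Sigma_k / d) + gamma N(x, 0.1^2 delta I / d)
    where Sigma_k is the running sample covariance of the chain. Until
    at least 2d draws have been collected (or when Sigma_k is not
    positive definite) only the fallback component is used.
    """

    d: int
    gamma: float = 0.05
    log_delta: float = 0.0
    cov: np.ndarray | None = None
    n_batches: int = 0
    batch_accepts: int = 0
    batch_proposals: int = 0
    adaptation_active: bool = True
    _cov_chol: np.ndarray | None = field(default=None, repr=False)

    @property
    def delta(self) -> float:
        return float(np.exp(self.log_delta))

    def record(self, accepted: bool) -> None:
        self.batch_proposals += 1
        if accepted:
            self.batch_accepts += 1

    def freeze(self) -> None:
        self.adaptation_active = False


def propose(current: np.ndarray, prop: ProposalState, rng: np.random.Generator) -> np.ndarray:
    """Draw from the two-component mixture centred at ``current``."""
    current = np.asarray(current, dtype=np.float64)
    d = prop.d
    if current.shape != (d,):
        raise ValueError(f"current has shape {current.shape}, expected ({d},)")
    delta = prop.delta
    use_fallback = prop._cov_chol is None or rng.random() < prop.gamma
    z = rng.standard_normal(d)
    if use_fallback:
        step = (0.1 * np.sqrt(delta / d)) * z
    else:
        step = (2.38 * np.sqrt(delta / d)) * (prop._cov_chol @ z)
    return current + step


def adapt_step(prop: ProposalState, draws: np.ndarray, batch_accept_rate: float) -> ProposalState:
    """Adapt the proposal at a batch boundary (mutates and returns prop).

    Sets Sigma_k to the sample covariance of all kept draws so far and
    nudges log(delta) by +-min(0.5, 1/sqrt(k)) toward the 0.234 target,
    where k is the adaptation-batch index. No-op once adaptation is
    frozen.
    """
    if not prop.adaptation_active:
        return prop
    prop.n_batches += 1
    k = prop.n_batches
    draws = np.atleast_2d(np.asarray(draws, dtype=np.float64))
    if draws.shape[0] >= 2 * prop.d:
        cov = np.cov(draws, rowvar=False)
        cov = np.atleast_2d(cov)
        try:
            prop._cov_chol = cholesky(
                cov + 1e-10 * np.eye(prop.d), lower=True
            )
            prop.cov = cov
        except LinAlgError:
            prop._cov_chol = None
    step = min(0.5, 1.0 / np.sqrt(k))
    if batch_accept_rate < ACCEPT_TARGET:
        prop.log_delta -= step
    else:
        prop.log_delta += step
    prop.batch_accepts = 0
    prop.batch_proposals = 0
    return prop


def log_exchange_ratio(
    theta: np.ndarray,
    theta_prime: np.ndarray,
    s_y: np.ndarray,
    s_yprime: np.ndarray,
    prior: GaussianPrior,
) -> float:
    """Log acceptance ratio of the exchange move.

    (theta' - theta)' (s(y) - s(y')) plus the prior log-ratio; the
    intractable normalising constants have cancelled.
    """
    theta = np.asarray(theta, dtype=np.float64)
    theta_prime = np.asarray(theta_prime, dtype=np.float64)
    s_y = np.asarray(s_y, dtype=np.float64)
    s_yprime = np.asarray(s_yprime, dtype=np.float64)
    if not (theta.shape == theta_prime.shape == s_y.shape == s_yprime.shape):
        raise ValueError("theta/statistic dimension mismatch")
    lr = float((theta_prime - theta) @ (s_y - s_yprime))
    lr += prior.logpdf_unnorm(theta_prime) - prior.logpdf_unnorm(theta)
    return lr


def exchange_update(
    theta: np.ndarray,
    y: Graph,
    spec: StatisticSpec,
    prior: GaussianPrior,
    prop: ProposalState,
    aux: AuxSamplerConfig,
    rng: np.random.Generator,
    s_obs: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """One exchange-algorithm update of a single ERGM parameter block.

    Proposes theta' from the adaptive mixture, simulates an auxiliary
    network at theta', and accepts with probability
    min(1, exp(log_exchange_ratio)). ``s_obs`` may carry the cached
    observed statistics s(y).
    """
    theta = np.asarray(theta, dtype=np.float64)
    if s_obs is None:
        s_obs = summary_stats(y, spec)
    theta_prime = propose(theta, prop, rng)
    y_prime = simulate_ergm(theta_prime, spec, y, aux, rng)
    s_prime = summary_stats(y_prime, spec)
    lr = log_exchange_ratio(theta, theta_prime, s_obs, s_prime, prior)
    accepted = np.log(rng.random()) < lr
    prop.record(bool(accepted))
    return (theta_prime if accepted else theta.copy()), bool(accepted)


def ncp_beta_log_ratio(
    beta: np.ndarray,
    beta_prime: np.ndarray,
    X: np.ndarray,
    s_obs: list[np.ndarray],
    s_aux: list[np.ndarray],
    prior_on_beta: MatrixNormalPrior,
    col_scale: np.ndarray,
) -> float:
    """Log acceptance ratio of the non-centred beta exchange move.

    sum_i [x_i'(beta' - beta)]' [s(y_i) - s(y_i')] plus the conditional
    matrix-normal prior log-ratio; requires one auxiliary network per
    observed network, simulated at theta_i' = x_i' beta' + eps_i.
    """
    beta = np.atleast_2d(np.asarray(beta, dtype=np.float64))
    beta_prime = np.atleast_2d(np.asarray(beta_prime, dtype=np.float64))
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = X.shape[0]
    if len(s_obs) != n or len(s_aux) != n:
        raise ValueError("need one observed and one auxiliary statistic vector per network")
    diff = X @ (beta_prime - beta)  # n x p, row i = x_i'(beta' - beta)
    lr = 0.0
    for i in range(n):
        lr += float(diff[i] @ (np.asarray(s_obs[i]) - np.asarray(s_aux[i])))
    lr += prior_on_beta.logpdf_unnorm(beta_prime, col_scale)
    lr -= prior_on_beta.logpdf_unnorm(beta, col_scale)
    return lr


def run_exchange(
    y: Graph,
    spec: StatisticSpec,
    prior: GaussianPrior,
    aux: AuxSamplerConfig,
    n_iter: int,
    rng: np.random.Generator,
    theta0: np.ndarray | None = None,
    adapt_window: int = 1000,
) -> dict:
    """Single-network exchange-algorithm chain with adaptive proposals.

    Adapts every ADAPT_BATCH iterations during the first ``adapt_window``
    iterations, then freezes the proposal. Returns the full chain, the
    per-iteration acceptance flags and the delta trace.
    """
    p = spec.p
    theta = np.zeros(p) if theta0 is None else np.asarray(theta0, dtype=np.float64).copy()
    prop = ProposalState(d=p)
    s_obs = summary_stats(y, spec)
    draws = np.empty((n_iter, p))
    accepts = np.zeros(n_iter, dtype=bool)
    deltas = []
    for it in range(1, n_iter + 1):
        theta, acc = exchange_update(theta, y, spec, prior, prop, aux, rng, s_obs=s_obs)
        draws[it - 1] = theta
        accepts[it - 1] = acc
        if prop.adaptation_active and it % ADAPT_BATCH == 0:
            rate = prop.batch_accepts / max(prop.batch_proposals, 1)
            adapt_step(prop, draws[:it], rate)
            deltas.append(prop.delta)
        if it == adapt_window:
            prop.freeze()
    return {
        "draws": draws,
        "accepts": accepts,
        "deltas": np.asarray(deltas),
        "proposal": prop,
    }
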