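"""Population-level model: conjugate prior/posterior for the regression
block and the exchange-within-Gibbs samplers (centred, non-centred, and
interweaved parameterisations).

Model
-----
Each network y_i follows an ERGM with parameter theta_i; the theta_i
follow a multivariate linear regression

    theta_i ~ N(x_i' beta, Sigma_eps),   i = 1..n

with a conditionally conjugate matrix-normal / inverse-Wishart prior on
(beta, Sigma_eps):

    beta | Sigma_eps ~ MN(beta0, Lambda0^-1, Sigma_eps)
    Sigma_eps        ~ InvWishart(V0, nu0)

Dimension convention: beta is q x p, Lambda0 is q x q (row scale), V0 is
p x p and nu0 > p - 1. (The source formulation swaps p and q in the
hyperparameter dimensions; only this reading makes the conjugate
algebra well-defined — see the README.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve

from .ergm import AuxSamplerConfig, simulate_ergm
from .exchange import (
    ADAPT_BATCH,
    GaussianPrior,
    MatrixNormalPrior,
    ProposalState,
    adapt_step,
    exchange_update,
    ncp_beta_log_ratio,
    propose,
)
from .netstats import Graph, StatisticSpec, summary_stats

__all__ = [
    "PopulationData",
    "PopulationState",
    "PriorHyper",
    "PosteriorHyper",
    "SamplerConfig",
    "PosteriorSamples",
    "default_prior",
    "conjugate_posterior",
    "sample_beta",
    "sample_sigma",
    "gibbs_step_cp",
    "gibbs_step_ncp",
    "gibbs_step_asis",
    "run_sampler",
]

logger = logging.getLogger(__name__)


@dataclass
class PopulationData:
    """A population of n networks on a common node set plus an n x q
    design matrix of network-level covariates."""

    networks: list[Graph]
    X: np.ndarray
    spec: StatisticSpec

    def __post_init__(self) -> None:
        if len(self.networks) < 1:
            raise ValueError("need at least one network")
        n_nodes = self.networks[0].n_nodes
        if any(g.n_nodes != n_nodes for g in self.networks):
            raise ValueError("all networks must share the same node set")
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        if self.X.shape[0] != len(self.networks):
            raise ValueError("design matrix must have one row per network")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            logger.warning("design matrix is column-rank deficient")

    @property
    def n(self) -> int:
        return len(self.networks)

    @property
    def q(self) -> int:
        return self.X.shape[1]

    @property
    def p(self) -> int:
        return self.spec.p

    def observed_stats(self) -> np.ndarray:
        """n x p matrix of observed summary statistics."""
        return np.vstack([summary_stats(g, self.spec) for g in self.networks])


@dataclass
class PopulationState:
    """Current state of the Gibbs sampler.

    Maintains the identity theta = X beta + epsilon at all times; mu
    denotes X beta.
    """

    theta: np.ndarray  # n x p
    beta: np.ndarray  # q x p
    sigma_eps: np.ndarray  # p x p
    X: np.ndarray  # n x q

    @property
    def mu(self) -> np.ndarray:
        return self.X @ self.beta

    @property
    def epsilon(self) -> np.ndarray:
        return self.theta - self.mu

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.theta.copy(), self.beta.copy(), self.sigma_eps.copy(), self.X
        )


@dataclass
class PriorHyper:
    """Matrix-normal / inverse-Wishart prior hyperparameters."""

    beta0: np.ndarray  # q x p
    lambda0: np.ndarray  # q x q
    V0: np.ndarray  # p x p
    nu0: float

    def __post_init__(self) -> None:
        self.beta0 = np.atleast_2d(np.asarray(self.beta0, dtype=np.float64))
        self.lambda0 = np.atleast_2d(np.asarray(self.lambda0, dtype=np.float64))
        self.V0 = np.atleast_2d(np.asarray(self.V0, dtype=np.float64))
        q, p = self.beta0.shape
        if self.lambda0.shape != (q, q):
            raise ValueError("lambda0 must be q x q")
        if self.V0.shape != (p, p):
            raise ValueError("V0 must be p x p")
        for M, name in ((self.lambda0, "lambda0"), (self.V0, "V0")):
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.linalg.eigvalsh(M) <= 0):
                raise ValueError(f"{name} must be positive definite")
        if not self.nu0 > p - 1:
            raise ValueError("nu0 must exceed p - 1")

    @property
    def q(self) -> int:
        return self.beta0.shape[0]

    @property
    def p(self) -> int:
        return self.beta0.shape[1]


@dataclass
class PosteriorHyper:
    """Conditional posterior hyperparameters given theta and X."""

    beta_n: np.ndarray
    lambda_n: np.ndarray
    V_n: np.ndarray
    nu_n: float


def default_prior(p: int, q: int) -> PriorHyper:
    """Weakly informative defaults: beta0 = 0, Lambda0^-1 = 100 I,
    V0 = I, nu0 = p + 1."""
    if p < 1 or q < 1:
        raise ValueError("p and q must be >= 1")
    return PriorHyper(
        beta0=np.zeros((q, p)),
        lambda0=np.eye(q) / 100.0,
        V0=np.eye(p),
        nu0=p + 1,
    )


def conjugate_posterior(theta: np.ndarray, X: np.ndarray, prior: PriorHyper) -> PosteriorHyper:
    """Conditional posterior of (beta, Sigma_eps) given the latent theta.

    nu_n = nu0 + n; Lambda_n = X'X + Lambda0;
    beta_n = Lambda_n^-1 (X' theta + Lambda0 beta0);
    V_n = V0 + (theta - X beta_n)'(theta - X beta_n)
             + (beta_n - beta0)' Lambda0 (beta_n - beta0).
    """
    theta = np.asarray(theta, dtype=np.float64).reshape(-1, prior.p)
    X = np.asarray(X, dtype=np.float64).reshape(-1, prior.q)
    n = theta.shape[0]
    if X.shape[0] != n:
        raise ValueError("theta and X must have the same number of rows")
    lambda_n = X.T @ X + prior.lambda0
    try:
        beta_n = solve(lambda_n, X.T @ theta + prior.lambda0 @ prior.beta0, assume_a="pos")
    except np.linalg.LinAlgError as e:  # pragma: no cover - lambda0 is PD
        raise ValueError("posterior row precision is singular") from e
    resid = theta - X @ beta_n
    dbeta = beta_n - prior.beta0
    V_n = prior.V0 + resid.T @ resid + dbeta.T @ prior.lambda0 @ dbeta
    V_n = 0.5 * (V_n + V_n.T)
    return PosteriorHyper(beta_n=beta_n, lambda_n=lambda_n, V_n=V_n, nu_n=prior.nu0 + n)


def sample_beta(
    post: PosteriorHyper, sigma_eps: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Matrix-normal draw MN(beta_n, Lambda_n^-1, Sigma_eps)."""
    q, p = post.beta_n.shape
    lam_chol = cholesky(post.lambda_n, lower=True)
    sig_chol = cholesky(np.atleast_2d(sigma_eps), lower=True)
    Z = rng.standard_normal((q, p))
    # row scale Lambda_n^-1 => multiply by inv(chol(Lambda_n))' on the left
    row_half = solve(lam_chol.T, Z)
    return post.beta_n + row_half @ sig_chol.T


def sample_sigma(post: PosteriorHyper, rng: np.random.Generator) -> np.ndarray:
    """Inverse-Wishart draw IW(V_n, nu_n)."""
    p = post.V_n.shape[0]
    if not post.nu_n > p - 1:
        raise ValueError("degrees of freedom too small for inverse-Wishart")
    draw = stats.invwishart.rvs(df=post.nu_n, scale=post.V_n, random_state=rng)
    draw = np.atleast_2d(draw)
    return 0.5 * (draw + draw.T)


@dataclass
class SamplerConfig:
    """Run-length, parameterisation and auxiliary-sampler settings.

    Defaults mirror the reference configuration: 12000 iterations with
    2000 burn-in, adaptation of the random-walk proposals during the
    first 1000 iterations, and 1000 auxiliary toggle steps per network
    simulation.
    """

    n_iter: int = 12000
    burn_in: int = 2000
    parameterization: str = "asis"
    aux: AuxSamplerConfig = field(default_factory=AuxSamplerConfig)
    rng_seed: int = 0
    thinning: int = 1
    adapt_window: int = 1000

    def __post_init__(self) -> None:
        if self.parameterization not in ("cp", "ncp", "asis"):
            raise ValueError("parameterization must be cp, ncp or asis")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class PosteriorSamples:
    """Stacked kept draws plus mixing diagnostics."""

    beta: np.ndarray  # K x q x p
    sigma_eps: np.ndarray  # K x p x p
    theta: np.ndarray  # K x n x p
    theta_accept_rate: np.ndarray  # per-network, post burn-in
    beta_accept_rate: float | None  # NCP move (ncp / asis only)
    delta_traces: dict
    stat_labels: list[str]
    config: SamplerConfig

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def beta_mean(self) -> np.ndarray:
        return self.beta.mean(axis=0)

    def beta_credible_interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        a = (1.0 - level) / 2.0
        return (
            np.quantile(self.beta, a, axis=0),
            np.quantile(self.beta, 1.0 - a, axis=0),
        )


class _GibbsRuntime:
    """Bookkeeping shared by the Gibbs step functions: per-network RNG
    streams, proposal states and adaptation histories.

    Per-network exchange updates each consume an independent child
    stream of the seed, so a hypothetical parallel execution would
    reproduce the serial chain exactly.
    """

    def __init__(self, data: PopulationData, cfg: SamplerConfig):
        n, p, q = data.n, data.p, data.q
        seq = np.random.SeedSequence(cfg.rng_seed)
        children = seq.spawn(n + 2)
        self.rng_theta = [np.random.Generator(np.random.PCG64(c)) for c in children[:n]]
        self.rng_gibbs = np.random.Generator(np.random.PCG64(children[n]))
        self.rng_beta = np.random.Generator(np.random.PCG64(children[n + 1]))
        self.props_theta = [ProposalState(d=p) for _ in range(n)]
        self.prop_beta = ProposalState(d=q * p)
        self.theta_history: list[list[np.ndarray]] = [[] for _ in range(n)]
        self.beta_history: list[np.ndarray] = []
        self.s_obs = data.observed_stats()
        self.theta_accepts = np.zeros(n, dtype=np.int64)
        self.theta_updates = 0
        self.beta_accepts = 0
        self.beta_updates = 0
        self.delta_traces: dict = {"theta": [[] for _ in range(n)], "beta": []}

    def record_history(self, state: PopulationState) -> None:
        for i in range(len(self.props_theta)):
            self.theta_history[i].append(state.theta[i].copy())
        self.beta_history.append(state.beta.ravel().copy())

    def adapt_all(self) -> None:
        for i, prop in enumerate(self.props_theta):
            rate = prop.batch_accepts / max(prop.batch_proposals, 1)
            adapt_step(prop, np.asarray(self.theta_history[i]), rate)
            self.delta_traces["theta"][i].append(prop.delta)
        if self.beta_updates > 0:
            rate = self.prop_beta.batch_accepts / max(self.prop_beta.batch_proposals, 1)
            adapt_step(self.prop_beta, np.asarray(self.beta_history), rate)
            self.delta_traces["beta"].append(self.prop_beta.delta)

    def freeze(self) -> None:
        for prop in self.props_theta:
            prop.freeze()
        self.prop_beta.freeze()
        self.theta_history = [[] for _ in self.props_theta]
        self.beta_history = []


def _update_thetas(
    state: PopulationState,
    data: PopulationData,
    rt: _GibbsRuntime,
    cfg: SamplerConfig,
) -> None:
    """Exchange update of each theta_i given (beta, Sigma_eps)."""
    mu = state.mu
    rt.theta_updates += 1
    for i, y in enumerate(data.networks):
        prior_i = GaussianPrior(mu[i], state.sigma_eps)
        theta_i, acc = exchange_update(
            state.theta[i],
            y,
            data.spec,
            prior_i,
            rt.props_theta[i],
            cfg.aux,
            rt.rng_theta[i],
            s_obs=rt.s_obs[i],
        )
        state.theta[i] = theta_i
        if acc:
            rt.theta_accepts[i] += 1


def _ncp_beta_move(
    state: PopulationState,
    data: PopulationData,
    prior: PriorHyper,
    rt: _GibbsRuntime,
    cfg: SamplerConfig,
) -> None:
    """Non-centred exchange update of beta holding epsilon fixed.

    Requires one auxiliary network per observed network, simulated at
    theta_i' = x_i' beta' + eps_i; Sigma_eps is held fixed.
    """
    eps = state.epsilon
    q, p = state.beta.shape
    beta_prime = propose(state.beta.ravel(), rt.prop_beta, rt.rng_beta).reshape(q, p)
    theta_prime = data.X @ beta_prime + eps
    s_aux = []
    for i, y in enumerate(data.networks):
        y_prime = simulate_ergm(theta_prime[i], data.spec, y, cfg.aux, rt.rng_beta)
        s_aux.append(summary_stats(y_prime, data.spec))
    beta_prior = MatrixNormalPrior(prior.beta0, prior.lambda0)
    lr = ncp_beta_log_ratio(
        state.beta,
        beta_prime,
        data.X,
        list(rt.s_obs),
        s_aux,
        beta_prior,
        state.sigma_eps,
    )
    accepted = np.log(rt.rng_beta.random()) < lr
    rt.prop_beta.record(bool(accepted))
    rt.beta_updates += 1
    if accepted:
        rt.beta_accepts += 1
        state.beta = beta_prime
    state.theta = state.X @ state.beta + eps


def gibbs_step_cp(
    state: PopulationState,
    data: PopulationData,
    prior: PriorHyper,
    rt: _GibbsRuntime,
    cfg: SamplerConfig,
) -> PopulationState:
    """One sweep of the centred exchange-within-Gibbs sampler:
    (a) exchange update of each theta_i, (b) conjugate redraw of
    (Sigma_eps, beta)."""
    _update_thetas(state, data, rt, cfg)
    post = conjugate_posterior(state.theta, data.X, prior)
    state.sigma_eps = sample_sigma(post, rt.rng_gibbs)
    state.beta = sample_beta(post, state.sigma_eps, rt.rng_gibbs)
    return state


def gibbs_step_ncp(
    state: PopulationState,
    data: PopulationData,
    prior: PriorHyper,
    rt: _GibbsRuntime,
    cfg: SamplerConfig,
) -> PopulationState:
    """One sweep of the non-centred sampler: exchange updates of the
    theta_i, an NCP exchange move of beta with epsilon fixed, then a
    conjugate redraw of Sigma_eps given (epsilon, beta)."""
    _update_thetas(state, data, rt, cfg)
    _ncp_beta_move(state, data, prior, rt, cfg)
    # Sigma_eps | eps, beta: both the residuals and the conditional
    # matrix-normal prior on beta carry Sigma_eps
    eps = state.epsilon
    dbeta = state.beta - prior.beta0
    scale = prior.V0 + eps.T @ eps + dbeta.T @ prior.lambda0 @ dbeta
    post = PosteriorHyper(
        beta_n=state.beta,
        lambda_n=prior.lambda0,
        V_n=0.5 * (scale + scale.T),
        nu_n=prior.nu0 + data.n + prior.q,
    )
    state.sigma_eps = sample_sigma(post, rt.rng_gibbs)
    return state


def gibbs_step_asis(
    state: PopulationState,
    data: PopulationData,
    prior: PriorHyper,
    rt: _GibbsRuntime,
    cfg: SamplerConfig,
) -> PopulationState:
    """One interweaved sweep: the centred sweep followed by a
    non-centred redraw of beta (epsilon and Sigma_eps held fixed),
    finishing with theta = X beta + epsilon."""
    gibbs_step_cp(state, data, prior, rt, cfg)
    _ncp_beta_move(state, data, prior, rt, cfg)
    return state


_STEPS = {"cp": gibbs_step_cp, "ncp": gibbs_step_ncp, "asis": gibbs_step_asis}


def run_sampler(
    data: PopulationData, prior: PriorHyper, cfg: SamplerConfig
) -> PosteriorSamples:
    """Run the configured exchange-within-Gibbs sampler.

    Proposals adapt every 20 iterations during the first
    ``cfg.adapt_window`` iterations and are frozen afterwards
    (diminishing adaptation). Deterministic given ``cfg.rng_seed``.
    """
    n, p, q = data.n, data.p, data.q
    if prior.p != p or prior.q != q:
        raise ValueError("prior dimensions do not match the data")
    step = _STEPS[cfg.parameterization]
    rt = _GibbsRuntime(data, cfg)

    # neutral start: theta at the prior regression mean
    beta = prior.beta0.copy()
    sigma = prior.V0 / max(prior.nu0 - p - 1, 1.0)
    state = PopulationState(
        theta=data.X @ beta, beta=beta, sigma_eps=sigma.copy(), X=data.X
    )
    logger.info(
        "starting %s sampler: n=%d networks, p=%d stats, q=%d covariates, "
        "%d iterations (%d burn-in)",
        cfg.parameterization,
        n,
        p,
        q,
        cfg.n_iter,
        cfg.burn_in,
    )

    n_keep = (cfg.n_iter - cfg.burn_in + cfg.thinning - 1) // cfg.thinning
    kept_beta = np.empty((n_keep, q, p))
    kept_sigma = np.empty((n_keep, p, p))
    kept_theta = np.empty((n_keep, n, p))
    k = 0
    post_burn_updates = 0
    post_burn_accepts = np.zeros(n, dtype=np.int64)
    for it in range(1, cfg.n_iter + 1):
        pre_accepts = rt.theta_accepts.copy()
        step(state, data, prior, rt, cfg)
        if it <= cfg.adapt_window:
            rt.record_history(state)
            if it % ADAPT_BATCH == 0:
                rt.adapt_all()
            if it == cfg.adapt_window:
                rt.freeze()
                logger.info("adaptation frozen after %d iterations", it)
        if it > cfg.burn_in:
            post_burn_updates += 1
            post_burn_accepts += rt.theta_accepts - pre_accepts
            if (it - cfg.burn_in - 1) % cfg.thinning == 0:
                kept_beta[k] = state.beta
                kept_sigma[k] = state.sigma_eps
                kept_theta[k] = state.theta
                k += 1

    beta_rate = rt.beta_accepts / rt.beta_updates if rt.beta_updates else None
    return PosteriorSamples(
        beta=kept_beta[:k],
        sigma_eps=kept_sigma[:k],
        theta=kept_theta[:k],
        theta_accept_rate=post_burn_accepts / max(post_burn_updates, 1),
        beta_accept_rate=beta_rate,
        delta_traces=rt.delta_traces,
        stat_labels=data.spec.labels,
        config=cfg,
    )
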