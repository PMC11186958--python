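"""Synthetic-population generators and correlation-matrix thresholding.

Three simulation designs produce populations of 30-node, two-hemisphere
networks from a 3-term ERGM (edges, nodematch on hemisphere, gwesp with
decay 0.9), with network-level parameters drawn from a Gaussian around
a design-dependent mean:

* ``no_covariate`` - a single group with mean mu = (-3, 0.5, 0.5);
* ``continuous``   - means uniformly spaced between b = (-2.6, 0.5, 0.2)
  and a = (-3, 0.5, 0.5), fitted with design rows (1, (i-1)/(n-1));
* ``binary``       - two groups with means a and b and a one-hot
  two-column design.

The shared residual covariance is (1/50) [[1, -.5, 0], [-.5, .5, 0],
[0, 0, .5]]. A factor-model generator of subject correlation matrices
plus degree-targeted thresholding covers the correlation-network path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ergm import AuxSamplerConfig, simulate_ergm
from .multilevel import PopulationData
from .netstats import Graph, StatisticSpec

__all__ = [
    "DEFAULT_MU",
    "DEFAULT_MU_A",
    "DEFAULT_MU_B",
    "DEFAULT_SIGMA",
    "SimulationDesign",
    "ThresholdRule",
    "default_spec",
    "hemisphere_template",
    "generate_population",
    "threshold_correlation",
    "find_threshold",
    "generate_correlation_population",
]

DEFAULT_MU = np.array([-3.0, 0.5, 0.5])
DEFAULT_MU_A = np.array([-3.0, 0.5, 0.5])
DEFAULT_MU_B = np.array([-2.6, 0.5, 0.2])
DEFAULT_SIGMA = (
    np.array(
        [
            [1.0, -0.5, 0.0],
            [-0.5, 0.5, 0.0],
            [0.0, 0.0, 0.5],
        ]
    )
    / 50.0
)

#: toggle steps used to simulate each data network (long run, well past
#: the auxiliary-draw default, so the networks are close to exact draws)
DATA_SIM_STEPS = 20000


def default_spec(tau: float = 0.9) -> StatisticSpec:
    """The 3-term spec: edges, nodematch(hemisphere), gwesp(tau)."""
    return StatisticSpec.from_strings(["edges", "nodematch(hemisphere)", f"gwesp({tau:g})"])


def hemisphere_template(n_nodes: int = 30) -> Graph:
    """Empty graph with two hemispheres of N/2 nodes and mirror
    homotopy partners (node j in hemisphere L pairs with j + N/2)."""
    if n_nodes % 2 != 0:
        raise ValueError("hemisphere template needs an even node count")
    half = n_nodes // 2
    hemi = np.array(["L"] * half + ["R"] * half)
    partner = np.concatenate([np.arange(half) + half, np.arange(half)])
    return Graph.empty(n_nodes, hemisphere=hemi, homotopy_partner=partner)


@dataclass
class SimulationDesign:
    """Description of one synthetic-population draw."""

    setting: str = "no_covariate"
    n: int = 10  # networks per group for "binary", total otherwise
    n_nodes: int = 30
    tau: float = 0.9
    mu: np.ndarray = field(default_factory=lambda: DEFAULT_MU.copy())
    mu_a: np.ndarray = field(default_factory=lambda: DEFAULT_MU_A.copy())
    mu_b: np.ndarray = field(default_factory=lambda: DEFAULT_MU_B.copy())
    sigma: np.ndarray = field(default_factory=lambda: DEFAULT_SIGMA.copy())
    rng_seed: int = 0
    sim_steps: int = DATA_SIM_STEPS

    def __post_init__(self) -> None:
        if self.setting not in ("no_covariate", "continuous", "binary"):
            raise ValueError(f"unknown simulation setting {self.setting!r}")
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if not np.allclose(self.sigma, self.sigma.T) or np.any(
            np.linalg.eigvalsh(self.sigma) <= 0
        ):
            raise ValueError("sigma must be symmetric positive definite")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _design_means(design: SimulationDesign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-network means mu_i, the design matrix X and true beta."""
    n = design.n
    if design.setting == "no_covariate":
        mu = np.tile(design.mu, (n, 1))
        X = np.ones((n, 1))
        beta_true = design.mu[None, :]
    elif design.setting == "continuous":
        # means uniformly spaced from b (i=1) to a (i=n); covariate
        # t_i = (i-1)/(n-1) so that beta rows are (b, a-b)
        t = np.arange(n) / max(n - 1, 1)
        mu = design.mu_b[None, :] + t[:, None] * (design.mu_a - design.mu_b)[None, :]
        X = np.column_stack([np.ones(n), t])
        beta_true = np.vstack([design.mu_b, design.mu_a - design.mu_b])
    else:  # binary: n networks per group, one-hot design
        mu = np.vstack([np.tile(design.mu_a, (n, 1)), np.tile(design.mu_b, (n, 1))])
        X = np.zeros((2 * n, 2))
        X[:n, 0] = 1.0
        X[n:, 1] = 1.0
        beta_true = np.vstack([design.mu_a, design.mu_b])
    return mu, X, beta_true


def generate_population(design: SimulationDesign) -> tuple[PopulationData, dict]:
    """Draw theta_i ~ N(mu_i, Sigma), simulate each network from the
    3-term ERGM with a long toggle run, and return the population plus
    the generative truth (mu_i, theta_i, beta, Sigma, seed)."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(design.rng_seed)))
    spec = default_spec(design.tau)
    template = hemisphere_template(design.n_nodes)
    mu, X, beta_true = _design_means(design)
    n_total = mu.shape[0]
    chol = np.linalg.cholesky(design.sigma)
    theta = mu + rng.standard_normal((n_total, design.sigma.shape[0])) @ chol.T
    aux = AuxSamplerConfig(n_aux=design.sim_steps, init_mode="random", init_density=0.1)
    networks = [
        simulate_ergm(theta[i], spec, template, aux, rng) for i in range(n_total)
    ]
    truth = {
        "setting": design.setting,
        "mu": mu,
        "theta": theta,
        "beta": beta_true,
        "sigma": design.sigma,
        "rng_seed": design.rng_seed,
    }
    return PopulationData(networks=networks, X=X, spec=spec), truth


@dataclass
class ThresholdRule:
    """How to binarise correlation matrices: a fixed cut-off r or a
    population-wide mean-degree target (default 3)."""

    mode: str = "target_mean_degree"
    r: float | None = None
    target_degree: float = 3.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_r", "target_mean_degree"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "fixed_r":
            if self.r is None or not -1.0 <= self.r <= 1.0:
                raise ValueError("fixed_r mode needs r in [-1, 1]")


def threshold_correlation(
    C: np.ndarray,
    r: float,
    hemisphere=None,
    homotopy_partner=None,
) -> Graph:
    """Binarise a correlation matrix: edge iff C_kl >= r (k != l)."""
    C = np.asarray(C, dtype=np.float64)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    A = (C >= r).astype(np.int8)
    np.fill_diagonal(A, 0)
    A = np.maximum(A, A.T)  # guard against asymmetric float ties
    return Graph(A, hemisphere, homotopy_partner)


def _mean_degree_at(Cs: list[np.ndarray], r: float) -> float:
    degs = []
    for C in Cs:
        g = threshold_correlation(C, r)
        degs.append(g.degrees().mean())
    return float(np.mean(degs))


def find_threshold(Cs: list[np.ndarray], target_degree: float = 3.0) -> float:
    """Threshold r whose population mean node degree is the largest
    value not exceeding the target.

    Mean degree is a decreasing step function of r with jumps at the
    observed off-diagonal values, so the search scans that candidate
    set. If every candidate overshoots the target (unreachable), the
    sparsest achievable threshold is returned with a warning.
    """
    if not Cs:
        raise ValueError("need at least one correlation matrix")
    candidates = set()
    for C in Cs:
        C = np.asarray(C, dtype=np.float64)
        iu = np.triu_indices(C.shape[0], k=1)
        candidates.update(np.unique(C[iu]).tolist())
    candidates = np.asarray(sorted(candidates))
    # degrees are monotone in r: binary search for the smallest r with
    # mean degree <= target
    lo, hi = 0, len(candidates) - 1
    if _mean_degree_at(Cs, candidates[0]) <= target_degree:
        return float(candidates[0])
    if _mean_degree_at(Cs, candidates[-1]) > target_degree:
        import warnings

        warnings.warn(
            "target mean degree unreachable; returning the sparsest achievable threshold"
        )
        return float(np.nextafter(candidates[-1], np.inf))
    while lo < hi:
        mid = (lo + hi) // 2
        if _mean_degree_at(Cs, candidates[mid]) <= target_degree:
            hi = mid
        else:
            lo = mid + 1
    return float(candidates[lo])


def generate_correlation_population(
    n: int,
    n_nodes: int,
    n_factors: int = 3,
    noise: float = 0.3,
    rng_seed: int = 0,
    loadings: np.ndarray | None = None,
) -> list[np.ndarray]:
    """fMRI-like subject correlation matrices from a shared factor model.

    Each subject's loadings are the shared loadings plus independent
    Gaussian noise; the implied covariance (plus a small diagonal) is
    normalised to a correlation matrix. With ``noise = 0`` all subjects
    are identical.
    """
    if n < 1 or n_nodes < 2:
        raise ValueError("need n >= 1 subjects and >= 2 nodes")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(rng_seed)))
    if loadings is None:
        loadings = rng.standard_normal((n_nodes, n_factors))
    else:
        loadings = np.asarray(loadings, dtype=np.float64)
        n_factors = loadings.shape[1]
    out = []
    for _ in range(n):
        W = loadings + noise * rng.standard_normal((n_nodes, n_factors))
        S = W @ W.T + 0.1 * np.eye(n_nodes)
        d = 1.0 / np.sqrt(np.diag(S))
        C = d[:, None] * S * d[None, :]
        np.fill_diagonal(C, 1.0)
        out.append(0.5 * (C + C.T))
    return out
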