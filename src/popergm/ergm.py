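"""The ERGM distribution: unnormalised log-probability, network
simulation by dyad-toggle Metropolis-Hastings, and an exact-enumeration
oracle for tiny node sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from . import _kernels
from .netstats import GWESP, NODEMATCH, Graph, StatisticSpec, summary_stats

__all__ = [
    "AuxSamplerConfig",
    "log_unnorm",
    "exact_log_partition",
    "enumerate_graphs",
    "simulate_ergm",
]

logger = logging.getLogger(__name__)

_ENUM_MAX_NODES = 6
_LARGE_N_WARN = 60


@dataclass
class AuxSamplerConfig:
    """Configuration of the auxiliary network sampler.

    ``init_mode``: "observed" starts the chain at the template's edge
    set (the variance-reduction convention for exchange updates),
    "empty" at the empty graph, "random" at an Erdos-Renyi draw of
    density ``init_density``.
    """

    n_aux: int = 1000
    init_mode: str = "observed"
    init_density: float = 0.5

    def __post_init__(self) -> None:
        if self.n_aux < 1:
            raise ValueError("n_aux must be >= 1")
        if self.init_mode not in ("observed", "empty", "random"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


def _check_theta(theta: np.ndarray, spec: StatisticSpec) -> np.ndarray:
    theta = np.asarray(theta, dtype=np.float64)
    if theta.shape != (spec.p,):
        raise ValueError(f"theta has shape {theta.shape}, expected ({spec.p},)")
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    return theta


def log_unnorm(g: Graph, theta: np.ndarray, spec: StatisticSpec) -> float:
    """theta' s(y) - the log-probability up to the normalising constant."""
    theta = _check_theta(theta, spec)
    return float(theta @ summary_stats(g, spec))


def enumerate_graphs(template: Graph):
    """Yield every graph on the template's node set (N <= 6 only)."""
    n = template.n_nodes
    if n > _ENUM_MAX_NODES:
        raise ValueError(f"exhaustive enumeration supports N <= {_ENUM_MAX_NODES}")
    dyads = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for bits in itertools.product((0, 1), repeat=len(dyads)):
        A = np.zeros((n, n), dtype=np.int8)
        for (i, j), b in zip(dyads, bits):
            A[i, j] = A[j, i] = b
        yield template.with_adjacency(A)


def exact_log_partition(theta: np.ndarray, spec: StatisticSpec, template: Graph) -> float:
    """log Z(theta) by literal summation over all 2^(N(N-1)/2) graphs."""
    theta = _check_theta(theta, spec)
    logw = [theta @ summary_stats(g, spec) for g in enumerate_graphs(template)]
    return float(logsumexp(logw))


def _encode_spec(spec: StatisticSpec, g: Graph):
    """Map a StatisticSpec + graph attributes to kernel arrays."""
    codes = np.empty(spec.p, dtype=np.int64)
    taus = np.zeros(spec.p, dtype=np.float64)
    labels = np.zeros(g.n_nodes, dtype=np.int64)
    partner = np.full(g.n_nodes, -1, dtype=np.int64)
    for m, term in enumerate(spec.terms):
        if term.kind == "edges":
            codes[m] = _kernels.TERM_EDGES
        elif term.kind == NODEMATCH:
            codes[m] = _kernels.TERM_NODEMATCH
            if g.hemisphere is None:
                raise ValueError("spec needs hemisphere labels but graph has none")
            _, labels = np.unique(np.asarray(g.hemisphere), return_inverse=True)
            labels = labels.astype(np.int64)
        elif term.kind == "nodematch_homotopy":
            codes[m] = _kernels.TERM_HOMOTOPY
            if g.homotopy_partner is None:
                raise ValueError("spec needs a homotopy partner map but graph has none")
            partner = g.homotopy_partner.astype(np.int64)
        elif term.kind == GWESP:
            codes[m] = _kernels.TERM_GWESP
            taus[m] = term.tau
    return codes, taus, labels, partner


def _initial_adjacency(template: Graph, cfg: AuxSamplerConfig, rng: np.random.Generator):
    n = template.n_nodes
    if cfg.init_mode == "observed":
        return template.adjacency.copy()
    if cfg.init_mode == "empty":
        return np.zeros((n, n), dtype=np.int8)
    upper = (rng.random((n, n)) < cfg.init_density).astype(np.int8)
    A = np.triu(upper, k=1)
    return (A + A.T).astype(np.int8)


def simulate_ergm(
    theta: np.ndarray,
    spec: StatisticSpec,
    template: Graph,
    cfg: AuxSamplerConfig,
    rng: np.random.Generator,
) -> Graph:
    """Approximate draw from the ERGM at theta.

    Runs ``cfg.n_aux`` single-dyad toggle Metropolis-Hastings steps
    (uniform random dyad, accept with probability min(1, exp(+-theta'
    delta))) from the configured initial state and returns the final
    graph. Deterministic given the generator state.
    """
    theta = _check_theta(theta, spec)
    n = template.n_nodes
    if n < 2:
        return template.copy()
    if n > _LARGE_N_WARN:
        logger.warning(
            "simulating an ERGM on %d nodes; fixed n_aux=%d may be too short "
            "for networks this large",
            n,
            cfg.n_aux,
        )
    A = _initial_adjacency(template, cfg, rng)
    codes, taus, labels, partner = _encode_spec(spec, template)

    # pre-draw the chain's randomness: dyads i<j and acceptance uniforms
    flat = rng.integers(0, n * (n - 1) // 2, size=cfg.n_aux)
    ii, jj = _dyad_from_flat(flat, n)
    logu = np.log(rng.random(cfg.n_aux))
    _kernels.toggle_chain(A, theta, codes, taus, labels, partner, ii, jj, logu)
    return template.with_adjacency(A)


def _dyad_from_flat(flat: np.ndarray, n: int):
    """Map flat indices 0..n(n-1)/2-1 to dyads (i < j)."""
    iu, ju = np.triu_indices(n, k=1)
    return iu[flat].astype(np.int64), ju[flat].astype(np.int64)
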