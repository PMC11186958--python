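"""Posterior predictive goodness-of-fit assessment.

Networks are simulated at posterior draws of the group-level mean
parameters and their degree / geodesic / edgewise-shared-partner
distributions are compared to those of the observed networks via
pointwise quantile bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ergm import AuxSamplerConfig, simulate_ergm
from .multilevel import PosteriorSamples
from .netstats import Graph, StatisticSpec, metric_distributions

__all__ = ["GofConfig", "GofSummary", "posterior_predictive", "gof_summary"]

METRICS = ("degree", "geodesic", "esp")


@dataclass
class GofConfig:
    """S posterior draws are used, one predictive network per distinct
    design row per draw; bands are central quantile intervals."""

    S: int = 100
    band: float = 0.90
    rng_seed: int = 0
    include_residual: bool = False  # add a Sigma_eps draw to the mean

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if not 0.0 < self.band < 1.0:
            raise ValueError("band must lie in (0, 1)")


@dataclass
class GofSummary:
    """Observed metric distributions and predictive quantile bands.

    ``table`` is long-format with columns metric, group, abscissa,
    observed_median, observed_lo, observed_hi, band_lo, band_hi,
    predictive_median.
    """

    table: pd.DataFrame
    band: float

    def metric(self, name: str) -> pd.DataFrame:
        return self.table[self.table["metric"] == name]


def _distinct_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique design rows and the per-network group index."""
    X = np.atleast_2d(X)
    uniq, inverse = np.unique(X, axis=0, return_inverse=True)
    return uniq, inverse


def posterior_predictive(
    samples: PosteriorSamples,
    X: np.ndarray,
    spec: StatisticSpec,
    template: Graph,
    cfg: GofConfig,
    aux: AuxSamplerConfig | None = None,
) -> list[tuple[int, int, Graph]]:
    """Simulate predictive networks at S random posterior beta draws.

    For each chosen draw s and each distinct design row x_g, one network
    is simulated at the mean parameter x_g' beta^(s) (optionally plus a
    residual drawn from the paired Sigma_eps sample). Returns
    (draw index, group index, graph) tags.
    """
    if samples.n_draws < 1:
        raise ValueError("posterior sample is empty")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg.rng_seed)))
    if aux is None:
        aux = AuxSamplerConfig(n_aux=samples.config.aux.n_aux, init_mode="random")
    # predictive chains start from matched-density Erdos-Renyi draws
    if aux.init_mode == "observed":
        aux = AuxSamplerConfig(aux.n_aux, "random", template.density() or 0.5)
    rows, _ = _distinct_rows(X)
    picks = rng.integers(0, samples.n_draws, size=cfg.S)
    out = []
    for s in picks:
        beta = samples.beta[s]
        for g_idx, x in enumerate(rows):
            theta = x @ beta
            if cfg.include_residual:
                chol = np.linalg.cholesky(samples.sigma_eps[s])
                theta = theta + chol @ rng.standard_normal(beta.shape[1])
            graph = simulate_ergm(theta, spec, template, aux, rng)
            out.append((int(s), int(g_idx), graph))
    return out


def _metric_matrix(graphs: list[Graph], metric: str) -> np.ndarray:
    """Stack one metric distribution per graph (rows)."""
    rows = []
    for g in graphs:
        md = metric_distributions(g)
        if metric == "degree":
            rows.append(md.degree)
        elif metric == "geodesic":
            rows.append(np.concatenate([md.geodesic, [md.geodesic_inf]]))
        else:
            rows.append(md.esp)
    return np.asarray(rows, dtype=np.float64)


def _abscissae(metric: str, n_cols: int) -> list[str]:
    if metric == "degree":
        return [str(d) for d in range(n_cols)]
    if metric == "geodesic":
        return [str(d) for d in range(1, n_cols)] + ["inf"]
    return [str(w) for w in range(n_cols)]


def gof_summary(
    observed: list[Graph],
    predictive: list[tuple[int, int, Graph]],
    cfg: GofConfig,
    X: np.ndarray | None = None,
) -> GofSummary:
    """Pointwise predictive quantile bands against observed metrics.

    Observed networks are grouped by their design row when ``X`` is
    given (matching the per-group predictive tags); otherwise a single
    group is assumed.
    """
    if not observed or not predictive:
        raise ValueError("observed and predictive network sets must be non-empty")
    if X is not None:
        _, group_of = _distinct_rows(X)
    else:
        group_of = np.zeros(len(observed), dtype=int)
    alpha = (1.0 - cfg.band) / 2.0
    records = []
    for g_idx in np.unique(group_of):
        obs_g = [g for g, gi in zip(observed, group_of) if gi == g_idx]
        pred_g = [g for _, gi, g in predictive if gi == g_idx]
        if not pred_g:
            continue
        for metric in METRICS:
            obs_m = _metric_matrix(obs_g, metric)
            pred_m = _metric_matrix(pred_g, metric)
            n_cols = max(obs_m.shape[1], pred_m.shape[1])
            obs_m = np.pad(obs_m, ((0, 0), (0, n_cols - obs_m.shape[1])))
            pred_m = np.pad(pred_m, ((0, 0), (0, n_cols - pred_m.shape[1])))
            labels = _abscissae(metric, n_cols)
            for c in range(n_cols):
                records.append(
                    {
                        "metric": metric,
                        "group": int(g_idx),
                        "abscissa": labels[c],
                        "observed_median": float(np.median(obs_m[:, c])),
                        "observed_lo": float(np.min(obs_m[:, c])),
                        "observed_hi": float(np.max(obs_m[:, c])),
                        "band_lo": float(np.quantile(pred_m[:, c], alpha)),
                        "band_hi": float(np.quantile(pred_m[:, c], 1.0 - alpha)),
                        "predictive_median": float(np.median(pred_m[:, c])),
                    }
                )
    return GofSummary(table=pd.DataFrame.from_records(records), band=cfg.band)
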