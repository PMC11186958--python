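"""Run configuration: a YAML-serialisable record of every knob a
simulate/fit/gof run needs. Defaults equal the reference values
(12000/2000/1000/1000 run lengths, gamma = 0.05 proposals, S = 100
predictive draws, 90% bands)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .ergm import AuxSamplerConfig
from .gof import GofConfig
from .multilevel import SamplerConfig
from .netstats import StatisticSpec

__all__ = ["RunConfig"]

_DEFAULT_TERMS = ["edges", "nodematch(hemisphere)", "gwesp(0.9)"]


@dataclass
class RunConfig:
    """All settings of a full simulate -> fit -> gof workflow."""

    spec_terms: list[str] = field(default_factory=lambda: list(_DEFAULT_TERMS))
    prior: str = "default"
    n_iter: int = 12000
    burn_in: int = 2000
    adapt_window: int = 1000
    n_aux: int = 1000
    parameterization: str = "asis"
    thinning: int = 1
    gof_S: int = 100
    gof_band: float = 0.90
    seed: int = 0
    bundle: str | None = None
    out: str | None = None

    def statistic_spec(self) -> StatisticSpec:
        return StatisticSpec.from_strings(self.spec_terms)

    def sampler_config(self) -> SamplerConfig:
        return SamplerConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            parameterization=self.parameterization,
            aux=AuxSamplerConfig(n_aux=self.n_aux),
            rng_seed=self.seed,
            thinning=self.thinning,
            adapt_window=self.adapt_window,
        )

    def gof_config(self) -> GofConfig:
        return GofConfig(S=self.gof_S, band=self.gof_band, rng_seed=self.seed)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.statistic_spec()  # validate terms
        cfg.sampler_config()  # validate run lengths
        cfg.gof_config()
        return cfg
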