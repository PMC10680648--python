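"""JSON-serializable run configuration.

A :class:`RunConfig` captures everything a simulation run needs -- the
populations, the effect model, the design flags and the seed -- and
round-trips losslessly through JSON. Unknown keys are rejected so that a
typo in a config file fails loudly rather than silently using a default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import simulate as sim

__all__ = [
    "PopulationConfig",
    "EffectModelConfig",
    "TwoLocusConfig",
    "PGSConfig",
    "RunConfig",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PopulationConfig(_Strict):
    label: str
    allele_freq: float | list[float] | None = None
    env_effect_dev: float = 0.0
    n_families: int = Field(default=1, ge=1)
    inbreeding_F: float = Field(default=0.0, ge=0.0, le=1.0)

    def to_spec(self) -> sim.PopulationSpec:
        return sim.PopulationSpec(
            label=self.label,
            allele_freq=self.allele_freq,
            env_effect_dev=self.env_effect_dev,
            n_families=self.n_families,
            inbreeding_F=self.inbreeding_F,
        )


class EffectModelConfig(_Strict):
    intercept: float = 0.0
    alpha: float = 1.0
    sd_family_dev: float = Field(default=0.0, ge=0.0)
    sd_indiv_dev: float = Field(default=0.0, ge=0.0)
    sd_env_family: float = Field(default=0.0, ge=0.0)
    sd_env_indiv: float = Field(default=0.0, ge=0.0)

    def to_model(self) -> sim.LocusEffectModel:
        return sim.LocusEffectModel(**self.model_dump())


class TwoLocusConfig(_Strict):
    hap_freqs: dict[str, list[float]] = Field(default_factory=dict)
    recomb_fraction: float = Field(default=0.0, ge=0.0, le=0.5)
    causal_alpha: float = 1.0
    intercept: float = 0.0
    sd_env_indiv: float = Field(default=0.0, ge=0.0)

    def to_model(self) -> sim.TwoLocusModel:
        return sim.TwoLocusModel(**self.model_dump())


class PGSConfig(_Strict):
    p: list[float]
    alpha: list[float]
    beta_hat: list[float]
    pgs_loci: list[int] | None = None
    population_dev: dict[str, list[float]] | None = None
    multiplicative_C: dict[str, float] | None = None
    indiv_dev_sd: float | list[float] = 0.0
    intercept: float = 0.0
    sd_env_family: float = Field(default=0.0, ge=0.0)
    sd_env_indiv: float = Field(default=0.0, ge=0.0)

    def to_model(self) -> sim.PGSModel:
        return sim.PGSModel(
            p=np.asarray(self.p),
            alpha=np.asarray(self.alpha),
            beta_hat=np.asarray(self.beta_hat),
            pgs_loci=None if self.pgs_loci is None else np.asarray(self.pgs_loci),
            population_dev=self.population_dev,
            multiplicative_C=self.multiplicative_C,
            indiv_dev_sd=np.asarray(self.indiv_dev_sd)
            if isinstance(self.indiv_dev_sd, list)
            else self.indiv_dev_sd,
            intercept=self.intercept,
            sd_env_family=self.sd_env_family,
            sd_env_indiv=self.sd_env_indiv,
        )


class RunConfig(_Strict):
    """Top-level configuration for one simulation or prediction run."""

    seed: int = 0
    kind: Literal["single_locus", "two_locus", "pgs"] = "single_locus"
    populations: list[PopulationConfig]
    effect_model: EffectModelConfig = Field(default_factory=EffectModelConfig)
    two_locus: TwoLocusConfig | None = None
    pgs: PGSConfig | None = None
    children_per_family: int = Field(default=1, ge=1)
    parental_control: Literal["separate", "sum"] = "separate"
    out_prefix: str | None = None
    verbosity: Literal["debug", "info", "warning"] = "info"

    # ------------------------------------------------------------------
    def specs(self) -> list[sim.PopulationSpec]:
        return [p.to_spec() for p in self.populations]

    def simulate(self, seed: int | None = None):
        """Generate the cohort this configuration describes."""
        use_seed = self.seed if seed is None else seed
        if self.kind == "single_locus":
            return sim.simulate_cohort(
                self.specs(), self.effect_model.to_model(),
                self.children_per_family, use_seed,
            )
        if self.kind == "two_locus":
            if self.two_locus is None:
                raise ValueError("kind='two_locus' requires a two_locus section")
            return sim.simulate_two_locus_cohort(
                self.two_locus.to_model(), self.specs(),
                self.children_per_family, use_seed,
            )
        if self.pgs is None:
            raise ValueError("kind='pgs' requires a pgs section")
        return sim.simulate_pgs_cohort(
            self.pgs.to_model(), self.specs(), self.children_per_family, use_seed
        )

    # ------------------------------------------------------------------
    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.model_dump(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text
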