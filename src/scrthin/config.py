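"""Study configuration: a flat, validated, round-trippable YAML mapping.

Defaults reproduce the reference design (8x8 grid / 800 m spacing,
sigma = 1000 m, lam0 = 0.1, K = 5, N = 10, 2500 m buffer, 3 colonies with
2000 m radius, removal fractions 0/0.25/0.5, 100 replicates, 3 chains of
5000 iterations with 1000 burn-in), so an empty config file runs the full
study as designed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from scrthin.estimator import MCMCConfig, PriorSpec
from scrthin.simulate import ScenarioConfig


@dataclass(frozen=True)
class StudyConfig:
    """Flat bag of every knob the study needs; unknown keys are rejected."""

    # geometry & detection
    nx: int = 8
    ny: int = 8
    spacing: float = 800.0
    buffer: float = 2500.0
    lam0: float = 0.1
    sigma: float = 1000.0
    K: int = 5
    n_true: int = 10
    # interference
    n_colonies: int = 3
    colony_radius: float = 2000.0
    removal_fractions: tuple[float, ...] = (0.0, 0.25, 0.5)
    # study size
    n_replicates: int = 100
    master_seed: int = 0
    # priors (uniform bounds; psi is Beta(a, b))
    lam0_prior: tuple[float, float] = (0.0, 5.0)
    sigma_prior: tuple[float, float] = (0.0, 5000.0)
    psi_prior: tuple[float, float] = (1.0, 1.0)
    # MCMC
    n_chains: int = 3
    n_iter: int = 5000
    n_burnin: int = 1000
    M: int = 60
    # execution
    out_dir: str = "scrthin_out"
    n_jobs: int = 1
    verbosity: int = 1

    def __post_init__(self) -> None:
        for frac in self.removal_fractions:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"removal fraction {frac} outside [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        # delegate the rest to the component configs
        self.scenario_config()
        self.mcmc_config()
        self.priors()

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        data = dict(data)
        for key in ("removal_fractions", "lam0_prior", "sigma_prior", "psi_prior"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("removal_fractions", "lam0_prior", "sigma_prior", "psi_prior"):
            d[key] = list(d[key])
        return d

    def scenario_config(self, removal_fraction: float = 0.0) -> ScenarioConfig:
        return ScenarioConfig(
            nx=self.nx,
            ny=self.ny,
            spacing=self.spacing,
            buffer=self.buffer,
            lam0=self.lam0,
            sigma=self.sigma,
            K=self.K,
            n_true=self.n_true,
            n_colonies=self.n_colonies,
            colony_radius=self.colony_radius,
            removal_fraction=removal_fraction,
            n_replicates=self.n_replicates,
            master_seed=self.master_seed,
        )

    def priors(self) -> PriorSpec:
        return PriorSpec(
            lam0=tuple(self.lam0_prior),
            sigma=tuple(self.sigma_prior),
            psi=tuple(self.psi_prior),
        )

    def mcmc_config(self) -> MCMCConfig:
        return MCMCConfig(
            n_chains=self.n_chains,
            n_iter=self.n_iter,
            n_burnin=self.n_burnin,
            M=self.M,
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path) -> StudyConfig:
    """Load a YAML config; omitted keys take the reference-design defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config at {path} must be a mapping")
    return StudyConfig.from_dict(data)
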