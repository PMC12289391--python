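"""Synthetic SCR data with colony-driven encounter removal.

The generator reproduces the study design this package quantifies: a fixed
population of activity centers uniform over a buffered state space, Poisson
encounters on a detector grid under the half-normal model, and an
interference process in which scavenging colonies delete each encounter
within a fixed radius independently with a given probability (binomial
thinning). Control and removal datasets are paired: they share activity
centers, colonies, and pre-removal encounters.

Defaults throughout are the study conditions: an 8x8 grid at 800 m spacing,
N = 10 individuals, sigma = 1000 m, lam0 = 0.1, K = 5 occasions, a 2.5 sigma
(2500 m) buffer, 3 colonies with 2000 m removal radius, removal fractions
{0, 0.25, 0.5} and 100 replicate configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from scrthin.geometry import DetectorGrid, StateSpace, build_detector_grid, build_state_space
from scrthin.model import DetectionParams, _rate_matrix

SeedLike = "int | np.random.SeedSequence | np.random.Generator"


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Population:
    """True abundance and activity-center coordinates for one replicate."""

    n: int
    centers: np.ndarray  # (n, 2) meters


@dataclass(frozen=True)
class EncounterData:
    """Individual-by-detector encounter counts accumulated over K occasions."""

    counts: np.ndarray  # (n_individuals, J) non-negative ints
    K: int

    @property
    def detected_mask(self) -> np.ndarray:
        return self.counts.sum(axis=1) > 0

    @property
    def n_detected(self) -> int:
        return int(self.detected_mask.sum())

    def observed(self) -> np.ndarray:
        """Rows of detected individuals only (what a survey yields)."""
        return self.counts[self.detected_mask]


@dataclass(frozen=True)
class ColonySet:
    """Interference sources: coordinates, removal radius and fraction."""

    coords: np.ndarray  # (n_colonies, 2) meters
    radius: float
    removal_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.removal_fraction <= 1.0:
            raise ValueError(
                f"removal_fraction must be in [0, 1], got {self.removal_fraction}"
            )
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")

    @property
    def n_colonies(self) -> int:
        return len(self.coords)

    def affected_detectors(self, grid: DetectorGrid) -> np.ndarray:
        """Boolean mask of detectors within ``radius`` of any colony."""
        if self.n_colonies == 0:
            return np.zeros(grid.n_detectors, dtype=bool)
        d2 = ((grid.coords[:, None, :] - self.coords[None, :, :]) ** 2).sum(axis=-1)
        return (d2.min(axis=1) <= self.radius**2)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one simulation scenario.

    ``master_seed`` plus a replicate index determines every random draw;
    sub-seeds for centers, encounters, colonies, thinning and MCMC are
    derived as independent substreams so that control and removal scenarios
    of the same replicate stay paired.
    """

    nx: int = 8
    ny: int = 8
    spacing: float = 800.0
    buffer: float = 2500.0
    lam0: float = 0.1
    sigma: float = 1000.0
    K: int = 5
    n_true: int = 10
    n_colonies: int = 3
    colony_radius: float = 2000.0
    removal_fraction: float = 0.0
    n_replicates: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.removal_fraction <= 1.0:
            raise ValueError("removal_fraction must be in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_true < 1:
            raise ValueError("n_true must be >= 1")

    def detector_grid(self) -> DetectorGrid:
        return build_detector_grid(self.nx, self.ny, self.spacing)

    def state_space(self) -> StateSpace:
        return build_state_space(self.detector_grid(), self.buffer)

    def detection_params(self) -> DetectionParams:
        return DetectionParams(lam0=self.lam0, sigma=self.sigma, K=self.K)


# named substreams per replicate; MCMC seeds live alongside (key 4 + scenario)
_STREAM_CENTERS, _STREAM_ENCOUNTERS, _STREAM_COLONIES, _STREAM_THIN, _STREAM_MCMC = range(5)


def replicate_seed(master_seed: int, replicate_index: int, stream: int, extra: int = 0):
    """Deterministic, collision-free substream for one replicate and purpose."""
    return np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(int(replicate_index), int(stream), int(extra))
    )


def simulate_activity_centers(n: int, space: StateSpace, seed) -> Population:
    """Draw ``n`` i.i.d. uniform activity centers in the state-space rectangle."""
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    rng = _rng(seed)
    xy = np.column_stack(
        [
            rng.uniform(space.xmin, space.xmax, size=n),
            rng.uniform(space.ymin, space.ymax, size=n),
        ]
    )
    return Population(n=int(n), centers=xy)


def simulate_encounters(
    pop: Population,
    grid: DetectorGrid,
    params: DetectionParams,
    seed,
) -> EncounterData:
    """Poisson encounters: counts[i, j] ~ Pois(K * lambda(d(center_i, x_j)))."""
    rng = _rng(seed)
    mu = params.K * _rate_matrix(pop.centers, grid.coords, params)
    counts = rng.poisson(mu)
    return EncounterData(counts=counts, K=params.K)


def place_colonies(
    n_colonies: int,
    grid: DetectorGrid,
    seed,
    radius: float = 2000.0,
    removal_fraction: float = 0.0,
) -> ColonySet:
    """Place colonies i.i.d. uniform over the detector-grid bounding box."""
    if n_colonies < 0:
        raise ValueError("n_colonies must be >= 0")
    rng = _rng(seed)
    xmin, xmax, ymin, ymax = grid.bounding_box()
    xy = np.column_stack(
        [
            rng.uniform(xmin, xmax, size=n_colonies),
            rng.uniform(ymin, ymax, size=n_colonies),
        ]
    )
    return ColonySet(coords=xy, radius=radius, removal_fraction=removal_fraction)


def apply_removal(
    y: EncounterData,
    grid: DetectorGrid,
    colonies: ColonySet,
    seed,
) -> EncounterData:
    """Thin encounters at detectors inside any colony's removal radius.

    Each encounter at an affected detector is deleted independently with
    probability ``colonies.removal_fraction`` (binomial thinning), so thinned
    counts remain Poisson with rate scaled by ``1 - removal_fraction``.
    Detectors outside all radii are untouched.
    """
    p = colonies.removal_fraction
    if p == 0.0 or colonies.n_colonies == 0:
        return EncounterData(counts=y.counts.copy(), K=y.K)
    rng = _rng(seed)
    affected = colonies.affected_detectors(grid)
    counts = y.counts.copy()
    kept = rng.binomial(counts[:, affected], 1.0 - p)
    counts[:, affected] = kept
    return EncounterData(counts=counts, K=y.K)


def generate_replicate(
    config: ScenarioConfig,
    replicate_index: int,
) -> tuple[Population, ColonySet, EncounterData, EncounterData]:
    """Generate one paired replicate: (population, colonies, control, removed).

    Control and removed datasets share the population, the colonies and the
    pre-removal encounters; only the thinning differs. Sub-seeds derive
    deterministically from ``(master_seed, replicate_index)``, so the same
    call is bit-reproducible and scenarios with different removal fractions
    stay paired.
    """
    if not 0 <= replicate_index < config.n_replicates:
        raise ValueError(
            f"replicate_index {replicate_index} outside [0, {config.n_replicates})"
        )
    grid = config.detector_grid()
    space = config.state_space()
    params = config.detection_params()
    ms, idx = config.master_seed, replicate_index

    pop = simulate_activity_centers(
        config.n_true, space, replicate_seed(ms, idx, _STREAM_CENTERS)
    )
    control = simulate_encounters(
        pop, grid, params, replicate_seed(ms, idx, _STREAM_ENCOUNTERS)
    )
    colonies = place_colonies(
        config.n_colonies,
        grid,
        replicate_seed(ms, idx, _STREAM_COLONIES),
        radius=config.colony_radius,
        removal_fraction=config.removal_fraction,
    )
    # thinning seed keyed by removal fraction so distinct fractions thin
    # independently while everything upstream stays shared
    thin_key = int(round(config.removal_fraction * 1000))
    removed = apply_removal(
        control, grid, colonies, replicate_seed(ms, idx, _STREAM_THIN, thin_key)
    )
    return pop, colonies, control, removed


def mcmc_seed(config: ScenarioConfig, replicate_index: int) -> np.random.SeedSequence:
    """Per-replicate, per-scenario seed for the sampler."""
    thin_key = int(round(config.removal_fraction * 1000))
    return replicate_seed(config.master_seed, replicate_index, _STREAM_MCMC, thin_key)
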