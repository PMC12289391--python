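"""Core SCR model objects: detection function and likelihoods.

The observation model is the Poisson encounter model with a half-normal
encounter-rate function,

    lambda(d) = lam0 * exp(-d^2 / (2 sigma^2)),

so the count of individual i at detector j accumulated over K occasions is
Poisson with mean ``K * lambda(d(s_i, x_j))`` given the activity center s_i.
Two likelihoods are provided:

* :func:`augmented_loglik` — the complete-data (augmented) log density used
  by the MCMC sampler, with explicit inclusion indicators z and activity
  centers s for a superpopulation of size M;
* :func:`marginal_loglik` — an integrated likelihood with activity centers
  marginalized over a mesh, under a Poisson point-process model for centers.
  It shares no code path with the sampler and serves as an independent
  cross-check (maximum-likelihood fits on small instances).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from scrthin.geometry import DetectorGrid, StateSpace


@dataclass(frozen=True)
class DetectionParams:
    """Half-normal detection parameters.

    Attributes
    ----------
    lam0 : float
        Baseline encounter rate: expected encounters per individual per
        detector per occasion at distance zero.
    sigma : float
        Spatial scale of detection decay, meters.
    K : int
        Number of sampling occasions; counts accumulate across occasions.
    """

    lam0: float
    sigma: float
    K: int

    def __post_init__(self) -> None:
        if self.lam0 <= 0:
            raise ValueError(f"lam0 must be positive, got {self.lam0}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if int(self.K) < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        object.__setattr__(self, "K", int(self.K))


@dataclass
class AugmentedState:
    """Current state of the data-augmented SCR model.

    The unknown population size N is embedded in a superpopulation of fixed
    size M; each member carries a Bernoulli(psi) inclusion indicator z and a
    latent activity center s, so N = sum(z).
    """

    M: int
    z: np.ndarray  # (M,) 0/1 inclusion indicators
    s: np.ndarray  # (M, 2) activity centers, meters
    psi: float
    params: DetectionParams

    @property
    def n_included(self) -> int:
        return int(self.z.sum())

    def copy(self) -> "AugmentedState":
        return AugmentedState(
            M=self.M,
            z=self.z.copy(),
            s=self.s.copy(),
            psi=self.psi,
            params=self.params,
        )


def encounter_rate(d, params: DetectionParams):
    """Half-normal encounter rate lambda(d) per individual-detector-occasion.

    Parameters
    ----------
    d : float or ndarray
        Distance(s) from activity center to detector, meters; must be >= 0.

    Returns
    -------
    float or ndarray
        ``lam0 * exp(-d^2 / (2 sigma^2))``, same shape as ``d``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = params.lam0 * np.exp(-(d**2) / (2.0 * params.sigma**2))
    return float(out) if out.ndim == 0 else out


def _rate_matrix(s: np.ndarray, detectors: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Per-occasion encounter rates, shape (n_centers, n_detectors)."""
    d2 = ((s[:, None, :] - detectors[None, :, :]) ** 2).sum(axis=-1)
    return params.lam0 * np.exp(-d2 / (2.0 * params.sigma**2))


def augmented_loglik(
    y: np.ndarray,
    state: AugmentedState,
    grid: DetectorGrid,
) -> float:
    """Complete-data log density of the augmented Poisson SCR model.

    ``log p(y, z | s, psi, params) = sum_i log Bern(z_i | psi)
    + sum_{i: z_i=1} sum_j log Pois(y_ij | K * lambda(d(s_i, x_j)))``.

    Individuals with z_i = 0 have y_i identically zero; the uniform prior on
    s is a constant and is omitted.

    Parameters
    ----------
    y : ndarray of shape (M, J)
        Encounter counts; observed individuals occupy the leading rows and
        augmented (all-zero) rows follow.
    """
    y = np.asarray(y)
    if y.shape[0] != state.M:
        raise ValueError(
            f"y has {y.shape[0]} rows but the augmented state has M={state.M}"
        )
    if y.shape[1] != grid.n_detectors:
        raise ValueError(
            f"y has {y.shape[1]} columns but the grid has {grid.n_detectors} detectors"
        )
    z = state.z.astype(bool)
    if np.any(y[~z].sum(axis=1) > 0):
        raise ValueError("individual with observed encounters has z = 0")

    psi = state.psi
    n_in = int(z.sum())
    ll = n_in * np.log(psi) + (state.M - n_in) * np.log1p(-psi) if 0 < psi < 1 else (
        -np.inf if (psi == 0 and n_in > 0) or (psi == 1 and n_in < state.M) else 0.0
    )

    if n_in:
        mu = state.params.K * _rate_matrix(state.s[z], grid.coords, state.params)
        yz = y[z]
        ll += float((yz * np.log(mu) - mu - gammaln(yz + 1)).sum())
    return float(ll)


def make_mesh(space: StateSpace, nx: int, ny: int) -> tuple[np.ndarray, float]:
    """Discretize the state space into an ``nx`` x ``ny`` grid of cells.

    Returns the cell centers (shape ``(nx*ny, 2)``) and the common cell area.
    """
    if nx < 1 or ny < 1:
        raise ValueError("mesh must have at least one cell per axis")
    dx = space.width / nx
    dy = space.height / ny
    xs = space.xmin + dx * (np.arange(nx) + 0.5)
    ys = space.ymin + dy * (np.arange(ny) + 0.5)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()]), float(dx * dy)


def marginal_loglik(
    y_observed: np.ndarray,
    params: DetectionParams,
    density_per_cell,
    mesh_centers: np.ndarray,
    cell_area: float,
    detectors: np.ndarray | DetectorGrid,
) -> float:
    """Integrated log-likelihood with activity centers marginalized on a mesh.

    Activity centers are modelled as a Poisson point process with intensity
    ``density_per_cell`` (individuals per square meter, scalar or one value
    per mesh cell). Writing ``p_det(g) = 1 - exp(-K * sum_j lambda(d_gj))``
    for the detection probability of a center in cell g, the likelihood of
    the n observed encounter histories is

        exp(-sum_g D_g a_g p_det(g)) / n! *
        prod_i sum_g D_g a_g prod_j Pois(y_ij | K lambda(d_gj)).

    This marginal form is independent of the data-augmentation machinery and
    is used as an oracle for cross-checking the MCMC sampler.
    """
    y = np.atleast_2d(np.asarray(y_observed, dtype=float))
    X = detectors.coords if isinstance(detectors, DetectorGrid) else np.asarray(detectors, float)
    centers = np.asarray(mesh_centers, dtype=float)
    if centers.size == 0:
        raise ValueError("mesh is empty")
    D = np.broadcast_to(np.asarray(density_per_cell, dtype=float), (centers.shape[0],))
    if np.any(D < 0):
        raise ValueError("density must be non-negative")

    mu = params.K * _rate_matrix(centers, X, params)  # (G, J)
    total_mu = mu.sum(axis=1)  # K * sum_j lambda, per cell
    mass = D * cell_area  # expected centers per cell

    # expected number of *detected* individuals
    p_det = -np.expm1(-total_mu)
    lam_det = float((mass * p_det).sum())

    n = y.shape[0]
    ll = -lam_det - gammaln(n + 1)
    if n == 0:
        return float(ll)

    log_mu = np.log(mu)  # (G, J)
    with np.errstate(divide="ignore"):
        log_mass = np.log(mass)
    # log P(y_i | center in cell g): (n, G)
    per_cell = y @ log_mu.T - total_mu[None, :] - gammaln(y + 1).sum(axis=1)[:, None]
    ll += float(logsumexp(per_cell + log_mass[None, :], axis=1).sum())
    return float(ll)
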