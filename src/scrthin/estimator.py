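"""Bayesian SCR fitting by parameter-expanded data augmentation.

The unknown abundance N is embedded in a superpopulation of fixed size M
with Bernoulli(psi) inclusion indicators z_i and latent activity centers
s_i uniform over the state space. Counts are Poisson,
``y_ij | z_i = 1 ~ Pois(K * lam0 * exp(-d(s_i, x_j)^2 / (2 sigma^2)))``,
and ``y_ij | z_i = 0 == 0``. One MCMC sweep applies four kernels:

* random-walk Metropolis on each included activity center (uniform prior
  redraw for excluded individuals, whose likelihood is flat);
* the exact Bernoulli full conditional for each undetected individual's z;
* the conjugate Beta update for psi;
* log-scale random-walk Metropolis (with Jacobian) for lam0 and sigma.

Proposal scales are adapted toward ~0.35 acceptance during burn-in only
(Robbins-Monro) and frozen afterwards so the post-burn-in chain is a valid
Markov chain. All chains are advanced together as stacked arrays, which
keeps a full fit at the default 3 x 5000 sweeps around a second.

:class:`PoissonSCR` wraps the sampler as a scikit-learn style estimator;
:func:`fit_scr` is the equivalent functional entry point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from scrthin.geometry import DetectorGrid, StateSpace
from scrthin.model import AugmentedState, DetectionParams
from scrthin.simulate import EncounterData


class NotIdentifiableError(ValueError):
    """Raised when a dataset cannot support an SCR fit (e.g. no detections)."""


@dataclass(frozen=True)
class PriorSpec:
    """Priors: uniform boxes for lam0 and sigma, Beta for psi.

    ``lam0`` and ``sigma`` are (low, high) bounds of uniform priors; equal
    bounds denote a point mass (the parameter is held fixed). ``psi`` holds
    Beta hyperparameters (a, b); the default (1, 1) is the uniform prior
    under which the conjugate update is Beta(1 + sum z, 1 + M - sum z).
    """

    lam0: tuple[float, float] = (0.0, 5.0)
    sigma: tuple[float, float] = (0.0, 5000.0)
    psi: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("lam0", "sigma"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid {name} prior bounds ({lo}, {hi})")
        a, b = self.psi
        if a <= 0 or b <= 0:
            raise ValueError(f"psi Beta hyperparameters must be positive, got {self.psi}")

    @property
    def lam0_fixed(self) -> bool:
        return self.lam0[0] == self.lam0[1]

    @property
    def sigma_fixed(self) -> bool:
        return self.sigma[0] == self.sigma[1]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings: chains, sweeps, augmentation size, proposal scales."""

    n_chains: int = 3
    n_iter: int = 5000
    n_burnin: int = 1000
    M: int = 60
    s_step: Optional[float] = None  # meters; default sigma-scaled at init
    lam0_step: float = 0.4
    sigma_step: float = 0.15
    adapt: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 <= self.n_burnin < self.n_iter:
            raise ValueError("need 0 <= n_burnin < n_iter")
        if self.M < 1:
            raise ValueError("M must be >= 1")


def _as_counts(y, K: Optional[int] = None) -> tuple[np.ndarray, int]:
    """Extract a detected-individuals count matrix and K."""
    if isinstance(y, EncounterData):
        return y.observed(), y.K
    arr = np.asarray(y)
    if arr.ndim != 2:
        raise ValueError("encounter counts must be a 2-D individuals x detectors array")
    arr = arr[arr.sum(axis=1) > 0]
    if K is None:
        raise ValueError("K (number of occasions) is required with a raw count matrix")
    return arr.astype(float), int(K)


def _moment_starts(
    y_obs: np.ndarray, X: np.ndarray, K: int, spacing: float, priors: PriorSpec
) -> tuple[float, float]:
    """Coarse method-of-moments starting values for (lam0, sigma)."""
    rowsum = y_obs.sum(axis=1)
    centroids = (y_obs @ X) / rowsum[:, None]
    # rms spread of an individual's detections about its centroid informs sigma
    spreads = []
    for i in range(y_obs.shape[0]):
        jj = y_obs[i] > 0
        if jj.sum() >= 2:
            d2 = ((X[jj] - centroids[i]) ** 2).sum(axis=1)
            spreads.append(math.sqrt(float((y_obs[i, jj] * d2).sum() / rowsum[i])))
    sigma0 = float(np.mean(spreads)) if spreads else float(spacing)
    sigma0 = min(max(sigma0, 0.25 * spacing), 10 * spacing)
    # expected counts per individual ~ K * lam0 * 2 pi sigma^2 / spacing^2
    lam0_0 = float(rowsum.mean()) * spacing**2 / (K * 2 * math.pi * sigma0**2)
    if priors.lam0_fixed:
        lam0_0 = priors.lam0[0]
    else:
        lo, hi = priors.lam0
        lam0_0 = float(np.clip(lam0_0, lo + 1e-6 * (hi - lo), hi - 1e-6 * (hi - lo)))
    if priors.sigma_fixed:
        sigma0 = priors.sigma[0]
    else:
        lo, hi = priors.sigma
        sigma0 = float(np.clip(sigma0, lo + 1e-6 * (hi - lo), hi - 1e-6 * (hi - lo)))
    return lam0_0, sigma0


def initialize_state(
    y,
    grid: DetectorGrid,
    config: MCMCConfig,
    space: StateSpace,
    seed,
    K: Optional[int] = None,
    priors: Optional[PriorSpec] = None,
) -> AugmentedState:
    """Build an initial augmented state for one chain.

    Detected individuals get z = 1 with s at their detection-weighted
    centroid; augmented individuals get z ~ Bernoulli(0.5) and s uniform.
    lam0 and sigma start at jittered moment-based values inside the prior
    support, so chains with different seeds start overdispersed.
    """
    priors = priors or PriorSpec()
    y_obs, K = _as_counts(y, K)
    n_obs = y_obs.shape[0]
    if config.M <= n_obs:
        raise ValueError(f"augmentation size M={config.M} must exceed detected count {n_obs}")
    rng = np.random.default_rng(seed)
    M = config.M

    s = np.column_stack(
        [
            rng.uniform(space.xmin, space.xmax, size=M),
            rng.uniform(space.ymin, space.ymax, size=M),
        ]
    )
    if n_obs:
        cent = (y_obs @ grid.coords) / y_obs.sum(axis=1)[:, None]
        s[:n_obs, 0] = np.clip(cent[:, 0], space.xmin, space.xmax)
        s[:n_obs, 1] = np.clip(cent[:, 1], space.ymin, space.ymax)
    z = np.zeros(M, dtype=bool)
    z[:n_obs] = True
    z[n_obs:] = rng.random(M - n_obs) < 0.5

    lam0_0, sigma0 = _moment_starts(y_obs, grid.coords, K, grid.spacing, priors)
    if not priors.lam0_fixed:
        lo, hi = priors.lam0
        lam0_0 = float(np.clip(lam0_0 * math.exp(0.3 * rng.standard_normal()), lo + 1e-9, hi - 1e-9))
    if not priors.sigma_fixed:
        lo, hi = priors.sigma
        sigma0 = float(np.clip(sigma0 * math.exp(0.2 * rng.standard_normal()), lo + 1e-9, hi - 1e-9))
    psi0 = float(rng.uniform(0.3, 0.7))
    return AugmentedState(
        M=M,
        z=z,
        s=s,
        psi=psi0,
        params=DetectionParams(lam0=lam0_0, sigma=sigma0, K=K),
    )


class _StackedSampler:
    """All chains advanced together; shapes are (C, M, ...) throughout."""

    def __init__(
        self,
        y_obs: np.ndarray,
        grid: DetectorGrid,
        space: StateSpace,
        K: int,
        priors: PriorSpec,
        states: list[AugmentedState],
        rng: np.random.Generator,
        s_step: Optional[float],
        lam0_step: float,
        sigma_step: float,
    ) -> None:
        self.Y = np.asarray(y_obs, dtype=float)
        self.X = np.asarray(grid.coords, dtype=float)
        self.space = space
        self.K = int(K)
        self.priors = priors
        self.rng = rng
        self.n_obs, self.J = self.Y.shape
        self.C = len(states)
        self.M = states[0].M
        self.Ytot = float(self.Y.sum())

        self.z = np.stack([st.z for st in states]).astype(bool)
        self.s = np.stack([st.s for st in states]).astype(float)
        self.lam0 = np.array([st.params.lam0 for st in states], dtype=float)
        self.sigma = np.array([st.params.sigma for st in states], dtype=float)
        self.psi = np.array([st.psi for st in states], dtype=float)
        self.z[:, : self.n_obs] = True

        self.tau = np.full(self.C, s_step if s_step is not None else float(self.sigma.mean()) / 2)
        self.lam0_scale = np.full(self.C, lam0_step)
        self.sigma_scale = np.full(self.C, sigma_step)
        self._refresh()

    # -- cached quantities -------------------------------------------------
    def _refresh(self) -> None:
        self.inv2s2 = 1.0 / (2.0 * self.sigma**2)
        self.d2 = ((self.s[:, :, None, :] - self.X[None, None, :, :]) ** 2).sum(-1)
        self.G = np.exp(-self.d2 * self.inv2s2[:, None, None])
        self.T = (self.K * self.lam0)[:, None] * self.G.sum(-1)
        self.Yd2 = np.einsum("nj,cnj->cn", self.Y, self.d2[:, : self.n_obs])

    def _contains(self, pts: np.ndarray) -> np.ndarray:
        sp = self.space
        return (
            (pts[..., 0] >= sp.xmin)
            & (pts[..., 0] <= sp.xmax)
            & (pts[..., 1] >= sp.ymin)
            & (pts[..., 1] <= sp.ymax)
        )

    # -- kernels -----------------------------------------------------------
    def step_s(self) -> np.ndarray:
        """Per-individual random-walk Metropolis; uniform redraw when z=0."""
        C, M, n_obs = self.C, self.M, self.n_obs
        prop = self.s + self.tau[:, None, None] * self.rng.standard_normal((C, M, 2))
        inside = self._contains(prop)
        d2p = ((prop[:, :, None, :] - self.X[None, None, :, :]) ** 2).sum(-1)
        Gp = np.exp(-d2p * self.inv2s2[:, None, None])
        Tp = (self.K * self.lam0)[:, None] * Gp.sum(-1)
        Yd2p = np.einsum("nj,cnj->cn", self.Y, d2p[:, :n_obs])
        dll = self.T - Tp
        dll[:, :n_obs] += (self.Yd2 - Yd2p) * self.inv2s2[:, None]
        accept = self.z & inside & (np.log(self.rng.random((C, M))) < dll)
        self.s[accept] = prop[accept]
        self.d2[accept] = d2p[accept]
        self.G[accept] = Gp[accept]
        self.T[accept] = Tp[accept]
        aobs = accept[:, :n_obs]
        self.Yd2[aobs] = Yd2p[aobs]

        # excluded individuals: likelihood is flat, draw from the uniform prior
        m0 = ~self.z
        k0 = int(m0.sum())
        if k0:
            sp = self.space
            fresh = np.column_stack(
                [
                    self.rng.uniform(sp.xmin, sp.xmax, size=k0),
                    self.rng.uniform(sp.ymin, sp.ymax, size=k0),
                ]
            )
            self.s[m0] = fresh
            d2n = ((fresh[:, None, :] - self.X[None, :, :]) ** 2).sum(-1)
            self.d2[m0] = d2n
            ci = np.nonzero(m0)[0]
            Gn = np.exp(-d2n * self.inv2s2[ci][:, None])
            self.G[m0] = Gn
            self.T[m0] = self.K * self.lam0[ci] * Gn.sum(-1)
        nz = np.maximum(self.z.sum(1), 1)
        return accept.sum(1) / nz

    def step_z(self) -> None:
        """Exact Bernoulli full conditional for undetected individuals."""
        n_obs = self.n_obs
        if n_obs == self.M:
            return
        logit = (
            np.log(self.psi) - np.log1p(-self.psi)
        )[:, None] - self.T[:, n_obs:]
        p = expit(logit)
        self.z[:, n_obs:] = self.rng.random((self.C, self.M - n_obs)) < p

    def step_psi(self) -> None:
        a, b = self.priors.psi
        nz = self.z.sum(1)
        self.psi = self.rng.beta(a + nz, b + self.M - nz)

    def step_lam0(self) -> np.ndarray:
        """Log-scale Metropolis; the likelihood is Gamma-shaped in lam0."""
        if self.priors.lam0_fixed:
            return np.ones(self.C)
        lo, hi = self.priors.lam0
        Gz = (self.G.sum(-1) * self.z).sum(-1)
        cur = np.log(self.lam0)
        step = cur + self.lam0_scale * self.rng.standard_normal(self.C)
        lam0p = np.exp(step)
        ok = (lam0p > lo) & (lam0p < hi)
        dll = (self.Ytot + 1.0) * (step - cur) - self.K * (lam0p - self.lam0) * Gz
        acc = ok & (np.log(self.rng.random(self.C)) < dll)
        factor = np.where(acc, lam0p / self.lam0, 1.0)
        self.lam0 = np.where(acc, lam0p, self.lam0)
        self.T *= factor[:, None]
        return acc.astype(float)

    def step_sigma(self) -> np.ndarray:
        if self.priors.sigma_fixed:
            return np.ones(self.C)
        lo, hi = self.priors.sigma
        cur = np.log(self.sigma)
        step = cur + self.sigma_scale * self.rng.standard_normal(self.C)
        sigp = np.exp(step)
        ok = (sigp > lo) & (sigp < hi)
        inv2s2p = 1.0 / (2.0 * sigp**2)
        Gp = np.exp(-self.d2 * inv2s2p[:, None, None])
        Gz = (self.G.sum(-1) * self.z).sum(-1)
        Gpz = (Gp.sum(-1) * self.z).sum(-1)
        Yd2tot = self.Yd2.sum(-1)
        dll = (
            Yd2tot * (self.inv2s2 - inv2s2p)
            - (self.K * self.lam0) * (Gpz - Gz)
            + (step - cur)
        )
        acc = ok & (np.log(self.rng.random(self.C)) < dll)
        if acc.any():
            self.sigma = np.where(acc, sigp, self.sigma)
            self.inv2s2 = np.where(acc, inv2s2p, self.inv2s2)
            self.G = np.where(acc[:, None, None], Gp, self.G)
            self.T = (self.K * self.lam0)[:, None] * self.G.sum(-1)
        return acc.astype(float)

    def sweep(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        acc_s = self.step_s()
        self.step_z()
        self.step_psi()
        acc_l = self.step_lam0()
        acc_g = self.step_sigma()
        return acc_s, acc_l, acc_g

    def adapt(self, t: int, acc_s, acc_l, acc_g, target: float = 0.35) -> None:
        gamma = (t + 1.0) ** -0.6
        self.tau *= np.exp(gamma * (acc_s - target))
        self.lam0_scale *= np.exp(gamma * (acc_l - target))
        self.sigma_scale *= np.exp(gamma * (acc_g - target))


def compute_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws). With a single chain the split
    variant (first half vs second half) is used. The value is clamped at 1,
    so identical chains give exactly 1.0; chains with zero within-chain
    variance but differing means give +inf.
    """
    arr = np.atleast_2d(np.asarray(chains, dtype=float))
    if arr.shape[0] == 1:
        n = arr.shape[1] // 2
        if n < 2:
            raise ValueError("need at least 4 draws for split R-hat on one chain")
        arr = np.stack([arr[0, :n], arr[0, n : 2 * n]])
    m, n = arr.shape
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else float("inf")
    var_plus = (n - 1) / n * W + B / n
    return max(1.0, float(np.sqrt(var_plus / W)))


@dataclass
class FitResult:
    """Posterior draws and diagnostics from one SCR fit."""

    draws: dict  # param -> (n_chains, n_draws) arrays; params N, lam0, sigma, psi
    n_hat: float  # posterior mean of N
    n_median: float
    n_ci: tuple[float, float]  # central 95% credible interval for N
    posterior_sd: float
    rhat: dict
    ess: dict
    acceptance: dict
    n_detected: int
    M: int
    saturated: bool

    @property
    def n_chains(self) -> int:
        return self.draws["N"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["N"].shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws: one row per (chain, iteration)."""
        C, n = self.draws["N"].shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(C), n),
                "iteration": np.tile(np.arange(n), C),
                "N": self.draws["N"].ravel(),
                "lam0": self.draws["lam0"].ravel(),
                "sigma": self.draws["sigma"].ravel(),
                "psi": self.draws["psi"].ravel(),
            }
        )

    def summary(self) -> dict:
        return {
            "n_hat": self.n_hat,
            "n_median": self.n_median,
            "ci95": list(self.n_ci),
            "posterior_sd": self.posterior_sd,
            "rhat": self.rhat,
            "ess": self.ess,
            "acceptance": self.acceptance,
            "n_detected": self.n_detected,
            "M": self.M,
            "saturated": self.saturated,
        }


def _ess(arr: np.ndarray) -> float:
    import arviz as az

    return float(az.ess(np.asarray(arr)))


class PoissonSCR(BaseEstimator):
    """Bayesian Poisson SCR estimator with data augmentation.

    Scikit-learn style: hyperparameters at construction, ``fit`` consumes an
    individuals-by-detectors count matrix (or :class:`EncounterData`), and
    fitted attributes carry the posterior summaries.

    Parameters
    ----------
    grid : DetectorGrid
        Detector array the counts refer to.
    space : StateSpace
        Rectangle over which activity centers are distributed a priori.
    K : int
        Number of sampling occasions (ignored when fitting EncounterData,
        which carries its own K).
    priors : PriorSpec, optional
        Defaults: lam0 ~ U(0, 5), sigma ~ U(0, 5000 m), psi ~ U(0, 1).
    M : int
        Data-augmentation size; must exceed the detected count and be large
        enough that the posterior of N does not pile up at M.
    n_chains, n_iter, n_burnin : int
        Chain layout; pooled draws = n_chains * (n_iter - n_burnin).
    s_step, lam0_step, sigma_step : float
        Initial proposal scales (meters for s; log-scale for the rest).
    adapt : bool
        Robbins-Monro adaptation of proposal scales during burn-in.
    engine : {"numba", "numpy"}
        "numba" runs each chain through the compiled sweep loop in
        :mod:`scrthin._engine` (fast; the default); "numpy" runs all chains
        through the vectorized reference sampler. Both implement the same
        kernels.
    random_state : int or None
        Seed for the whole fit; fits with equal seeds are bit-identical.

    Attributes
    ----------
    result_ : FitResult
    n_hat_ : float
        Posterior mean abundance.
    samples_ : dict of (n_chains, n_draws) arrays for N, lam0, sigma, psi.
    rhat_, ess_, acceptance_ : dict
    saturated_ : bool
        True when the posterior of N places non-negligible mass at M.
    """

    def __init__(
        self,
        grid: DetectorGrid = None,
        space: StateSpace = None,
        K: int = 5,
        priors: Optional[PriorSpec] = None,
        M: int = 60,
        n_chains: int = 3,
        n_iter: int = 5000,
        n_burnin: int = 1000,
        s_step: Optional[float] = None,
        lam0_step: float = 0.4,
        sigma_step: float = 0.15,
        adapt: bool = True,
        engine: str = "numba",
        random_state: Optional[int] = None,
    ) -> None:
        self.grid = grid
        self.space = space
        self.K = K
        self.priors = priors
        self.M = M
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.n_burnin = n_burnin
        self.s_step = s_step
        self.lam0_step = lam0_step
        self.sigma_step = sigma_step
        self.adapt = adapt
        self.engine = engine
        self.random_state = random_state

    def fit(self, X, y=None):
        """Run the sampler on encounter counts ``X`` and store posteriors."""
        if self.grid is None or self.space is None:
            raise ValueError("PoissonSCR requires grid and space")
        priors = self.priors or PriorSpec()
        K = X.K if isinstance(X, EncounterData) else self.K
        y_obs, K = _as_counts(X, K)
        n_obs = y_obs.shape[0]
        if n_obs == 0:
            raise NotIdentifiableError("no detected individuals: nothing to fit")
        if self.M <= n_obs:
            raise ValueError(f"M={self.M} must exceed the detected count {n_obs}")
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")

        master = np.random.SeedSequence(self.random_state)
        children = master.spawn(2 * self.n_chains + 1)
        states = [
            initialize_state(
                y_obs,
                self.grid,
                MCMCConfig(
                    M=self.M,
                    n_chains=self.n_chains,
                    n_iter=self.n_iter,
                    n_burnin=self.n_burnin,
                ),
                self.space,
                children[2 * c],
                K=K,
                priors=priors,
            )
            for c in range(self.n_chains)
        ]

        keep = self.n_iter - self.n_burnin
        out = {
            "N": np.empty((self.n_chains, keep)),
            "lam0": np.empty((self.n_chains, keep)),
            "sigma": np.empty((self.n_chains, keep)),
            "psi": np.empty((self.n_chains, keep)),
        }
        if self.engine == "numba":
            from scrthin._engine import counts_to_csr, run_chain

            ptr, obs_j, obs_cnt = counts_to_csr(y_obs)
            X = np.ascontiguousarray(self.grid.coords, dtype=float)
            sp = self.space
            acc_sums = np.zeros(3)
            for c, st in enumerate(states):
                chain_seed = int(children[2 * c + 1].generate_state(1)[0] % (2**31))
                tau0 = self.s_step if self.s_step is not None else st.params.sigma / 2
                res = run_chain(
                    chain_seed,
                    self.n_iter,
                    self.n_burnin,
                    ptr,
                    obs_j,
                    obs_cnt,
                    n_obs,
                    X,
                    float(y_obs.sum()),
                    float(K),
                    sp.xmin,
                    sp.xmax,
                    sp.ymin,
                    sp.ymax,
                    float(priors.lam0[0]),
                    float(priors.lam0[1]),
                    bool(priors.lam0_fixed),
                    float(priors.sigma[0]),
                    float(priors.sigma[1]),
                    bool(priors.sigma_fixed),
                    float(priors.psi[0]),
                    float(priors.psi[1]),
                    st.z.astype(np.int64),
                    np.ascontiguousarray(st.s, dtype=float),
                    float(st.params.lam0),
                    float(st.params.sigma),
                    float(st.psi),
                    float(tau0),
                    float(self.lam0_step),
                    float(self.sigma_step),
                    bool(self.adapt),
                    0.35,
                )
                out["N"][c], out["lam0"][c], out["sigma"][c], out["psi"][c] = res[:4]
                acc_sums += res[4:7]
            acc_sums = acc_sums / self.n_chains * keep  # same units as numpy path
        elif self.engine == "numpy":
            rng = np.random.default_rng(children[-1])
            smp = _StackedSampler(
                y_obs,
                self.grid,
                self.space,
                K,
                priors,
                states,
                rng,
                self.s_step,
                self.lam0_step,
                self.sigma_step,
            )
            acc_sums = np.zeros(3)
            for t in range(self.n_iter):
                acc_s, acc_l, acc_g = smp.sweep()
                if t < self.n_burnin:
                    if self.adapt:
                        smp.adapt(t, acc_s, acc_l, acc_g)
                else:
                    k = t - self.n_burnin
                    out["N"][:, k] = smp.z.sum(1)
                    out["lam0"][:, k] = smp.lam0
                    out["sigma"][:, k] = smp.sigma
                    out["psi"][:, k] = smp.psi
                    acc_sums += [acc_s.mean(), acc_l.mean(), acc_g.mean()]
        else:
            raise ValueError(f"unknown engine {self.engine!r}")

        pooled_N = out["N"].ravel()
        rhat = {p: compute_rhat(out[p]) for p in out} if self.n_chains >= 1 else {}
        ess = {p: _ess(out[p]) for p in out}
        lo, hi = np.percentile(pooled_N, [2.5, 97.5])
        result = FitResult(
            draws=out,
            n_hat=float(pooled_N.mean()),
            n_median=float(np.median(pooled_N)),
            n_ci=(float(lo), float(hi)),
            posterior_sd=float(pooled_N.std(ddof=1)),
            rhat=rhat,
            ess=ess,
            acceptance={
                "s": float(acc_sums[0] / keep),
                "lam0": float(acc_sums[1] / keep),
                "sigma": float(acc_sums[2] / keep),
            },
            n_detected=n_obs,
            M=self.M,
            saturated=bool((pooled_N == self.M).mean() > 0.01),
        )
        self.result_ = result
        self.samples_ = result.draws
        self.n_hat_ = result.n_hat
        self.n_median_ = result.n_median
        self.n_ci_ = result.n_ci
        self.posterior_sd_ = result.posterior_sd
        self.rhat_ = result.rhat
        self.ess_ = result.ess
        self.acceptance_ = result.acceptance
        self.saturated_ = result.saturated
        self.n_detected_ = result.n_detected
        return self


def fit_scr(
    y,
    grid: DetectorGrid,
    space: StateSpace,
    priors: Optional[PriorSpec] = None,
    config: Optional[MCMCConfig] = None,
    K: Optional[int] = None,
    engine: str = "numba",
) -> FitResult:
    """Functional wrapper around :class:`PoissonSCR`."""
    config = config or MCMCConfig()
    est = PoissonSCR(
        grid=grid,
        space=space,
        K=K if K is not None else 5,
        priors=priors,
        M=config.M,
        n_chains=config.n_chains,
        n_iter=config.n_iter,
        n_burnin=config.n_burnin,
        s_step=config.s_step,
        lam0_step=config.lam0_step,
        sigma_step=config.sigma_step,
        adapt=config.adapt,
        engine=engine,
        random_state=config.seed,
    )
    est.fit(y)
    return est.result_


# ---------------------------------------------------------------------------
# single-chain kernel views (reference semantics; the fit loop uses the
# stacked sampler directly)
# ---------------------------------------------------------------------------


def _sampler_from_state(
    state: AugmentedState, y: np.ndarray, grid: DetectorGrid, space: StateSpace,
    priors: PriorSpec, rng, s_step=None, lam0_step=0.4, sigma_step=0.15,
) -> _StackedSampler:
    y = np.asarray(y, dtype=float)
    n_obs = int((y.sum(axis=1) > 0).sum())
    if np.any(y[n_obs:].sum(axis=1) > 0):
        raise ValueError("observed individuals must occupy the leading rows of y")
    return _StackedSampler(
        y[:n_obs], grid, space, state.params.K, priors, [state],
        np.random.default_rng(rng), s_step, lam0_step, sigma_step,
    )


def _state_from_sampler(smp: _StackedSampler, template: AugmentedState) -> AugmentedState:
    return AugmentedState(
        M=template.M,
        z=smp.z[0].copy(),
        s=smp.s[0].copy(),
        psi=float(smp.psi[0]),
        params=DetectionParams(
            lam0=float(smp.lam0[0]), sigma=float(smp.sigma[0]), K=template.params.K
        ),
    )


def update_inclusion(state: AugmentedState, y, grid: DetectorGrid, space: StateSpace, seed=None) -> AugmentedState:
    """Gibbs update of the inclusion indicators z (one chain).

    For undetected i, ``P(z_i = 1 | ...) = psi L0_i / (psi L0_i + 1 - psi)``
    with ``L0_i = exp(-K sum_j lambda(d(s_i, x_j)))``; detected i keep z = 1.
    """
    smp = _sampler_from_state(state, y, grid, space, PriorSpec(), seed)
    smp.step_z()
    return _state_from_sampler(smp, state)


def update_psi(state: AugmentedState, seed=None, priors: Optional[PriorSpec] = None) -> AugmentedState:
    """Conjugate Beta update of psi (one chain)."""
    priors = priors or PriorSpec()
    a, b = priors.psi
    nz = state.n_included
    rng = np.random.default_rng(seed)
    new = state.copy()
    new.psi = float(rng.beta(a + nz, b + state.M - nz))
    return new


def update_activity_centers(
    state: AugmentedState, y, grid: DetectorGrid, space: StateSpace, seed=None,
    s_step: Optional[float] = None,
) -> AugmentedState:
    """Random-walk Metropolis on included centers; prior redraw for z=0."""
    smp = _sampler_from_state(state, y, grid, space, PriorSpec(), seed, s_step=s_step)
    smp.step_s()
    return _state_from_sampler(smp, state)


def update_detection_params(
    state: AugmentedState, y, grid: DetectorGrid, space: StateSpace,
    priors: Optional[PriorSpec] = None, seed=None,
    lam0_step: float = 0.4, sigma_step: float = 0.15,
) -> AugmentedState:
    """Log-scale Metropolis updates of lam0 and sigma with Jacobian."""
    priors = priors or PriorSpec()
    smp = _sampler_from_state(
        state, y, grid, space, priors, seed, lam0_step=lam0_step, sigma_step=sigma_step
    )
    smp.step_lam0()
    smp.step_sigma()
    return _state_from_sampler(smp, state)
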