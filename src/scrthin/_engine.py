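"""Numba-compiled single-chain sweep loop for the augmented SCR sampler.

Semantically identical to the numpy reference engine in
:mod:`scrthin.estimator` (``_StackedSampler``); this version runs one chain
with scalar loops and no per-sweep allocations, which is what makes
replicate studies with hundreds of fits cheap. Randomness comes from
numba's internal legacy RNG, seeded once per chain, so chains are
bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_chain(
    seed,
    n_iter,
    n_burnin,
    # data (CSR layout of the detected individuals' nonzero counts)
    obs_ptr,
    obs_j,
    obs_cnt,
    n_obs,
    X,
    Ytot,
    K,
    # state space
    xmin,
    xmax,
    ymin,
    ymax,
    # priors
    lam0_lo,
    lam0_hi,
    lam0_fixed,
    sigma_lo,
    sigma_hi,
    sigma_fixed,
    psi_a,
    psi_b,
    # initial state
    z0,
    s0,
    lam0_init,
    sigma_init,
    psi_init,
    # proposal scales
    tau0,
    lscale0,
    sscale0,
    adapt,
    target,
):
    np.random.seed(seed)
    M = z0.shape[0]
    J = X.shape[0]
    keep = n_iter - n_burnin

    z = z0.copy()
    s = s0.copy()
    lam0 = lam0_init
    sigma = sigma_init
    psi = psi_init
    tau = tau0
    lscale = lscale0
    sscale = sscale0

    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    d2 = np.empty((M, J))
    gsum = np.empty(M)  # sum_j exp(-d2_ij / (2 sigma^2))
    yd2 = np.zeros(M)  # sum_j y_ij * d2_ij (zero beyond detected rows)
    for i in range(M):
        acc = 0.0
        for j in range(J):
            dx = s[i, 0] - X[j, 0]
            dy = s[i, 1] - X[j, 1]
            d2[i, j] = dx * dx + dy * dy
            acc += np.exp(-d2[i, j] * inv2s2)
        gsum[i] = acc
    for i in range(n_obs):
        t = 0.0
        for p in range(obs_ptr[i], obs_ptr[i + 1]):
            t += obs_cnt[p] * d2[i, obs_j[p]]
        yd2[i] = t

    N_out = np.empty(keep, dtype=np.int64)
    lam0_out = np.empty(keep)
    sigma_out = np.empty(keep)
    psi_out = np.empty(keep)
    acc_s_sum = 0.0
    acc_l_sum = 0.0
    acc_g_sum = 0.0

    d2row = np.empty(J)

    for it in range(n_iter):
        Klam0 = K * lam0
        # --- activity centers -------------------------------------------
        n_try = 0
        n_acc = 0
        for i in range(M):
            if z[i] == 1:
                n_try += 1
                px = s[i, 0] + tau * np.random.normal(0.0, 1.0)
                py = s[i, 1] + tau * np.random.normal(0.0, 1.0)
                if px < xmin or px > xmax or py < ymin or py > ymax:
                    continue
                gs = 0.0
                for j in range(J):
                    dx = px - X[j, 0]
                    dy = py - X[j, 1]
                    d2row[j] = dx * dx + dy * dy
                    gs += np.exp(-d2row[j] * inv2s2)
                yd2p = 0.0
                if i < n_obs:
                    for p in range(obs_ptr[i], obs_ptr[i + 1]):
                        yd2p += obs_cnt[p] * d2row[obs_j[p]]
                dll = (yd2[i] - yd2p) * inv2s2 + Klam0 * (gsum[i] - gs)
                if np.log(np.random.random()) < dll:
                    n_acc += 1
                    s[i, 0] = px
                    s[i, 1] = py
                    for j in range(J):
                        d2[i, j] = d2row[j]
                    gsum[i] = gs
                    yd2[i] = yd2p
            else:
                # excluded: flat likelihood, redraw from the uniform prior
                px = xmin + (xmax - xmin) * np.random.random()
                py = ymin + (ymax - ymin) * np.random.random()
                s[i, 0] = px
                s[i, 1] = py
                gs = 0.0
                for j in range(J):
                    dx = px - X[j, 0]
                    dy = py - X[j, 1]
                    d2[i, j] = dx * dx + dy * dy
                    gs += np.exp(-d2[i, j] * inv2s2)
                gsum[i] = gs
        acc_s = n_acc / n_try if n_try > 0 else 1.0

        # --- inclusion indicators ---------------------------------------
        for i in range(n_obs, M):
            w = psi * np.exp(-Klam0 * gsum[i])
            p = w / (w + 1.0 - psi)
            z[i] = 1 if np.random.random() < p else 0

        # --- psi ---------------------------------------------------------
        nz = 0
        for i in range(M):
            nz += z[i]
        psi = np.random.beta(psi_a + nz, psi_b + M - nz)

        # --- lam0 (log-scale Metropolis; Gamma-shaped likelihood) --------
        acc_l = 1.0
        if not lam0_fixed:
            acc_l = 0.0
            gz = 0.0
            for i in range(M):
                if z[i] == 1:
                    gz += gsum[i]
            step = np.log(lam0) + lscale * np.random.normal(0.0, 1.0)
            lam0p = np.exp(step)
            if lam0_lo < lam0p < lam0_hi:
                dll = (Ytot + 1.0) * (step - np.log(lam0)) - K * (lam0p - lam0) * gz
                if np.log(np.random.random()) < dll:
                    lam0 = lam0p
                    acc_l = 1.0

        # --- sigma -------------------------------------------------------
        acc_g = 1.0
        if not sigma_fixed:
            acc_g = 0.0
            step = np.log(sigma) + sscale * np.random.normal(0.0, 1.0)
            sigp = np.exp(step)
            if sigma_lo < sigp < sigma_hi:
                inv2s2p = 1.0 / (2.0 * sigp * sigp)
                gz = 0.0
                gpz = 0.0
                yd2tot = 0.0
                for i in range(M):
                    if z[i] == 1:
                        gz += gsum[i]
                        yd2tot += yd2[i]
                        for j in range(J):
                            gpz += np.exp(-d2[i, j] * inv2s2p)
                dll = (
                    yd2tot * (inv2s2 - inv2s2p)
                    - K * lam0 * (gpz - gz)
                    + (step - np.log(sigma))
                )
                if np.log(np.random.random()) < dll:
                    sigma = sigp
                    inv2s2 = inv2s2p
                    acc_g = 1.0
                    for i in range(M):
                        gs = 0.0
                        for j in range(J):
                            gs += np.exp(-d2[i, j] * inv2s2)
                        gsum[i] = gs

        # --- bookkeeping -------------------------------------------------
        if it < n_burnin:
            if adapt:
                gamma = (it + 1.0) ** -0.6
                tau *= np.exp(gamma * (acc_s - target))
                lscale *= np.exp(gamma * (acc_l - target))
                sscale *= np.exp(gamma * (acc_g - target))
        else:
            k = it - n_burnin
            nz = 0
            for i in range(M):
                nz += z[i]
            N_out[k] = nz
            lam0_out[k] = lam0
            sigma_out[k] = sigma
            psi_out[k] = psi
            acc_s_sum += acc_s
            acc_l_sum += acc_l
            acc_g_sum += acc_g

    return (
        N_out,
        lam0_out,
        sigma_out,
        psi_out,
        acc_s_sum / keep,
        acc_l_sum / keep,
        acc_g_sum / keep,
    )


def counts_to_csr(y_obs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compressed layout of the nonzero counts, row-major."""
    n_obs, _ = y_obs.shape
    ptr = np.zeros(n_obs + 1, dtype=np.int64)
    jj_all = []
    cc_all = []
    for i in range(n_obs):
        jj = np.nonzero(y_obs[i])[0]
        ptr[i + 1] = ptr[i] + len(jj)
        jj_all.append(jj)
        cc_all.append(y_obs[i, jj])
    obs_j = np.concatenate(jj_all) if jj_all else np.empty(0, dtype=np.int64)
    obs_cnt = np.concatenate(cc_all).astype(np.float64) if cc_all else np.empty(0)
    return ptr, obs_j.astype(np.int64), obs_cnt
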