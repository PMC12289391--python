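# scrthin

Spatial capture-recapture (SCR) under spatially structured sample removal.

Non-invasive genetic monitoring of the Iberian lynx (*Lynx pardinus*)
estimates abundance from scat collected on a survey grid. Corvid colonies
(western jackdaws) have been observed removing lynx scat — rapidly and
wholesale — within their foraging range, which silently deletes detections
near each colony before surveyors arrive. `scrthin` quantifies what that
does to SCR abundance estimates: it simulates scat-survey SCR data, thins
encounters inside fixed-radius interference zones, fits the SCR model by
Bayesian MCMC, and measures the bias and root-mean-square error (RMSE)
that the unmodelled removal induces.

## Model

Each of N individuals has a latent activity center s_i, uniform over a
rectangular state space 𝒮 (the detector grid buffered by 2.5σ). Counts at
detector j accumulate over K occasions as

    y_ij ~ Poisson( K · λ0 · exp( −‖s_i − x_j‖² / (2σ²) ) )

with baseline encounter rate λ0 and half-normal spatial scale σ. Abundance
is estimated by parameter-expanded data augmentation: a superpopulation of
fixed size M carries inclusion indicators z_i ~ Bernoulli(ψ), and
N = Σ z_i is sampled by Metropolis-within-Gibbs (random-walk updates of
s_i, exact Bernoulli updates of z_i, conjugate Beta update of ψ, log-scale
Metropolis for λ0 and σ).

Colony interference is binomial thinning: every encounter at a detector
within radius r of any colony is deleted independently with probability
p_rem, which keeps the thinned counts exactly Poisson with rate scaled by
(1 − p_rem).

The reference study design simulated throughout: an 8×8 detector grid at
800 m spacing, N = 10, σ = 1000 m, λ0 = 0.1, K = 5 occasions, three
colonies with 2 km removal radius, removal fractions {0, 0.25, 0.5}, and
100 replicate configurations fitted with 3 chains × 5000 iterations
(burn-in 1000).

## Worked example

```python
import scrthin as st
from scrthin.estimator import MCMCConfig

grid = st.build_detector_grid(8, 8, 800)        # 64 detectors
space = st.build_state_space(grid, 2500)        # 2.5 sigma buffer
cfg = st.ScenarioConfig(removal_fraction=0.5, master_seed=42)
pop, colonies, control, removed = st.generate_replicate(cfg, 0)
print(f"detected (control): {control.n_detected} of {pop.n}; total counts {control.counts.sum()}")
print(f"detected (50% removal): {removed.n_detected}; total counts {removed.counts.sum()}")

fit_c = st.fit_scr(control, grid, space, config=MCMCConfig(seed=1))
fit_r = st.fit_scr(removed, grid, space, config=MCMCConfig(seed=1))
print(f"control:  N_hat = {fit_c.n_hat:.2f}  95% CI ({fit_c.n_ci[0]:.0f}, {fit_c.n_ci[1]:.0f})")
print(f"removed:  N_hat = {fit_r.n_hat:.2f}  95% CI ({fit_r.n_ci[0]:.0f}, {fit_r.n_ci[1]:.0f})")
```

prints

```
detected (control): 5 of 10; total counts 16
detected (50% removal): 4; total counts 13
control:  N_hat = 8.49  95% CI (5, 15)
removed:  N_hat = 7.22  95% CI (4, 14)
```

The two fits share the same population and pre-removal encounters (the
paired design), so the difference is attributable to removal alone: here
thinning deleted one individual's detections entirely and widened the
posterior. Replicate-level noise is large on purpose — the headline
quantities are the mean bias `mean(N_hat − N)` and RMSE over many
replicates, computed by `scrthin.experiment.run_full_study`.

The same pipeline is scriptable from the shell:

```sh
scrthin study --replicates 100 --seed 0 --out results/
scrthin summarize --replicates-csv results/replicates.csv
```

The estimator is scikit-learn style (`PoissonSCR(...).fit(counts)` with
fitted attributes `n_hat_`, `n_ci_`, `rhat_`, ...), so it composes with
sklearn tooling; `fit_scr` is the functional shortcut.

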