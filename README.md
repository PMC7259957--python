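# erlumen

Analysis pipelines for studying how the ER lumen regulates the InsP₃R
calcium-release channel. The package re-implements, as tested reusable
components, the four bespoke computations behind the identification of a
luminal protein inhibitor of the InsP₃R:

1. **Spectral-count enrichment** (`erlumen.counts`) — a hierarchical
   Bayesian spike-and-slab Poisson model for bait-vs-control
   affinity-enrichment spectral counts,

       y_gct + 1 ~ Poisson(λ_gct),  log λ_gct = log μ_c + α_gc + t·β_g,
       β_g ~ π₀δ₀ + (1−π₀)N(0, τ²),  α_gc ~ N(0, σ_c²),

   with MCMC inference on the local false sign rate
   lfsr_g = P(β_g ≤ 0 | Y) and selection at lfsr ≤ 0.2.
2. **Single-channel gating** (`erlumen.gating`) — half-amplitude
   idealization of patch-clamp current traces, open probability P_o,
   dwell times, active-channel count N_A with a >99%-confidence
   acceptance rule, and current–voltage ramp fits.
3. **Dose inhibition** (`erlumen.dose_response`) — least-squares fits of
   the inhibitory Hill curve P_o = P_max·[1 + ([Ca²⁺]_ER/K_inh)^H_inh]⁻¹
   describing suppression of channel activity by luminal Ca²⁺.
4. **Ca²⁺-imaging classification** (`erlumen.cell_signals`) — Fura-2
   R/R₀ normalization, responder/oscillation logic tests (%CV > 15%),
   and population exponential-rise fits (ΔR_max, τ).

`erlumen.simulate` provides seeded generators with exactly the
statistical structure each analysis assumes, so every stage is testable
with no external data. The intended users are ion-channel biophysicists
and proteomics analysts who want these computations scripted,
reproducible and validated rather than embedded in one-off notebooks.

## Worked example

Enrichment analysis on synthetic counts (120 proteins, 3 blocks, 10%
true positives), then a Hill fit to a simulated dose-response dataset:

```python
import numpy as np
from erlumen import counts, simulate
from erlumen.dose_response import fit_hill

cfg = simulate.CountSimConfig(p=120, n_blocks=3, pi0=0.9, tau=1.5,
                              sigma=0.5, seed=7)
table, truth = simulate.simulate_counts(cfg)
draws = counts.run_mcmc(table, n_iter=2000, burn_in=1000, seed=11)
res = counts.compute_lfsr(draws)
print(res.table[res.table.selected].sort_values("lfsr").to_string(index=False))
print("global false sign rate:", round(res.global_false_sign_rate, 4))

ds, _ = simulate.simulate_po_dataset(seed=1)
fit = fit_hill(ds)
print(f"P_max={fit.p_max:.3f}  K_inh={fit.k_inh_um:.1f} ± {fit.se_k_inh:.1f} uM"
      f"  H_inh={fit.h_inh:.2f} ± {fit.se_h_inh:.2f}")
```

Output:

```
protein_id  post_mean_beta  post_prob_slab  lfsr  selected
     P0013        1.812369           1.000 0.000      True
     P0024        1.362504           1.000 0.000      True
     P0065        1.137681           0.999 0.001      True
     P0074        1.046313           0.986 0.014      True
     P0073        0.861903           0.892 0.109      True
global false sign rate: 0.0248
P_max=0.651  K_inh=258.8 ± 2.3 uM  H_inh=2.31 ± 0.03
```

All five selected proteins are true positives here; the posterior mean
effects are on the log-rate scale (β ≈ 1.8 means an e^1.8 ≈ 6-fold
enrichment of the bait counts), and the mean lfsr of the selected set
(0.0248) estimates the global false sign rate of the selection. The Hill
fit recovers the generator's inhibition parameters — a half-maximal
inhibitory luminal Ca²⁺ of ~260 µM with Hill coefficient ~2.3, i.e.
cooperative suppression within the physiological range of ER luminal
Ca²⁺.

The same stages are scriptable from the shell via the `erlumen` CLI:
`simulate-counts`, `simulate-traces`, `simulate-po`, `simulate-cells`,
`fit-counts`, `fit-hill`, `gating analyze`, `gating iv`,
`classify-cells`, `fit-rise` — run `erlumen --help` for options.

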