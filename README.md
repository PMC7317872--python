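# transdimer

Solution and single-molecule biophysics of protein trans-dimerization, built
around the quantitative workflow used to characterize the adhesive
homodimer of the cadherin-23 N-terminal extracellular domains (EC1-2): an
elongated "extended handshake" complex with two binding interfaces, a
micromolar dissociation constant, and an intrinsic bond lifetime of
hundreds of seconds.

The package implements, as tested reusable code, every analysis stage of
that study together with matched synthetic-data generators, so each stage
is validated end-to-end by parameter recovery without any instrument data:

| Stage | Module | Core model |
| --- | --- | --- |
| Dynamic force spectroscopy (AFM) | `transdimer.smfs` | FJC tether `l(F) = Lc[coth(Fa/kBT) − kBT/(Fa)]`; series-compliance loading rate `vF = kc v / (1 + kc dl/dF)`; Bell–Evans `Fmp = (kBT/xβ) ln(vF xβ τ0 / kBT)` |
| smFRET | `transdimer.fret` | `E = I_A/(I_A + γ I_D)`; `E = 1/(1 + (R/R0)^6)` |
| Time-resolved anisotropy | `transdimer.anisotropy` | `r(t) = r0[A1 e^(−t/φ1) + A2 e^(−t/φ2)]` |
| Sedimentation equilibrium (AUC) | `transdimer.aucse` | two-species Boltzmann gradients with mass action `c_d = c_m²/K_D`, global shared-`K_D` fit |
| SAXS | `transdimer.saxs` | Guinier, normalized Kratky, regularized P(r) IFT, volume-of-correlation MW, model z-tests |
| SEC calibration | `transdimer.secalib` | `Kav = (Ve − V0)/(Vc − V0)` linear in log10 MW |
| Synthetic data | `transdimer.synthdata` | Bell–Evans first-passage rupture sampling, FJC curves, SE gradients, bleaching FRET traces, polarized decays, sphere profiles |
| Recovery drivers / orchestration | `transdimer.study`, `transdimer.cli` | generate → analyze → report |

Each analysis exposes a statsmodels-style surface: a model object built
from data whose `fit()` returns a results object with estimates,
uncertainties and a `summary()` — e.g. `DynamicForceSpectroscopy(events,
tether).fit()`, `MonomerDimerSE(scans, species).fit()`,
`FRETExperiment(traces).fit()`, `AnisotropyDecayModel(decay).fit()` — with
the individual operations also available as plain functions.

## Worked example

Recover the Bell–Evans kinetics of the weak (single-interface) bound state
from a fully synthetic dynamic-force-spectroscopy experiment — 1000 rupture
events at each of the seven pulling speeds (500–15 000 nm/s), Gaussian
force histograms per speed, tether-corrected loading rates, and the
force-vs-log(rate) line:

```python
from transdimer.study import LOW_FORCE_STATE, recover_dfs_state

fit, points = recover_dfs_state(LOW_FORCE_STATE, n_per_speed=1000, seed=1)
print(fit.summary())
```

```
Bell-Evans fit (state, kBT=4.11 pN.nm, n=7)
  tau0   = 1.476 +/- 0.1 s
  x_beta = 0.5388 +/- 0.0048 nm
  koff   = 0.6776 1/s
```

The planted state has τ0 = 1.86 s and xβ = 0.55 nm: the pipeline recovers
the transition-state distance to ~2% and the lifetime — a log-extrapolated
intercept, hence the hard part — to ~20%. The same driver with `HIGH_FORCE_STATE`
(τ0 = 1224.2 s, xβ = 0.31 nm) recovers the strong, two-interface state.

The equivalent sedimentation-equilibrium round trip:

```python
from transdimer.study import recover_se
print(recover_se(KD=18e-6, seed=1).summary())
```

```
Sedimentation-equilibrium global fit (3 scans)
  K_D  = 17.8 uM  [17.4, 18.2] uM (95% profile CI)
  rms  = 4.54e-03 AU
```

A command-line entry point mirrors the library
(`transdimer simulate dfs|se|fret|aniso|saxs`, `transdimer smfs ...`,
`transdimer aucse fit`, `transdimer saxs guinier|pr|kratky|vc`,
`transdimer sec calibrate|mw`, `transdimer study`); `transdimer study
--seed 1 --out out/` runs every stage and writes a JSON report of planted
vs recovered parameters.

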