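# Methods

This note documents the models implemented in `transdimer`, the
assumptions behind the synthetic-data generators, the defaults chosen
where the underlying study leaves a parameter unstated, and the numerical
choices that matter for reproducing the results.

## Dynamic force spectroscopy (`smfs`, `synthdata`)

**Bond model.** Unbinding follows Bell–Evans kinetics: a pulling force `F`
lowers the unbinding barrier so the off-rate grows as
`k(F) = koff exp(F xβ / kBT)`, with `koff = 1/τ0` the zero-force off-rate
and `xβ` the distance from the bound state to the transition state. Under
a constant loading rate `r` the first-passage density of rupture forces is

    p(F) = (koff/r) e^(F xβ/kBT) exp[ −(koff kBT/(r xβ)) (e^(F xβ/kBT) − 1) ]

whose mode (the most probable rupture force) is
`F* = (kBT/xβ) ln(r xβ τ0 / kBT)`, zero when the argument drops below 1.
The generator samples this law exactly by inverse-CDF transform of the
closed-form CDF; at n = 10^5 the empirical distribution matches the
analytic CDF to KS < 0.01 across lifetimes spanning 1–2000 s.

**Tether model.** Each event is mechanically in series with a PEG tether
described by the freely jointed chain, `l(F) = Lc[coth(Fa/kBT) − kBT/(Fa)]`.
The inverse (force at given extension) is computed from Cohen's Padé
approximant of the inverse Langevin function refined by Newton iterations
to machine precision. The tether softens the pull: the loading rate at
force `F` is

    vF = kc v / (1 + kc (Lc a/kBT) [ (kBT/(F a))² − csch²(F a/kBT) ])

which is monotone in `F` and bounded by the bare cantilever rate `kc v`.

**Loading rate used in generation and analysis.** Sampling rupture forces
requires a single rate per condition, but the physical rate depends on the
force at rupture. Generation therefore uses the self-consistent fixed
point `r = vF(F*(r))`, iterated from `kc v`; analysis applies the same
compliance correction at the *fitted* most probable force of each state,
one pass, no iteration. This makes the generator and the analysis meet at
the distribution mode by construction, which is exactly the quantity the
Bell–Evans line is built from.

**Event selection.** Retract traces are screened for exactly one sharp
drop (≥ 5× the baseline noise sd within ≤ 3 samples, on a median-filtered
trace) that returns to baseline; the rupture force is the force maximum
immediately preceding the drop. The stretching segment from liftoff to the
peak is fitted with the FJC after boxcar smoothing (window 5) — standard
for 6 kHz retract data, and necessary for the fit's R² to be meaningful
when the force range of an event is only a few times the raw noise.
Acceptance requires R² ≥ 0.9 and a fitted contour length in 20–120 nm (two
5-kDa PEGs). On pure-noise curves the combination of the single-drop rule
and the FJC criteria yields a false-positive rate below 0.5%.

**Force histograms.** Bin widths follow Scott's rule
`h = 3.49 sd n^(−1/3)`. Scott's rule presumes a single Gaussian, so for
two-state histograms it is applied per cluster of a 1-D two-means split
and the finer width is kept. Distributions are fitted by least squares
with one Gaussian or a sum of two; because the rupture-force law is
left-skewed, a symmetric Gaussian over the full histogram centers ~0.26
kBT/xβ below the peak, so each component's center is refitted inside its
fitted full-width-half-maximum window (the other component subtracted).
This two-stage estimator tracks the peak maximum with residual bias
~0.12 kBT/xβ, which is what bounds the accuracy of the extrapolated τ0.
Two fitted components closer than one combined sd are treated as
overfitting and collapse to a single component with a warning.

**Bell–Evans fit.** `Fmp` against `ln vF` is an exact linear
re-parameterization: slope `m = kBT/xβ`, intercept `b = m ln(xβ τ0/kBT)`.
A weighted linear fit (weights from the per-speed Gaussian-center standard
errors) gives `xβ = kBT/m` and `τ0 = m e^(b/m)` with delta-method standard
errors. τ0 is an exponential of an extrapolated intercept, so its relative
error is inherently ~an order of magnitude larger than xβ's; recovery
tests bound it by 30% for the weak state and a factor of 2 for the
long-lived state.

**Defaults.** kBT = 4.11 pN·nm (298 K; the study does not state the
spectroscopy temperature), cantilever kc = 20 pN/nm (nominal for the soft
Si3N4 lever used), sampling 6 kHz, ramp 200 nm, Gaussian force noise 6 pN,
tether Lc = 58.7 nm with Kuhn length a = 0.7 nm (Lc is the reported
two-PEG value; the Kuhn length is a literature-typical PEG value, not a
reported one). All are configurable.

## smFRET (`fret`)

Per frame, the raw efficiency is `E = (I_A − bg_A)/[(I_A − bg_A) +
γ(I_D − bg_D)]` with γ = 1 by default (detection corrections are left to
upstream software in the original workflow and no values are stated). The
acceptor bleach frame is the largest single-step drop of the 3-frame
median-filtered acceptor trace, validated against the post-bleach noise
level; traces without a credible acceptor signal, or with fewer than 10
pre-bleach frames, are excluded rather than erroring. A population's most
probable efficiency (EFRETmp) is the center of a Gaussian fitted to the
Scott-binned per-trace histogram; degenerate histograms fall back to the
sample mean, and multimodal histograms are flagged and summarized by the
dominant mode. Distances follow `R = R0 (1/E − 1)^(1/6)`; R0 must be
supplied (the study's Förster radii are in supplementary material not
reproduced here), so distance outputs are validated by round-trip
identities rather than reference values.

The generator emits anticorrelated donor/acceptor pairs with conserved
mean total intensity `I_total` before a geometric-time single-step
acceptor bleach (mean 150 frames, 400 frames at 1 Hz, background 30
counts, Gaussian shot-noise approximation `sd = sqrt(mean)` per channel).
Donor blinking, direct acceptor excitation and spectral crosstalk are not
modeled — passing recovery tests therefore demonstrates correctness of the
ratio/bleach/histogram machinery, not robustness to those artifacts.

## Time-resolved anisotropy (`anisotropy`)

The anisotropy is `r(t) = (I∥ − G I⊥)/(I∥ + 2 G I⊥)` (G = 1 by default; a
`convention="perpendicular"` switch reproduces the transposed ratio for
comparison, which yields negative values for polarized emission). Points
below 1% of the peak total intensity are masked. The rotational model is
the biexponential `r(t) = r0[A1 e^(−t/φ1) + A2 e^(−t/φ2)]` with
`A1 + A2 = 1` enforced by parameterization; φ1 is the fast local motion of
the fluorophore, φ2 whole-molecule tumbling. Fits with `φ2/φ1 < 3` are
ill-conditioned and fall back to a monoexponential with a warning; fitted
`r(0) > 0.4` (the one-photon fundamental limit) is flagged, never clamped.
No IRF reconvolution is performed (tail fitting from a configurable
`t_start`); the generator correspondingly produces IRF-free decays with a
3 ns monoexponential total-intensity lifetime and channel noise
proportional to the instantaneous intensity, which keeps the anisotropy
noise approximately stationary.

## Sedimentation equilibrium (`aucse`)

Each species at equilibrium follows a Boltzmann exponential in r² with
reduced buoyant molar mass `σ = M(1 − v̄ρ)ω²/(RT)` (CGS gas constant, r in
cm). Mass action ties the dimer to the monomer at every radius,
`c_d(r) = c_m(r)²/K_D`, giving the absorbance model

    A(r) = ε·l c_ref e^(σ_m Δ/2) + 2 ε·l (c_ref²/K_D) e^(σ_m Δ),
    Δ = r² − r_meniscus²,

the factor 2 because a dimer carries two chromophores. The global fit
shares `ln K_D` across rotor speeds while the reference concentration and
baseline float per scan; meniscus and bottom are fixed geometry (floating
them is ill-posed on absorbance data with known geometry, unlike the
original SEDPHAT workflow that floats them against real cells). A coarse
K_D grid seeds the optimizer to avoid the no-association local minimum.
The 95% confidence interval is a profile likelihood in `ln K_D`
(Δ-SSR = 3.84 × the residual variance at the optimum, bracket expansion +
Brent root-finding); a fit running to the 1 M bound, or with an unbounded
upper profile, is reported as a no-association outcome rather than a
silent boundary value. Coverage measured over 100 synthetic replicates at
0.005 AU noise is ≈ 95%.

The generator plants scans whose meniscus concentration honours mass
conservation of the sector-shaped cell (radially r-weighted average of
monomer equivalents equals the loading concentration) and adds Gaussian
absorbance noise. Defaults: 26 kDa monomer at 36 µM loading (or 15 kDa at
45 µM for the single-domain construct), v̄ = 0.73 mL/g, ρ = 1.0 g/mL
(plausible values; the study computed but did not print them),
ε·l = 14 400 AU/M, cell 6.9–7.2 cm, 293.15 K, rotor speeds 24/28/32 krpm
(the rpm values given in the study's methods; its g-value figures are not
used). Nonideality, baseline drift and interference optics are not
modeled.

## SAXS (`saxs`)

*Guinier*: weighted linear regression of `ln I` vs `q²` over a low-q
window auto-iterated until `qmax·Rg` falls below the limit (default 1.3,
the practical globular choice; configurable). A non-negative slope raises
an aggregation error. Because the Guinier law is exact only as q → 0, the
sphere-oracle validations use a narrow window (`qmax·Rg ≤ 0.6`), where the
closed-form `Rg = R√(3/5)` is reproduced within 0.5%; at the 1.3 window
the systematic Guinier error for a sphere is ~1.6%, a property of the
approximation, not of the fit.

*Normalized Kratky*: `(qRg)² I/I0` vs `qRg` with a parabola-refined peak;
the idealized globular (Gaussian) profile peaks at `qRg = √3 ≈ 1.73` with
height `3/e`, and elongated shapes shift the peak upward — the flag used
to diagnose rod-like character.

*P(r) by regularized IFT*: solves `I(q) = 4π ∫ p(r) sinc(qr) dr` on an
`n_r = 101` grid with non-negative least squares, endpoint constraints
`p(0) = p(Dmax) = 0`, and a second-difference smoothness penalty of weight
α (operator rows scaled to the kernel norm so α is dimensionless). When α
is not given, the largest value keeping χ² within 5% of the best over a
17-point log scan is used — an L-curve-style criterion; the perceptual
criteria of the original GNOM program are not reproduced. Real-space
invariants `Rg² = ∫r²p dr / (2∫p dr)` and `I(0) = 4π ∫p dr` agree with
the Guinier values within 2–3% on noiseless data, and the sphere's
analytic pair-distance distribution `p(r) ∝ r²(1 − 3r/(4R) + r³/(16R³))`
is matched to < 2% sup-norm. `scan_dmax` picks the smallest candidate
whose χ² is within 5% of the plateau, warning when no plateau exists
inside the range.

*Volume of correlation*: `Vc = I(0)/∫ q I dq` (trapezoidal), with a
truncation warning when the last 10% of the q-range carries over 5% of the
integral, and a reported sensitivity to removing the top 20% of the
q-range. Molecular weight uses the published protein calibration
`MW = QR/0.1231` with `QR = Vc²/Rg` in Å-based units (constants recorded
as function defaults). Desmearing of slit-collimated data is out of scope;
profiles are treated as pinhole-equivalent, q in nm⁻¹ with Å⁻¹ input
converted on read.

*Model consistency*: per-parameter z-scores `(model − experiment)/sd` with
two-sided normal p-values; the minimum-p parameter decides a consistency
flag at p > 0.05 and Fisher's method supplies a combined p.

## SEC calibration (`secalib`)

`Kav = (Ve − V0)/(Vc − V0)` against `log10 MW`, the standard semi-log
relationship; a literal linear-in-MW variant is available behind a flag
but cannot reproduce typical column behaviour. A non-negative slope is
rejected as a calibration-order error; apparent MWs outside the calibrated
Kav range carry an extrapolation flag. Default geometry V0 = 8 mL,
Vc = 24 mL. The study's standard elution volumes are not printed, so the
module is validated by planted-line and round-trip identities.

## Synthetic data: what it does and does not show

All noise is Gaussian (shot-noise approximation), matching the
least-squares estimators downstream; generators are bit-reproducible for a
fixed seed. The generators reproduce the statistical structure each
analysis assumes — not instrument artifacts (detector nonlinearity, drift,
optical smearing, donor blinking, pressure effects in the
ultracentrifuge). Passing the recovery suite therefore certifies the
estimators against their own model classes at realistic noise and sample
sizes; it does not certify robustness to model misspecification.

## Problem sizes

The recovery studies use 1000 events per pulling speed at seven speeds for
the force-spectroscopy fits, 500 force curves for the contour-length
distribution, 25 traces for the FRET population (the study's own
population size), 3 rotor speeds × 80 radial points (0.005 AU noise) with
100 replicates for the K_D coverage study, and 400–500-point scattering
profiles for the SAXS oracles. These sizes hold every stochastic recovery
within its stated tolerance while keeping the full suite fast.
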