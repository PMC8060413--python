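# Methods

This note documents the models, numerical choices and known limitations of
the spintrace pipeline. Units are fixed package-wide: time in µs, distance
in nm, magnetic field in gauss, frequency in MHz (GHz for microwave
frequencies).

## Forward DEER model

The dipolar coupling between two S = 1/2 electron spins at distance r is
ν_dd = D/r³ with D = μ₀g²μ_B²/(4πh), computed at runtime from CODATA
constants with the free-electron g-factor (D ≈ 52.041 MHz·nm³). The
spectroscopic g-value of the nitroxide (≈ 2.006) governs the resonance
field, not the spin–spin coupling, so it enters only the CW generator's
center field B₀ = hν/(gμ_B).

The powder-average kernel K(t, r) = ∫₀¹ cos[(1 − 3z²)·2πν_dd t] dz is
evaluated in closed form with Fresnel sine/cosine integrals; a fixed-order
(1001-point) Gauss–Legendre quadrature fallback agrees to < 1e-6 and is
kept as an independent implementation for cross-checking. Every kernel
column equals 1 at t = 0.

A trace is V(t) = [(1 − λ) + λ·K p]·B(t) + ε with modulation depth λ,
p the distance density discretized with trapezoid quadrature weights
(normalized so K p = 1 at t = 0), and B(t) = exp(−k t^(d/3)) the
stretched-exponential background of a homogeneous d-dimensional spin bath
(d = 3 for solution samples; k in µs^(−d/3)). Traces are rescaled so
V(0) = 1 before analysis. The parametric background family is this
package's substitute for neural-network background extraction; it is exact
for the synthetic data the package generates and approximate for real
samples with structured intermolecular contributions.

## Inversion

The form factor F̃ = (V/B − (1 − λ))/λ is inverted by Tikhonov
regularization with a second-difference roughness penalty and a hard
non-negativity constraint, solved as non-negative least squares on the
stacked system [W·K; α·L₂]. Non-negativity is part of the optimization, not
a post-hoc clip (clipping destroys the monotonicity of the L-curve). The
row weights W = diag(B(t)) whiten the residuals: dividing by the background
amplifies the measurement noise at late times, so unweighted fitting would
over-trust exactly the noisiest points. Recovered distributions are
renormalized to ∫P dr = 1 (trapezoid rule).

**Distance grid.** Default 128 points on [1.5, 6.5] nm. The upper edge
follows the information-content rule for a 4 µs evolution window: mean
distances are reliable to roughly 6·(t_max/2)^{1/3} ≈ 7.6 nm but widths
only to about 4·(t_max/2)^{1/3} ≈ 5.0 nm, and kernel columns beyond
~6.5 nm degenerate toward the background over this window, admitting
unconstrained probability mass. Callers analysing longer windows should
widen the grid accordingly (`--rmax`).

**Background estimation.** The tail fit (t ≥ 0.55·t_max by default) of
(1 − λ)·B(t) is biased whenever the dipolar oscillation has not decayed
inside the fit window — significant for r ≳ 4 nm where the period exceeds
1 µs. The full analysis therefore refines (λ, k) against the entire trace
by alternating: invert at a fixed moderate α (2.0), refit (λ, k) with the
recovered signal held fixed, repeat. The refinement is started from every
rung of the fit-start ladder {0.55, 0.45, 0.65, 0.35, 0.75} and the start
whose refined k is closest to the ladder median is kept; the median guard
prevents a single start that stalled in a local minimum (background decay
traded against spurious long-distance mass) from being selected on the
basis of raw residual alone.

**Choice of α.** 40 log-spaced values over 10⁻³–10³. The corner of the
log–log L-curve (residual norm vs penalty norm) is located by the
derivative-free knee criterion: both axes are scaled to unit range and the
corner is the sample farthest from the chord joining the endpoints, with
ties broken toward larger α. Finite-difference curvature was evaluated and
rejected: on L-curves produced by an active-set solver the curvature
denominator vanishes wherever both slopes are small, so solver jitter
produces spurious curvature spikes and the maximizer does not converge
under refinement of the α ladder. The chord criterion has a single
well-separated maximum on the same curves and agrees between a 40-point
ladder and a 10×-denser scan to well within one ladder step.

**Uncertainty band.** The full analysis is repeated for an ensemble of
background models (the point estimate's own background plus refinements
started from successive ladder rungs, 5 by default) crossed with 5 noise
realizations per background at the noise level estimated from the residuals
of the point-estimate fit. The first realization of each background is the
unperturbed trace, so a noiseless single-background ensemble reproduces the
point estimate exactly and yields a zero-width band. The band is the
pointwise min/max envelope (clipped below at 0) — conservative, and by
construction containing the point estimate. Members whose inversion fails
are dropped with a warning; more than half failing is an error.

## CW mobility (LFPR)

Spectra are field-rescaled to 9.6355 GHz (B′ = B·ν_ref/ν, preserving
g-values), normalized so the center-line maximum is 1 (searched within
±8 G of the zero crossing between the global maximum and minimum of the
derivative spectrum), and optionally Savitzky–Golay smoothed (order 2,
frame 101 — applied only on request, since smoothing is cosmetic and the
ratio should be computed on raw data). The LFPR is the linearly
interpolated intensity ratio I(3415.3 G)/I(3404.6 G) — mobile over
immobilized low-field peak — normalized to the same ratio of a reference
spectrum. The two field positions are exposed as parameters because the
mobile landmark is quoted both as 3415.3 G and 3414.8 G in different
contexts; the defaults follow the ratio's defining formula. The error bar
is the standard deviation of the intensity over the outermost 5% of the
field axis on each side (the nitroxide signal is confined to the central
~80 G) divided by the intensity at the immobilized peak position.

## Structure-based prediction

Conformers are compared by Cα RMSD after optimal superposition (Kabsch SVD
with the determinant correction restricting to proper rotations; RMSD is
computed from the actual aligned residuals, which is numerically exact for
identical structures where the singular-value identity cancels
catastrophically). Clustering is greedy gromos: repeatedly the frame with
the most neighbors within the cutoff (0.15 nm default) becomes a cluster
center and its neighborhood is removed; ties break toward the lowest frame
index. Clusters with more than 5% of the frames (the 50-of-1000 rule,
scaled proportionally for other ensemble sizes) are kept.

Label flexibility is modelled by an isotropic Gaussian displacement of the
effective label position at each site (σ = 0.25 nm per site per axis,
applied to the Cβ reference atom, falling back to Cα). This pseudo-label
reproduces the ~0.5–0.7 nm breadth of a nitroxide tether's rotamer cloud
without an external rotamer library; it does not reproduce rotamer
multimodality or surface-dependent rotamer exclusion. Distance samples from
each kept cluster's center frame are turned into a density by Gaussian KDE
(Silverman bandwidth by default) and averaged with cluster-size weights;
the reported band is the weighted standard deviation across clusters,
clipped at zero below.

## Synthetic data

The generator provides the study conditions for all tests:

* **DEER**: Gaussian-mixture P(r); default single component 3.5 ± 0.3 nm,
  λ = 0.3, background k = 0.05 µs⁻¹ (d = 3), 4 µs window sampled every
  16 ns (251 points), noise σ = 0.01 — an SNR of 30 referenced to the
  modulation amplitude λ, the convention of the neural-network background
  literature. (Referencing SNR 30 to the echo amplitude V(0) would mean
  σ = 0.033, i.e. 11% of the modulated signal, beyond what any
  regularized inversion resolves to sub-0.15 nm moments.)
* **CW**: two-component X-band nitroxide spectrum at 9.6355 GHz,
  spectrum = (1 − f)·mobile + f·immobilized. The mobile component is an
  equal-area triplet of derivative Lorentzians (HWHM 1.5 G center line,
  outer lines broadened ×1.2 by the partially averaged hyperfine
  anisotropy); the immobilized component an equal-area triplet of broad
  derivative Gaussians (σ = 9 G). Splittings are *effective peak
  splittings*: line centers are offset by one derivative-extremum width so
  the observable low-field extrema fall at B₀ − a_N (a_N = 17.0 G) and
  B₀ − A_zz_eff (A_zz_eff = 27.7 G) — at a line's own center the
  derivative is zero, so anchoring centers instead of extrema would put
  the landmarks at zero crossings. σ = 9 G is the narrowest immobilized
  width for which the intensity at the mobile landmark stays positive at
  every immobilized fraction, which keeps log LFPR defined across the full
  binding range. A cosine taper to zero beyond ±70–85 G of B₀ emulates
  baseline-corrected spectra, so the noise-estimation margins carry no
  signal. The parametrization is deliberately phenomenological: its
  acceptance surface is LFPR behaviour (monotone response to the
  immobilized fraction), not slow-motion lineshape realism.
* **Helix ensembles**: ideal α-helix backbone (rise 0.15 nm/residue,
  100°/residue, Cα radius 0.23 nm, pseudo-Cβ 0.15 nm further out) with
  per-frame Gaussian jitter (default σ = 0.05 nm); the unfolded control is
  a self-avoiding random walk with the helical Cα–Cα step (0.383 nm) and a
  0.35 nm clash distance, giving several-fold broader inter-site distance
  spread. The closed-form inter-site distance
  d = √(2R²(1 − cos Δθ) + (rise·Δ)²) serves as the oracle.

All generators are bit-reproducible under a fixed seed and can emit
machine-readable truth side-cars.

## What passing tests do and do not show

The synthetic traces share the exact background family, kernel
discretization and noise model with the analysis, so recovery tests
measure the inversion's statistical performance under a correctly
specified model — they do not probe model misfit from structured
backgrounds, orientation selection, multispin effects or nuclear
modulation artifacts present in real data. The CW generator reproduces the
two-landmark geometry and monotone mixing behaviour of real two-component
spectra, not slow-motion lineshapes; LFPR results on it validate the
statistic's arithmetic and sensitivity, not spectral simulation.

## Known limitations

* Width (second-moment) recovery degrades for mean distances ≳ 4.3 nm in a
  4 µs window: fewer than two dipolar periods are observed, the
  background–signal decomposition becomes nearly degenerate, and
  noise-realization-specific pedestals inflate the recovered σ at every α.
  In the 20-trace benchmark (means 2.5–5 nm, σ 0.2–0.5 nm, SNR 30) the
  pipeline recovers mean and σ within 0.15 nm in ~15/20 cases; the misses
  concentrate at long means with narrow widths, where a per-case scan over
  the entire α ladder shows no admissible solution — an information limit
  of the window, not a solver failure. Mean recovery alone succeeds in
  essentially all cases.
* The min/max validation band widens with ensemble size and should be read
  as a support envelope, not a confidence interval.
* gromos clustering is O(n²) in frames with a Kabsch superposition per
  pair; 1000-frame ensembles are feasible (~minutes) but not interactive.
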