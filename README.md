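# spintrace

Analysis tools for site-directed spin labeling (SDSL) EPR studies of protein
complexes: recovery of inter-label distance distributions from four-pulse
DEER (PELDOR) time traces, continuous-wave nitroxide mobility analysis via
the low-field peak ratio (LFPR), and prediction of distance distributions
from conformer ensembles of structural models. A synthetic-data module
generates every input with known ground truth, so the whole pipeline is
testable end to end without instrument data.

The intended user is a spectroscopist or structural biologist who wants to
(a) turn DEER echo traces V(t) into distance distributions P(r) with honest
uncertainty bands, (b) quantify binding-induced immobilization from CW
spectra, and (c) compare measured distributions against a structural model.

## The methods

**DEER inversion.** A spin pair at distance r (nm) couples at the dipolar
frequency ν_dd = D/r³ with D = μ₀g²μ_B²/(4πh) ≈ 52.04 MHz·nm³. Powder
averaging over orientations z = cos θ gives the kernel

    K(t, r) = ∫₀¹ cos[(1 − 3z²)·2π·ν_dd(r)·t] dz,

evaluated in closed form via Fresnel integrals. A measured trace is modelled
as V(t) = [(1 − λ) + λ·K p]·B(t) + noise, with modulation depth λ and a
stretched-exponential intermolecular background B(t) = exp(−k t^(d/3)).
After background fitting (tail fit refined against the full window from a
ladder of starting points), the form factor is inverted by non-negative
Tikhonov regularization,

    P_α = argmin_{P ≥ 0} ‖W(K P − F)‖² + α²‖L₂ P‖²,

with the second-difference roughness penalty L₂ and noise whitening W.
The regularization parameter α is chosen at the corner of the L-curve
(log residual norm vs log penalty norm), and an uncertainty band is built
from an ensemble of background models crossed with noise re-realizations.
Every returned distribution satisfies ∫P(r) dr = 1.

**LFPR.** CW spectra are rescaled to a common microwave frequency
(9.6355 GHz), normalized to the center-line maximum, and the mobility
statistic LFPR = I(3415.3 G)/I(3404.6 G) is computed — the intensity ratio
between the mobile and immobilized low-field peaks — then normalized to a
reference spectrum of the free protein. Error bars are the baseline noise
relative to the immobilized-peak intensity.

**Structure-based prediction.** Conformer ensembles (multi-model PDB) are
clustered with the greedy gromos algorithm on Cα RMSD (Kabsch
superposition); clusters holding more than 5% of frames (50 of 1000) are
kept; per-cluster distance distributions from a Gaussian pseudo-label
broadening model are averaged with cluster-size weights, with a
±weighted-std band clipped at zero.

## Worked example

```python
from spintrace import GroundTruth, make_deer_dataset, validate_uncertainty

truth = GroundTruth(pr_components=[(3.5, 0.3, 1.0)], lam=0.3,
                    background_k=0.05, noise_sigma=0.01, seed=1)
trace, p_true = make_deer_dataset(truth)
result = validate_uncertainty(trace, seed=1)
d = result.distribution
print(f"integral {d.integral():.6f}  mean {d.mean():.2f} nm  "
      f"mode {d.mode():.2f} nm  alpha {result.alpha:.3g}  "
      f"lambda {result.lam:.3f}")
```

prints

```
integral 1.000000  mean 3.49 nm  mode 3.51 nm  alpha 3.46  lambda 0.303
```

i.e. the recovered distribution is unit-normalized, its mean and mode sit
within a few hundredths of a nanometre of the 3.5 nm ground truth, the
L-curve selected α ≈ 3.5, and the fitted modulation depth matches the
simulated 0.3. `result.band_low`/`band_high` bound the density pointwise
across the validation ensemble.

The same analyses are available from the shell:

```
spintrace simulate --kind deer --seed 1 --out run/
spintrace invert-deer --trace run/trace.dat --validate --seed 1 --out run/inv
spintrace lfpr --spectrum bound.dat --reference free.dat --out lfpr.json
spintrace predict-distances --pdb model.pdb --site-a 351 --site-b 363 --out pred.tsv
spintrace compare --experimental run/inv_distribution.tsv --predicted pred.tsv
```

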