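# Methods

## The problem and the model

NIR reflectance spectra of meat in the 908–1676 nm window are dominated by
broad overtone bands of O–H, C–H and N–H vibrations. Species, freeze–thaw
history and muscle identity shift the intensities of these bands (moisture
loss lowers the 970 nm water band and raises the apparent 1193 nm fat band;
protein denaturation lowers the 1428 nm band), while the measurement adds
baseline offset and slope, multiplicative scatter, and channel noise. The
package implements the standard chemometric treatment of this situation:
per-spectrum pre-treatments that remove the nuisance terms, a deterministic
calibration/validation split, PLS-DA classification, and a hierarchical
cascade when several label fields must be predicted at once.

## Synthetic data generator

Each class (species × treatment × muscle) is a `ClassProfile`: a sum of
Gaussian bands `A_b exp(-(λ-c_b)²/(2s_b²))` plus four per-scan nuisances,

```
a(λ) = gain · Σ_b band_b(λ) + offset + slope·(λ - λ_mid) + ε(λ)
```

with `gain ~ 1 + N(0, gain_sd²)` truncated at 0.1 (spectra keep a positive
gain), `offset ~ N(0, offset_sd²)`, `slope ~ N(0, slope_sd²)` and i.i.d.
`ε ~ N(0, noise_sd²)`. Gaussian bands with additive offset/slope and a
multiplicative gain are chosen deliberately: they make SNV, detrend and
derivative pre-treatments *provably* appropriate (SNV removes gain and
offset exactly; detrend removes polynomial baselines; derivatives remove
low-order baselines), so pipeline properties can be asserted analytically.

Default axis: 125 channels, 908–1676 nm, uniform ≈6.19 nm spacing (the
instrument's pixel interval). Default design: 22 zebra and 19 springbok
animals × 7 muscles, 10 ostriches × 2 muscles, both treatments, triplicate
scans — 1842 scans, 614 averaged steak spectra, mirroring the n = 307
steaks-per-treatment inventory of the emulated study.

Default amplitudes (absorbance units): shared bands 970/0.50, 1193/0.30,
1428/0.45; species signatures at 1031 and 1143 nm of (0.20, 0.10) zebra,
(0.12, 0.18) springbok, (0.05, 0.26) ostrich; fresh adds +0.05 at 970 and
+0.04 at 1428; frozen–thawed adds +0.04 at 1193; hindquarter (and FF)
muscles add +0.05 at 1193. Default nuisances: offset_sd 0.02, slope_sd
2·10⁻⁵ per nm, gain_sd 0.03, noise_sd 0.002. These encode the qualitative
contrasts reported for game meat (fresh > frozen–thawed at the water and
protein bands, the reverse at the fat band) at a signal-to-noise where the
cascade separates classes well but not trivially. `high_snr_noise()` scales
all four nuisances by 1/10 and is the named condition for end-to-end
separability checks. Absolute amplitudes are arbitrary — no compositional
reference values exist to anchor them — so only contrasts, not absolute
absorbances, are meaningful.

What the generator does **not** emulate: temperature and bloom kinetics,
detector nonlinearity, wavelength-correlated noise, animal-level random
effects, and any radiative-transfer physics. Passing tests therefore show
the *pipeline* is correct and recovers planted structure; they do not show
that real game-meat spectra are this separable.

## Pre-treatments

* **Moving average** (default 5 points): truncated windows at the edges so
  length is preserved.
* **SNV**: per-row centring and scaling with `ddof=1` (the convention of
  common chemometrics software; the choice only rescales rows).
* **Detrend**: per-row least-squares polynomial subtraction, default order
  2 (offset + slope + curvature), axis rescaled to [-1, 1] internally for
  conditioning. Order 2 is the standard choice after SNV.
* **Savitzky–Golay**: convolution weights derived from the local
  least-squares polynomial fit (solved directly from the Vandermonde normal
  equations, scaled by `d!/spacing^d` so derivatives are per nm). Edge
  channels are evaluated from the polynomial fitted to the first/last full
  window, which keeps the output length equal to the input and the filter
  exact on polynomials up to the fit order everywhere. A uniform axis
  (within 1 % of the mean spacing) is required.

Pipelines apply steps strictly left to right; the composite label
(`SNV+DT+SGd2(7)`) is derived from the steps and reads in application
order. Smoothing is an explicit optional first step (default off in node
pipelines; the bundled experiment runner applies MA(5) once after
averaging/trimming, reflecting the emulated protocol).

All pre-treatments are per-spectrum row operations. This is why
leave-one-out cross-validation does not refit them inside the loop: no
training-set statistic enters any transformed spectrum, so there is no
leakage channel.

## Kennard–Stone split

Seed pair = the globally most distant pair; thereafter maximin (select the
sample with the largest minimum distance to the selected set). Ties break
to the smallest row index, making runs reproducible. Calibration size is
`round_half_up(0.70·N)`. The split runs on the *pre-processed* spectra of
the model at hand (the cascade uses the root pipeline's representation).
A class-stratified variant exists behind a flag for experimentation; the
default is unstratified, pooled selection.

## PCA exploration and outlier screening

Plain SVD of the mean-centred matrix, capped at 7 components by default.
Sign convention: the largest-magnitude loading element of each component is
positive. Influence statistics are Hotelling's T² (scores over training
score variances) and the Q residual (squared off-plane norm). The outlier
rule is a quantitative surrogate for visual influence-plot inspection:
samples beyond the empirical 97.5 % quantile of either statistic are
flagged, one removal-and-refit round is performed, and both quantiles are
exposed as parameters. This is a declared stand-in for a visual procedure,
not a reconstruction of it.

## PLS-DA

Classes are one-hot (dummy) coded. The core is NIPALS PLS2 on
column-centred X and Y with deflation of both blocks per component;
regression coefficients `B = W (PᵀW)⁻¹ Qᵀ`. NIPALS was chosen over SIMPLS
for transparency of the weight/loading/score quantities VIP needs;
equivalence with a tightly-converged reference implementation is asserted
in tests to 1e-6 on predictions. The inner loop errors after 500
iterations at a 1e-12 relative tolerance; if the Y residual is exactly
orthogonal to X in sample space (degenerate duplicated-spectra inputs) the
component falls back to the dominant X direction and the Y loading comes
out zero, so predictions degrade gracefully to the class priors.

Class assignment is argmax over predicted responses (ties → lowest class
index, logged); an optional 0.5-threshold rule exists for two-class
models. Because the responses are linear in the spectrum, three *collinear*
class means are not argmax-separable regardless of signal strength — the
generator's species signatures vary over two bands to avoid that geometry,
and the test suite documents the effect.

Accuracy is the TN-inclusive form `100·(TP+TN)/(TP+TN+FP+FN)` per class
(one-vs-rest) and `100·nC/nT` overall. Cross-validation is leave-one-out
by default, with venetian blinds (`venetian:k`) and leave-one-animal-out
(grouped) variants; the unit of analysis is the averaged steak spectrum,
so plain LOO leaves out steaks, not animals — muscles of one animal are
correlated, and the grouped variant exists precisely because plain LOO is
optimistic in that respect.

VIP uses calibration Y-variance per component, `SSY_a = ‖q_a‖²·t_aᵀt_a`,
and `VIP_j = sqrt(p·Σ_a SSY_a w_ja² / Σ_a SSY_a)` with unit-norm weights;
mean squared VIP is identically 1 and channels above 1 are deemed
discriminating. Derivative pre-treatments shift where a band's influence
peaks (a symmetric band's first derivative vanishes at its center), so
"recovering a band" is operationalised as: at least one VIP > 1 channel
within one band sigma of the band center.

## Hierarchical cascade

The bundled tree has seven nodes: a species root (SGd1(7), 8 LVs) and, per
species, a fresh/frozen–thawed node (zebra SGd1(5)/5, springbok SNV+DT/2,
ostrich SGd1(5)/3) and a muscle node (zebra SNV+DT+SGd2(9)/6 and springbok
SNV+DT+SGd2(7)/5 on forequarter {IS, SS} vs hindquarter {BF, fillet, LTL,
SM, ST}; ostrich SNV+DT/5 on BD vs FF). The species-node LV count follows
the hierarchical-model configuration (8) rather than the standalone species
model (7); both values appear in the emulated study and the discrepancy is
resolved in favour of the hierarchy table. Two-group muscle discrimination
is the default because anatomically adjacent muscles are spectrally too
similar for reliable 7-class separation; full muscle-level models can be
configured through the same node spec.

Each node re-applies its own pipeline to the raw (averaged, trimmed)
spectra — sibling nodes use incompatible pre-treatments, so chaining
transformed spectra is not meaningful. Nodes are trained on
truth-conditioned subsets (the calibration samples whose ancestors' true
labels match the path) and evaluated on routed samples (whatever the
fitted cascade sends them), so a sample misrouted at the root is judged by
the wrong species' sub-models and the per-sample route trace records the
divergence. The ostrich muscle node targets the `muscle_group` field, in
which BD and FF are their own groups; this keeps the joint prediction
tuple (species, treatment, muscle_group) total for every sample, including
misrouted ones. Joint accuracy is the fraction of samples with every tuple
element correct.

## Reporting

Percentages are formatted by round-half-up at one decimal, with whole
values printed bare ("100", not "100.0"). Published tables of this kind
round inconsistently (80.952 appears as "80.9" but 96.875 as "96.9"), so
tests hold the formatter to ±0.1 of quoted values rather than guessing a
convention. Report CSVs carry a provenance header (package version, config
hash excluding output paths, seed), making identical-seed runs
byte-identical.

## Problem sizes and numerical choices

The test suite runs the full 614-spectrum design for end-to-end checks and
a 4/4/3-animal scaled design elsewhere; the end-to-end separability
criterion uses 50 seeded runs at the high-SNR condition and the
permutation-null check uses five independent permutations of 100
structureless samples (mean LOOCV accuracy, expected 50 %). Key
tolerances: SNV row statistics to 1e-12; detrend annihilation to 1e-10;
SG weights vs the dense least-squares oracle to 1e-10; NIPALS vs
least-squares at full rank to 1e-8; VIP identity to 1e-10. Kennard–Stone
tie-breaks, the PCA sign convention, and seeded generation make every
pipeline stage deterministic.

## Known limitations

Real-data accuracies of the emulated study are not reproducible — its
spectra are not deposited — so all quantitative claims here are about
synthetic data and arithmetic/analytic identities. Per-class accuracies of
the TN-inclusive form depend on tallies the published tables do not print,
and are therefore computable but not externally checkable. The outlier
rule is a quantitative surrogate for a visual procedure. The generator's
class contrasts are qualitative, not compositionally calibrated.
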