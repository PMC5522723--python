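# Methods

## The model

`specsens` treats an eye's spectral sensitivity as the absorptance of a
vertically tiered, fused photoreceptor array. Each class *i* contributes a
normalized pigment absorbance template αᵢ(λ) weighted by its relative
cross-sectional area Aᵢ/A and peak absorption coefficient kᵢ; a tier of
length lⱼ absorbs `1 − exp(−ξⱼ lⱼ)` of the light reaching it, where
`ξⱼ = Σ αᵢ (Aᵢ/A) kᵢ` is the tier's per-μm absorbance. Tiers are traversed
distal → proximal with explicit transmittance bookkeeping, so absorptance
plus residual transmittance is exactly 1 in the absence of pre-receptor
filters — a property the test suite checks to 1e-12. Long arrays self-screen:
distal pigment filters the light reaching proximal pigment, broadening the
normalized absorptance; the bandwidth of a single class is strictly
increasing in the optical density k·l.

Two A1 template families are implemented and cross-checked against each
other (they agree within 0.1 over the main lobe for any common λmax):

* **SSH**: `exp(−a x²(1 + b x + c x²))` with `x = log10(λ/λmax)`,
  a = 380, b = 6.09, c = 3b²/8;
* **GFKRD**: `1/(exp(A(a−x)) + exp(B(b−x)) + exp(C(c−x)) + D)` with
  `x = λmax/λ`, A = 69.7, B = 28, C = −14.9, D = 0.674, b = 0.922,
  c = 1.104, and `a = 0.8795 + 0.0459·exp(−(λmax−300)²/11940)`.

The UV beta band is a Gaussian centred at `189 + 0.315·λmax` nm with width
`−40.5 + 0.195·λmax` nm and amplitude 0.26 relative to the alpha peak; the
same parameterization is used for both families. It is off by default —
whole-eye inference in this package follows the alpha-only convention —
and when enabled the combined curve is renormalized to peak 1 so k keeps
its meaning as peak absorbance per μm.

Templates are evaluated analytically on an internal 1 nm grid (no lookup
tables); model curves are sampled down to the binned data grid only when
residuals are computed, because binning first would distort peak positions
and bandwidths. RSS is defined between the peak-normalized model and the
peak-normalized data *on the binned grid*, so generator output and fit
predictions share one normalization convention. Pre-receptor filters are
applied before normalization and resampled by clamped linear interpolation
(with a warning when clamping extrapolates).

### Tier replacement

In many insect and crustacean ommatidia the shortest-wavelength receptor is
confined to the distal part of the rhabdom, becoming axon-like below. A
tiered `ArrayStructure` with `replace_shortest=True` drops the shortest-λ
class from every tier after the first and reassigns its cross-sectional
area to a replacement receptor (by default the longest-wavelength one),
keeping the other fractions. With one class the replacement is a no-op, so
a single candidate structure serves the whole 1–5-class model universe.
Relative areas are renormalized to sum to 1 within each tier, which also
absorbs published area sets that sum to slightly more than 1 (rounding, or
double-cone frequency corrections, which are treated as a user-supplied
input rather than hard-coded).

### Thin-section absorbance mode

For very long rhabdoms whole-array absorptance saturates, and a
cross-section absorbance model (the tier's normalized ξ, no self-screening)
is the appropriate comparison. `cross_section_absorbance` selects the tier
containing a given depth fraction of the total length; a depth exactly on a
tier boundary belongs to the distal side, so a depth fraction of 2/3 in a
two-thirds/one-third split addresses the distal tier that carries every
class. Fits in absorbance mode use the full class composition of that
section.

## Likelihood, AICc and model choice

With i.i.d. Gaussian residuals the concentrated log-likelihood at the MLE
σ̂² = RSS/n is `−(n/2)ln(RSS/n) − (n/2)ln 2π − n/2`, and
`AICc = −2 log L + 2K + 2K(K+1)/(n−K−1)`. Lower AICc is better; tables in
this literature often print the magnitude of a negative AICc and rank on
it, so selection tables carry an `aicc_printed = |AICc|` column for direct
comparison. Parameter counts follow the published bookkeeping: class-count
models use K = 2m + 1 (λmax and area per class plus the residual variance,
even though areas carry m − 1 free dimensions); fixed-array k models use
K = (free k) + 1. An RSS floor of 1e-12 guards the likelihood against
pathological exact fits. Akaike weights, evidence ratios `e^{Δ/2}` and a
nested extra-sum-of-squares F-test (upper-tail p, accept the larger model
at p < 0.05) complete the comparison toolkit.

Candidate enumeration is deterministic: class counts ascending, SSH before
GFKRD, ten candidates for the default 1–5 × 2 universe. Candidates whose K
exceeds what the data can support (n ≤ K + 1) are skipped with a warning.

## Optimization

Free parameters are fit by bounded trust-region least squares from 32
seeded Latin-hypercube starts (the reproducibility-relevant setting; a
fixed seed gives bitwise-identical results). Constraints are made smooth by
reparameterization rather than rejection:

* λmax ordering: (λ₁, positive gaps) with a 0.1 nm minimum separation;
  a soft penalty residual pulls the last class back when the gap sum
  overshoots the upper bound. Default λmax bounds are the data range
  ± 30 nm clipped to [310, 650] nm.
* areas: softmax of m − 1 logits, so Σ Aᵢ/A = 1 exactly; the tier
  replacement is recomputed every evaluation.
* k: log10-space within [0.001, 1.0] μm⁻¹; fits pinned at a bound are
  flagged. Default k is 0.008 μm⁻¹ for invertebrates and 0.015 μm⁻¹ for
  vertebrates, overridable per receptor.

Local optimization uses `scipy.optimize.least_squares` (trf, tolerances
1e-8, at most 400 residual evaluations per start); the reported RSS is
recomputed at the solution without the penalty term.

## Synthetic data

The generator emulates the study conditions this framework is used under:
relative sensitivity binned at 20 nm over 310–690, 350–690 or 410–690 nm,
additive Gaussian noise (sd 0.02 by default — an arbitrary but visually
realistic choice for ERG scatter, since no noise model accompanies such
published curves), clipped at zero and peak-renormalized; multi-region
recordings are simulated as independent noisy realizations averaged before
renormalization. The scenario library fixes truth parameters to
published-style values: velvet worm (one class, 481 nm, 100 μm), human
scotopic (420/497 nm, areas 0.16/0.84, 22.5 μm, lens + macula filters),
Daphnia (356/440/521/592 nm, areas 0.52/0.21/0.12/0.15, two 6 μm tiers with
distal-only UV class), Papilio (360/390/460/520/600 nm, 500 μm split into
exact thirds — 333.3/166.7 μm — so the two-thirds cross-section addresses
the distal tier), and a killifish fixed array (18 μm, five pigments with
spring-population k truth and a negligible SWS2A). The killifish
sensitivity range is not published; 350–690 nm (18 bins) is used. Prefilter
curves are explicitly synthetic stand-ins (sigmoid lens cut-off, Gaussian
macular/ellipsosome bands); tests are written not to depend on their exact
shape.

What passing synthetic tests do **not** show: robustness to real-data
features the generator omits — wavelength-correlated noise, adaptation
state, metarhodopsin contamination, filtering pigments, and digitization
error in published curves.

## Validation and known limitations

* **Optics oracle**: the closed-form tiered absorptance agrees with a
  10,000-slab sequential-absorption simulation to 1e-4 pointwise on random
  1–3-tier models.
* **Recovery**: across seeded replicates at noise sd 0.02 with 32 starts,
  the AICc-best candidate has the true class count in ≥ 80% of replicates
  for the one-, two- and four-class scenarios, with median λmax error
  ≤ 5 nm.
* **Failure mode reproduced**: fitting the 500 μm tiered absorptance model
  to a sharp five-peaked sensitivity (what a real compound-eye ERG
  resembles, receptors being sharpened by filtering pigments the model
  omits) selects fewer than five classes — self-screening over-estimated —
  while thin-section absorbance fits on the same kind of data recover all
  five. Whole-array absorptance inference should therefore be applied
  judiciously to eyes with strong intra-rhabdom filtering.
* Model weights are meaningful only relative to the candidate set supplied;
  adding or removing candidates rescales them.
* No uncertainty intervals on fitted parameters; no Bayesian averaging;
  A1 chromophore templates only; no waveguide or polarization optics.

Problem sizes in the test suite and acceptance script (replicate counts,
random-model counts) are the package's own verification choices and are
stated alongside each reported number.
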