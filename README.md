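# specsens

Multi-model inference of photoreceptor spectral classes from whole-eye
spectral sensitivity.

Extracellular electroretinogram (ERG) spectral sensitivity sums the
contributions of every photoreceptor class in an eye. Given such a curve and
basic histology (photoreceptor lengths, tiering, pre-receptor filters),
`specsens` asks: *how many opsin-based spectral classes are present, at what
λmax, in what relative cross-sectional area — and, for a known array, at
what visual pigment concentration?* Competing hypotheses are fit as
self-screening absorptance models and ranked by the small-sample Akaike
information criterion. The intended users are visual ecologists and sensory
physiologists relating ERG spectral sensitivity, histology and opsin
expression.

## Model

A fused photoreceptor tier *j* absorbs per micrometre

```
ξⱼ(λ) = Σᵢ αᵢ(λ) · (Aᵢ/A) · kᵢ
```

where αᵢ is a normalized visual-pigment template (SSH modified log-normal or
GFKRD rational-exponential A1 nomogram, parameterized by λmax), Aᵢ/A the
relative cross-sectional area of class *i*, and k its peak absorption
coefficient (μm⁻¹). The whole tiered array, traversed distal → proximal,
absorbs

```
S(λ) = Σⱼ T₍ⱼ₋₁₎(λ) · (1 − e^(−ξⱼ(λ) lⱼ)),   T₀ = 1
```

optionally multiplied by lens/macula/ellipsosome transmittances, and
peak-normalized for comparison with relative sensitivity data binned at
20 nm. Each candidate model (1–5 classes × template family) is fit by
bounded multi-start least squares, scored by the concentrated Gaussian
likelihood `log L = −(n/2)·ln(RSS/n) − (n/2)·ln 2π − n/2`, and ranked by

```
AICc = −2 log L + 2K + 2K(K+1)/(n−K−1)
```

with Akaike weights `wᵢ = e^(−Δᵢ/2) / Σᵣ e^(−Δᵣ/2)` and evidence ratios
`e^(Δᵢ/2)` relative to the best model. A nested extra-sum-of-squares F-test
is provided for the classical pairwise comparison. With λmax and areas held
to known constants, the same machinery fits per-pigment k, whose normalized
values kᵢ/Σk are comparable to relative opsin expression.

## Worked example

Simulate a four-class tiered water-flea-like eye (two 6 μm tiers, UV
receptor distal only) and sweep candidate models:

```python
import specsens as ss

scen = ss.scenario_library()["daphnia"]          # truth: 356/440/521/592 nm
data, truth = ss.generate(scen, seed=1)          # 18 bins, noise sd 0.02
config = ss.CandidateConfig(structure=scen.structure, k=scen.k)
table = ss.fit_candidates(data, config, seed=1, n_starts=32)
print(table.to_frame()[["model", "rss", "aicc", "delta_aicc", "evidence_ratio"]])
```

which prints (values from this exact run):

```
   model      rss       aicc  delta_aicc  evidence_ratio
  1, SSH 2.334505  22.029781   94.528111    3.361387e+20
1, GFKRD 2.514796  23.368831   95.867160    6.565826e+20
  2, SSH 0.675091   6.982750   79.481079    1.815921e+17
2, GFKRD 0.743321   8.715813   81.214143    4.319436e+17
  3, SSH 0.056753 -27.387742   45.110587    6.246541e+09
3, GFKRD 0.057775 -27.066470   45.431860    7.335048e+09
  4, SSH 0.001979 -72.498330    0.000000    1.000000e+00
4, GFKRD 0.002178 -70.769085    1.729245    2.374110e+00
  5, SSH 0.001958 -47.191883   25.306447    3.127700e+05
5, GFKRD 0.001553 -51.365254   21.133075    3.881405e+04
```

The four-class SSH model wins decisively (lowest AICc; the three-class
alternative has an evidence ratio of ~10⁹ against it), and its fitted λmax
(355.9, 440.6, 523.2, 592.3 nm) recover the ground truth to a few
nanometres. The five-class SSH model fits no better and is rejected by the
parameter penalty. A `specsens` command-line interface wraps the same
pipeline (`specsens simulate`, `fit`, `fit-k`, `select`).

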