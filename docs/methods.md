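# Methods

## The model

The object of study is the degree distribution of a voxel-level functional
connectivity graph. Nodes are grey-matter voxels; an edge joins voxels
`i, j` when the Pearson correlation of their cleaned BOLD time series
satisfies `r_ij ≥ T`, for an absolute threshold `T`. Only positive
correlations define edges, and pairs whose centers are closer than 20 mm
are excluded so that spatially shared signal between neighbours does not
masquerade as connectivity ("within 20 mm" is implemented as strictly
`< 20 mm`; distances are Euclidean in mm, from the NIfTI affine for real
data or from the lattice for synthetic scenes). Subnetwork degree
sequences restrict the *global* degrees to the voxels of one of seven
canonical resting-state subnetworks — membership selects the nodes, but
each node's degree still counts connections to the whole brain.

Three candidate laws are fitted to each degree sequence on integer support
`k ≥ xmin`:

| model | density | discrete form |
|---|---|---|
| power law | `x^(−α)` | exact, `P(k) = k^(−α) / ζ(α, xmin)` |
| power law with exponential cutoff | `x^(−α) e^(−λx)` | rounding |
| Weibull (stretched exponential) | `x^(β−1) e^(−λx^β)` | rounding |

"Rounding" assigns integer `k` the mass of the continuous density on
`[k−½, k+½]`, renormalized to the support:
`P(k) = [S(k−½) − S(k+½)] / S(xmin−½)` with `S` the continuous survival
function. For the Weibull `S(t) = exp(−λ t^β)` is elementary; for the
cutoff law `S(t) ∝ Γ(1−α, λt)`, the upper incomplete gamma function of
negative order, which we evaluate by downward recurrence from a positive
order (nonpositive integer orders via the generalized exponential
integral). Normalization is therefore exact — pmf tables are checked to
sum to 1 within 1e-6 with the analytic tail appended.

The Weibull shape β interpolates between regimes: `β = 1` is an
exponential (short-tailed) law, and as `β → 0` the density approaches
power-law-like (heavy-tailed, hub-rich) behavior. A fall in β therefore
reads as a shift toward more hub nodes.

### Fitting

The Weibull and cutoff models are fitted by bounded maximum likelihood
(L-BFGS-B) inside the boxes β ∈ (0.01, 3], λ ∈ (1e-6, 100] (Weibull) and
α ∈ (1.01, 6], λ ∈ (1e-6, 10] (cutoff), from a moment-based start (Weibull
shape from the coefficient of variation, `β ≈ (μ/σ)^1.086`) plus two
seeded random restarts; bounded multi-start optimization avoids the flat
likelihood ridges of stretched exponentials. Degrees of 0 are excluded
before fitting (the support starts at `xmin = 1`, the value used for all
model comparisons) with the excluded count logged.

For the discrete power law the package exposes two estimators:

* the closed form `α̂ ≈ 1 + n [Σ ln(x_i/(xmin − ½))]^(−1)` — the exact
  maximizer of the continuous likelihood with support shifted to
  `xmin − ½`;
* the exact discrete MLE, maximizing the zeta-normalized likelihood
  numerically.

These agree to ~1e-3 for `xmin ≳ 20` but diverge at `xmin = 1`, where the
closed form is biased low by ~0.3–0.5 for α ≈ 2.5 (a known small-`xmin`
limitation of the approximation). Consequently `fit_powerlaw_discrete`
reports the closed form (with the exact MLE in `extras`), while
`fit_discrete_mle` — whose contract is that parameters maximize the
discrete likelihood, and which feeds the model comparisons — uses the
exact MLE. The KS-minimizing `xmin` scan likewise fits candidate tails
with the exact MLE; with the biased closed form the scan drifts away from
small candidates even on pure power-law data.

### Model comparison

Two fitted models are compared with the Vuong construction: pointwise
loglikelihood differences `d_i = ln p_a(x_i) − ln p_b(x_i)`,
`R = Σ d_i / (σ√n)` with σ the standard deviation of the `d_i`, and a
two-sided normal p-value for the sign of R (R > 0 favors the first model).
If the two fitted pmfs coincide on the sample (σ = 0) the comparison is
returned degenerate with R = 0, p = 1. At the group level the mean R is
taken over subjects whose individual comparison reaches p < 0.05; subjects
with non-significant comparisons contribute nothing and are counted.

A caveat the test suite encodes: the Vuong test assumes non-nested models.
The power law is the λ → 0 boundary of the cutoff law, so on power-law
data the fitted cutoff model collapses onto the power law and the
comparison is (nearly) degenerate — the correct consistency property is
that the generating model is never significantly *beaten*, not that it
always wins significantly.

## Group statistics

Diagnosis is coded HC = 0 / aMCI = 1 and gender F = 0 / M = 1, so negative
diagnosis coefficients mean the patient group is lower. Two OLS models
carry the inference: the fitted model parameter regressed on diagnosis +
age + gender + education (group difference), and cognitive ability — the
raw mean of the MMSE and MoCA scores, unstandardized — regressed on the
parameter + covariates within the patient group (association), plus a
diagnosis×parameter interaction model across both groups. BH-FDR is
applied across the 8 networks (whole brain + 7 subnetworks) within one
threshold, each threshold corrected separately; non-finite p-values from
saturated fits are propagated, not adjusted. The gender contrast uses the
Yates-corrected two-tailed Pearson χ² — on a 28/13 vs 17/13 table the
corrected statistic gives p = 0.45 where the uncorrected gives 0.32, and
the corrected convention is the one adopted; continuous demographics use
the pooled two-sample t (Welch available as an option). Voxelwise FCS
group maps run the same diagnosis GLM per voxel (vectorized) with FDR
across voxels; voxels fitted exactly (zero residual variance) report t = 0.

## The synthetic generator

The generator defines the study conditions under which the pipeline is
validated; it emulates *cleaned* band-limited voxel series and their
derived degree sequences, not raw scanner data (no hemodynamics, motion,
or physiological noise — so passing tests certify the analysis chain, not
robustness to acquisition artifacts).

**Degrees mode (default, the precise path).** Each subject's per-network
degree sequence is drawn directly from the discrete Weibull with known
parameters: shape `β_subj,net = β0_net − Δβ·[aMCI] + N(0, 0.05)` (network
baselines 0.52–0.68, all in the short-tailed (0, 1) regime; rate λ = 0.1;
within-group SD 0.05), with 600 whole-brain and 150 per-subnetwork degrees
per subject. Sequence sizes are chosen so that per-subject estimation
noise on β (≈ 0.01–0.04) stays below the within-group spread while a full
multi-cohort calibration still runs in minutes on one CPU. Samplers are
exact: the Weibull and cutoff laws via continuous inverse-CDF/rejection
draws rounded to integers (the rounding *is* the discretization), the
power law via inverse-CDF lookup on a pmf table truncated at cumulative
mass `1 − 1e-9`.

**Timeseries mode.** Voxel `i` on a 3-mm lattice carries
`x_i(t) = √c_i·s_g(i)(t) + √(1−c_i)·ε_i(t)`: one shared signal per
community (7 interdigitated atlas labels — spatially mixed so the 20-mm
exclusion does not wipe out within-community edges) plus private noise,
with hubness `c_i ~ Beta(2, 5)` for controls. Two same-community voxels
correlate at `√(c_i c_j)` in expectation, so high-coupling voxels become
hubs after thresholding. The aMCI hubness default Beta(1.5, 4) puts more
mass on extreme couplings — more hubs, heavier degree tail, lower fitted β
— but the mapping from the hubness shift to Δβ is indirect; the injected
effect size is exact only in degrees mode, which is why the calibration
studies use it. The lattice is a two-layer slab to maximize in-plane
extent (a compact cube of a few hundred 3-mm voxels would fall almost
entirely within the 20-mm exclusion radius).

**Demographics and cognition.** Ages, gender frequencies and education
follow the two-group elderly template (patients older on average);
cognitive ability is `27 + slope·(β_wb − β0_wb) − 2.8·[aMCI] −
0.05·(age − 70) + N(0, 1.5)` score points, with the default coupling slope
of 20 points per unit β chosen so the association is detectable (t ≈ 3.5)
in a 30-patient group; MMSE and MoCA are emitted ±1.4 points around
ability with 0.75-point instrument noise, rounded and clipped to [0, 30].
Covariate effects other than the small negative age slope default to zero.

## Numerical choices and edge cases

* pmf values are floored at 1e-300 inside loglikelihoods; optimizer
  failures across all restarts raise, carrying the best point found.
* Ties in the KS `xmin` scan break toward the smallest candidate
  (retaining the most data).
* Binarization uses `r ≥ T` while FCS uses strict `r > r0` — the asymmetry
  between the two printed rules is retained deliberately. The FCS
  denominator is the full eligible-voxel count regardless of how many
  terms survive the floor, and distance-excluded pairs are removed from
  the sum only.
* The grey-matter mask boundary is inclusive (`probability ≥ cutoff`).
* Constant voxels are detected with a relative tolerance (1e-12 of the
  data scale) — an exact zero-variance test misses float-rounding noise —
  and removed with a logged count before correlation.
* Thresholds must be positive: `T ≤ 0` would admit negative correlations
  as edges and is rejected.
* Cohort generation derives per-subject streams from a single seed
  sequence, making every output bit-reproducible; the pipeline writes its
  config and seed into each run directory.

## Known limitations

* The closed-form power-law estimator is intentionally reported as printed
  even where it is biased (`xmin = 1`); consumers wanting the MLE should
  read `extras["alpha_exact"]` or use `fit_discrete_mle`.
* The cutoff-law sampler requires α > 1 (its proposal law must be
  normalizable), although the fitted model itself is defined for any α
  with λ > 0 inside the box.
* Degrees mode samples network sequences independently per subject; in
  real data subnetwork degrees are a partition of the whole-brain sequence
  and are correlated. The timeseries mode preserves that structure at the
  cost of only approximate control over effect sizes.
* BH-FDR adjustment is not idempotent (no step-up procedure is); the
  guaranteed properties are dominance over raw p-values, capping at 1, and
  order preservation.
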