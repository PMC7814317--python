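# neurodegree

Degree-distribution analysis of voxelwise resting-state functional brain
networks: which probability law describes how many functional connections a
grey-matter voxel has, and does that law change in amnestic mild cognitive
impairment (aMCI)?

The package is aimed at researchers analysing resting-state fMRI
connectivity at the voxel level. It implements the full analysis chain:

1. **Graph construction** (`netbuild`): Pearson correlation between all
   pairs of voxel time series inside a grey-matter mask (probability cutoff
   0.2), binarized at thresholds T ∈ {0.4, 0.5, 0.6} counting positive
   correlations only (`a_ij = 1` iff `r_ij ≥ T`), with connectivity
   terminating within 20 mm of the source voxel removed to suppress shared
   local signal. Nodal degree is `degree(i) = Σ_j a_ij`; a subnetwork's
   degree sequence is the *global* degree of its member voxels (labels from
   a 7-network parcellation: V, SM, DA, VA, Lim, FP, DM). Functional
   connectivity strength (FCS, weighted degree centrality) is
   `FCS(i) = (1/N) Σ_j z_ij` over `r_ij > r0 = 0.2`, with `z = atanh(r)`.
2. **Model fitting and comparison** (`heavytail`): discrete maximum
   likelihood fits of three candidate degree laws on support `k ≥ xmin = 1` —
   power law `f(x) ∝ x^(−α)` (exact zeta-normalized discrete form, plus the
   closed-form estimator `α̂ ≈ 1 + n [Σ ln(x_i/(x_min − ½))]^(−1)`),
   power law with exponential cutoff `f(x) ∝ x^(−α) e^(−λx)`, and Weibull
   (stretched exponential) `f(x) ∝ x^(β−1) e^(−λx^β)`. The latter two are
   discretized by rounding (bin mass of the continuous density on
   `[k−½, k+½]`). Competing fits are compared with a Vuong-style normalized
   loglikelihood ratio `R = Σ d_i / (σ√n)` with a two-sided normal p-value;
   `R > 0` favors the first model, and group-level preference is the mean R
   over subjects with individually significant comparisons.
3. **Group statistics** (`cohortstats`): demographic contrasts (Yates-
   corrected Pearson χ² for gender, pooled two-sample t otherwise), the
   covariate-adjusted GLMs
   `parameter ~ β0 + β1·diagnosis + β2·age + β3·gender + β4·education` and
   `cognition ~ β0 + β1·parameter + β2·age + β3·gender + β4·education`
   (cognitive ability = mean of MMSE and MoCA), a diagnosis×parameter
   interaction model, Benjamini–Hochberg FDR across networks, and voxelwise
   FCS group t-maps.
4. **Synthetic cohorts** (`synthetic`): exact samplers for all three
   discrete laws, voxel time-series scenes with community structure and
   per-voxel "hubness", and two-group cohort tables with known ground truth
   (injected Weibull-shape deficit and cognition coupling), so every
   downstream stage is testable without scanner data.
5. **Orchestration** (`pipeline`, `neurodegree` CLI): `simulate`, `build`,
   `fit`, `compare`, `stats` and `run-all` subcommands; bit-reproducible
   run directories; NIfTI I/O for real data.

## Worked example

```python
import neurodegree as nd

# a 10+10 HC/aMCI cohort; aMCI whole-brain Weibull shape lower by 0.1
records, degrees, truth = nd.generate_cohort(n_hc=10, n_amci=10,
                                             delta_beta=0.1, seed=42)
x = degrees["hc000"]["whole_brain"]          # one subject's degree sequence
fw = nd.fit_discrete_mle(x[x >= 1], "weibull")
fp = nd.fit_discrete_mle(x[x >= 1], "powerlaw")
c = nd.compare_models(x[x >= 1], fw, fp)
print(f"beta={fw.params['beta']:.3f} lam={fw.params['lam']:.3f} "
      f"R={c.R:.1f} p={c.p:.2g}")
```

prints

```
beta=0.519 lam=0.112 R=14.9 p=1.6e-50
```

— the fitted Weibull shape β ≈ 0.52 (its generative value for this subject
is 0.546), and the normalized ratio R = 14.9 with p ≪ 0.05 says this degree
sequence is fitted far better by the Weibull than by a power law. Running
the group stage,

```python
betas = {"whole_brain": [nd.fit_discrete_mle(
             degrees[s]["whole_brain"], "weibull").params["beta"]
         for s in records.subject_id]}
tab = nd.group_difference_table(betas, records)
print(tab[tab.term == "diagnosis"][["estimate", "t", "p_raw"]].round(4))
```

```
   estimate       t   p_raw
1   -0.1167 -2.8852  0.0113
```

recovers the injected group deficit: the aMCI coefficient is ≈ −0.12
(truth −0.1) with p ≈ 0.01. From a shell, the same end-to-end run is
`neurodegree run-all --seed 42 --n-hc 10 --n-amci 10 --out run/`.

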