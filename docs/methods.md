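# Methods

This note documents the modelling choices behind scnkit: what each stage
computes, the defaults and why, what the synthetic cohort does and does not
emulate, and the numerical conventions that change values.

## Feature schema

Networks are built on 76 nodes: average cortical thickness of the 31
Desikan–Killiany–Tourville regions per hemisphere (62 features, mm) and the
volumes of thalamus, caudate, putamen, pallidum, hippocampus, amygdala and
accumbens area per hemisphere (14 features, mm³). Canonical node order is
left thicknesses, right thicknesses, then Left/Right volume per structure.
Tables are validated strictly: missing, extra or duplicated columns and
non-numeric cells are errors, never silently imputed — the analysis assumes
complete data.

## Covariate adjustment and reference z-scoring

Each feature is residualized by OLS on intercept + age + gender (M = 1,
reference F) + eTIV. The regression pools all subjects: the nuisance slopes
are estimated with maximal power, and the reference group only anchors the
z-scale (a `per_group` flag fits within groups instead). Residuals are
z-scored with the NCI-group mean and n−1 standard deviation per feature.
The design must be full rank (e.g. a single-gender cohort with the gender
covariate is rejected), and a zero reference sd is an error naming the
feature.

**A property worth knowing.** Reference-group z-scoring is asymmetric:
reference subjects are scored *in-sample* (each contributes to the mean and
sd that scale it, which shrinks their extremes slightly), non-reference
subjects *out-of-sample*. Because the similarity kernel is sensitive to the
shape of a subject's z-profile, this induces a small systematic tilt —
reference-group networks come out slightly more locally coherent. On
synthetic null cohorts (no group differences, n = 18/33) the
covariate-adjusted E_loc-AUC group test rejects at ~15 % instead of the
nominal 5 %, and the CI−NCI sign is negative in ~93 % of null cohorts;
z-scoring against all subjects restores exactly nominal calibration. We
keep the reference-group convention because it is the field's standard for
patient-vs-norm scoring, but inference should be read accordingly: the
permutation test over group labels of the *computed* AUCs remains exactly
calibrated (verified ~5 %), whereas the parametric test inherits the tilt.
Nothing in this paragraph is specific to synthetic data — the same
asymmetry operates on real cohorts scored against a patient subgroup.

## Similarity networks and thresholding

Edge weight w(x, y) = exp(−(z_x − z_y)²); the diagonal is zero by
convention. Weights lie in (0, 1] with w = 1 iff the two z-scores are
equal. Binarization keeps the k = round(D·N(N−1)/2) largest-weight edges at
density D (round half away from zero; at N = 76 and D = 0.10 that is 285 of
2850 possible edges). Ties at the k-th weight are broken by lexicographic
(i, j) order, making ensembles deterministic; edge sets are nested across
densities by construction, and any strictly increasing transform of the
weights leaves every binarized graph unchanged. Densities retaining zero
edges are rejected.

## Density admission

A density is admitted when (1) the fraction of non-isolated nodes exceeds
0.8, (2) modularity of the best-found Louvain partition (fixed seed, best
of 10 restarts) exceeds 0.3, and (3) small-world σ exceeds 1. The
connectivity criterion reads "more than 80 % of nodes are connected to
other nodes" literally as degree ≥ 1; a giant-component variant is
available (`connectivity="giant"`). Criteria are evaluated on cohort means
of the per-subject diagnostics at each density (stable at small n; an
`aggregate="all"` option requires every subject to pass) and the longest
contiguous passing run is returned. The default analysis range is the fixed
interval 0.10–0.34 with the sweep available as `density_range="auto"`.

## Topology metrics

All metrics operate on simple undirected binary graphs. Conventions for
fragmented graphs: characteristic path length L averages over *reachable*
ordered pairs only; unreachable pairs contribute 0 to global efficiency.
Nodal local efficiency of node i is the global efficiency of the subgraph
induced by its neighbors (0 for degree < 2); the global value is the nodal
mean. Clustering uses triangles/(k choose 2) with 0 for k < 2. Betweenness
is reported unnormalized (geodesic fractions summed over unordered pairs);
degree as raw edge counts. Assortativity is the Pearson correlation of
degrees over edge endpoints and is NaN (not an error) for regular graphs.
Shortest paths are computed by simultaneous dense BFS (numpy matrix
products), which on these 76-node graphs outruns sparse-graph libraries
and is tested to agree exactly with networkx and with brute-force oracles.

γ, λ and σ = γ/λ normalize C and L by their means over a Maslov–Sneppen
ensemble: repeated double-edge swaps (numba kernel; 10 × |E| swaps per
null, accepted only when the graph stays simple) preserve the exact degree
sequence. `random_reference` defaults to 100 nulls; the pipeline default is
20 per (subject, density) — at 51 subjects × 25 densities that is the
pragmatic problem size, and AUC-level group statistics are insensitive to
ensemble size well before 20 (the acceptance script uses 8). Complete or
otherwise unrewirable graphs are returned unrewired and flagged, so σ = 1
there by construction. Per-null seeds derive from one master seed via
`numpy.random.SeedSequence`, making every ensemble reproducible.

## AUC aggregation

Metric curves are integrated over the admitted range with the trapezoid
rule on the density grid (order-h² accurate; a constant curve c over a
width-w range gives exactly c·w). Both range endpoints must be grid points.

## Group statistics

Univariate comparisons follow normality routing: Shapiro–Wilk per group,
two-sample Student t (equal variances — the conventional reading of an
"unpaired two-tailed t-test") if both groups have p > 0.05, Mann–Whitney U
otherwise, chi-square for categoricals; summaries are mean ± sd or
median (IQR) accordingly. Metric AUCs are compared with OLS
AUC ~ group + age + gender, reporting the group coefficient's t (CI coded
1, so negative t = lower in CI); Benjamini–Hochberg FDR is applied across
the six global metrics, and across the 76 nodes per nodal metric. Note that
BH adjustment is order-invariant and monotone but *not* idempotent:
re-adjusting adjusted values changes them, because the step-up minimum
re-multiplies by m/rank.

Volume ratios divide each (left+right summed) subcortical volume by eTIV
and are expressed in percent, so logistic-regression coefficients are O(1);
a per-hemisphere analysis is available by passing unsummed volumes.
Logistic models (outcome ~ predictor + age + gender + duration) are fitted
by maximum likelihood with Wald 95 % intervals exp(B ± 1.96·SE); separation
and non-convergence raise explicit errors rather than returning silent
coefficients. Cognitive-impairment classification uses the
education-dependent MMSE cutoffs ≤ 19 (illiterate), ≤ 22 (elementary,
1–6 years), ≤ 26 (secondary, ≥ 7 years).

## Synthetic cohort

The generator emulates the study conditions the pipeline targets: 18 CI vs
33 NCI patients, ages uniform 60–80, P(female) = 0.55, disease duration
1–6 y, education weights (0.25, 0.50, 0.25) over
illiterate/elementary/secondary, eTIV ~ N(1.43 × 10⁶, 1.7 × 10⁵) mm³, MMSE
group-conditional (CI 18.8 ± 4.2, NCI 25.9 ± 2.7, truncated to [0, 30]).
Features follow

  value = baseline + loadings·latent factors + slopes·(age, male, eTIV) + noise,

with 4 shared latent factors (per-factor loading sd 4 % of baseline)
inducing inter-regional covariance, idiosyncratic noise sd 3 % of baseline,
and default nuisance slopes of −0.2 %/year (age), +1 % (male) and a volume
elasticity of ~0.3 on eTIV. Thickness baselines span 2.0–3.0 mm; volumes
use typical per-hemisphere values. Two plantable CI-group effects exist:
**atrophy** (fractional mean reduction of named ROIs, capped at 0.5) and
**decoherence** — extra independent Gaussian noise whose sd is
`decoherence_sd` × the feature's noise sd (a unitless multiplier, because
features mix mm and mm³). Added idiosyncratic noise disperses a subject's
z-profile, weakening the tight near-neighbour similarity structure, so it
lowers clustering-type metrics (E_loc, γ) of the thresholded graphs — the
direction reported for impaired cohorts. The reference planted condition
used in tests and the acceptance script is decoherence_sd = 3.0 with 5 %
bilateral thalamus/hippocampus atrophy, fixed after a standalone probe of
the mechanism; at that condition the CI group's E_loc AUC is lower in
20/20 replicate cohorts.

What the generator does **not** emulate: spatial autocorrelation on the
cortical surface, non-Gaussian morphometric distributions, scanner/site
effects, missing data, and any coupling between MMSE and the features
(cognitive status is sampled, not caused by the planted atrophy). Passing
tests therefore demonstrate that the pipeline recovers effects of the
planted kinds at realistic sample sizes — not that real PD cohorts carry
such effects.

## Problem sizes and determinism

Default test and pipeline sizes: 51 subjects, 25 admitted densities,
20-null ensembles (8 in the acceptance script), 1000-replicate calibration
nulls for the univariate router, 200-replicate coverage checks for the
logistic layer, 20 replicate cohorts for direction recovery. One master
seed expands into per-stage and per-(subject, density) seeds via
`SeedSequence`; rerunning any fit or the CLI with the same config and seed
reproduces every output file bit-for-bit (tested by byte comparison).

## Known limitations

* The admission sweep at full cohort scale is the most expensive stage;
  the default fixed 0.10–0.34 range bypasses it.
* The reference-scoring tilt described above means parametric group tests
  are mildly anti-conservative in the E_loc direction; permutation tests
  are the calibrated alternative and are what the test suite relies on.
* σ, λ, γ depend on the null-ensemble size through ⟨C_null⟩ and ⟨L_null⟩
  noise; with 8–20 nulls the per-subject values carry a few percent of
  ensemble noise, which AUC aggregation and group averaging largely cancel.
* Weighted-graph metric variants, rich-club/hub analyses and directed
  graphs are out of scope; modularity is computed only for admission.
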