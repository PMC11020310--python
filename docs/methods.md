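# Methods

`protstoich` implements the computational chain of a factorial chemostat
proteomics study on marine *Synechococcus*: peak-area preprocessing and
%PA_Total trait allocation, Nonparametric Bayesian Local Clustering
(NoB-LoC) of proteins, and nutrient-vs-temperature variance partitioning
of elemental quotas, ratios, and the proteome. This note records the
models, the numerical choices, and what the synthetic test surface does
and does not establish.

## Study design and units

The reference design is 2 nutrient regimes (N:P input ratio 1.7 =
N-stress, 80 = P-stress) × 3 temperatures (20, 24, 28 °C) × 5 replicate
chemostats = 30 samples. Elemental measurements are particulate C, N, P
concentrations in μmol L⁻¹ of culture, a cell density in cells L⁻¹, and
flow-cytometric forward scatter (FSC_H, arbitrary units) as a cell-size
proxy. Cell quotas are

    Q_X [fmol cell⁻¹] = X [μmol L⁻¹] × 10⁹ / cell density [cells L⁻¹],

and C:P, N:P, C:N are molar quota quotients. Because the convention is
ambiguous in practice, per-treatment summaries report both the mean of
per-sample ratios and the ratio of treatment-mean quotas
(`stoich.treatment_ratio_summary`).

## Peak-area preprocessing and %PA_Total

A DIA-MS experiment yields per protein and sample a summed peptide peak
area (PA). Preprocessing follows the study's rules: keep proteins with
≥ 2 representative peptides, then drop proteins missing in more than 2
of the 30 samples; both losses are reported as percent of summed PA.
Missing cells count as 0 in PA sums — no imputation — which preserves
deposited totals. Per-sample totals are then equalized to the grand
mean total (`total_sum`), standing in for the instrument vendor's
unstated cross-sample normalization; a median-ratio size-factor
alternative is available and the method applied is recorded in the
matrix metadata. The allocation metric is

    %PA_Total = PA(protein or group) / PA_Total × 100,

with PA_Total summed over the retained protein set by default (a
`universe="identified"` option uses a wider identification set when one
is supplied). Summed PA is read as resource allocation, not copy
number: proteins differ in length, peptide count, and ionization
efficiency, so no copy-number claim is made. `log_prop_diff` computes
the proportional difference from each protein's mean natural-log PA;
the log base cancels between numerator and denominator.

## NoB-LoC: the model

Proteins are partitioned into *biclusters* — sets sharing a local
partition of the samples — with zero-enrichment on both axes. The
priors are zero-enriched Pólya urns:

* protein g is variant with probability π₀ (default 0.01: most
  biological responses involve few proteins) and variant proteins
  follow a Dirichlet-process urn with concentration α_protein;
* within each bicluster, a sample is active with probability
  π₀_sample (default 0.5; no value is established for this layer) and
  active samples follow their own urn with α_sample.

The sampling model is conjugate Normal–Inverse-Gamma: for protein g in
bicluster k, the values of the samples in subcluster j are i.i.d.
Normal with NIG(m₀, k₀, a₀, b₀) on their mean and variance, integrated
in closed form. Invariant proteins and inactive samples follow a fixed
Normal(0, 1) baseline. Defaults m₀=0, k₀=0.1, a₀=1, b₀=1 are diffuse
and configurable. Rows (log peak areas) are standardized to mean 0,
SD 1 before sampling, so clustering is by response pattern rather than
mean abundance, and the N(0, 1) baseline is exactly calibrated to an
unstructured standardized row. Missing cells are skipped in all block
products (ignorable missingness; at most 2 per protein after
filtering).

Because each protein keeps its own mean and variance per subcluster, a
bicluster is identified by its local sample partition alone. Two
consequences matter for interpretation: (i) protein sets with identical
partitions are merged by the DP prior; (ii) a partition that refines
another can absorb the coarser set's proteins at a per-block overhead
cost, so nested planted patterns are only weakly identified (see
"Synthetic data" below).

## NoB-LoC: inference

Inference is collapsed Gibbs sampling. One iteration is a pass of
sample-level urn updates over every bicluster followed by a pass of
protein-level urn updates. The protein move proposes a *new* bicluster
via one auxiliary component whose sample partition is drawn from its
prior (Neal 2000, Algorithm 8 with m = 1), which keeps the chain exact
for the joint posterior; correctness is verified against brute-force
enumeration of the full zero-enriched posterior on small instances
(co-clustering probabilities agree within Monte-Carlo error).

The sample pass runs first because freshly initialized biclusters carry
a single all-sample subcluster whose likelihood is weaker than the
baseline; judging protein memberships before the local partitions adapt
empties the state. Initialization follows the study: agglomerative
clustering of proteins (Euclidean, average linkage) cut into
`n_init_sets` groups with singletons designated invariant. By default
`n_init_sets = max(20, G/5)`: over-splitting at initialization is the
safe bias, since same-partition sets merge readily during sampling
whereas one-at-a-time Gibbs cannot cheaply nucleate a split inside a
large bicluster (split-merge moves are out of scope by design). For
the same reason each initial bicluster's sample partition starts from a
likelihood-scored cut of a sample-side hierarchical clustering rather
than from a single subcluster; all of this affects only the starting
point, not the stationary distribution.

The point estimate ω^LS is Dahl's least-squares partition restricted to
visited states under the pairwise co-clustering L1 distance
H(ω, ω′) = Σ_{g<g′} |I(ω_g=ω_{g′}) − I(ω′_g=ω′_{g′})| (the indicator is
literal, so two invariant proteins count as co-clustered). Ties take
the earliest minimizer. Posterior uncertainty is summarized by
H(ω_t, ω^LS) scaled by G(G−1)/2, making the "low variability around
zero" diagnostic comparable across matrix sizes. Summary statistics
are invariant to thinning within Monte-Carlo error; full-scale runs may
thin to bound memory.

## Variance partitioning

Scalar responses use a two-way ANOVA with interaction (statsmodels OLS,
sequential SS; the balanced design makes the decomposition orthogonal).
Reported fractions split total SS three ways — nutrient, temperature,
and "other" = interaction + residual — matching the study's three-way
display. The multivariate proteome uses a two-way sequential PERMANOVA
built on the Gower-centered distance matrix via the McArdle–Anderson
trace identities, nutrient entered first (immaterial when balanced),
with p-values from free permutation of sample rows under a fixed seed;
a restricted scheme is not needed for the balanced reference design.
On Euclidean distances of a single centered variable the PERMANOVA
fractions equal the ANOVA fractions to 1e−9, and the implementation is
cross-checked against R `vegan::adonis2` in the test suite. Pairwise
group comparisons use Welch t-tests (the study names only the
Benjamini–Hochberg correction, not the base test) with BH step-up
adjustment.

## Synthetic data

The generator emulates the 30-sample design. Log peak areas are
Normal: cells of protein g in bicluster k, sample s in subcluster j are
drawn N(block mean_{k,j}, noise_sd²); invariant proteins and inactive
samples are N(baseline_mean = 14, baseline_sd = 1) — log-normal peak
areas spanning decades, matching the positive, wide-ranging scale of
DIA-MS data. Planted sample partitions follow the design factors
(regime split; temperature split; 20 °C vs rest; regime × temperature),
are pairwise distinct, and block means are spread by `separation` (log
units; baseline_sd = 1, so separation 2.0 is a 2-SD pattern). Missing
values are injected uniformly at random (default rate 0) to exercise
the missingness filter. Elemental tables draw quotas around additive
factor effects (noise is a CV, default 5%, typical of replicate
chemostats) and convert them to concentrations with a configurable cell
density, so quota computation inverts the generation exactly. Default
effects encode the study's qualitative structure: the P quota ~3-fold
higher under N- than P-stress, slightly carbon-denser cells under
N-stress, cells smallest at 24 °C and largest at 28 °C. Effect sizes
on FSC_H are not established quantitatively anywhere and are plain
configurable defaults.

The planted-recovery benchmark runs G=60, S=30, K=3 (15 proteins per
bicluster, 15 invariant) at separation 2.0 and noise_sd 0.5, ten seeds,
with a neutral π₀ = 0.5 (appropriate when structure prevalence is not
known to be rare) and 150 iterations / 60 burn-in; mean adjusted Rand
index vs truth exceeds 0.9, and mean ARI degrades monotonically along
the noise grid (0.5, 1.0, 2.0). Two caveats established during
development, recorded here deliberately:

* at separation/noise = 2 with row standardization, the *posterior
  itself* — not the sampler — dissolves planted structure: a chain
  started at the truth drifts to ~half the planted assignments across a
  range of π₀ and base measures, because the per-block NIG overhead
  cancels the modest per-protein likelihood gain. Recovery claims are
  therefore made at separation/noise = 4; the noise grid documents the
  degradation;
* occasional seeds settle in a local mode where two planted biclusters
  with nested partitions merge under their common refinement; the
  aggregate (mean-ARI) criterion absorbs this known mixing limitation;
* on matrices with many unstructured proteins (e.g. the G=200 pipeline
  demonstration with 140 invariant rows), a weak variant prior
  (π₀ ≳ 0.1) lets a spurious bicluster absorb noise rows through a
  co-adapted sample partition — the Dirichlet-process analogue of
  overfitting. The sparse default π₀ = 0.01 suppresses this mode,
  which is one reason the reference analysis uses it; the G=60
  benchmark uses the neutral π₀ = 0.5 safely because only 15
  unstructured rows exist there.

What passing synthetic tests do **not** show about real data: the
generator draws independent Gaussian cells with exactly log-normal
abundances, no peptide-level structure, no correlated instrument drift,
no intensity-dependent missingness, and trait groups aligned perfectly
with planted biclusters. Reproduction of the deposited study numbers
is a separate, stronger check that requires the archived supplementary
tables (see README).

## Problem sizes and runtimes

Scales were chosen as the package's own test surface: enumeration
oracles at G ≤ 4, S ≤ 4 (the exact posterior sums ~15 × 15 partition
combinations); sampler-vs-oracle agreement at 20 000 sweeps; recovery
at G=60 with 150-sweep chains; the end-to-end pipeline demonstration at
G=200 with 400-sweep chains. The full study scale (G=1146, 35 000
iterations, 5 000 burn-in, π₀=0.01, 20 initial variant sets) is reached
with the same `run_mcmc` call and the `paper_defaults` configuration
preset; it is not part of the routine test surface.

## Known limitations

* No split-merge or sequentially-allocated sampler; mixing across
  partition modes relies on initialization (documented above).
* PERMANOVA offers free permutations only; no PERMDISP-style dispersion
  diagnostics.
* Normalization reproduces the *form* of cross-sample equalization, not
  the vendor's exact algorithm; exact reproduction of deposited
  normalized values may require consuming the deposited table directly.
* The PA_Total denominator defaults to the retained set; the deposited
  analysis is ambiguous between the identification and retained sets,
  so both are exposed.
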