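# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical choices behind `linesense`, in the order the pipeline
runs them.

## Phenotype model and line means

Individual records follow a factorial design over inbred lines, two (or
more) ages, two (or more) treatments, with blocks nested within age and
body mass as a nuisance covariate.  The full ANCOVA is

    value = c + m·mass + line * treatment * age + block(age) + ε

fitted by ordinary least squares with **sum-to-zero factor coding**, so
that on a balanced design every term is orthogonal and partial
(Type III-style) and sequential tests coincide.  Partial F tests come from
full-vs-reduced model comparison on precomputed normal equations: for each
term the residual SS of the model without that term's columns minus the
full model's residual SS, divided by the term's rank deficit, over the
full-model MSE.  Mass-by-factor interactions are not modelled (the design
treats mass as a pure covariate).  An empty line × age × treatment cell is
a hard error naming the cell, since the three-way interaction is then
unidentifiable.

**Least-squares line means** are computed per (age, treatment) stratum
from `value = c + β·mass + line + block + ε` with one common slope; each
line is evaluated at the stratum grand-mean mass with block effects
weighted equally (deviation-coded blocks, so the prediction simply drops
the block columns).  Consequences asserted by the tests: LS-means are
invariant to translating all masses and to relabeling blocks, reduce to
raw means when mass is constant *and* blocks are balanced, and standard
errors come from the OLS covariance of the corresponding prediction
vector.  A constant mass drops the slope; a line absent from the stratum
is omitted with a warning.

## Variance components and genetic correlations

Among-line variance per stratum uses the one-way ANOVA method of moments
on mass-adjusted values:

    σ²_e = MS_within
    σ²_L = (MS_between − MS_within) / n₀,   n₀ = (N − Σ nᵢ²/N)/(k − 1)

The mass slope is estimated jointly with line effects (so adjusting for
mass does not absorb genetic signal), then subtracted before the one-way
decomposition.  Negative moment estimates are truncated at zero but the
raw value is kept alongside; all-singleton strata are an error because
σ²_e is then inestimable.

The genetic correlation between two strata is

    r_G = cov₁₂ / (σ_L1 · σ_L2)

with cov₁₂ the (n−1)-denominator sample covariance of paired line means
over shared lines and the σ's square roots of the truncated components.
This estimator is **not** a bounded correlation: sampling noise can push
|r̂| past 1, and it is reported as-is.  When either truncated component is
zero the correlation is flagged undefined rather than silently set to 0 or
∞.  Labels follow the two-age/two-treatment convention of an
assayed-at-weeks-1-and-5 design: `rGT1`, `rGT5` (across treatments within
age), `rGAC`, `rGAL` (across ages within treatment).

## Sensitivity index

For line *i* at one age, with treated and control line means m̂ᵢᵀ and
m̂ᵢᶜ:

    dᵢ = m̂ᵢᵀ − m̂ᵢᶜ,   D̄ = mean over complete lines of dⱼ,   Sᵢ = dᵢ / D̄

Lines missing either treatment mean are excluded from both the numerators
and the denominator average, which preserves the exact identity
mean(S) = 1 over included lines.  S is dimensionless and invariant to
positive scaling and translation of the phenotype.  |D̄| at or below a
tolerance (default 10⁻¹²) raises an explicit "undefined panel response"
error — no silent infinities.  By default the index is computed on
mass-adjusted LS-means, keeping it commensurable with the GWA phenotypes;
a raw-means switch (`sensitivity_on: raw`) is provided because the choice
between raw and adjusted averages is a genuine design fork.

## Single-marker scans

Inbred lines are coded 0/1 per site (two homozygous classes; heterozygous
or missing calls become missing).  The trait model `y = u + m·x + ε` on
line means reduces to the two-class comparison: m̂ is the difference of
class means, its t statistic has n−2 df, p-values are two-sided.  The
sensitivity model adds the trait line mean z as cofactor and reports the
partial genotype test with n−3 df; a variant whose classes differ in z is
thereby discounted for its trait effect.  Both are computed in closed form
(Frisch–Waugh residualization for the cofactor model) across the whole
genotype matrix at once, with complete cases per marker; the test suite
pins them to brute-force OLS at 10⁻¹⁰.

Skip rules, never p-values: monomorphic variants, minor-class count below
the floor (default 4 lines, mirroring common inbred-panel practice), or a
cofactor that exactly determines the genotype column.  Degenerate
perfect-fit cases give statistic 0 / p = 1 when the effect is zero and a
p clipped to the smallest positive float when it is not, so p ∈ (0, 1]
always holds for tested variants.

Candidates use strict inequality p < threshold (default 10⁻⁵; the network
stage re-filters at 10⁻⁶).  A candidate variant maps to every gene whose
body contains it or whose nearer boundary is strictly less than 5000 bp
away; the boundary case (gap exactly 5000) does not map.

## Subnetworks and permutation test

Given a global undirected interaction graph, the subnetwork of a candidate
set is: mapped candidates, plus every non-candidate adjacent to **two or
more** mapped candidates (the "one missing gene in between" rule), with
candidate–candidate and candidate–bridge edges only.  Bridge–bridge edges
are excluded — a path through two consecutive non-candidates would exceed
the one-missing-gene allowance — and a node bridging a single candidate
adds no connectivity, hence the ≥2 qualification.  Isolated candidates
remain as singleton components.  The statistic is the node count of the
largest component (candidates + recruited bridges together).

The permutation null redraws n genes (n = mapped candidates) uniformly
without replacement from the mappable universe, rebuilds the subnetworks
and records the largest size, N_perm = 1000 times; ties count toward A and
`p = (A + 1)/(N_perm + 1)`, so p is bounded below by 1/(N_perm+1) and the
test is exact-valid.  No degree matching is applied — the null is plain
uniform sampling.  The permutation loop uses a dense boolean-adjacency
fast path proven equal to the networkx construction on random graphs in
the test suite, and is checked against exhaustive enumeration on graphs
small enough to enumerate.

Hubs are nodes with more than ten connections, counted within the
subnetwork by default; a `scope="global"` switch counts degree in the
global graph instead, since either reading of "connections in the network"
is defensible.

## Synthetic-data generator

The generator emulates the study design end to end: 126 lines × 2 ages ×
2 treatments × 30 flies by default, blocks nested within age and balanced
across lines, body mass drawn per fly (0.8 ± 0.08 mg, the scale of a male
fly) with an optional line-level mass heritability knob, and trait units
calibrated to a climbing-speed-like assay (baseline 1.54, old-age effect
−0.77, treatment effect +0.10).

Line effects are sums of independent normal components — line, line×age,
line×treatment, line×age×treatment — drawn per level combination.  The
default components (0.010, 0.025, 0.011, 0.094) deliberately put most
genetic variance in the three-way term, so the background line-effect
correlation is ≈0.25 across treatments and ≈0.15 across ages: allelic
effects are mostly condition-specific, the regime the analysis is designed
to detect.  Planted causal loci then modify this background: trait
variants add an allelic effect to the shared line term; **sensitivity
variants add their effect to the treated-level line×treatment term only**,
so they shift a genotype's response without moving its control mean —
making sensitivity signal orthogonal to control-trait signal by
construction.  Because planted trait loci are shared across conditions,
realized genetic correlations in a default run sit above the background
values; the ground-truth object reports both the component-implied and the
realized correlations.

Genotypes are 0/1 per line at allele frequencies uniform on the
configured range (default 0.05–0.5), independent across sites — no linkage
disequilibrium, by design.  Variants and genes share one coordinate
system: genes are tiled along five chromosome arms in 5 kb slots with
randomized starts and lengths (1–2.5 kb), leaving intergenic gaps so the
annotation window rule is genuinely exercised.

The interaction network is a preferential-attachment (Barabási–Albert)
backbone over the genes (default 2000 genes, attachment 2).  The planted
module is a uniformly chosen gene set made internally dense — a random
spanning tree plus extra internal edges, average internal degree ≈4 —
mimicking a functional pathway whose members interact far more among
themselves than typical genes do.  A `plant_module_edges=False` switch
selects a connected subgraph of the untouched backbone instead (useful for
testing pure backbone properties, e.g. attachment 1 yields a tree).  The
2000-gene default matters: candidate lists are then a realistic small
fraction of the graph, whereas in a few-hundred-gene graph random
candidate sets recruit hub bridges so often that the permutation null
swamps planted signal.  Causal sensitivity variants are placed inside
planted-module gene bodies with probability 0.9 (else anywhere), so the
module is recoverable from the GWA output.

What the generator does **not** emulate — and hence what green tests do
not certify about real data: linkage disequilibrium and local correlation
of test statistics, population structure or cryptic relatedness,
non-normal trait distributions, shared-environment covariance beyond the
block term, genotype-dependent mass, and the composition of real
interaction databases (curation bias, hub artifacts).  The analysis side
deliberately omits relatedness/structure corrections and genomic-control
adjustment, which the underlying web-tool-based study design also did not
apply at this stage.

## Numerical choices and seeds

- All fits run through OLS on normal equations or statsmodels OLS; rank
  deficiencies are resolved by minimum-norm least squares, with empty-cell
  pre-checks providing the interpretable errors.
- The covariance in r_G uses the n−1 denominator; this is stated so
  oracles can match bit-for-bit.
- A master seed derives per-stage seeds by hashing the stage name into a
  `SeedSequence`, giving stage-level reproducibility without seed
  collisions; every simulated artifact is byte-identical under a fixed
  seed.
- Replicate counts in the calibration experiments (100 panels for
  variance recovery, 200 for correlation recovery and planted-variant
  power, 50 for module recovery, 2×10⁶ null tests) keep each summary's
  Monte-Carlo error several-fold inside the tolerance being asserted.

## Known limitations

- Method-of-moments components, not REML; no standard errors or
  confidence intervals on heritabilities or genetic correlations.
- The cofactor sensitivity scan is a covariate-adjusted regression; the
  original web tool's two-phenotype option is not publicly specified, so
  this is the functional reading of "significant after accounting for the
  SNP's effect on the trait value".
- Per-line sensitivity values carry no standard errors.
- The pipeline analyzes one trait per run; multi-trait designs mean
  multiple runs.
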