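# Methods

`phenoscreen` implements the statistics of a pooled-knockdown,
high-content neuronal morphology screen and its downstream proteomics
pathway analysis, together with seeded synthetic-data generators that
reproduce the statistical structure those methods assume. This note
documents the models, the defaults and why they were chosen, and what the
synthetic studies do and do not demonstrate.

## Screen model and normalization

A screen measures 10 image-derived parameters per well: nuclei and neuron
counts, three dendritic measures (primary neurites, branch points, total
dendrite length per neuron), and five synaptic measures (pre-/postsynaptic
puncta densities and staining intensities, colocalized puncta density).
Wells sit on 96-well plates restricted to the inner 60 positions; each
plate carries ≥3 scrambled-control wells, 3 positive-control wells and 3
untreated wells, the rest being experimental shRNAs in randomized
positions. Knockdowns cover 41 genes × 4–5 shRNAs × 3 culture replicates,
fixed at DIV 7, 14 or 21 (one plate = one batch/DIV/replicate cell, so
plate is nested in batch).

Raw well values are normalized per plate as
`log2(value / median of the plate's scrambled wells)`, per parameter.
The scrambled **median** (not mean) is the reference; zero or negative raw
values become missing rather than −∞ and rows are kept, with downstream
statistics using pairwise-complete data. Normalization cancels any
multiplicative per-plate effect exactly (a tested invariant).

Outlier plates are flagged by a parameterized version of a qualitative
rule: a plate is removed when more than `excess_fraction` (default 0.5) of
its wells fall below the global `low_count_quantile` (default 0.1) of
total cell counts. The defaults are this package's own construction; both
knobs are part of the pipeline config so a run is reproducible.

## Variance decomposition

Each normalized parameter is modelled with random intercepts for batch,
plate (nested in batch via globally unique plate ids), a per-plate offset
shared by the border wells of the inner block (the "edge" component), DIV
and shRNA treatment, plus residual well noise. All five named sources are
random effects so their variance fractions are directly comparable; DIV
can be moved to the fixed part with `div_random=False`. Estimation is REML
via `statsmodels.MixedLM` (one pseudo-group, variance-component design
matrices). The quasi-Newton optimizer can stall on a local optimum of the
profiled REML surface when a true component is at the zero boundary, so
every fit is polished with a derivative-free Powell pass and the solution
with the better restricted likelihood is kept.

A variance estimated from L factor levels carries relative sampling error
of roughly √(2/L) no matter how many wells sit under each level — with 3
batches a single-screen batch-variance estimate is ±80%. The recovery
study therefore uses a purpose-built layout with many levels per factor
(12 batches × 8 time points, 48 shRNAs, ~3100 wells) and assesses recovery
on the **across-seed mean** of the estimated fractions (20 seeds), which
lands within ~8–9% relative error of the planted shares. Single fits on the
default screen layout are unbiased but individually noisy; the pipeline
report should be read accordingly.

## Gene-level permutation testing

Per DIV and parameter, the wells of all shRNAs of a gene are pooled and
compared with the scrambled wells by a two-sided Mann–Whitney U test
(exact enumeration for combined n ≤ 12 in the standalone function; the
screen always has combined n > 12, where the continuity-corrected normal
approximation applies). An alternative aggregation
(`aggregate="per-shrna-mean"`) tests the 4–5 per-shRNA mean effects
instead; pooling is the default.

The null distribution is built by randomly relabelling wells within each
plate. One relabelling per permutation is shared by **all** genes and
parameters of a DIV stratum, which is what preserves the correlation
between tests that the min-P correction exploits. Two details matter:

- **Renormalization inside the shuffle.** The per-plate scrambled median
  is part of the analysis, so it is recomputed under every permuted
  labelling. Without this the observed labelling is special — its
  scrambled wells sit at median 0 by construction while a permuted
  labelling's do not — and the observed test statistic is over-dispersed
  relative to the permutation null. On fully null screens that
  inflates the min-P family-wise error rate to ~19%; with renormalization
  the measured rate is ~3.5% at a nominal 5%.
- **Tie-breaking.** Median subtraction creates exact zeros (the anchor
  well of each plate). A fixed per-well perturbation of order 1e−9 breaks
  these ties identically across observed and permuted labellings, keeping
  the statistic a valid permutation statistic while avoiding midrank
  bookkeeping in the vectorized engine. Observed p-values consequently
  agree with the classical tie-corrected test to within ~1%.

Empirical p-values use the add-one formula `(#{null ≤ observed}+1)/(B+1)`
and can never be 0. Family-wise correction is single-step Westfall–Young:
the distribution of the per-permutation **minimum** p across all gene
tests of a stratum (41 genes per parameter × DIV by default;
`minp_scope="global"` pools the full grid) gives each gene's corrected p.
Single-step min-P dominates the per-test empirical p by construction, a
tested invariant. The default B is 10,000; calibration studies use B=500.

## Phenotype clustering

Per-shRNA effect profiles are means of normalized values over the four
representative parameters (neuron count, dendrite length/neuron, pre- and
postsynaptic puncta density), either DIV-averaged (default, 4 features)
or concatenated per DIV (12 features). shRNAs whose per-DIV effects stay
within 2× the scrambled-control SD for **all** four parameters at **all**
three time points form the no-effect cluster "0"; the gate is
scale-consistent (doubling effects and SDs changes nothing). The retained
shRNAs are clustered by average-linkage (UPGMA) hierarchical clustering
on `1 − Pearson correlation` between profiles, the tree is cut at k=5,
and clusters are labelled I–V by descending severity (mean signed
effect). Constant profiles, whose correlation is undefined, are attached
to the Euclidean-nearest centroid afterwards with a warning. Genes with
≥3 shRNAs sharing a non-zero cluster are selected, with that cluster as
their consensus phenotype.

Co-clustering significance offers two constructions. The validated
default is a permutation test: shuffle the shRNA→cluster assignment
(preserving cluster sizes and each gene's shRNA count) and compare the
selected-gene count; because that count is coarsely discrete the p-value
is conservative (super-uniform), which the tests check explicitly. The
chi-square variant compares the observed selected-gene count to its exact
expectation under multinomial assignment with cluster-size probabilities
(1-df goodness of fit); it is provided because a chi-square construction
is conventional, but the contingency table behind it is this package's
own choice.

### Geometry of the planted archetypes

Pearson distance on 4 centred features lives in a 3-dimensional shape
space; it is impossible to plant five mutually well-separated "reduction"
phenotypes there, and a profile that lowers *all* parameters equally has
no shape at all (its centred vector is ~0, indistinguishable from noise).
The generator therefore plants four parameter-class-specific reductions —
late neuron loss (I), dendrite-led loss sparing neurons (II),
presynaptic-led (III) and postsynaptic-led (IV) synapse loss, each with
mild equal off-target weights so their centred profiles form a regular
tetrahedron (pairwise r = −1/3, the most separable configuration this
distance admits) — plus a weak, near-uniform broad reduction (V) that
passes the gate but, lacking shape, co-clusters with the null shRNAs that
leak past it. That mixed weak/no-shape cluster is a real feature of this
analysis design, not an artifact: any "overall reduction" phenotype ends
up there under pure correlation distance. At shRNA efficacy ≥0.8 the
pipeline recovers ~93% of planted multi-shRNA genes with the correct
consensus cluster (20 seeds).

## Proteomics filter chain

Protein-level DIA quantification tables (protein × sample intensities,
per-identification q-values, per-sample median q) pass through a fixed
filter order:

1. **q threshold** — cutoff = arithmetic mean of per-sample median
   q-values; identifications above it become undetected.
2. **Detection filter** — keep proteins detected in ≥(r−1) replicates of
   at least one group *and* in ≥1 sample of some other group. The
   original phrasing of the between-group rule admits several readings;
   "not private to a single group" is the one implemented, and it is a
   function argument, not an assumption baked in.
3. **Outlier replicates** — in groups whose replicate median-q CV exceeds
   0.12, drop replicates whose median q is >10× the median of the
   remaining replicates' (CV "of the sample" is read as CV of median
   q-values; with 3 replicates two large outliers shield each other, so
   the guard against leaving <2 replicates is defensive).
4. **Contaminants** — case-insensitive pattern removal (immunoglobulin,
   keratin, trypsin by default).
5. **Per-shRNA differential** — Welch t-test on log2 intensities against
   the scrambled group, on quantified samples only (no imputation); a
   1e−12 variance floor stabilises degenerate zero-variance comparisons.
6. **Concordance filter** — a protein is regulated for a gene iff p<0.05
   in ≥1 shRNA and its fold-change sign is identical in every shRNA in
   which it was quantified (zero counts as discordant; proteins testable
   in <2 shRNAs are excluded).

Because every shRNA contrast shares the scrambled replicates, null
fold-change estimates are positively correlated (ρ≈0.5), which raises the
chance concordance rate well above 2^(1−k): the null pass rate of the
full rule is ~7% for 4 shRNAs at α=0.05, a number the tests verify
against an independent Monte Carlo oracle of the same probability model.
This is an operating characteristic of the published rule itself, worth
knowing when reading regulated-set sizes.

The worked-example generator plants regulated sets of 94, 61 and 67
proteins (one shared by all three experiments, pairwise overlaps 2–4)
in noise-free tables: unregulated proteins then have exactly zero fold
change, which the concordance rule discards, so the filter chain's output
counts are determined by its logic alone — contaminant rows, a planted
outlier replicate and a small dubious-q tail keep every stage active.
That fixture audits the rules; the noisy operating characteristics above
are measured separately.

## Enrichment

Interaction networks are weighted undirected edge lists
(`combined_score` in [0,1]); analysis uses edges at or above the
high-confidence cutoff 0.7. First-shell expansion adds up to 10 non-query
nodes ranked by number of edges into the query, then summed edge score,
then lexicographic id. Interaction enrichment counts query-internal edges
and compares against node sets drawn from degree-decile bins of the
background (an explicit, documented replacement for web-service analytic
p-values, which are not reproducible offline); the p-value is add-one.
On random queries these p-values are approximately uniform once the
edge-count statistic has enough resolution; a planted clique on a sparse
background sits at the permutation floor. Annotation enrichment is the
upper-tail hypergeometric test per term within a user-supplied
background, restricted to molecular-function sets by prefix, with
Benjamini–Hochberg adjustment (a deliberate, simpler stand-in for
bespoke web-service corrections).

The qPCR utility implements 2^−ΔΔCp with ΔCp = target − mean(reference
Cps) and ΔΔCp = mean ΔCp(knockdown) − mean ΔCp(control).

## Synthetic data: what it does and does not show

The generators are seeded and fully deterministic. The screen generator
plants additive Gaussian components on the log2 scale (batch, plate
within batch, a per-plate random offset shared by edge wells, DIV, an
optional per-shRNA offset and block-correlated residual noise; synaptic
staining intensities anti-correlate with puncta densities, ρ≈−0.4), a
deterministic maturation trend for dendritic/synaptic parameters, and
gene effects scaled by per-shRNA efficacy drawn from [0.5,1] with a
configurable dud fraction emulating ineffective or off-target constructs.
Default noise magnitudes (residual SD 0.15 log2 units) make the 2×SD gate
meaningful: planted-null shRNA profiles mostly fall under it, with a
realistic ~10–15% leak driven by the per-plate median-estimation noise
that three scrambled wells imply.

Passing studies demonstrate that the implementations are correct and
calibrated **under this model**: Gaussian noise, exchangeable wells
within plates, protein-level independence. They do not show robustness to
image-segmentation artifacts, spatial gradients beyond a shared edge
offset, heavy-tailed or correlated proteomics noise, or peptide-level
effects — none of which the generators emulate.

## Problem sizes of the shipped studies

Family-wise calibration: 200 null screens, 41 genes, B=500, single
replicate per screen (the test is per-DIV-stratum, so calibration does
not depend on replicate count). Variance recovery: 20 seeds × ~3100
wells. Clustering recovery: 20 default-size screens. Concordance study:
500 simulated tables per arm at 3 replicates, with a 20,000-draw oracle.
These sizes were chosen so the whole validation battery runs in minutes
on a single core while leaving each check's Monte Carlo error well below
the margins it asserts.
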