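# phenoscreen

Statistics for pooled-knockdown, high-content neuronal morphology screens
and their downstream proteomics pathway analysis.

The scientific setting: dozens of candidate disease genes are knocked down
in primary neuronal cultures with 4–5 independent shRNAs each, and every
well is summarised into 10 image-derived morphology parameters (cell
counts, dendritic arborisation, synaptic puncta densities and staining
intensities) at three culture ages (DIV 7/14/21). The question is which
genes produce *consistent* phenotypes — robust to ineffective and
off-target shRNA constructs — and whether genes sharing a phenotype also
converge on shared molecular pathways in knockdown proteomics.

`phenoscreen` implements the full analysis chain:

- **Plate QC and normalization** — outlier-plate detection,
  per-plate log2 normalization against the scrambled-control median,
  parameter rank-correlation structure, and the qPCR 2^−ΔΔCp utility.
- **Variance decomposition** — random-intercept models quantifying the
  share of each parameter's variance due to batch, plate-within-batch,
  edge position, DIV and shRNA treatment.
- **Gene-level permutation testing** — per parameter and DIV, pooled
  shRNA wells vs scrambled controls by Mann–Whitney U, with a
  within-plate permutation null (renormalized under every relabelling),
  add-one empirical p-values
  `p = (#{null ≤ observed} + 1)/(B + 1)`,
  and single-step Westfall–Young min-P family-wise correction: each
  observed p is compared with the permutation distribution of
  `min_g p_g` across all gene tests, preserving the correlation between
  tests.
- **Phenotype clustering** — per-shRNA effect profiles over four
  representative parameters, a no-effect gate at 2× the scrambled SD
  (all parameters, all time points), average-linkage clustering on
  `1 − Pearson r`, selection of genes with ≥3 co-clustered shRNAs, and
  permutation / χ² co-clustering tests.
- **Proteomics concordance filtering** — q-value thresholding at the mean
  per-sample median q, detection and outlier-replicate filters,
  contaminant removal, per-shRNA Welch t-tests vs scrambled, and the
  concordance rule: a protein is regulated for a gene iff it changes
  significantly in ≥1 shRNA and in the *same direction* in every shRNA
  in which it is quantified.
- **Offline enrichment** — first-shell expansion (≤10 best-connected
  interactors), interaction enrichment against a degree-matched sampling
  null, and hypergeometric annotation enrichment with BH adjustment, all
  on local edge-list/GMT files.
- **Synthetic generators** — seeded well-level screens (planted phenotype
  archetypes, variance components, block-correlated parameters),
  proteomics tables (planted sign-concordant regulated sets, contaminants,
  outlier replicates), and networks/annotations with planted modules, so
  every stage is testable without downloads.

See `docs/methods.md` for models, defaults and known limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with planted ground truth:

```bash
python analysis/01_simulate_screen.py --seed 0
python analysis/02_normalize_and_qc.py
python analysis/03_variance_components.py
python analysis/04_gene_tests.py --seed 0
python analysis/05_phenotype_clusters.py --seed 0
python analysis/06_proteomics_filters.py --seed 0
python analysis/07_network_enrichment.py --seed 0
```

Step 1 simulates 1989 wells on 36 plates with 16 planted effect genes
spanning five phenotype archetypes. Step 2 flags one outlier plate,
normalizes, and confirms the planted anti-correlation between synaptic
staining intensities and puncta densities:

```
removed outlier plates: ['P006']
normalized 1929 wells
synaptic intensity vs density correlations: presynaptic -0.35, postsynaptic -0.44
```

Step 4 (B = 2000 permutations) finds exactly the planted multi-shRNA
effect genes significant after min-P correction:

```
genes significant (corrected p < 0.05) in >= 1 stratum: 15
```

Step 5 gates 110 of 186 shRNAs into the no-effect cluster and recovers
the planted phenotype classes, 13 genes having ≥3 co-clustered shRNAs
(permutation p = 0.0005 — labels I–V are ordered by severity, so planted
classes map onto them up to relabelling):

```
cluster sizes: {'0': 110, 'I': 7, 'II': 21, 'III': 24, 'IV': 23, 'V': 1}
genes with >= 3 co-clustered shRNAs: 13
  ...
  Tbr1: cluster III
  Tcf4: cluster III
  Top3b: cluster III
```

Step 6 runs the full filter chain on three knockdown proteomics
experiments with planted regulated sets and recovers them exactly —
including removal of a planted outlier replicate — with one protein
regulated in all three knockdowns:

```
Tcf4: 94 regulated proteins of 2382 quantified (q cutoff 0.0001)
Tbr1: 61 regulated proteins of 2281 quantified (outlier replicates removed: ['Tbr1_sh2_r3'])
Top3b: 67 regulated proteins of 2498 quantified (q cutoff 0.0001)
Tbr1&Tcf4&Top3b  1
```

Step 7 detects the planted pathway module by interaction enrichment
(p = 0.0002 against the degree-matched null) and by annotation
enrichment (hypergeometric p = 1.3e−13).

The same workflow is available as a library (`phenoscreen.pipeline.run_pipeline`)
and a CLI (`phenoscreen run --config config.yaml`, plus per-stage
subcommands `simulate`, `normalize`, `variance`, `genetest`, `cluster`,
`proteomics`, `ppi`, `go`).

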