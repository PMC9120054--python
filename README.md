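# connstat

Structural connectome nodal-centrality statistics for case–control cohorts.

Given per-subject weighted structural connectivity matrices (tractography
streamline counts over a parcellation), `connstat` runs the full analysis
chain:

1. **Proportional sparsity thresholding** — retain the top-S fraction of
   connections per subject across a grid of sparsities (default
   0.10–0.30 in steps of 0.01), weights preserved.
2. **Weighted nodal centrality** — node strength, betweenness centrality
   (shortest paths on lengths 1/w, fractional credit for ties), and the
   geometric-mean weighted clustering coefficient.
3. **AUC summarization** — trapezoidal area under each metric-vs-sparsity
   curve, giving one threshold-independent feature per region, metric and
   subject.
4. **Group inference** — ANCOVA-style contrasts (group indicator +
   covariates: age, sex, per-region volume, optionally medication history),
   label-shuffling permutation p-values, and Benjamini–Hochberg FDR within
   each metric's family of regions. Exploratory per-edge t-tests and plain
   volume t-tests are included.
5. **Symptom associations** — partial Spearman correlations (rank, then
   residualize on covariates, then correlate) between limbic-subregion
   features and symptom scores within the patient group, with separate
   8-test (hippocampus) and 12-test (amygdala) FDR families.
6. **Demographics** — summary-statistic pooled t-tests, 2×2 chi-square and
   frequency percentages for a Table-1-style cohort description.

The default parcellation fixture has 98 regions: 68 Desikan–Killiany
cortical parcels, 10 bilateral subcortical structures, 8 hippocampal
subregion groups (CA1, CA3/4, subicular complex, GC-DG per hemisphere) and
12 amygdala nuclei (LA, BA, ABA, CoA, CeA, CAT per hemisphere).

A seeded synthetic-cohort generator (`connstat.simulate`) produces
realistic log-normal connectomes with hemispheric modular structure,
subject noise, planted group deficits, planted symptom associations and
covariates — with a ground-truth sidecar — so every inference stage can be
validated end to end.

## CLI

```sh
# simulate a cohort with a 25% strength deficit planted at region 50
connstat simulate --seed 1 --strength-deficit 0.25 --deficit-node 50 --out cohort/

# full pipeline: metrics -> AUC -> group comparison -> volumes -> associations
connstat run cohort/ --n-perm 1000 --seed 1 --covariates age,sex,volume --out results/

# individual stages
connstat metrics cohort/ --grid 0.10:0.30:0.01 --out features.csv
connstat compare cohort/ --features features.csv --out group.csv
connstat associate cohort/ --features features.csv --score MADRS --out assoc.csv

# human-readable markdown report from a results bundle
connstat report results/ --out report.md
```

Cohort layout: one square numeric TSV per subject (region order defined by
`regions.csv`), a `metadata.csv` with subject group/covariates/scores, and
a region table CSV. All configuration can also be supplied as YAML via
`--config` (flags override the file).

### Notes on the FDR input

Group-comparison FDR can be fed either the add-one permutation p
(default, `p_source="perm"`) or the parametric ANCOVA p
(`p_source="parametric"`). The add-one permutation p is floored at
1/(n_perm+1), so with many regions and moderate n_perm the step-up
procedure cannot certify a lone strong discovery from the permutation
source; the parametric source resolves this. Both p-values are always
reported.

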