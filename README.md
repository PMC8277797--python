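# phenospace

Single-cell phenotyping and spatial statistics for tumor-microenvironment
profiling. The package reimplements, as a tested and reusable library, an
analysis workflow for lung-adenocarcinoma cohorts measured by mass
cytometry (CyTOF) and multiplex immunofluorescence (mIF):

1. **Event QC** — dead-cell removal (nuclear Histone H3 raw signal < 10)
   and singlet gating (event length in [10, 70]), then the
   variance-stabilizing transform `asinh(x / 5)`.
2. **Two-round phenotyping** — pooled k-means (k = 10) on six lineage
   markers with rule-based annotation (epithelial cancer cells
   EpCAM⁺/CK⁺/CK7⁺; endothelial CD45⁻/CD31⁺; mesenchymal
   vimentin⁺/CD45⁻/CD31⁻/EpCAM⁻/CK⁻/CK7⁻; immune CD45⁺), then a second
   k-means round on the immune subset (CD8, CD24, CD3, CD11b, CD56,
   HLA-DR) resolving helper T (CD3⁺/CD4⁺), cytotoxic T (CD3⁺/CD8⁺),
   myeloid (CD3⁻/CD11b⁺) and other immune cells. The number of clusters
   can also be chosen automatically by the elbow criterion on the
   within-cluster sum of squares.
3. **Cancer-cell subclustering** — k-means (k = 10) of the epithelial
   cancer cells (ECC) on a 28-marker functional panel, exposing
   subpopulations such as HLA-DR⁺ (antigen-presenting) tumor cells.
4. **Abundance statistics** — per-sample relative abundances (percent),
   sample–sample Spearman-correlation dendrograms (average linkage on
   1 − ρ), cross-compartment Spearman correlations with Benjamini–Hochberg
   adjustment, and two-sided Mann–Whitney U group comparisons.
5. **Spatial analysis** — mIF cell classification from binary marker
   calls (probability ≥ 0.9: tumor PanCK⁺CD45⁻CD3⁻, T cell
   CD3⁺CD45⁺PanCK⁻, …), per-tumor-cell neighborhood statistics in a
   100 µm-diameter disc (T-cell count; median HLA-DR of neighboring tumor
   cells), and exact 1st/2nd-nearest tumor-cell distances per T cell
   compared between patient groups.

Because patient-level cytometry data of this kind are rarely deposited,
the package ships a first-class synthetic-cohort generator
(`phenospace.simulate`) that plants the reported structure with known
ground truth — seven cell archetypes, dead/doublet events separable by the
QC gates, a tunable sample-level correlation between the HLA-DR⁺
cancer-cell share and T-cell abundance, and spatial point patterns in
which one group's T cells sit closer to tumor cells — so every stage of
the pipeline is verifiable end to end.

Intended users: computational biologists analysing CyTOF / mIF cohorts who
want scripted, reproducible equivalents of the usual interactive gating
and clustering steps, with statistics they can unit-test.

## Worked example

```python
from phenospace import (CohortConfig, arcsinh_transform, filter_events,
                        generate_cytof_cohort, two_round_phenotype)

data, truth = generate_cytof_cohort(CohortConfig(seed=1, n_events_per_sample=2000))
filtered, report = filter_events(data)       # Histone H3 >= 10, length in [10, 70]
print(report.totals())
transformed = arcsinh_transform(filtered)    # asinh(x / 5)
result = two_round_phenotype(transformed, seed=1)
print(result.cell_type.value_counts())
```

prints

```
{'n_input': 20000, 'n_removed_dead': 947, 'n_removed_nonsinglet': 1014, 'n_retained': 18039}
Epithelial cancer cells    7656
Mesenchymal                2799
Helper T cells             2228
Cytotoxic T cells          2046
Myeloid                    1353
Other immune               1120
Endothelial                 837
```

The QC gates remove almost exactly the 1961 planted dead/doublet events,
and the recovered labels agree with the planted archetypes for >99% of
events (the generator's compartments are well separated by design). The
`examples/` directory contains one short script per capability — QC,
phenotyping, cancer-cell subclustering and the HLA-DR/T-cell correlation,
spatial analysis, and the full pipeline — each printing the numbers it
computes and what they mean. A thin CLI mirrors the stages
(`phenospace simulate | qc | phenotype | abundance | spatial | run-all`).

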