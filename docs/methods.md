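# Methods

This note documents the models, conventions and design choices behind
`phenospace`: what each stage assumes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where genuinely
open design decisions were resolved.

## Event QC and normalization

Mass-cytometry events are gated with fixed, cohort-wide rules on the raw
ion-count scale:

* **Dead-cell gate** — events with nuclear Histone H3 signal strictly
  below 10 are treated as dead and removed. The boundary is read
  literally: an event at exactly 10 survives.
* **Singlet gate** — the per-event acquisition length must lie in the
  closed interval [10, 70] instrument units. Doublets (two cells acquired
  as one event) have longer acquisitions and summed ion counts.
* **Transform** — surviving events are mapped through `asinh(x / c)` with
  cofactor `c = 5`, the standard variance-stabilizing transform for ion
  counts. The transform is applied exactly once; the container tracks the
  scale state and refuses a second application.

The gates are global (no per-sample adaptation) and `filter_events` is
idempotent. Both thresholds, the death marker, and the cofactor are
configurable through `QCConfig`.

`subsample_events` implements random equal subsampling without
replacement; samples smaller than the quota are retained in full and
logged, never upsampled.

## Choosing k: the elbow criterion

`elbow_select_k` computes the total within-cluster sum of squares (WCSS)
over a candidate range, normalizes the curve to [0, 1], and selects the
interior candidate maximizing the second difference (the discrete
curvature). A maximizer only counts as a genuine elbow if the drop into it
dominates the entire residual tail: `drop / tail >= 3` by default.
Featureless data (a single Gaussian blob) produces a smooth power-law-like
WCSS curve whose largest second difference still sits on a heavy tail; the
ratio test rejects it, the scan is flagged elbow-free, and the smallest
candidate is returned. The ratio threshold is a tunable argument; 3 gives
a wide margin between the two regimes (well-separated mixtures score in
the tens to hundreds, smooth curves near 1).

## Clustering and annotation

k-means uses Euclidean distance on arcsinh values with no additional
per-marker scaling, greedy k-means++ initialization, `n_init = 10`
restarts and a fixed seed (scikit-learn's `KMeans`). Clustering is pooled
across samples — compartments are expected to mix across samples rather
than cluster by sample — and cluster ids are 1-based. Median profiles are
computed over *all* panel markers, not only the clustering features, so
annotation rules may reference markers outside the feature set (CD4 in
round 2).

**Positivity policy.** Manual gating studies call a marker "+" or "−" by
inspection. To make that reproducible, a marker counts as high in a
cluster when the cluster's median exceeds the midpoint between the
cohort's 10th and 90th percentile for that marker. The policy is
deterministic, scale-aware, and shared by both clustering rounds; the
quantile pair is configurable.

**Two rounds.** Round 1 runs on six lineage markers (EpCAM, CD31, CD45,
vimentin, cytokeratin, CK7) with k = 10 — deliberately more clusters than
compartments so rare populations are not engulfed — and labels clusters by
priority-ordered rules (cancer cells, endothelial, mesenchymal, immune;
unmatched clusters become "Other"). Clusters hitting the same rule are
merged by label; no profile-distance merging is attempted. Round 2
re-clusters the CD45⁺ subset on six immune markers (CD8, CD24, CD3, CD11b,
CD56, HLA-DR) with k = 10. CD4 participates in labeling (helper T cells)
but not in the feature set. Unmatched immune clusters become "Other
immune". Cytotoxic and helper T rules require the opposite coreceptor to
be low, so double-positive profiles fall through to "Other immune" rather
than being assigned arbitrarily.

**Cancer-cell subclustering.** Epithelial cancer cells pooled across
samples are subclustered with k = 10 on a 28-marker functional panel
(EpCAM, c-casp3, TP53, HLA-DR, HLA-ABC, CD31, thioredoxin, beta-catenin,
HER2, p-STAT3, p-STAT5, p-STAT6, TTF1, p-AKT, Ki67, CD56, vimentin, MDM2,
cytokeratin, MET, TP63, CK7, EGFR, CD44, p-ERK, CD24, p-S6, PDL1). If
fewer events than k are available, k is reduced with a warning. A
subcluster is called HLA-DR⁺ when its median HLA-DR exceeds the cohort
positivity threshold.

## Abundance statistics

Relative abundances are percentages of each sample's included events; at
the subcluster level the denominator is the sample's cancer cells. Rows
sum to 100 by construction and the container validates this.

* **Spearman correlation** — average ranks for ties; the p-value is exact
  (full enumeration of pairings, two-sided on |ρ|) for n ≤ 8 without
  ties, and the usual large-sample approximation otherwise. Enumeration at
  n = 9 (362,880 pairings) buys little over the approximation at
  substantial cost, so the exact path stops at 8. Constant vectors yield
  missing ρ and p.
* **Benjamini–Hochberg** — the step-up adjustment is applied once per
  declared analysis family (e.g. all subcluster × immune-type pairs
  together), via statsmodels; missing p-values pass through untouched.
* **Mann–Whitney U** — two-sided, with scipy's method selection: exact for
  small tie-free samples, tie-corrected normal approximation otherwise.
  Identical groups give p = 1 and the {1,2,3} vs {10,11,12} example gives
  the exact p = 0.1.
* **Dendrograms** — sample–sample Spearman ρ on abundance profiles,
  average linkage on the distance 1 − ρ. Average linkage is a stable
  default for correlation distances; the choice is encapsulated and easy
  to change. Pairs involving a constant profile have undefined ρ,
  recorded as missing and imputed as distance 1 with a warning. Trees are
  serialized to Newick with branch lengths.

## Spatial analysis

Cells carry µm coordinates and per-marker classifier probabilities (or
intensities plus thresholds). A marker is positive at probability ≥ 0.9
(boundary inclusive); the four-row class table (tumor, T cell, immune
non-T, other) covers only the marker combinations it lists — anything
else (e.g. PanCK⁺CD45⁺) is "Unassigned" rather than forced into a class.

"100 µm-diameter neighborhoods" are implemented as radius-50 µm discs,
boundary inclusive. The focal tumor cell is excluded from its own
neighborhood HLA-DR median ("neighboring" read literally); inclusion is
available as a flag. The HLA-DR vs T-cell-count correlation supports two
aggregation units — per-sample averages (default) and pooled
per-neighborhood records — because published descriptions of this
statistic differ between the two; both are first-class modes and neither
is asserted as canonical.

Nearest-distance records (1st and 2nd nearest tumor cell per T cell) are
computed with a k-d tree but are required — and property-tested — to equal
the O(n²) brute force exactly. Group comparisons use the per-sample median
distance with the sample as the unit of analysis, avoiding
pseudoreplication across cells.

## The synthetic-data generator

**Expression cohorts.** Each of seven archetypes (epithelial cancer
cells, endothelial, mesenchymal, helper T, cytotoxic T, myeloid, other
immune) is a diagonal Gaussian on the arcsinh scale (positive markers at
2–3.6, baseline 0.45, spreads 0.12/0.30) mapped to raw counts through
`5·sinh(v)` (clipped at 0), so the pipeline's `asinh(x/5)` inverts the
generator in expectation; per-archetype means are recovered within
sampling error at n ≥ 5000. Dead events get a nuclear signal far below
the death gate (arcsinh mean 0.5 vs 4.0 for live events); doublets are
sums of two live events' raw counts with event length uniform in
[75, 120] vs [20, 60] for singlets, so the stated QC gates separate both
contaminant classes essentially perfectly — a deliberately clean
semantics that makes QC testable, not a claim about real acquisition.

Sample composition is Dirichlet-distributed per group. The default
two-group design (4 immune-rich "LPS" vs 6 immune-poor "SPS" samples)
contrasts T-cell mass (≈39% vs ≈7% of Dirichlet weight) and mesenchymal
content. Two latent standard-normal factors per sample, correlated at the
planted `hladr_tcell_rho` (default 0.9), drive (a) the HLA-DR⁺ share of
that sample's cancer cells, mapped through the normal CDF onto
[0.1, 0.9], and (b) a log-normal tilt (sd 0.5) on the combined T-cell
Dirichlet mass. Both factors carry a group-level mean offset (+1 / −1), so
the immune-rich group is simultaneously enriched for HLA-DR⁺ cancer cells
and T cells — the planted analogue of the co-occurrence the pipeline is
meant to detect — while the within-group correlation stays at the planted
ρ. The "HLA-DR⁺ cancer-cell fraction" entering the planted correlation is
the share *of cancer cells* (matching the subcluster-abundance
denominator), not the share of all events: a fraction-of-total definition
is compositionally anticorrelated with the T-cell fraction and cannot
carry a strong positive coupling. With this design, a planted ρ of 0.9
yields measured sample-level Spearman values around 0.8–0.86 at 40
samples — attenuated by Dirichlet and counting noise — and the measured
correlation increases monotonically with the planted value.

The Dirichlet concentrations (totals ≈ 300 per group) were chosen so the
planted group structure is identifiable from realized compositions: the
generator's stated purpose is *recoverable* ground truth, and a
concentration low enough to let samples cross the group contrast would
make the dendrogram-recovery property false of the data itself, not of
the method. Real patient cohorts are more dispersed than this.

**Spatial cohorts.** Tumor cells are uniform in a 1000 × 1000 µm field;
T cells are displaced offspring of randomly chosen tumor cells
(Thomas-process style) with per-group Gaussian displacement scale — 15 µm
(infiltrated) vs 60 µm (excluded) by default — clipped to the field; an
infinite scale degrades to uniform placement. Tumor-cell HLA-DR intensity
is baseline + 0.15 × (number of T cells within 50 µm) + Gaussian noise,
coupling antigen presentation to local T-cell density. Classifier
probabilities are drawn high (0.92–0.999) for a class's positive markers
and low (≤0.08) otherwise.

**What the generator does not emulate.** Spillover between channels, bead
normalization drift, acquisition-time effects, batch effects, partially
overlapping or continuous phenotypes, doublets of unequal cell sizes,
tissue morphology (vessels, stroma regions, necrosis), segmentation
errors, and classifier miscalibration. Passing tests therefore certify
the pipeline's logic and statistics under clean, separable conditions —
they do not certify performance on noisy real cohorts, where annotation
accuracy and correlation recovery will be lower.

## Problem sizes and numerical conventions

Tests and the acceptance script run the default cohorts at 300–2000
events per sample (up to 40 samples), sizes at which every planted
property is comfortably measurable while the full suite stays fast.
Determinism: every stochastic stage takes a single seed; k-means restarts
derive from it; rerunning the pipeline with one seed reproduces all CSV
artifacts byte for byte. Degenerate inputs resolve explicitly: empty
immune subsets return empty results with a warning; fewer cancer cells
than k reduces k; a single tumor cell yields only first-nearest
distances; constant vectors yield missing correlations; samples with no
T cells are excluded from distance comparisons with a warning.

## Known limitations

* Annotation quality is bounded by the positivity policy: markers whose
  cohort-wide 10th–90th percentile span is dominated by one compartment
  get thresholds that may misread small clusters.
* The elbow rule assumes a contiguous candidate range and a single
  dominant scale of structure; nested structure (blobs within blobs)
  yields the coarse k.
* Exact Spearman p-values stop at n = 8; at n = 9–15 the approximation
  can be off by a few hundredths in the tails.
* FCS containers are not parsed; cohorts are exchanged as flat CSV with a
  documented column contract (markers + `sample_id` + `event_length`).
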