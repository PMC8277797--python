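"""Multiplex-immunofluorescence spatial analysis on synthetic point patterns.

Each synthetic field has uniformly placed tumor cells; T cells are placed
around randomly chosen tumor cells with a per-group displacement scale
(15 µm for the immune-infiltrated group, 60 µm for the excluded group).
Cells are classified from PanCK/CD45/CD3 probabilities (cutoff 0.9). We
then compute (a) per-tumor-cell neighborhood statistics in a 100 µm-
diameter disc and the per-sample HLA-DR vs T-cell-count correlation, and
(b) each T cell's distance to its 1st and 2nd nearest tumor cell, compared
between groups with the sample as unit.
"""

import pandas as pd

from phenospace import (
    SpatialConfig,
    classify_cells,
    compare_distance_groups,
    correlate_hladr_tcells,
    generate_spatial_cohort,
    neighborhood_stats,
    t_to_tumor_distances,
)

cells, truth = generate_spatial_cohort(SpatialConfig(seed=4))
cells = classify_cells(cells)
print("cell classes:", cells["cell_class"].value_counts().to_dict())

neighborhoods, distances = [], {}
for sid, sub in cells.groupby("sample_id"):
    sub = sub.reset_index(drop=True)
    nb = neighborhood_stats(sub, radius_um=50.0)
    nb.insert(0, "sample_id", sid)
    neighborhoods.append(nb)
    distances[sid] = t_to_tumor_distances(sub)
neighborhoods = pd.concat(neighborhoods, ignore_index=True)

corr = correlate_hladr_tcells(neighborhoods, aggregation="per_sample")
print(f"\nHLA-DR vs T-cell count (per-sample averages, n = {corr['n']}): "
      f"rho = {corr['rho']:.2f}, p = {corr['p']:.2g}")

cmp = compare_distance_groups(distances, truth.sample_table["group"])
med = cmp.per_sample.groupby("group")["median_d1"].median()
print(f"\nmedian T-to-nearest-tumor distance: "
      f"LPS {med['LPS']:.1f} um vs SPS {med['SPS']:.1f} um "
      f"(Mann-Whitney p = {cmp.p_d1:.2g})")
print("shorter distances in the immune-infiltrated group reproduce the")
print("planted proximity contrast")
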