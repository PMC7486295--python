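"""Differential expression between OR-rich and OR-poor cells.

Cells are split at the global median OR count (applied within each stage
cluster), then every gene is tested with a two-sided Mann-Whitney U on TPM;
the primary gate is |fold change| >= 4 at p < 0.05.  One-vs-rest stage
markers are computed with the laxer marker gate (FC >= 2)."""

from _common import out_dir, study_config
from orsmell.activation import binarize_activation, zfpkm_transform
from orsmell.differential import cluster_markers, median_split, wilcoxon_de
from orsmell.repertoire import or_counts_per_cell
from orsmell.synthetic_data import simulate_catalog, simulate_cells

cfg = study_config(n_cells=300)
catalog = simulate_catalog(cfg)
matrix, truth = simulate_cells(cfg, catalog)
amat = binarize_activation(zfpkm_transform(matrix))
profile = or_counts_per_cell(amat, catalog)

labels, degenerate = median_split(profile, truth.cluster)
de = wilcoxon_de(matrix, labels)
markers = cluster_markers(matrix, truth.cluster)

out = out_dir("05_differential")
de.sort_values("p").to_csv(out / "or_split_de.tsv", sep="\t", index=False)
for c, table in markers.items():
    table.head(50).to_csv(out / f"markers_cluster{c}.tsv", sep="\t", index=False)

n_high = int((labels == "high").sum())
print(f"median split: {n_high} OR-rich vs {len(labels) - n_high} OR-poor cells"
      + (f" ({len(degenerate)} one-sided clusters excluded)" if degenerate else ""))
print(f"{int(de['pass'].sum())} genes pass the |FC| >= 4, p < 0.05 gate "
      f"of {len(de)} tested")
for c, table in markers.items():
    print(f"stage cluster {c}: {int(table['pass'].sum())} markers at FC >= 2")
print(f"tables in {out}")
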