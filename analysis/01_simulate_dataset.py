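"""Simulate the study's single-cell tumor dataset and record its ground truth.

Writes the chemoreceptor catalog and the per-cell truth table (latent time,
stemness, planted OR count, stage cluster) under results/01_dataset/; the
raw TPM matrix itself is large and is re-derived deterministically by the
later drivers instead of being stored.
"""

import numpy as np

from _common import out_dir, study_config
from orsmell.io_catalog import write_catalog
from orsmell.synthetic_data import simulate_catalog, simulate_cells

cfg = study_config()
catalog = simulate_catalog(cfg)
matrix, truth = simulate_cells(cfg, catalog)

out = out_dir("01_dataset")
write_catalog(catalog, out / "catalog.tsv")
truth.frame(matrix.sample_ids).to_csv(out / "cell_truth.tsv", sep="\t", index=False)

chr11 = (catalog.table["chromosome"] == "chr11").mean()
print(f"simulated {matrix.n_genes} genes x {matrix.n_samples} cells (TPM)")
print(f"catalog: {len(catalog.functional_ors())} functional ORs, "
      f"{len(catalog) - len(catalog.functional_ors())} pseudogenes; "
      f"{chr11:.0%} of the catalog sits on chr11")
print(f"planted OR count per cell: mean {truth.or_count.mean():.2f}, "
      f"range {truth.or_count.min()}-{truth.or_count.max()}")
print(f"corr(stemness, planted OR count) = "
      f"{np.corrcoef(truth.stemness, truth.or_count)[0, 1]:.2f}")
print(f"tables in {out}")
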