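# orsmell

Analysis of ectopically expressed olfactory receptors (ORs) in single-cell
tumor transcriptomes — and what their repertoire says about differentiation
state and prognosis.

Mature olfactory sensory neurons express a single OR allele; malignant
cells do not respect that rule.  This package implements the full analysis
chain for studying that phenomenon, for computational biologists working
with genes x cells TPM matrices:

* **Activation calling** — the zFPKM transform per cell: a Gaussian-KDE
  peak `mu` and half-Gaussian right-tail scale `sigma` standardize
  log2(TPM) to `z = (x - mu)/sigma`; a gene is active at `z > -3`
  (zero-TPM entries are sentineled and can never be active).
* **Repertoire statistics** — per-cell expressed-OR counts `K_c`,
  co-expression distributions and the one-or-none fraction, tumor-type
  breadth of each OR, and the coupling between OR count and expression
  level (Shapiro-Wilk-gated Pearson/Spearman).
* **Doublet QC** — a simulated-doublet kNN scorer with an Otsu auto
  threshold.
* **Single-sample enrichment** — a GSVA-style weighted KS random walk
  (kernel CDF, sd/4 bandwidth, tau = 1, max_diff scoring) over the
  fourteen canonical tumor-state signatures; per-cell stemness is the
  enrichment of a stemness gene set.
* **Differential expression** — global-median OR-count split applied
  cluster-wise, two-sided Mann-Whitney U (exact by enumeration for small
  groups), pseudocounted linear fold change gated at |FC| >= 4, p < 0.05.
* **Trajectory** — PCA embedding, kNN-graph communities, root at the
  max-stemness cluster's medoid, geodesic (Dijkstra) pseudotime in [0, 1],
  and its correlations with stemness and the OR repertoire.
* **Signature projection & survival** — cells clustered on binary OR
  profiles (Jaccard/average linkage), per-cluster mean-expression
  signatures projected onto bulk patients with
  `cos(A, B) = A·B / (||A|| ||B||)`, patients Ward-clustered on their
  similarity rows, and groups compared by Kaplan-Meier curves and the
  log-rank test.
* **Synthetic data** — a fully deterministic generator producing single
  cells with a latent differentiation axis, a stemness-coupled OR
  repertoire, planted doublets, and bulk cohorts with group-dependent
  survival, so every stage is testable with no download.

File formats: dense TSV/CSV and Matrix Market (+`genes.tsv`/`barcodes.tsv`)
expression matrices, tab-separated chemoreceptor catalogs and survival
tables, GMT gene sets.

## Worked example

Run the whole synthetic study from the shell:

```bash
orsmell pipeline --seed 5 --out-dir study/
```

```
pipeline done: 99.7% OR-positive cells, 2 signatures, log-rank p = 7.15e-09
```

or drive the stages from Python:

```python
from orsmell.pipeline import run_synthetic_study
from orsmell.synthetic_data import SimulationConfig

result = run_synthetic_study(SimulationConfig(seed=1))
print(result.correlations)
```

```
            x                   y         r              p test_used
0  pseudotime            stemness -0.896594   0.000000e+00  spearman
1  pseudotime            or_count -0.641880  1.037353e-112  spearman
2  pseudotime  mean_or_expression -0.208691   6.443529e-11  spearman
3    stemness            or_count  0.641144  2.240352e-112  spearman
```

Reading the output: under the study's tumor conditions the expressed-OR
count per cell falls along the differentiation trajectory (r = -0.64
between pseudotime and `K_c`) exactly as stemness does (r = -0.90), and
stemness and OR count rise together (r = +0.64) — the OR repertoire tracks
differentiation state.  The same pipeline in "healthy" mode
(`or_stemness_slope=0`) shows no pseudotime-OR-count association.  On the
bulk side, the three OR-centric signatures stratify the 200 simulated
patients into three groups whose survival differs at log-rank
p = 3.5e-07, with the group mortality ranking matching the planted
hazards.

The `analysis/` directory holds numbered drivers (`01_simulate_dataset.py`
… `07_signatures_survival.py`) that walk the same chain step by step and
write their tables under `results/`; `docs/methods.md` documents every
procedure, convention and generator assumption.

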