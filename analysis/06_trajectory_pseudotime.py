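"""Differentiation trajectory and its coupling to the OR repertoire.

Stemness is scored per cell by GSVA over the stemness program, the cells are
embedded (non-chemoreceptor genes only) and clustered, the trajectory is
rooted at the max-stemness cluster's medoid, and geodesic pseudotime is
correlated with stemness and OR counts.  A healthy-mode control (no
OR-stemness coupling) is run alongside."""

import numpy as np
import pandas as pd

from _common import out_dir, study_config
from orsmell.pipeline import run_trajectory_study

cfg = study_config()
traj, corr, truth = run_trajectory_study(cfg)

healthy_cfg = study_config(seed=cfg.seed + 1, or_rate_base=2.0,
                           or_stemness_slope=0.0)
_, h_corr, _ = run_trajectory_study(healthy_cfg)

out = out_dir("06_trajectory")
pd.DataFrame({
    "cell_id": traj.sample_ids,
    "cluster": traj.clusters,
    "pseudotime": traj.pseudotime,
    "latent_time_truth": truth.latent_time,
    "or_count_truth": truth.or_count,
}).to_csv(out / "pseudotime.tsv", sep="\t", index=False)
corr.assign(condition="tumor").to_csv(out / "correlations_tumor.tsv",
                                      sep="\t", index=False)
h_corr.assign(condition="healthy").to_csv(out / "correlations_healthy.tsv",
                                          sep="\t", index=False)


def get(table, x, y):
    return float(table[(table["x"] == x) & (table["y"] == y)]["r"].iloc[0])


print(f"root cluster {traj.root_cluster}; "
      f"{int(np.isfinite(traj.pseudotime).sum())}/{len(traj.sample_ids)} cells ordered")
print(f"tumor mode:   r(pseudotime, stemness) = {get(corr, 'pseudotime', 'stemness'):+.2f}, "
      f"r(pseudotime, OR count) = {get(corr, 'pseudotime', 'or_count'):+.2f}, "
      f"r(stemness, OR count) = {get(corr, 'stemness', 'or_count'):+.2f}")
print(f"healthy mode: r(pseudotime, OR count) = "
      f"{get(h_corr, 'pseudotime', 'or_count'):+.2f}  (no coupling planted)")
print(f"tables in {out}")
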