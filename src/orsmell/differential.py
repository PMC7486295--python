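"""Differential expression between OR-rich and OR-poor cells, and
one-vs-rest cluster markers.

The OR-count split follows the analysis recipe: one global median of K_c
across all cells, applied within each cluster, so "high" cells exceed the
dataset-wide median no matter which cluster they sit in.  Gene-level tests
are two-sided Mann-Whitney on TPM with a pseudocounted linear fold change;
the primary gate is |FC| >= 4 (either direction) at raw p < 0.05, with a
Benjamini-Hochberg column emitted for transparency but not gated on.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._stats import mann_whitney_u
from .errors import ValidationError
from .io_catalog import ExpressionMatrix
from .repertoire import RepertoireProfile


def median_split(
    profile: RepertoireProfile, clusters: np.ndarray
) -> tuple[np.ndarray, list[int]]:
    """Label cells high/low by the global median OR count, cluster-wise.

    Returns per-cell labels (``"high"``/``"low"``) and the list of clusters
    that ended up entirely on one side (excluded from DE, with a warning).
    """
    clusters = np.asarray(clusters)
    if len(clusters) != len(profile):
        raise ValidationError("cluster labels do not match profile length")
    m = float(np.median(profile.or_count))
    labels = np.where(profile.or_count > m, "high", "low")
    degenerate = []
    for c in np.unique(clusters):
        sub = labels[clusters == c]
        if len(set(sub)) < 2:
            degenerate.append(int(c))
    if degenerate:
        warnings.warn(
            f"clusters {degenerate} fall entirely on one side of the median split",
            stacklevel=2,
        )
    return labels, degenerate


def wilcoxon_de(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    fc_cutoff: float = 4.0,
    p_cutoff: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Two-group Mann-Whitney DE on TPM with a pseudocounted fold change.

    ``fold_change = (mean_high + 1) / (mean_low + 1)``; a gene passes iff
    FC >= fc_cutoff or FC <= 1/fc_cutoff, and p < p_cutoff.
    """
    labels = np.asarray(labels)
    hi = labels == "high"
    lo = labels == "low"
    if hi.sum() < 3 or lo.sum() < 3:
        raise ValidationError("need at least 3 cells per group for DE")
    values = matrix.values
    rows = []
    for i, gene in enumerate(matrix.gene_ids):
        x = values[i, hi]
        y = values[i, lo]
        mean_hi = float(x.mean())
        mean_lo = float(y.mean())
        fc = (mean_hi + pseudocount) / (mean_lo + pseudocount)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0
        else:
            _, p, _ = mann_whitney_u(x, y)
        rows.append(
            {
                "gene": gene,
                "mean_high": mean_hi,
                "mean_low": mean_lo,
                "fc": fc,
                "log2fc": float(np.log2(fc)),
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_bh"] = multipletests(table["p"], method="fdr_bh")[1]
    table["pass"] = (
        ((table["fc"] >= fc_cutoff) | (table["fc"] <= 1.0 / fc_cutoff))
        & (table["p"] < p_cutoff)
    )
    return table


def cluster_markers(
    matrix: ExpressionMatrix,
    clusters: np.ndarray,
    fc_cutoff: float = 2.0,
    p_cutoff: float = 0.05,
) -> dict[int, pd.DataFrame]:
    """One-vs-rest markers per cluster (upregulated genes only).

    Uses the same Mann-Whitney statistic as :func:`wilcoxon_de` with a
    laxer, marker-specific gate (FC >= 2, p < 0.05 by default); singleton
    clusters are skipped with a warning.
    """
    clusters = np.asarray(clusters)
    if len(np.unique(clusters)) < 2:
        raise ValidationError("need at least two clusters for markers")
    out: dict[int, pd.DataFrame] = {}
    for c in np.unique(clusters):
        mask = clusters == c
        if mask.sum() < 3 or (~mask).sum() < 3:
            warnings.warn(f"cluster {c} too small for marker testing; skipped",
                          stacklevel=2)
            continue
        labels = np.where(mask, "high", "low")
        table = wilcoxon_de(matrix, labels, fc_cutoff=fc_cutoff, p_cutoff=p_cutoff)
        table["pass"] = (table["fc"] >= fc_cutoff) & (table["p"] < p_cutoff)
        out[int(c)] = table.sort_values(["pass", "fc"], ascending=[False, False]).reset_index(
            drop=True
        )
    return out
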