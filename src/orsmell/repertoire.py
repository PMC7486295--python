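"""Per-cell OR repertoire statistics.

"Expressed OR" here always means an activation call (zFPKM > -3), never raw
TPM > 0, so cellular counts, co-expression distributions and tumor-breadth
tables all share one definition of expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import CorrelationResult, shapiro_gated_correlation
from .activation import ActivationMatrix, ZScoreMatrix, call_active_genes
from .errors import ValidationError
from .io_catalog import ExpressionMatrix, GeneCatalog


@dataclass
class RepertoireProfile:
    """Per-cell expressed-OR counts and mean OR expression levels."""

    sample_ids: list[str]
    or_count: np.ndarray             # K_c, integer
    mean_or_expression: np.ndarray   # mean log2(TPM+1) over the cell's active ORs; 0 if none

    def __len__(self) -> int:
        return len(self.sample_ids)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.sample_ids,
                "or_count": self.or_count,
                "mean_or_expression": self.mean_or_expression,
            }
        )


def or_counts_per_cell(
    activation: ActivationMatrix,
    catalog: GeneCatalog,
    expression: ExpressionMatrix | None = None,
) -> RepertoireProfile:
    """Count active functional ORs per cell (K_c).

    If ``expression`` is given (TPM or log2(TPM+1)), the mean log2(TPM+1) of
    each cell's active ORs is computed too; otherwise it is all zeros.
    """
    ors = catalog.functional_ors()
    block = activation.restrict(ors)
    counts = block.values.sum(axis=0).astype(int)
    mean_expr = np.zeros(len(activation.sample_ids))
    if expression is not None:
        log_expr = expression.log2_tpm1()
        expr_block = {g: i for i, g in enumerate(log_expr.gene_ids)}
        rows = [expr_block[g] for g in block.gene_ids if g in expr_block]
        if len(rows) != len(block.gene_ids):
            raise ValidationError("expression matrix is missing active OR genes")
        sub = log_expr.values[rows, :]
        active = block.values.astype(bool)
        with np.errstate(invalid="ignore"):
            sums = np.where(active, sub, 0.0).sum(axis=0)
            mean_expr = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return RepertoireProfile(list(activation.sample_ids), counts, mean_expr)


def coexpression_distribution(profile: RepertoireProfile) -> tuple[pd.DataFrame, float]:
    """Distribution of K over cells and the fraction of cells with K <= 1.

    Cancer cells violating the one-receptor-one-neuron rule show up here as
    mass at K >= 2; glioma-like data concentrate at K in {0, 1}.
    """
    n = len(profile)
    if n == 0:
        raise ValidationError("empty repertoire profile")
    ks, counts = np.unique(profile.or_count, return_counts=True)
    table = pd.DataFrame(
        {"or_count": ks, "n_cells": counts, "percent": 100.0 * counts / n}
    )
    one_or_none = float((profile.or_count <= 1).sum()) / n
    return table, one_or_none


def tumor_specificity(
    zscores_by_dataset: dict[str, ZScoreMatrix],
    catalog: GeneCatalog,
    threshold: float = -3.0,
) -> pd.DataFrame:
    """Breadth of each OR across datasets/tumor types.

    An OR counts as active in a dataset iff the gene-level (median-z) rule
    marks it active there.  ORs active nowhere are omitted.  Breadth 1 is the
    "exclusive" class; anything wider is "broad".
    """
    if not zscores_by_dataset:
        raise ValidationError("need at least one dataset")
    ors = set(catalog.functional_ors())
    hits: dict[str, list[str]] = {}
    for name, zmat in zscores_by_dataset.items():
        active = call_active_genes(zmat, threshold)
        for g, a in zip(zmat.gene_ids, active):
            if a and g in ors:
                hits.setdefault(g, []).append(name)
    rows = [
        {
            "or_symbol": g,
            "breadth": len(datasets),
            "datasets": ";".join(sorted(datasets)),
            "class": "exclusive" if len(datasets) == 1 else "broad",
        }
        for g, datasets in sorted(hits.items())
    ]
    return pd.DataFrame(rows, columns=["or_symbol", "breadth", "datasets", "class"])


def count_expression_correlation(profile: RepertoireProfile) -> CorrelationResult:
    """Association between a cell's OR count and its mean OR expression.

    Cells with K = 0 carry no expression information and are excluded.  The
    Pearson/Spearman choice is Shapiro-Wilk gated and reported.
    """
    mask = profile.or_count > 0
    if int(mask.sum()) < 3:
        raise ValidationError("need at least 3 cells with expressed ORs")
    return shapiro_gated_correlation(
        profile.or_count[mask].astype(float), profile.mean_or_expression[mask]
    )
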