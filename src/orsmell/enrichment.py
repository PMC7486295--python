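"""Single-sample gene-set scoring with the GSVA random-walk statistic.

Stages, per the published algorithm's defaults:

1. For every gene i, estimate a kernel CDF across samples: the value for
   sample j is the mean over samples j' of Phi((x_ij - x_ij') / h_i) with a
   Gaussian kernel of bandwidth h_i = s_i / 4 (s_i = the gene's sample sd,
   floored at 1e-8 for constant genes).
2. Per sample, rank genes by that CDF value in decreasing order and center
   the ranks symmetrically about zero.
3. For each gene set, run a weighted Kolmogorov-Smirnov-like random walk
   down the ranked list: set members step up proportionally to
   |centered rank|^tau, non-members step down uniformly.
4. The enrichment score in max_diff mode is the maximum positive deviation
   plus the minimum negative deviation of the walk.

Scores are rank-based, hence invariant to per-gene location shifts and to
gene/sample order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from ._stats import shapiro_gated_correlation
from .errors import ValidationError
from .io_catalog import ExpressionMatrix

#: the fourteen tumor-state signature names scored throughout the analysis
CANONICAL_SIGNATURES = (
    "angiogenesis", "apoptosis", "cell cycle", "differentiation", "DNA damage",
    "DNA repair", "EMT", "hypoxia", "inflammation", "invasion", "metastasis",
    "proliferation", "quiescence", "stemness",
)

_BW_FLOOR = 1e-8


@dataclass
class EnrichmentScoreMatrix:
    """Gene sets x samples enrichment scores plus the parameters used."""

    scores: np.ndarray
    set_names: list[str]
    sample_ids: list[str]
    tau: float
    es_mode: str

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.set_names, columns=self.sample_ids)

    def row(self, name: str) -> np.ndarray:
        return self.scores[self.set_names.index(name)]


def _kernel_cdf(x: np.ndarray) -> np.ndarray:
    """Gaussian-kernel CDF values, gene by gene (stage 1)."""
    p, n = x.shape
    bw = np.maximum(x.std(axis=1, ddof=1) / 4.0, _BW_FLOOR)
    out = np.empty_like(x)
    for i in range(p):  # per-gene loop keeps the n x n broadcast small
        out[i] = ndtr((x[i][:, None] - x[i][None, :]) / bw[i]).mean(axis=1)
    return out


def gsva_scores(
    matrix: ExpressionMatrix,
    sets: dict[str, list[str]],
    tau: float = 1.0,
    es_mode: str = "max_diff",
) -> EnrichmentScoreMatrix:
    """Score every gene set in every sample.

    ``matrix`` may be TPM (log2(TPM+1) is applied) or already log scale.
    Sets with no genes in the matrix are dropped with a warning.
    """
    if matrix.n_samples < 2:
        raise ValidationError("GSVA needs at least two samples")
    if es_mode not in ("max_diff", "abs_max"):
        raise ValidationError(f"unknown es_mode {es_mode!r}")
    log_m = matrix.log2_tpm1()
    x = log_m.values
    p, n = x.shape
    gene_pos = {g: i for i, g in enumerate(log_m.gene_ids)}

    retained: list[tuple[str, np.ndarray]] = []
    for name, members in sets.items():
        idx = np.array(sorted({gene_pos[g] for g in members if g in gene_pos}), dtype=int)
        if idx.size == 0:
            warnings.warn(f"gene set {name!r} has no genes in the matrix; dropped",
                          stacklevel=2)
            continue
        if idx.size == p:
            raise ValidationError(f"gene set {name!r} covers every gene; walk undefined")
        retained.append((name, idx))
    if not retained:
        raise ValidationError("no gene set overlaps the matrix")

    cdf = _kernel_cdf(x)
    # stage 2: per-sample descending order; ranks run p (top) .. 1 (bottom)
    # and are centered about zero by subtracting p/2 — the published
    # convention, so both extremes of the list carry large weight
    order = np.argsort(-cdf, axis=0, kind="stable")        # positions -> gene index
    centered = np.arange(p, 0, -1) - p / 2.0               # p/2 ... 1 - p/2
    weight = np.abs(centered) ** tau

    scores = np.zeros((len(retained), n))
    member_mask = np.zeros(p, dtype=bool)
    for s_i, (name, idx) in enumerate(retained):
        member_mask[:] = False
        member_mask[idx] = True
        m = idx.size
        for j in range(n):
            in_set = member_mask[order[:, j]]
            up = np.where(in_set, weight, 0.0)
            total_up = up.sum()
            down = (~in_set) / (p - m)
            walk = np.cumsum(up / total_up - down)
            if es_mode == "max_diff":
                scores[s_i, j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
            else:
                mx, mn = walk.max(), walk.min()
                scores[s_i, j] = mx if abs(mx) >= abs(mn) else mn
    return EnrichmentScoreMatrix(
        scores, [name for name, _ in retained], list(log_m.sample_ids), tau, es_mode
    )


def threshold_activated_sets(
    scores: EnrichmentScoreMatrix, min_score: float = 0.0
) -> pd.DataFrame:
    """Generic per-sample activated/inactivated call on the score sign.

    A plain threshold utility: a set is "activated" in a sample when its
    score exceeds ``min_score``.  No significance claim is attached.
    """
    act = scores.scores > min_score
    return pd.DataFrame(act, index=scores.set_names, columns=scores.sample_ids)


def correlate_or_pathways(
    scores: EnrichmentScoreMatrix,
    or_log_expression: ExpressionMatrix,
) -> pd.DataFrame:
    """Correlate each OR's expression with each signature score across cells.

    ``or_log_expression`` is a log2(TPM+1) matrix restricted to the ORs of
    interest, with the same samples as ``scores``.  Zero-variance rows (an OR
    never detected, a constant signature) are flagged and skipped.
    """
    if list(or_log_expression.sample_ids) != list(scores.sample_ids):
        raise ValidationError("sample ids of scores and OR expression differ")
    expr = or_log_expression.log2_tpm1()
    rows = []
    for g_i, gene in enumerate(expr.gene_ids):
        x = expr.values[g_i]
        for s_i, sig in enumerate(scores.set_names):
            y = scores.scores[s_i]
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append(
                    {"or_symbol": gene, "signature": sig, "r": np.nan, "p": np.nan,
                     "test_used": "skipped_zero_variance", "direction": 0}
                )
                continue
            res = shapiro_gated_correlation(x, y)
            rows.append(
                {"or_symbol": gene, "signature": sig, "r": res.r, "p": res.p,
                 "test_used": res.test_used, "direction": int(np.sign(res.r))}
            )
    return pd.DataFrame(
        rows, columns=["or_symbol", "signature", "r", "p", "test_used", "direction"]
    )
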