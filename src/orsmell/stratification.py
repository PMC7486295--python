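"""OR-centric signatures and their cosine projection onto bulk cohorts.

Cells are grouped by hierarchical clustering of their binary OR activation
profiles (Jaccard distance, average linkage - Euclidean on sparse binaries
would be dominated by co-absence of rarely expressed receptors).  Each group
yields a signature: the mean log2(TPM+1) of its cells over the OR genes,
annotated with the group's mean expressed-OR count.  Signatures are
projected onto bulk patients with the cosine similarity

    cos(A, B) = sum_i A_i B_i / (sqrt(sum_i A_i^2) * sqrt(sum_i B_i^2)),

which lies in [0, 1] for non-negative expression vectors, and patients are
then grouped by Ward clustering of their similarity rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .activation import ActivationMatrix
from .errors import ValidationError
from .io_catalog import ExpressionMatrix, GeneCatalog


@dataclass
class Signature:
    """Mean OR expression vector of one cell cluster."""

    cluster_id: int
    gene_ids: list[str]
    values: np.ndarray            # mean log2(TPM+1), non-negative
    n_cells: int
    mean_or_count: float


@dataclass
class SimilarityMatrix:
    """Patients x signatures cosine similarities."""

    values: np.ndarray
    patient_ids: list[str]
    signature_ids: list[int]
    valid: np.ndarray             # False for patients with all-zero OR vectors
    groups: np.ndarray | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=self.patient_ids,
            columns=[f"signature_{s}" for s in self.signature_ids],
        )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Plain cosine similarity of two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("vectors must be 1-D and of equal length")
    na = np.sqrt(np.sum(a * a))
    nb = np.sqrt(np.sum(b * b))
    if na == 0 or nb == 0:
        raise ValidationError("cosine similarity undefined for a zero vector")
    return float(np.sum(a * b) / (na * nb))


def _auto_k(dist_condensed: np.ndarray, link: np.ndarray, k_range: range) -> int:
    """Silhouette-selected cluster count on a precomputed distance."""
    square = squareform(dist_condensed)
    best_k, best_s = k_range[0], -np.inf
    for k in k_range:
        labels = sch.fcluster(link, k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(square, labels, metric="precomputed")
        if s > best_s:
            best_k, best_s = k, s
    return best_k


def build_or_signatures(
    or_expression: ExpressionMatrix,
    activation: ActivationMatrix,
    n_clusters: int | str = "auto",
    detected_only: bool = True,
) -> list[Signature]:
    """Cluster cells on their binary OR profiles and average each cluster.

    ``or_expression`` must be restricted to functional OR genes (TPM or
    log2(TPM+1)); ``activation`` supplies the binary profiles over the same
    cells and genes.  By default only ORs active in at least one cell enter
    the signatures.  ``n_clusters='auto'`` picks k in [2, 8] by silhouette.
    """
    if list(or_expression.sample_ids) != list(activation.sample_ids):
        raise ValidationError("expression and activation cells differ")
    act = activation.restrict(list(or_expression.gene_ids))
    if act.values.shape[0] != or_expression.n_genes:
        raise ValidationError("activation matrix is missing OR genes")
    expr = or_expression.log2_tpm1()
    genes = list(expr.gene_ids)
    binary = act.values.astype(bool)
    if detected_only:
        keep = binary.any(axis=1)
        if not keep.any():
            raise ValidationError("no OR is active in any cell")
        binary = binary[keep]
        genes = [g for g, k in zip(genes, keep) if k]
        expr_values = expr.values[keep]
    else:
        expr_values = expr.values

    cells = binary.T  # cells x ORs
    with np.errstate(invalid="ignore"):
        dist = pdist(cells, metric="jaccard")
    dist = np.nan_to_num(dist, nan=0.0)  # two all-zero cells are identical
    if np.all(dist == 0):
        if n_clusters not in ("auto", 1):
            raise ValidationError(
                "all cells share one binary OR profile; cannot split into "
                f"{n_clusters} clusters"
            )
        labels = np.ones(cells.shape[0], dtype=int)
    else:
        link = sch.linkage(dist, method="average")
        if n_clusters == "auto":
            k = _auto_k(dist, link, range(2, min(9, cells.shape[0])))
        else:
            k = int(n_clusters)
            if k > cells.shape[0]:
                raise ValidationError("more clusters requested than cells")
        labels = sch.fcluster(link, k, criterion="maxclust")

    or_counts = act.values.sum(axis=0)
    signatures = []
    for cid in sorted(np.unique(labels)):
        members = labels == cid
        sig = Signature(
            cluster_id=int(cid),
            gene_ids=genes,
            values=expr_values[:, members].mean(axis=1),
            n_cells=int(members.sum()),
            mean_or_count=float(or_counts[members].mean()),
        )
        if np.all(sig.values == 0):
            # a cluster of OR-silent cells carries no projectable information
            warnings.warn(
                f"cluster {cid} ({sig.n_cells} cells) has an all-zero OR "
                "signature; dropped",
                stacklevel=2,
            )
            continue
        signatures.append(sig)
    if not signatures:
        raise ValidationError("every cluster produced a zero OR signature")
    return signatures


def project_signatures(
    bulk: ExpressionMatrix,
    signatures: list[Signature],
    min_shared: int = 10,
) -> SimilarityMatrix:
    """Cosine-project signatures onto bulk patient profiles.

    The bulk matrix is restricted to the signatures' OR genes on the
    log2(TPM+1) scale; OR genes missing from the bulk are treated as zero
    (with a warning).  Patients whose restricted vector is all zero are
    flagged invalid and excluded from downstream grouping.
    """
    if not signatures:
        raise ValidationError("no signatures to project")
    genes = signatures[0].gene_ids
    for s in signatures[1:]:
        if s.gene_ids != genes:
            raise ValidationError("signatures disagree on OR gene order")
    bulk_log = bulk.log2_tpm1()
    pos = {g: i for i, g in enumerate(bulk_log.gene_ids)}
    shared = [g for g in genes if g in pos]
    if len(shared) == 0:
        raise ValidationError("bulk matrix shares no OR genes with the signatures")
    if len(shared) < len(genes):
        warnings.warn(
            f"{len(genes) - len(shared)} signature OR genes missing from bulk; "
            "treated as zero",
            stacklevel=2,
        )
    if len(shared) < min_shared:
        warnings.warn(
            f"only {len(shared)} OR genes shared with bulk (min recommended "
            f"{min_shared})",
            stacklevel=2,
        )
    b = np.zeros((len(genes), bulk_log.n_samples))
    for gi, g in enumerate(genes):
        if g in pos:
            b[gi] = bulk_log.values[pos[g]]

    sig_mat = np.column_stack([s.values for s in signatures])  # genes x k
    patient_norm = np.sqrt((b * b).sum(axis=0))
    valid = patient_norm > 0
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} patients have all-zero OR vectors; flagged",
            stacklevel=2,
        )
    sim = np.zeros((bulk_log.n_samples, len(signatures)))
    for si, s in enumerate(signatures):
        if np.all(s.values == 0):
            raise ValidationError(f"signature {s.cluster_id} is a zero vector")
    for pi in np.nonzero(valid)[0]:
        for si in range(len(signatures)):
            sim[pi, si] = cosine_similarity(sig_mat[:, si], b[:, pi])
    return SimilarityMatrix(
        sim, list(bulk_log.sample_ids), [s.cluster_id for s in signatures], valid
    )


def stratify_patients(
    sim: SimilarityMatrix, n_groups: int | str = "auto"
) -> SimilarityMatrix:
    """Group patients by Ward clustering of their similarity rows.

    ``n_groups='auto'`` silhouette-selects k in [2, 6].  Invalid patients
    (all-zero OR vectors) receive group -1.  Group ids are renumbered by
    first appearance so the labeling is deterministic.
    """
    rows = sim.values[sim.valid]
    n_valid = rows.shape[0]
    if isinstance(n_groups, int) and n_groups > n_valid:
        raise ValidationError("more groups requested than valid patients")
    groups = np.full(len(sim.patient_ids), -1, dtype=int)
    if n_groups == 1:
        groups[sim.valid] = 0
    else:
        dist = pdist(rows, metric="euclidean")
        link = sch.linkage(dist, method="ward")
        if n_groups == "auto":
            k = _auto_k(dist, link, range(2, min(7, n_valid)))
        else:
            k = int(n_groups)
        raw = sch.fcluster(link, k, criterion="maxclust")
        remap: dict[int, int] = {}
        for r in raw:
            if r not in remap:
                remap[r] = len(remap)
        groups[np.nonzero(sim.valid)[0]] = [remap[r] for r in raw]
    sim.groups = groups
    return sim
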