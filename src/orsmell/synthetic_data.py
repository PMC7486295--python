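"""Synthetic single-cell and bulk data with the statistical structure the
downstream analysis assumes.

The generative model, in brief:

* each cell carries a latent differentiation time t ~ Uniform(0, 1) and a
  stemness s = 1 - t + Gaussian noise, so stemness declines along the
  differentiation axis;
* the number of expressed functional olfactory receptors (ORs) per cell is
  Poisson with rate max(0, lambda0 + beta * s): a positive slope beta couples
  a rich OR repertoire to stem-like cells, beta = 0 is the "healthy" mode
  with no coupling;
* OR identities are drawn uniformly without replacement (stochastic
  selection), with intensities from the same log-normal family as expressed
  background genes;
* background genes have a per-gene detection probability (the zero spike of
  TPM data), cluster-specific mean shifts (discrete cell types along the
  axis), and a subset of "program" genes whose mean drifts linearly with t —
  the expression readout of the latent axis that makes trajectory inference
  possible.  Program genes that are high at t = 0 double as the stemness
  gene set for enrichment scoring;
* doublets are per-gene means of two random parents, renormalized (TPM is
  compositional, so mean vs sum is equivalent after renormalization);
* bulk patients are Dirichlet-weighted convex mixtures of cell-cluster
  signatures with multiplicative log-normal noise; the dominant signature is
  the truth group and drives an exponential survival time with optional
  uniform censoring.

Every output is fully determined by the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_catalog import ExpressionMatrix, GeneCatalog, SurvivalTable, TPM

#: chromosomes OR genes are placed on; chr11 carries the largest share
OR_CHROMOSOMES = (
    "chr11", "chr1", "chr3", "chr6", "chr7", "chr9", "chr12", "chr14", "chr17", "chr19",
)

TPM_TOTAL = 1_000_000.0


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int = 0
    n_cells: int = 1000
    n_background_genes: int = 600
    n_or_functional: int = 400
    n_or_pseudo: int = 600
    n_clusters: int = 4
    # OR repertoire model
    or_rate_base: float = 4.0       # lambda0: mean expressed ORs at stemness 0
    or_stemness_slope: float = 10.0  # beta: OR-count coupling to stemness
    stemness_noise_sd: float = 0.1
    # co-activation structure: each cluster prefers one OR subset; selection
    # stays stochastic but preferred ORs carry this relative weight
    or_cluster_bias: float = 30.0
    pseudogene_leak: float = 0.0    # per-cell expression prob. of a pseudogene
    # expression model (log2 TPM of expressed genes)
    mu_expr: float = 3.0
    sigma_expr: float = 1.5
    # dropout: P(detected) = logistic(steepness * (mean log2 TPM - midpoint)),
    # so lowly expressed genes are the ones that drop out, as in real data
    dropout_midpoint: float = 2.0
    dropout_steepness: float = 1.0
    cluster_marker_frac: float = 0.1
    cluster_marker_shift: float = 2.0
    program_frac: float = 0.1
    program_slope: float = 3.0
    # catalog
    chr11_prob: float = 0.4
    # doublets
    doublet_rate: float = 0.05
    # bulk cohort
    n_patients: int = 200
    dirichlet_concentration: float = 0.05
    hazards: tuple[float, ...] = (0.02, 0.06, 0.18)
    censoring_rate: float = 0.2
    bulk_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.or_rate_base <= 0:
            raise ValidationError("or_rate_base must be positive")
        if not (0 <= self.doublet_rate < 1):
            raise ValidationError("doublet_rate must be in [0, 1)")
        if not (0 <= self.censoring_rate <= 1):
            raise ValidationError("censoring_rate must be in [0, 1]")
        if any(h <= 0 for h in self.hazards):
            raise ValidationError("hazards must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        if "hazards" in kwargs:
            kwargs["hazards"] = tuple(kwargs["hazards"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hazards"] = list(d["hazards"])
        return d


@dataclass
class CellTruth:
    """Ground truth emitted alongside the simulated expression matrix."""

    latent_time: np.ndarray        # t_c
    stemness: np.ndarray           # s_c
    or_count: np.ndarray           # K_c
    cluster: np.ndarray            # integer stage labels along t
    expressed_ors: list[list[str]]
    stemness_genes: list[str]      # program genes high at t = 0
    cluster_marker_genes: dict[int, list[str]]
    is_doublet: np.ndarray | None = None

    def frame(self, sample_ids: list[str]) -> pd.DataFrame:
        t = pd.DataFrame(
            {
                "cell_id": sample_ids,
                "latent_time": self.latent_time,
                "stemness": self.stemness,
                "or_count": self.or_count,
                "cluster": self.cluster,
                "expressed_ors": [";".join(e) for e in self.expressed_ors],
            }
        )
        if self.is_doublet is not None:
            t["is_doublet"] = self.is_doublet.astype(int)
        return t


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, stream])


def simulate_catalog(config: SimulationConfig) -> GeneCatalog:
    """Generate an OR catalog: functional + pseudogene receptors with
    chromosome assignments enriched on chr11."""
    if config.n_or_functional <= 0 or config.n_or_pseudo < 0:
        raise ValidationError("OR counts must be positive")
    rng = _rng(config.seed, 0)
    n_f, n_p = config.n_or_functional, config.n_or_pseudo
    p_other = (1.0 - config.chr11_prob) / (len(OR_CHROMOSOMES) - 1)
    probs = [config.chr11_prob] + [p_other] * (len(OR_CHROMOSOMES) - 1)
    rows = []
    for i in range(n_f):
        rows.append(
            {
                "symbol": f"OR{i + 1}F",
                "family": "OR",
                "or_class": "ClassI" if rng.random() < 0.1 else "ClassII",
                "chromosome": rng.choice(OR_CHROMOSOMES, p=probs),
                "status": "functional",
            }
        )
    for i in range(n_p):
        rows.append(
            {
                "symbol": f"OR{i + 1}P",
                "family": "OR",
                "or_class": "",
                "chromosome": rng.choice(OR_CHROMOSOMES, p=probs),
                "status": "pseudogene",
            }
        )
    return GeneCatalog(pd.DataFrame(rows))


def simulate_cells(
    config: SimulationConfig, catalog: GeneCatalog | None = None
) -> tuple[ExpressionMatrix, CellTruth]:
    """Simulate a TPM single-cell matrix plus full ground truth."""
    if catalog is None:
        catalog = simulate_catalog(config)
    rng = _rng(config.seed, 1)
    n = config.n_cells
    n_bg = config.n_background_genes

    t = rng.uniform(0.0, 1.0, n)
    s = 1.0 - t + rng.normal(0.0, config.stemness_noise_sd, n)
    rate = config.or_rate_base + config.or_stemness_slope * s
    if np.all(rate < 0):
        raise ValidationError("OR rate is negative for every cell; check lambda0/beta")
    rate = np.clip(rate, 0.0, None)
    k = np.minimum(rng.poisson(rate), config.n_or_functional)
    # differentiation stages: equal-width segments of latent time
    edges = np.linspace(0.0, 1.0, config.n_clusters + 1)[1:-1]
    cluster = np.digitize(t, edges)

    # --- background genes -------------------------------------------------
    bg_names = [f"BG{i + 1}" for i in range(n_bg)]
    base_mu = rng.normal(config.mu_expr, 1.0, n_bg)

    n_marker = int(round(config.cluster_marker_frac * n_bg))
    marker_cluster = np.full(n_bg, -1)
    marker_cluster[:n_marker] = np.arange(n_marker) % config.n_clusters
    cluster_marker_genes = {
        c: [bg_names[g] for g in np.nonzero(marker_cluster == c)[0]]
        for c in range(config.n_clusters)
    }

    n_prog = int(round(config.program_frac * n_bg))
    prog_slope = np.zeros(n_bg)
    prog_idx = np.arange(n_marker, n_marker + n_prog)
    signs = np.where(np.arange(n_prog) % 2 == 0, -1.0, 1.0)  # half fall, half rise with t
    prog_slope[prog_idx] = signs * config.program_slope
    stemness_genes = [bg_names[g] for g in prog_idx[prog_slope[prog_idx] < 0]]

    mean = (
        base_mu[:, None]
        + config.cluster_marker_shift * (marker_cluster[:, None] == cluster[None, :])
        + prog_slope[:, None] * t[None, :]
    )
    # expression-dependent dropout: detection tracks the underlying mean, so
    # the zero pattern of marker/program genes carries their signal too
    detect_p = 1.0 / (1.0 + np.exp(-config.dropout_steepness * (mean - config.dropout_midpoint)))
    detected = rng.random((n_bg, n)) < detect_p
    log2_expr = rng.normal(mean, config.sigma_expr)
    bg = np.where(detected, np.exp2(log2_expr), 0.0)

    # --- OR genes ---------------------------------------------------------
    or_f = catalog.functional_ors()
    or_p = catalog.symbols(families={"OR"}, status={"pseudogene"})
    # per-cluster OR preference: cluster c's preferred subset is the c-th
    # stripe of the functional OR list (modular partition)
    or_cluster = np.arange(len(or_f)) % config.n_clusters
    orf = np.zeros((len(or_f), n))
    expressed: list[list[str]] = []
    for j in range(n):
        if k[j]:
            w = np.where(or_cluster == cluster[j], config.or_cluster_bias, 1.0)
            chosen = rng.choice(len(or_f), size=k[j], replace=False, p=w / w.sum())
        else:
            chosen = np.array([], int)
        names = sorted(or_f[i] for i in chosen)
        expressed.append(names)
        orf[chosen, j] = np.exp2(rng.normal(config.mu_expr, config.sigma_expr, k[j]))
    orp = np.zeros((len(or_p), n))
    if config.pseudogene_leak > 0 and or_p:
        leak = rng.random((len(or_p), n)) < config.pseudogene_leak
        orp = np.where(leak, np.exp2(rng.normal(config.mu_expr, config.sigma_expr, orp.shape)), 0.0)

    values = np.vstack([bg, orf, orp])
    values = values / values.sum(axis=0, keepdims=True) * TPM_TOTAL
    genes = bg_names + or_f + or_p
    sample_ids = [f"cell{j + 1}" for j in range(n)]
    meta = pd.DataFrame(
        {"dataset": "synthetic", "condition": "tumor-tissue", "cluster": cluster},
        index=sample_ids,
    )
    matrix = ExpressionMatrix(values, genes, sample_ids, TPM, meta)
    truth = CellTruth(t, s, k, cluster, expressed, stemness_genes, cluster_marker_genes)
    return matrix, truth


def inject_doublets(
    matrix: ExpressionMatrix,
    doublet_rate: float,
    seed: int,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Append floor(rate * n) synthetic doublets (parent means) to a TPM matrix.

    Returns the augmented matrix and a boolean label vector marking the
    appended doublets (singlets first, in original order).
    """
    if not (0 <= doublet_rate < 1):
        raise ValidationError("doublet_rate must be in [0, 1)")
    n = matrix.n_samples
    n_d = int(np.floor(doublet_rate * n))
    labels = np.zeros(n + n_d, dtype=bool)
    labels[n:] = True
    if n_d == 0:
        return matrix, labels[:n]
    if n < 2:
        raise ValidationError("need at least 2 parent cells to form doublets")
    rng = np.random.default_rng(seed)
    cols = []
    ids = []
    for i in range(n_d):
        a, b = rng.choice(n, size=2, replace=False)
        col = 0.5 * (matrix.values[:, a] + matrix.values[:, b])
        col = col / col.sum() * TPM_TOTAL
        cols.append(col)
        ids.append(f"doublet{i + 1}")
    values = np.column_stack([matrix.values] + [c[:, None] for c in cols])
    meta = None
    if matrix.sample_meta is not None:
        extra = pd.DataFrame(
            {c: pd.NA for c in matrix.sample_meta.columns}, index=ids
        )
        meta = pd.concat([matrix.sample_meta, extra])
    out = ExpressionMatrix(values, list(matrix.gene_ids), list(matrix.sample_ids) + ids,
                           matrix.scale, meta)
    return out, labels


def simulate_bulk_cohort(
    signatures: np.ndarray,
    gene_ids: list[str],
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, SurvivalTable, np.ndarray]:
    """Simulate a bulk cohort as noisy mixtures of cluster signatures.

    ``signatures`` is a genes x k non-negative matrix in TPM space.  Each
    patient draws Dirichlet mixture weights; the argmax weight is the truth
    group, which sets the exponential hazard (``config.hazards``, cyclic).
    With probability ``censoring_rate`` the observed time is Uniform(0, T)
    and the event indicator is 0.
    """
    signatures = np.asarray(signatures, dtype=float)
    if signatures.ndim != 2 or signatures.shape[1] < 2:
        raise ValidationError("need at least two signatures")
    if np.any(signatures < 0):
        raise ValidationError("signatures must be non-negative")
    k = signatures.shape[1]
    rng = np.random.default_rng(seed if seed is not None else [config.seed, 2])
    n_pat = config.n_patients
    alpha = np.full(k, config.dirichlet_concentration)
    weights = rng.dirichlet(alpha, size=n_pat)  # patients x k
    groups = np.argmax(weights, axis=1)
    values = signatures @ weights.T  # genes x patients
    if config.bulk_noise_sd > 0:
        values = values * np.exp2(rng.normal(0.0, config.bulk_noise_sd, values.shape))
    col_sums = values.sum(axis=0, keepdims=True)
    if np.any(col_sums == 0):
        raise ValidationError("a simulated patient has an all-zero profile")
    values = values / col_sums * TPM_TOTAL
    patient_ids = [f"patient{i + 1}" for i in range(n_pat)]
    bulk = ExpressionMatrix(values, list(gene_ids), patient_ids, TPM)

    hazards = np.array([config.hazards[g % len(config.hazards)] for g in groups])
    times = rng.exponential(1.0 / hazards)
    events = np.ones(n_pat, dtype=int)
    censor = rng.random(n_pat) < config.censoring_rate
    times = np.where(censor, rng.uniform(0.0, times), times)
    events[censor] = 0
    surv = SurvivalTable(
        pd.DataFrame(
            {"patient_id": patient_ids, "time": times, "event": events, "group": groups}
        )
    )
    return bulk, surv, groups
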