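"""zFPKM activation scoring.

The zFPKM transform standardizes log2 expression against the inactive
background of each cell: a kernel density estimate of the positive log2(TPM)
values locates the dominant expression peak mu, and the right tail above the
peak fits a half-Gaussian whose scale sigma converts distances from the peak
into z-scores, z = (log2(TPM) - mu) / sigma.  Genes with z above -3 are
conventionally called expressed/active.

Zero-TPM entries never enter the density fit and are assigned a -inf
sentinel.  This is the critical design choice of this module: fitting on the
full column would let the zero spike dominate the density peak and make
every detected gene look active.  With the sentinel, an entry of zero can
never be called active and a gene detected in fewer than half the cells has
a -inf median, hence is inactive at the dataset level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr  # noqa: F401  (used by callers cross-checking)

from .errors import FitError, ValidationError
from .io_catalog import ExpressionMatrix, GeneCatalog, TPM

#: activation threshold on the z scale; z strictly greater is "active"
DEFAULT_THRESHOLD = -3.0

_SQRT_HALF_PI = math.sqrt(math.pi / 2.0)


@dataclass
class ZScoreMatrix:
    """zFPKM values (genes x cells) with per-cell half-Gaussian fit parameters.

    ``z`` holds ``-inf`` sentinels wherever TPM was zero and for every entry
    of a cell that was skipped (too few positive genes to fit).
    """

    z: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    skipped_cells: list[str] = field(default_factory=list)


@dataclass
class ActivationMatrix:
    """Binary activation calls (genes x cells) at a fixed z threshold."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    threshold: float

    def restrict(self, genes: list[str]) -> "ActivationMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes if g in index]
        return ActivationMatrix(
            self.values[rows, :],
            [self.gene_ids[i] for i in rows],
            list(self.sample_ids),
            self.threshold,
        )


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, 0.9 min(sd, IQR/1.34) n^(-1/5).

    Falls back to the sd (then |x_0|, then 1) when the IQR collapses, matching
    the conventional guard for near-degenerate samples.
    """
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    lo = min(sd, iqr / 1.34) if iqr > 0 else sd
    if lo == 0:
        lo = abs(float(x[0])) or 1.0
    return 0.9 * lo * n ** (-0.2)


def kde_grid_density(
    x: np.ndarray, bandwidth: float, n_grid: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of ``x`` on an evenly spaced grid.

    The grid spans [min - 3h, max + 3h].  Returns (grid, density).
    """
    h = bandwidth
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, n_grid)
    u = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * u * u).sum(axis=1) / (len(x) * h * math.sqrt(2 * math.pi))
    return grid, dens


def fit_half_gaussian(x: np.ndarray, n_grid: int = 512) -> tuple[float, float]:
    """Fit (mu, sigma) of the zFPKM background to positive log2 values.

    mu is the KDE argmax; sigma is recovered from the mean U of the values
    above the peak through the half-Gaussian relation
    U - mu = sigma * sqrt(2/pi), i.e. sigma = (U - mu) * sqrt(pi/2).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2 or np.all(x == x[0]):
        raise FitError("degenerate expression column: no spread to fit")
    h = silverman_bandwidth(x)
    grid, dens = kde_grid_density(x, h, n_grid)
    mu = float(grid[int(np.argmax(dens))])
    tail = x[x > mu]
    if tail.size == 0:
        raise FitError("no values above the density peak; sigma undefined")
    sigma = (float(tail.mean()) - mu) * _SQRT_HALF_PI
    if sigma <= 0:
        raise FitError("non-positive sigma from half-Gaussian fit")
    return mu, sigma


def zfpkm_transform(
    matrix: ExpressionMatrix,
    min_positive: int = 50,
    n_grid: int = 512,
) -> ZScoreMatrix:
    """Per-cell zFPKM transform of a TPM matrix.

    Cells with fewer than ``min_positive`` positive entries are skipped with
    a warning (their column is all ``-inf`` and their fit parameters NaN).
    """
    if matrix.scale != TPM:
        raise ValidationError("zfpkm_transform expects a raw TPM matrix")
    values = matrix.values
    n_genes, n_cells = values.shape
    z = np.full((n_genes, n_cells), -np.inf)
    mu = np.full(n_cells, np.nan)
    sigma = np.full(n_cells, np.nan)
    skipped: list[str] = []
    for j in range(n_cells):
        col = values[:, j]
        pos = col > 0
        if int(pos.sum()) < min_positive:
            skipped.append(matrix.sample_ids[j])
            continue
        x = np.log2(col[pos])
        m, s = fit_half_gaussian(x, n_grid=n_grid)
        mu[j] = m
        sigma[j] = s
        z[pos, j] = (x - m) / s
    if skipped:
        warnings.warn(
            f"skipped zFPKM fit for {len(skipped)} cells with < {min_positive} "
            "positive genes",
            stacklevel=2,
        )
    return ZScoreMatrix(z, list(matrix.gene_ids), list(matrix.sample_ids), mu, sigma, skipped)


def call_active_genes(
    zmat: ZScoreMatrix, threshold: float = DEFAULT_THRESHOLD
) -> np.ndarray:
    """Gene-level activation: median z across cells strictly above threshold.

    Sentinels count as -inf, so a gene detected in fewer than half the cells
    can never be active.
    """
    with np.errstate(invalid="ignore"):
        med = np.median(zmat.z, axis=1)
    return med > threshold


def binarize_activation(
    zmat: ZScoreMatrix, threshold: float = DEFAULT_THRESHOLD
) -> ActivationMatrix:
    """Entry-level binarization: 1 iff z strictly above threshold.

    z exactly at the threshold maps to 0 (the boundary is inactive).
    """
    return ActivationMatrix(
        (zmat.z > threshold).astype(np.int8),
        list(zmat.gene_ids),
        list(zmat.sample_ids),
        threshold,
    )


def or_positive_cells(
    activation: ActivationMatrix, catalog: GeneCatalog
) -> tuple[np.ndarray, float]:
    """Per-cell flag for having >= 1 active functional OR, plus the percentage."""
    ors = catalog.functional_ors()
    block = activation.restrict(ors)
    if block.values.shape[0] == 0:
        raise ValidationError("no functional OR rows present in activation matrix")
    positive = block.values.sum(axis=0) >= 1
    return positive, 100.0 * float(positive.sum()) / len(positive)
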