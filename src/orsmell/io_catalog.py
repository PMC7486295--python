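"""Domain containers and file IO for expression matrices, gene catalogs,
survival tables and gene sets.

The on-disk contracts are deliberately plain: dense TSV/CSV with gene symbols
in the first column and sample ids in the header, Matrix Market triplets with
``genes.tsv``/``barcodes.tsv`` companions, tab-separated catalogs and survival
tables, and GMT gene-set files.  Gene identity is by case-sensitive symbol
string throughout; no alias resolution is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError, ValidationError

#: scale tags for ExpressionMatrix.values
TPM = "TPM"
LOG2_TPM1 = "LOG2_TPM1"
_SCALES = (TPM, LOG2_TPM1)

#: closed chemoreceptor family vocabulary
FAMILIES = ("OR", "TAAR", "V1R", "V2R", "T1R", "T2R")
STATUSES = ("functional", "pseudogene")
OR_CLASSES = ("ClassI", "ClassII", "")

CATALOG_COLUMNS = ["symbol", "family", "or_class", "chromosome", "status"]
SURVIVAL_COLUMNS = ["patient_id", "time", "event"]


@dataclass
class ExpressionMatrix:
    """A non-negative genes x samples abundance matrix.

    Parameters
    ----------
    values
        2-D float array, genes in rows, samples in columns.
    gene_ids, sample_ids
        Unique, ordered row/column identifiers.
    scale
        Either ``"TPM"`` or ``"LOG2_TPM1"``.
    sample_meta
        Optional per-sample metadata (dataset, condition, subtype, cluster),
        indexed by sample id.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    scale: str = TPM
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids are not unique")
        if self.scale not in _SCALES:
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        if self.sample_meta is not None and len(self.sample_meta) != self.n_samples:
            raise ValidationError("sample_meta length does not match samples")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_rows(self, rows: np.ndarray | list[int]) -> "ExpressionMatrix":
        rows = np.asarray(rows, dtype=int)
        return ExpressionMatrix(
            self.values[rows, :],
            [self.gene_ids[i] for i in rows],
            list(self.sample_ids),
            self.scale,
            self.sample_meta,
        )

    def subset_samples(self, cols: np.ndarray | list[int]) -> "ExpressionMatrix":
        cols = np.asarray(cols, dtype=int)
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.iloc[cols]
        return ExpressionMatrix(
            self.values[:, cols],
            list(self.gene_ids),
            [self.sample_ids[i] for i in cols],
            self.scale,
            meta,
        )

    def log2_tpm1(self) -> "ExpressionMatrix":
        """Return the matrix on the log2(TPM+1) scale (no-op if already there)."""
        if self.scale == LOG2_TPM1:
            return self
        return ExpressionMatrix(
            np.log2(self.values + 1.0),
            list(self.gene_ids),
            list(self.sample_ids),
            LOG2_TPM1,
            self.sample_meta,
        )


@dataclass
class GeneCatalog:
    """Chemoreceptor annotation table (symbol, family, or_class, chromosome, status)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in CATALOG_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"catalog is missing columns {missing}")
        t = t[CATALOG_COLUMNS].copy()
        t["or_class"] = t["or_class"].fillna("")
        if t["symbol"].duplicated().any():
            dup = t.loc[t["symbol"].duplicated(), "symbol"].iloc[0]
            raise ValidationError(f"duplicate catalog symbol {dup!r}")
        bad_family = set(t["family"]) - set(FAMILIES)
        if bad_family:
            raise ValidationError(f"unknown chemoreceptor family {sorted(bad_family)}")
        bad_status = set(t["status"]) - set(STATUSES)
        if bad_status:
            raise ValidationError(f"unknown gene status {sorted(bad_status)}")
        bad_class = set(t["or_class"].astype(str)) - set(OR_CLASSES)
        if bad_class:
            raise ValidationError(f"unknown OR class {sorted(bad_class)}")
        if (t["chromosome"].astype(str).str.len() == 0).any():
            raise ValidationError("empty chromosome name in catalog")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def symbols(
        self,
        families: set[str] | None = None,
        status: set[str] | None = None,
    ) -> list[str]:
        """Symbols matching a family/status selection, in catalog order."""
        t = self.table
        mask = pd.Series(True, index=t.index)
        if families is not None:
            mask &= t["family"].isin(families)
        if status is not None:
            mask &= t["status"].isin(status)
        return list(t.loc[mask, "symbol"])

    def functional_ors(self) -> list[str]:
        return self.symbols(families={"OR"}, status={"functional"})


@dataclass
class SurvivalTable:
    """Right-censored time-to-event records, one row per patient."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in SURVIVAL_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"survival table is missing columns {missing}")
        if "group" not in t.columns:
            t = t.copy()
            t["group"] = pd.NA
        t = t[SURVIVAL_COLUMNS + ["group"]].copy()
        if t["patient_id"].duplicated().any():
            raise ValidationError("duplicate patient_id in survival table")
        if (t["time"] < 0).any():
            raise ValidationError("negative survival time")
        if not set(t["event"].astype(int)) <= {0, 1}:
            raise ValidationError("event indicator must be 0 or 1")
        t["event"] = t["event"].astype(int)
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def with_groups(self, groups: pd.Series | dict) -> "SurvivalTable":
        t = self.table.copy()
        if isinstance(groups, dict):
            t["group"] = t["patient_id"].map(groups)
        else:
            t["group"] = t["patient_id"].map(groups.to_dict())
        return SurvivalTable(t)


@dataclass
class ValidationReport:
    """Outcome of the minimum-cell-count dataset gate."""

    passed: bool
    n_samples: int
    min_cells: int
    message: str = ""


# ---------------------------------------------------------------------------
# expression matrix IO
# ---------------------------------------------------------------------------

def _dedupe(values: np.ndarray, genes: list[str], policy: str) -> tuple[np.ndarray, list[str]]:
    seen: dict[str, int] = {}
    order: list[str] = []
    for g in genes:
        if g in seen:
            if policy != "sum":
                raise ValidationError(
                    f"duplicate gene symbol {g!r}; pass dedupe='sum' to aggregate"
                )
        else:
            seen[g] = len(order)
            order.append(g)
    if len(order) == len(genes):
        return values, genes
    out = np.zeros((len(order), values.shape[1]))
    for row, g in zip(values, genes):
        out[seen[g]] += row
    return out, order


def load_expression(
    path: str | Path,
    format: str = "tsv",
    scale: str = TPM,
    dedupe: str = "error",
    genes_file: str | Path | None = None,
    barcodes_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Load a genes x samples expression matrix.

    ``format`` is one of ``mtx`` (Matrix Market triplet with ``genes.tsv`` /
    ``barcodes.tsv`` companions next to the matrix unless paths are given),
    ``tsv`` or ``csv`` (dense, sample ids in the header, gene symbols in the
    first column).  Negative entries and dimension mismatches raise
    :class:`FormatError`; duplicate gene symbols raise
    :class:`ValidationError` unless ``dedupe='sum'``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx":
        genes_file = Path(genes_file) if genes_file else path.parent / "genes.tsv"
        barcodes_file = Path(barcodes_file) if barcodes_file else path.parent / "barcodes.tsv"
        for companion in (genes_file, barcodes_file):
            if not companion.exists():
                raise FileNotFoundError(companion)
        mat = scipy.io.mmread(str(path))
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        genes = [line.split("\t")[0] for line in _read_lines(genes_file)]
        samples = [line.split("\t")[0] for line in _read_lines(barcodes_file)]
        if values.shape != (len(genes), len(samples)):
            raise FormatError(
                f"matrix shape {values.shape} does not match {len(genes)} genes "
                f"and {len(samples)} barcodes"
            )
    elif format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        frame = pd.read_csv(path, sep=sep, index_col=0)
        values = frame.to_numpy(dtype=float)
        genes = [str(g) for g in frame.index]
        samples = [str(s) for s in frame.columns]
    else:
        raise FormatError(f"unknown matrix format {format!r}")
    if np.any(values < 0):
        raise FormatError("negative expression value in input matrix")
    values, genes = _dedupe(values, genes, dedupe)
    return ExpressionMatrix(values, genes, samples, scale)


def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def write_matrix(matrix: ExpressionMatrix, path: str | Path, format: str = "tsv") -> Path:
    """Write a matrix so that :func:`load_expression` round-trips it."""
    if matrix.n_samples == 0 or matrix.n_genes == 0:
        raise ValidationError("refusing to write an empty matrix")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.values))
        (path.parent / "genes.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
        (path.parent / "barcodes.tsv").write_text("\n".join(matrix.sample_ids) + "\n")
    elif format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        matrix.to_frame().to_csv(path, sep=sep, index_label="gene")
    else:
        raise FormatError(f"unknown matrix format {format!r}")
    return path


# ---------------------------------------------------------------------------
# catalog / survival / gene sets
# ---------------------------------------------------------------------------

def load_catalog(path: str | Path) -> GeneCatalog:
    return GeneCatalog(pd.read_csv(path, sep="\t", dtype=str))


def write_catalog(catalog: GeneCatalog, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    catalog.table.to_csv(path, sep="\t", index=False)
    return path


def load_survival(path: str | Path) -> SurvivalTable:
    t = pd.read_csv(path, sep="\t")
    return SurvivalTable(t)


def write_survival(table: SurvivalTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.table.to_csv(path, sep="\t", index=False)
    return path


def load_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file (name, description, tab-separated members)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            name = fields[0]
            if name in sets:
                raise FormatError(f"duplicate gene-set name {name!r} in GMT")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")
    return path


# ---------------------------------------------------------------------------
# catalog-aware matrix operations
# ---------------------------------------------------------------------------

def subset_genes(
    matrix: ExpressionMatrix,
    catalog: GeneCatalog,
    families: set[str],
    status: set[str] | None = None,
) -> ExpressionMatrix:
    """Restrict matrix rows to catalog members of the given families/status.

    Row order of the matrix is preserved.  Catalog genes absent from the
    matrix are reported with a warning, never an error; an empty intersection
    yields a 0-row matrix with a warning.
    """
    if not families:
        raise ValidationError("family selection must be non-empty")
    wanted = set(catalog.symbols(families=families, status=status))
    missing = wanted - set(matrix.gene_ids)
    if missing:
        warnings.warn(
            f"{len(missing)} selected catalog genes absent from matrix", stacklevel=2
        )
    rows = [i for i, g in enumerate(matrix.gene_ids) if g in wanted]
    if not rows:
        warnings.warn("gene selection has empty intersection with matrix", stacklevel=2)
        return ExpressionMatrix(
            np.zeros((0, matrix.n_samples)),
            [],
            list(matrix.sample_ids),
            matrix.scale,
            matrix.sample_meta,
        )
    return matrix.subset_rows(rows)


def validate_dataset(matrix: ExpressionMatrix, min_cells: int = 60) -> ValidationReport:
    """Dataset inclusion gate: at least ``min_cells`` samples (inclusive)."""
    passed = matrix.n_samples >= min_cells
    msg = (
        f"{matrix.n_samples} cells >= required {min_cells}"
        if passed
        else f"{matrix.n_samples} cells < required {min_cells}"
    )
    return ValidationReport(passed, matrix.n_samples, min_cells, msg)


def chromosome_summary(catalog: GeneCatalog, detected_genes: set[str]) -> pd.DataFrame:
    """Per-chromosome counts of catalog genes and of those detected.

    Returns one row per chromosome present in the catalog, with columns
    ``chromosome, n_catalog, n_detected, fraction_detected``.  Detected genes
    not present in the catalog are reported with a warning and ignored.
    """
    unknown = set(detected_genes) - set(catalog.table["symbol"])
    if unknown:
        warnings.warn(
            f"{len(unknown)} detected genes are not in the catalog", stacklevel=2
        )
    t = catalog.table
    rows = []
    for chrom, sub in t.groupby("chromosome", sort=True):
        n_cat = len(sub)
        n_det = int(sub["symbol"].isin(detected_genes).sum())
        rows.append(
            {
                "chromosome": chrom,
                "n_catalog": n_cat,
                "n_detected": n_det,
                "fraction_detected": n_det / n_cat if n_cat else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["chromosome", "n_catalog", "n_detected", "fraction_detected"])
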