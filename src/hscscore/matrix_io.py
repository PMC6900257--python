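"""Containers and file I/O for count matrices, gene sets, scores and scorers.

The in-memory convention is fixed: count matrices are oriented cells x genes,
counts are non-negative integers, and identifiers are unique strings matched
case-sensitively.  Readers normalize whatever orientation is on disk to that
convention or raise.

Supported formats
-----------------
* MatrixMarket coordinate triplets with one-entry-per-line gene and barcode
  sidecars (the 10x v2 layout; indices 1-based on disk, 0-based in memory).
* Dense TSV/CSV with a header row and an index column, either orientation.
* Two-column signed gene set TSV (gene id, sign token).
* Score tables as TSV (cell_id, hsc_score[, group_label]).
* Trained scorer archives: a zip container holding a JSON manifest
  (version, feature list, normalization target, scaler statistics, optional
  PCA basis, model family and hyperparameters) plus the pickled fitted
  regressor.  Archives are written deterministically (fixed timestamps) so
  identical scorers serialize to identical bytes.
"""

from __future__ import annotations

import io
import json
import pickle
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .exceptions import FormatError, ValidationError
from .geneset import SignedGeneSet

__all__ = [
    "CountMatrix",
    "ScoreTable",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_dense_counts",
    "read_signed_gene_set",
    "write_signed_gene_set",
    "read_score_table",
    "write_score_table",
    "save_scorer",
    "load_scorer",
]

SCORER_FORMAT_VERSION = 1


def _check_unique(ids: list[str], axis: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = [i for i in ids if i in seen or seen.add(i)]  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {axis} ids, e.g. {dup[:5]}")


@dataclass
class CountMatrix:
    """Cells x genes matrix of non-negative integer counts.

    ``cell_meta`` optionally carries per-cell QC metadata
    (``total_mapped_reads``, ``spikein_counts``) and/or a ``group_label``
    column; its index must equal ``cell_ids``.
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.size and np.issubdtype(counts.dtype, np.floating):
            if not np.all(np.isfinite(counts)):
                raise ValidationError("counts contain NaN or infinite entries")
            if not np.all(counts == np.floor(counts)):
                raise ValidationError("counts must be integral")
        elif not np.issubdtype(counts.dtype, np.integer) and counts.size:
            raise ValidationError(f"counts have non-numeric dtype {counts.dtype}")
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != self.counts.shape[0]:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {self.counts.shape[0]} rows"
            )
        if len(self.gene_ids) != self.counts.shape[1]:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {self.counts.shape[1]} columns"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if self.cell_meta is not None:
            if list(map(str, self.cell_meta.index)) != self.cell_ids:
                raise ValidationError("cell_meta index does not match cell_ids")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, indices) -> "CountMatrix":
        indices = np.asarray(indices)
        meta = self.cell_meta.iloc[indices] if self.cell_meta is not None else None
        return CountMatrix(
            counts=self.counts[indices],
            cell_ids=[self.cell_ids[i] for i in indices],
            gene_ids=list(self.gene_ids),
            cell_meta=meta,
        )

    def gene_indexer(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class ScoreTable:
    """Per-cell continuous HSC score; unbounded, negative values legal."""

    cell_ids: list[str]
    score: np.ndarray
    group_label: list[str] | None = None

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.score = np.asarray(self.score, dtype=float)
        if self.score.ndim != 1 or len(self.score) != len(self.cell_ids):
            raise ValidationError("need exactly one score per cell")
        if not np.all(np.isfinite(self.score)):
            raise ValidationError("scores must be finite")
        _check_unique(self.cell_ids, "cell")
        if self.group_label is not None:
            self.group_label = [str(g) for g in self.group_label]
            if len(self.group_label) != len(self.cell_ids):
                raise ValidationError("group_label length mismatch")

    def to_frame(self) -> pd.DataFrame:
        data = {"cell_id": self.cell_ids, "hsc_score": self.score}
        if self.group_label is not None:
            data["group_label"] = self.group_label
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# count matrices


def _read_sidecar(path) -> list[str]:
    """First tab-separated field of each non-empty line (10x sidecar style)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


def read_mtx_triplet(
    matrix_path,
    genes_path,
    barcodes_path,
    genes_in_rows: bool | None = None,
) -> CountMatrix:
    """Read a MatrixMarket triplet with gene/barcode sidecars.

    Orientation on disk is inferred from the sidecar lengths; when the matrix
    is square with equally long sidecars the ``genes_in_rows`` flag must be
    given explicitly.
    """
    try:
        mat = scipy_io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    genes = _read_sidecar(genes_path)
    barcodes = _read_sidecar(barcodes_path)
    mat = sparse.coo_matrix(mat)
    n_rows, n_cols = mat.shape
    if n_rows == len(genes) and n_cols == len(barcodes):
        if n_rows == n_cols and len(genes) == len(barcodes):
            if genes_in_rows is None:
                raise FormatError(
                    "square matrix with equal sidecar lengths: pass genes_in_rows"
                )
            oriented = mat.T if genes_in_rows else mat
        else:
            oriented = mat.T  # 10x convention: genes in rows
    elif n_rows == len(barcodes) and n_cols == len(genes):
        oriented = mat
    else:
        raise FormatError(
            f"matrix is {n_rows}x{n_cols} but sidecars list "
            f"{len(genes)} genes and {len(barcodes)} barcodes"
        )
    dense = np.asarray(oriented.todense())
    return CountMatrix(counts=dense, cell_ids=barcodes, gene_ids=genes)


def write_mtx_triplet(cm: CountMatrix, matrix_path, genes_path, barcodes_path) -> None:
    """Write a CountMatrix as a 10x-style triplet (genes in rows on disk)."""
    scipy_io.mmwrite(str(matrix_path), sparse.coo_matrix(cm.counts.T))
    Path(genes_path).write_text("".join(g + "\n" for g in cm.gene_ids))
    Path(barcodes_path).write_text("".join(b + "\n" for b in cm.cell_ids))


def read_dense_counts(path, genes_in_rows: bool = False) -> CountMatrix:
    """Read a dense TSV/CSV count table (header row + index column)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    columns = header[1:]  # first field is the index-column label
    if len(set(columns)) != len(columns):  # pandas would silently rename these
        raise ValidationError("duplicate ids in header row")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        raise ValidationError("duplicate ids in index column")
    if df.isna().any().any():
        raise ValidationError("table contains missing values")
    if genes_in_rows:
        df = df.T
    return CountMatrix(
        counts=df.to_numpy(),
        cell_ids=[str(i) for i in df.index],
        gene_ids=[str(c) for c in df.columns],
    )


# ---------------------------------------------------------------------------
# signed gene sets

_POS_TOKENS = {"+1", "+", "1", "molo", "pos", "positive"}
_NEG_TOKENS = {"-1", "−1", "-", "nomo", "neg", "negative"}


def read_signed_gene_set(path) -> SignedGeneSet:
    """Read a two-column TSV of (gene id, sign token).

    Sign tokens: ``+1``/``+``/``MolO`` for positive, ``-1``/``-``/``NoMO``
    for negative (case-insensitive labels).
    """
    positive: list[str] = []
    negative: list[str] = []
    signs: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 2 tab-separated columns")
            gene, token = parts[0].strip(), parts[1].strip()
            if token.lower() in _POS_TOKENS:
                sign = 1
            elif token.lower() in _NEG_TOKENS:
                sign = -1
            else:
                raise FormatError(f"{path}:{ln}: unknown sign token {token!r}")
            if gene in signs:
                if signs[gene] != sign:
                    raise ValidationError(f"gene {gene!r} listed with both signs")
                continue
            signs[gene] = sign
            (positive if sign > 0 else negative).append(gene)
    if not positive and not negative:
        warnings.warn(f"gene set file {path} is empty", stacklevel=2)
    return SignedGeneSet(positive_genes=positive, negative_genes=negative)


def write_signed_gene_set(gene_set: SignedGeneSet, path) -> None:
    with open(path, "w") as fh:
        for g in gene_set.positive_genes:
            fh.write(f"{g}\t+1\n")
        for g in gene_set.negative_genes:
            fh.write(f"{g}\t-1\n")


# ---------------------------------------------------------------------------
# score tables


def write_score_table(table: ScoreTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_score_table(path) -> ScoreTable:
    df = pd.read_csv(path, sep="\t")
    if "cell_id" not in df.columns or "hsc_score" not in df.columns:
        raise FormatError(f"{path}: expected columns cell_id and hsc_score")
    group = df["group_label"].astype(str).tolist() if "group_label" in df.columns else None
    return ScoreTable(
        cell_ids=df["cell_id"].astype(str).tolist(),
        score=df["hsc_score"].to_numpy(dtype=float),
        group_label=group,
    )


# ---------------------------------------------------------------------------
# trained scorer archives

_MANIFEST_REQUIRED = {
    "format_version",
    "feature_mode",
    "resolved_genes",
    "normalization",
    "scaler",
    "model",
}


def save_scorer(scorer, path) -> None:
    """Serialize a fitted scorer to a deterministic zip archive.

    The archive holds ``manifest.json`` (all pipeline state except the raw
    model weights, as plain JSON) and ``model.pkl`` (the pickled fitted
    regressor).  Timestamps are fixed so that identical scorers produce
    byte-identical archives.
    """
    from .scorer import HscScorer  # late import: io layer stays model-agnostic

    if not isinstance(scorer, HscScorer):
        raise ValidationError("save_scorer expects an HscScorer")
    if not hasattr(scorer, "model_"):
        raise ValidationError("scorer is not fitted")

    norm = {"method": scorer.normalization_.method}
    if scorer.normalization_.target_total is not None:
        norm["target_total"] = float(scorer.normalization_.target_total)
    manifest = {
        "format_version": SCORER_FORMAT_VERSION,
        "feature_mode": scorer.feature_mode,
        "resolved_genes": list(scorer.resolved_genes_),
        "gene_set": (
            {
                "positive": list(scorer.gene_set_.positive_genes),
                "negative": list(scorer.gene_set_.negative_genes),
            }
            if scorer.gene_set_ is not None
            else None
        ),
        "normalization": norm,
        "scaler": {
            "mean": scorer.scaler_.mean.tolist(),
            "std": scorer.scaler_.std.tolist(),
            "zero_variance": scorer.scaler_.zero_variance.tolist(),
        },
        "pca": (
            {
                "mean": scorer.pca_.mean.tolist(),
                "components": scorer.pca_.component_matrix.tolist(),
                "explained_variance": scorer.pca_.explained_variance.tolist(),
            }
            if scorer.pca_ is not None
            else None
        ),
        "model": {
            "family": scorer.model_family,
            "params": _jsonable(scorer.best_params_),
        },
        "params": _jsonable(scorer.get_params(deep=False)),
        "provenance": _jsonable(scorer.provenance_),
    }
    payload = pickle.dumps(scorer.model_, protocol=5)
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", compression=zipfile.ZIP_STORED) as zf:
        for name, data in (
            ("manifest.json", json.dumps(manifest, indent=1, sort_keys=True).encode()),
            ("model.pkl", payload),
        ):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, data)
    Path(path).write_bytes(buf.getvalue())


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays and tuples to JSON-safe types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return repr(obj)


def load_scorer(path):
    """Load a scorer archive written by :func:`save_scorer`."""
    from .geneset import SignedGeneSet
    from .preprocess import NormalizationSpec, PCAProjection, ScalerParams
    from .scorer import HscScorer

    try:
        with zipfile.ZipFile(path) as zf:
            names = set(zf.namelist())
            if "manifest.json" not in names or "model.pkl" not in names:
                raise FormatError(f"{path}: not a scorer archive")
            manifest = json.loads(zf.read("manifest.json"))
            payload = zf.read("model.pkl")
    except zipfile.BadZipFile as exc:
        raise FormatError(f"{path}: not a scorer archive: {exc}") from exc

    missing = _MANIFEST_REQUIRED - set(manifest)
    if missing:
        raise FormatError(f"{path}: manifest missing entries {sorted(missing)}")
    version = manifest["format_version"]
    if version != SCORER_FORMAT_VERSION:
        raise FormatError(
            f"{path}: archive format version {version} != supported "
            f"{SCORER_FORMAT_VERSION}"
        )
    scaler_entry = manifest["scaler"]
    if not isinstance(scaler_entry, dict) or {"mean", "std"} - set(scaler_entry):
        raise FormatError(f"{path}: scaler statistics missing or incomplete")

    params = {k: v for k, v in manifest.get("params", {}).items()}
    # JSON turns tuples into lists; the grid entries that need tuples are
    # restored by the model params below, the constructor args are tolerant.
    params.pop("gene_set", None)
    params.pop("param_grid", None)
    scorer = HscScorer(**params)
    scorer.feature_mode = manifest["feature_mode"]
    scorer.resolved_genes_ = list(manifest["resolved_genes"])
    gs = manifest.get("gene_set")
    scorer.gene_set_ = (
        SignedGeneSet(gs["positive"], gs["negative"]) if gs else None
    )
    norm = manifest["normalization"]
    scorer.normalization_ = NormalizationSpec(
        method=norm["method"], target_total=norm.get("target_total")
    )
    scorer.scaler_ = ScalerParams(
        mean=np.asarray(scaler_entry["mean"], dtype=float),
        std=np.asarray(scaler_entry["std"], dtype=float),
        zero_variance=np.asarray(
            scaler_entry.get("zero_variance", np.zeros(len(scaler_entry["mean"]))),
            dtype=bool,
        ),
    )
    pca = manifest.get("pca")
    scorer.pca_ = (
        PCAProjection(
            mean=np.asarray(pca["mean"], dtype=float),
            component_matrix=np.asarray(pca["components"], dtype=float),
            explained_variance=np.asarray(pca["explained_variance"], dtype=float),
        )
        if pca
        else None
    )
    scorer.model_family = manifest["model"]["family"]
    scorer.best_params_ = manifest["model"]["params"]
    scorer.model_ = pickle.loads(payload)
    scorer.provenance_ = manifest.get("provenance", {})
    return scorer
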