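"""Cell-by-gene matrices with subject/condition metadata: IO, QC, normalization.

The pipeline currency is :class:`CellMatrix`, a validated wrapper around an
:class:`anndata.AnnData` whose ``X`` holds raw counts (cells x genes) and whose
``obs`` carries the four metadata fields every downstream stage needs:
``subject_id``, ``condition`` ("case"/"control"), ``cell_type``, ``dataset_id``.
Log-normalized expression lives in ``layers["lognorm"]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.model_selection import train_test_split

REQUIRED_OBS = ("subject_id", "condition", "cell_type", "dataset_id")
CONDITIONS = ("case", "control")
LOGNORM = "lognorm"

DEFAULT_MITO_PREFIXES = ("MT-",)
DEFAULT_RIBO_PREFIXES = ("RPS", "RPL")


class SchemaError(ValueError):
    """A required metadata column or gene/cell identifier is missing or invalid."""


class FormatError(ValueError):
    """On-disk files disagree with each other (dimension / barcode mismatch)."""


class EmptyResultError(ValueError):
    """An operation removed every cell."""


@dataclass(frozen=True)
class QCThresholds:
    """Per-cell quality-control thresholds.

    ``max_pct_mito`` / ``max_pct_ribo`` follow the strict-exclusion convention:
    cells with strictly more than the threshold percentage of mitochondrial or
    ribosomal counts are removed. ``max_features=None`` means unbounded.
    """

    min_umi: int = 0
    min_features: int = 0
    max_features: int | None = None
    max_pct_mito: float = 10.0
    max_pct_ribo: float = 10.0

    def __post_init__(self) -> None:
        if self.max_features is not None and self.min_features > self.max_features:
            raise ValueError("min_features must be <= max_features")
        for name in ("max_pct_mito", "max_pct_ribo"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")


class CellMatrix:
    """Validated cells x genes count matrix with per-cell metadata.

    Parameters
    ----------
    adata
        AnnData with raw counts in ``X`` and the four required ``obs`` columns.
    validate
        Run invariant checks on construction (default True).
    """

    def __init__(self, adata: ad.AnnData, validate: bool = True):
        self.adata = adata
        if validate:
            self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        a = self.adata
        for col in REQUIRED_OBS:
            if col not in a.obs.columns:
                raise SchemaError(f"missing required metadata column: {col!r}")
            if a.obs[col].isna().any():
                raise SchemaError(f"metadata column {col!r} contains missing values")
        bad = set(map(str, a.obs["condition"].unique())) - set(CONDITIONS)
        if bad:
            raise SchemaError(f"condition values must be in {CONDITIONS}, got {sorted(bad)}")
        if a.obs_names.duplicated().any():
            raise SchemaError("duplicate cell identifiers")
        if a.var_names.duplicated().any():
            raise SchemaError("duplicate gene identifiers")
        X = a.X
        data = X.data if sp.issparse(X) else np.asarray(X)
        if data.size and (not np.all(np.isfinite(data)) or np.min(data) < 0):
            raise SchemaError("counts must be finite and non-negative")
        if LOGNORM in a.layers and a.layers[LOGNORM].shape != a.shape:
            raise SchemaError("lognorm layer shape differs from counts")

    # -- accessors ----------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def n_genes(self) -> int:
        return self.adata.n_vars

    @property
    def shape(self) -> tuple[int, int]:
        return self.adata.shape

    @property
    def gene_ids(self) -> pd.Index:
        return self.adata.var_names

    @property
    def cell_ids(self) -> pd.Index:
        return self.adata.obs_names

    @property
    def obs(self) -> pd.DataFrame:
        return self.adata.obs

    def counts(self, genes: Sequence[str] | None = None) -> np.ndarray:
        """Raw counts as a dense array, optionally restricted to ``genes``."""
        X = self.adata.X if genes is None else self.adata[:, list(genes)].X
        return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)

    def lognorm(self, genes: Sequence[str] | None = None) -> np.ndarray:
        """Log-normalized expression (requires :func:`normalize_log` first)."""
        if LOGNORM not in self.adata.layers:
            raise ValueError("no normalized layer; call normalize_log first")
        sub = self.adata if genes is None else self.adata[:, list(genes)]
        L = sub.layers[LOGNORM]
        return np.asarray(L.todense()) if sp.issparse(L) else np.asarray(L)

    def labels(self) -> np.ndarray:
        """Condition labels per cell as a string array ("case"/"control")."""
        return self.adata.obs["condition"].to_numpy(dtype=object)

    def subset_cells(self, mask_or_index) -> "CellMatrix":
        return CellMatrix(self.adata[mask_or_index].copy(), validate=False)

    def subset_cell_type(self, cell_type: str) -> "CellMatrix":
        mask = (self.obs["cell_type"] == cell_type).to_numpy()
        if not mask.any():
            raise ValueError(f"cell type {cell_type!r} absent from matrix")
        return self.subset_cells(mask)

    def copy(self) -> "CellMatrix":
        return CellMatrix(self.adata.copy(), validate=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CellMatrix({self.n_cells} cells x {self.n_genes} genes, "
            f"{self.obs['subject_id'].nunique()} subjects)"
        )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def load_matrix(path: str | Path, format: str = "mtx_dir",
                metadata: str | Path | None = None) -> CellMatrix:
    """Load a cells x genes count matrix plus per-cell metadata.

    ``mtx_dir`` expects the 10x-style triplet layout inside ``path``:
    ``matrix.mtx`` (genes x cells), ``features.tsv`` (gene ids), and
    ``barcodes.tsv`` (cell ids), plus a ``metadata.tsv`` (or the file named by
    ``metadata``) keyed by barcode with the four required columns. ``table``
    expects a single TSV with cells as rows, a leading barcode column, gene
    columns, and the same metadata file.
    """
    path = Path(path)
    if format == "mtx_dir":
        mtx, feats, barcs = path / "matrix.mtx", path / "features.tsv", path / "barcodes.tsv"
        for f in (mtx, feats, barcs):
            if not f.exists():
                raise FileNotFoundError(f)
        M = sp.csr_matrix(mmread(mtx)).T  # stored genes x cells -> cells x genes
        genes = pd.read_csv(feats, sep="\t", header=None)[0].astype(str)
        cells = pd.read_csv(barcs, sep="\t", header=None)[0].astype(str)
        if M.shape != (len(cells), len(genes)):
            raise FormatError(
                f"matrix shape {M.shape} does not match "
                f"{len(cells)} barcodes x {len(genes)} features"
            )
    elif format == "table":
        df = pd.read_csv(path, sep="\t", index_col=0)
        M = df.to_numpy()
        genes = pd.Series(df.columns.astype(str))
        cells = pd.Series(df.index.astype(str))
    else:
        raise ValueError(f"unknown format {format!r}")

    meta_path = Path(metadata) if metadata is not None else (
        path / "metadata.tsv" if format == "mtx_dir" else path.with_suffix(".metadata.tsv")
    )
    if not meta_path.exists():
        raise FileNotFoundError(meta_path)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    missing_cols = [c for c in REQUIRED_OBS if c not in meta.columns]
    if missing_cols:
        raise SchemaError(f"metadata missing required column(s): {missing_cols}")
    missing_cells = set(cells) - set(meta.index.astype(str))
    if missing_cells:
        raise FormatError(
            f"metadata does not cover {len(missing_cells)} barcode(s), "
            f"e.g. {sorted(missing_cells)[:3]}"
        )
    obs = meta.loc[list(cells), list(REQUIRED_OBS)].copy()
    obs.index = pd.Index(cells, name="cell_id")
    adata = ad.AnnData(X=M, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene_id")))
    return CellMatrix(adata)


def write_matrix(m: CellMatrix, path: str | Path) -> None:
    """Write ``m`` in the mtx_dir layout :func:`load_matrix` reads back."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = m.adata.X
    M = sp.coo_matrix(X.T if sp.issparse(X) else np.asarray(X).T)
    mmwrite(path / "matrix.mtx", M)
    pd.Series(m.gene_ids).to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    m.obs[list(REQUIRED_OBS)].to_csv(path / "metadata.tsv", sep="\t", index_label="cell_id")


def write_qc_report(m: CellMatrix, path: str | Path) -> None:
    """Write the (criterion, cells_removed) QC report attached by qc_filter."""
    report = m.adata.uns.get("qc_report")
    if report is None:
        raise ValueError("matrix carries no QC report; run qc_filter first")
    pd.DataFrame(
        {"criterion": list(report), "cells_removed": list(report.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC / normalization
# ---------------------------------------------------------------------------

def resolve_gene_sets(gene_ids: Iterable[str],
                      mito_genes: Iterable[str] | None = None,
                      ribo_genes: Iterable[str] | None = None,
                      ) -> tuple[set[str], set[str]]:
    """Resolve mitochondrial/ribosomal gene sets, by list or by prefix rule."""
    ids = list(map(str, gene_ids))
    if mito_genes is None:
        mito = {g for g in ids if g.upper().startswith(DEFAULT_MITO_PREFIXES)}
    else:
        mito = set(map(str, mito_genes))
    if ribo_genes is None:
        ribo = {g for g in ids if g.upper().startswith(DEFAULT_RIBO_PREFIXES)}
    else:
        ribo = set(map(str, ribo_genes))
    for name, s in (("mito", mito), ("ribo", ribo)):
        missed = s - set(ids)
        if missed:
            warnings.warn(f"{len(missed)} {name} gene(s) not in matrix, ignored")
    return mito & set(ids), ribo & set(ids)


def qc_filter(m: CellMatrix, t: QCThresholds,
              mito_genes: Iterable[str] | None = None,
              ribo_genes: Iterable[str] | None = None) -> CellMatrix:
    """Remove low-quality cells.

    A cell is retained iff UMI >= ``min_umi``, detected genes (count > 0) in
    [``min_features``, ``max_features``], %mito <= ``max_pct_mito`` and
    %ribo <= ``max_pct_ribo`` (strictly-greater percentages are excluded).
    Per-criterion removal counts are stored in ``uns["qc_report"]``.
    """
    mito, ribo = resolve_gene_sets(m.gene_ids, mito_genes, ribo_genes)
    X = m.adata.X
    Xc = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X)
    umi = np.asarray(Xc.sum(axis=1)).ravel()
    nfeat = (
        np.asarray((Xc > 0).sum(axis=1)).ravel()
        if sp.issparse(Xc) else (Xc > 0).sum(axis=1)
    )

    def _pct(gene_set: set[str]) -> np.ndarray:
        if not gene_set:
            return np.zeros(m.n_cells)
        idx = m.gene_ids.get_indexer(sorted(gene_set))
        part = np.asarray(Xc[:, idx].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(umi > 0, 100.0 * part / umi, 0.0)
        return pct

    pct_mito, pct_ribo = _pct(mito), _pct(ribo)
    ok_umi = umi >= t.min_umi
    ok_min = nfeat >= t.min_features
    ok_max = np.ones(m.n_cells, bool) if t.max_features is None else nfeat <= t.max_features
    ok_mito = pct_mito <= t.max_pct_mito
    ok_ribo = pct_ribo <= t.max_pct_ribo
    keep = ok_umi & ok_min & ok_max & ok_mito & ok_ribo

    report = {
        "min_umi": int((~ok_umi).sum()),
        "min_features": int((~ok_min).sum()),
        "max_features": int((~ok_max).sum()),
        "max_pct_mito": int((~ok_mito).sum()),
        "max_pct_ribo": int((~ok_ribo).sum()),
        "removed_total": int((~keep).sum()),
    }
    if not keep.any():
        raise EmptyResultError("QC filtering removed every cell")
    out = m.subset_cells(keep)
    out.adata.uns["qc_report"] = report
    return out


def normalize_log(m: CellMatrix, scale_target: float | None = None) -> CellMatrix:
    """Depth-normalize counts to ``scale_target`` per cell and log1p-transform.

    layer[c, g] = log(1 + count[c, g] * scale_target / total[c]). The default
    ``scale_target=None`` uses the median library size (the scanpy
    convention), which keeps per-gene normalized means on the scale the
    dispersion-based HVG mean window assumes regardless of panel size; pass
    10_000 for the fixed-target convention. Cells with a zero total are left
    all-zero with a warning. Returns a new CellMatrix with the ``lognorm``
    layer attached; counts are untouched.
    """
    C = m.counts().astype(np.float64)
    totals = C.sum(axis=1)
    if scale_target is None:
        positive = totals[totals > 0]
        if positive.size == 0:
            raise ValueError("all cells have zero counts")
        scale_target = float(np.median(positive))
    if scale_target <= 0:
        raise ValueError("scale_target must be positive")
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cell(s) have zero total counts")
    safe = np.where(zero, 1.0, totals)
    layer = np.log1p(C * (scale_target / safe)[:, None])
    layer[zero] = 0.0
    out = m.copy()
    out.adata.layers[LOGNORM] = layer
    return out


def percent_expression(m: CellMatrix, genes: Sequence[str]) -> np.ndarray:
    """Percent of cells expressing each gene: P_j = 100 * C_j / C.

    C_j counts cells with a raw count > 0 for gene j; C is the total cell
    count. Computed from raw counts, so it is invariant to normalization.
    """
    missing = [g for g in genes if g not in m.gene_ids]
    if missing:
        raise KeyError(f"unknown gene(s): {missing[:5]}")
    C = m.counts(genes)
    return 100.0 * (C > 0).sum(axis=0) / m.n_cells


def split_train_test(m: CellMatrix, test_fraction: float = 0.2, seed: int = 0,
                     stratify: bool = True) -> tuple[CellMatrix, CellMatrix]:
    """Disjoint train/test partition of cells, stratified by condition.

    Stratification keeps the case/control ratio equal (to within one cell) in
    both splits, which balanced-accuracy evaluation relies on; pass
    ``stratify=False`` for a plain random split.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    y = m.labels()
    if stratify:
        counts = pd.Series(y).value_counts()
        if len(counts) < 2 or counts.min() < 2:
            raise ValueError("need >= 2 cells of each condition to stratify")
    idx = np.arange(m.n_cells)
    tr, te = train_test_split(
        idx, test_size=test_fraction, random_state=seed,
        stratify=y if stratify else None, shuffle=True,
    )
    return m.subset_cells(np.sort(tr)), m.subset_cells(np.sort(te))
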