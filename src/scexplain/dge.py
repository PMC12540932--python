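"""Fold-changes, rank-sum differential expression, pseudobulk aggregation,
pan-dataset overlap, and the three-step candidate-gene prioritization.

Differential expression here is the rank-sum route (each cell an independent
replicate) with a 1%-expressed prefilter and Bonferroni correction; pseudobulk
subject-level count tables are exported for external count-model tools rather
than fitted natively. Prioritization removes housekeeping-confounded genes
(mitochondrial, ribosomal, sex-linked, non-coding — GWAS-implicated genes are
retained), requires |Log2FC| > 0.25, and keeps genes with importance Z > 5 in
a cell type or Z > 2 backed by membership in at least three cell types'
optimal sets.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CellMatrix

EXCLUSION_FLAGS = ("mitochondrial", "ribosomal", "sex_linked", "non_coding")


def _condition_split(m: CellMatrix, cell_type: str) -> tuple[CellMatrix, np.ndarray]:
    sub = m.subset_cell_type(cell_type)
    y = sub.labels()
    if not ((y == "case").any() and (y == "control").any()):
        raise ValueError(f"cell type {cell_type!r} lacks one of the conditions")
    return sub, y


def log2fc(m: CellMatrix, cell_type: str, pseudocount: float = 1e-9
           ) -> pd.Series:
    """Case-vs-control log2 fold change per gene for one cell type.

    Means are taken on de-logged normalized expression (expm1 of the lognorm
    layer), pooling all datasets present in ``m``; a small pseudocount guards
    the ratio. Positive values mean higher expression in case cells.
    """
    sub, y = _condition_split(m, cell_type)
    E = np.expm1(sub.lognorm())
    mean_case = E[y == "case"].mean(axis=0)
    mean_ctrl = E[y == "control"].mean(axis=0)
    fc = np.log2((mean_case + pseudocount) / (mean_ctrl + pseudocount))
    return pd.Series(fc, index=sub.gene_ids, name="log2fc")


def wilcoxon_dge(m: CellMatrix, cell_type: str, min_pct: float = 1.0
                 ) -> pd.DataFrame:
    """Per-gene two-sided rank-sum test of normalized expression.

    Genes expressed in less than ``min_pct`` percent of BOTH case and control
    cells are dropped before testing; Bonferroni adjustment runs over the
    tested genes only. Columns: log2fc, p, p_adj, pct_case, pct_control.
    """
    sub, y = _condition_split(m, cell_type)
    case, ctrl = y == "case", y == "control"
    C = sub.counts()
    pct_case = 100.0 * (C[case] > 0).mean(axis=0)
    pct_ctrl = 100.0 * (C[ctrl] > 0).mean(axis=0)
    tested = (pct_case >= min_pct) | (pct_ctrl >= min_pct)
    if not tested.any():
        warnings.warn("no gene passes the percent-expressed filter")
        return pd.DataFrame(columns=["log2fc", "p", "p_adj",
                                     "pct_case", "pct_control"])
    L = sub.lognorm()
    genes = sub.gene_ids[tested]
    pvals = np.empty(int(tested.sum()))
    for k, g in enumerate(np.where(tested)[0]):
        a, b = L[case, g], L[ctrl, g]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[k] = 1.0
            continue
        pvals[k] = stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="auto").pvalue
    n_tested = len(pvals)
    fc = log2fc(m, cell_type)
    out = pd.DataFrame({
        "log2fc": fc.loc[genes].to_numpy(),
        "p": pvals,
        "p_adj": np.minimum(1.0, pvals * n_tested),
        "pct_case": pct_case[tested],
        "pct_control": pct_ctrl[tested],
    }, index=genes)
    out.attrs["test"] = "wilcoxon_rank_sum"
    return out


def significant_genes(dge: pd.DataFrame, p_adj_max: float = 0.05,
                      lfc_min: float = 1.0) -> set[str]:
    """DEGs under the standard rule: adjusted P < 0.05 and |Log2FC| > 1."""
    hit = (dge["p_adj"] < p_adj_max) & (dge["log2fc"].abs() > lfc_min)
    return set(dge.index[hit])


def pseudobulk(m: CellMatrix, cell_type: str) -> pd.DataFrame:
    """Subject x gene integer count sums (subjects as biological replicates).

    The subject's condition is attached as a leading column; gene column sums
    equal the cell-level totals by construction.
    """
    sub = m.subset_cell_type(cell_type)
    C = sub.counts()
    df = pd.DataFrame(C, columns=sub.gene_ids,
                      index=sub.obs["subject_id"].to_numpy())
    agg = df.groupby(level=0, sort=True).sum()
    cond = (sub.obs.groupby("subject_id", sort=True, observed=True)["condition"]
            .first().loc[agg.index])
    agg.insert(0, "condition", cond.to_numpy())
    agg.index.name = "subject_id"
    return agg


def pan_dataset_overlap(a: set[str], b: set[str]) -> float:
    """Proportion of genes shared by two datasets' hit lists: |A∩B| / |A∪B|."""
    union = set(a) | set(b)
    if not union:
        raise ValueError("both gene sets are empty; overlap undefined")
    return len(set(a) & set(b)) / len(union)


def overlap_report(a: set[str], b: set[str]) -> dict[str, float]:
    """Jaccard overlap plus the per-set shared proportions."""
    inter = len(set(a) & set(b))
    return {
        "jaccard": pan_dataset_overlap(a, b),
        "share_of_a": inter / len(a) if a else float("nan"),
        "share_of_b": inter / len(b) if b else float("nan"),
    }


def prioritize(optimal_sets: Mapping[str, Sequence[str]],
               mean_z_tables: Mapping[str, pd.Series],
               log2fc_tables: Mapping[str, pd.Series],
               annotation: pd.DataFrame | None = None,
               lfc_min: float = 0.25, z_high: float = 5.0, z_mid: float = 2.0,
               min_celltypes: int = 3) -> pd.DataFrame:
    """Three-step candidate-gene prioritization across cell types.

    Per cell type's optimal set: (1) drop genes flagged mitochondrial,
    ribosomal, sex-linked or non-coding unless GWAS-implicated; (2) require
    |Log2FC| > ``lfc_min``; (3) keep genes with mean Z > ``z_high`` in that
    cell type, or Z > ``z_mid`` there plus membership in at least
    ``min_celltypes`` cell types' optimal sets. The output labels each
    retained gene single- vs multi-cell-type.
    """
    if annotation is None:
        annotation = pd.DataFrame(columns=["gene_id", *EXCLUSION_FLAGS, "gwas_pd"]
                                  ).set_index("gene_id")
    elif "gene_id" in annotation.columns:
        annotation = annotation.set_index("gene_id")

    membership: dict[str, int] = {}
    for ct, genes in optimal_sets.items():
        for g in genes:
            membership[g] = membership.get(g, 0) + 1

    rows = []
    for ct, genes in optimal_sets.items():
        zs = mean_z_tables[ct]
        fcs = log2fc_tables[ct]
        for g in genes:
            if g in annotation.index:
                ann = annotation.loc[g]
                flagged = any(bool(ann.get(f, False)) for f in EXCLUSION_FLAGS)
                gwas = bool(ann.get("gwas_pd", False))
            else:
                flagged, gwas = False, False
                if len(annotation):
                    warnings.warn(f"gene {g} missing from annotation; "
                                  "treated as unflagged")
            if flagged and not gwas:
                continue
            fc = float(fcs.get(g, np.nan))
            if not np.isfinite(fc) or abs(fc) <= lfc_min:
                continue
            z = float(zs.get(g, np.nan))
            n_ct = membership[g]
            if z > z_high:
                pass
            elif z > z_mid and n_ct >= min_celltypes:
                pass
            else:
                continue
            rows.append({
                "gene_id": g, "cell_type": ct, "mean_z": z, "log2fc": fc,
                "n_celltypes": n_ct, "gwas_pd": gwas,
                "category": "multi-cell-type" if n_ct >= min_celltypes
                            else "single-cell-type",
            })
    return pd.DataFrame(rows, columns=["gene_id", "cell_type", "mean_z",
                                       "log2fc", "n_celltypes", "gwas_pd",
                                       "category"])


def annotate_gene_set(genes: Sequence[str],
                      tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Left-join genes against external association tables (no statistics).

    Each table must carry a ``gene_id`` column (or index); matched rows are
    concatenated with a ``source`` provenance column, and unmatched genes
    pass through with source NaN.
    """
    base = pd.DataFrame({"gene_id": list(genes)})
    pieces = []
    for name, tbl in tables.items():
        t = tbl.reset_index() if "gene_id" not in tbl.columns else tbl.copy()
        t = t[t["gene_id"].isin(base["gene_id"])]
        if not t.empty:
            t = t.copy()
            t.insert(1, "source", name)
            pieces.append(t)
    if pieces:
        joined = pd.concat(pieces, ignore_index=True)
        matched = set(joined["gene_id"])
    else:
        joined = pd.DataFrame(columns=["gene_id", "source"])
        matched = set()
    unmatched = base[~base["gene_id"].isin(matched)]
    return pd.concat([joined, unmatched], ignore_index=True)
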