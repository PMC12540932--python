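"""Feature spaces fed to the classifiers: HVGs, PCA, and NMF factors.

All fits happen on the training split only; the resulting
:class:`FeatureSpace` applies the frozen transform (gene subset, centering /
scaling, loadings) to any other split so test cells never leak into fit
state. The number of principal components is chosen by a jackstraw-style
permutation test; the NMF rank by the Unit Invariant Knee of the
reconstruction-error curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import NMF, PCA
from sklearn.preprocessing import StandardScaler

import scanpy as sc

from .core_data import CellMatrix


class SelectionError(ValueError):
    """Feature selection cannot proceed (too few usable genes/points)."""


@dataclass
class FeatureSpace:
    """A fitted feature transform: gene list (hvg) or loadings (pca/nmf)."""

    kind: str  # {"hvg", "pca", "nmf"}
    gene_ids: list[str]
    n_features: int
    scaler: StandardScaler | None = None
    model: object | None = None
    metadata: dict = field(default_factory=dict)

    def transform(self, m: CellMatrix) -> np.ndarray:
        """cells x n_features matrix for any split, using frozen fit state."""
        X = m.lognorm(self.gene_ids)
        if self.kind == "hvg":
            return X
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return self.model.transform(X)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.Series(self.gene_ids, name="gene_id").to_csv(
            out_dir / "genes.tsv", sep="\t", index=False)
        params = {"kind": self.kind, "n_features": self.n_features, **{
            k: v for k, v in self.metadata.items() if np.isscalar(v)}}
        pd.Series(params).to_csv(out_dir / "params.tsv", sep="\t", header=False)
        if self.kind in ("pca", "nmf") and self.model is not None:
            comp = pd.DataFrame(self.model.components_, columns=self.gene_ids)
            comp.to_csv(out_dir / "loadings.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Highly variable genes
# ---------------------------------------------------------------------------

def select_hvg(train: CellMatrix, n_bins: int = 20,
               min_mean: float = 0.0125, max_mean: float = 3.0,
               min_disp: float = 0.5) -> FeatureSpace:
    """Dispersion-based highly-variable-gene selection on the training split.

    Per-gene mean and dispersion (variance/mean, on de-logged normalized
    expression) are computed, dispersions are z-standardized within 20 bins of
    genes with similar mean, and genes with mean in [0.0125, 3] and normalized
    dispersion >= 0.5 are kept — the threshold-free flavor that returns the
    gene list itself rather than a fixed top-k.
    """
    if train.n_cells < 2:
        raise SelectionError("need >= 2 cells for dispersion estimates")
    X = train.lognorm()
    tmp = ad.AnnData(X=X, var=pd.DataFrame(index=train.gene_ids))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(
            tmp, flavor="seurat", n_bins=n_bins,
            min_mean=min_mean, max_mean=max_mean, min_disp=min_disp,
        )
    kept = list(tmp.var.index[tmp.var["highly_variable"]])
    if len(kept) < 2:
        raise SelectionError("fewer than 2 highly variable genes found")
    return FeatureSpace(
        kind="hvg", gene_ids=kept, n_features=len(kept),
        metadata={
            "means": tmp.var["means"], "dispersions": tmp.var["dispersions"],
            "dispersions_norm": tmp.var["dispersions_norm"],
            "n_bins": n_bins, "min_mean": min_mean, "max_mean": max_mean,
            "min_disp": min_disp,
        },
    )


# ---------------------------------------------------------------------------
# PCA + jackstraw component count
# ---------------------------------------------------------------------------

def _scaled(train: CellMatrix, genes: Sequence[str] | None, scale: bool
            ) -> tuple[np.ndarray, list[str], StandardScaler | None]:
    genes = list(genes) if genes is not None else list(train.gene_ids)
    X = train.lognorm(genes)
    scaler = None
    if scale:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    return X, genes, scaler


def fit_pca(train: CellMatrix, n_components: int,
            genes: Sequence[str] | None = None, scale: bool = True
            ) -> FeatureSpace:
    """PCA of the (centered, unit-scaled) normalized layer on the train split."""
    X, genes, scaler = _scaled(train, genes, scale)
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(cells, genes)={min(X.shape)}")
    model = PCA(n_components=n_components, svd_solver="full").fit(X)
    return FeatureSpace(
        kind="pca", gene_ids=genes, n_features=n_components,
        scaler=scaler, model=model,
        metadata={"explained_variance_ratio": model.explained_variance_ratio_},
    )


def jackstraw_components(train: CellMatrix, n_components: int = 50,
                         n_permutations: int = 100, gene_fraction: float = 0.01,
                         alpha: float = 0.05, seed: int = 0,
                         genes: Sequence[str] | None = None,
                         scale: bool = True) -> int:
    """Permutation-based count of significant principal components.

    Each permutation scrambles a random ``gene_fraction`` of genes across
    cells and refits the PCA; the squared loadings of the scrambled genes form
    the null distribution of per-gene component association. Per gene,
    empirical p-values against the pooled null are computed; a component's P
    is a one-sided binomial test of the excess of genes with p < alpha over
    the alpha expectation. Components are kept in order up to (not including)
    the first with P >= alpha; if the very first fails, 1 is returned with a
    warning.
    """
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")
    if n_permutations < 10:
        warnings.warn("fewer than 10 permutations gives a coarse null")
    if not 0.0 < gene_fraction < 1.0:
        raise ValueError("gene_fraction must lie in (0, 1)")

    X, genes, _ = _scaled(train, genes, scale)
    n_cells, n_genes = X.shape
    K = min(n_components, n_cells - 1, n_genes)
    rng = np.random.default_rng(seed)
    obs = PCA(n_components=K, svd_solver="full").fit(X).components_ ** 2  # K x G

    m = max(1, int(round(gene_fraction * n_genes)))
    null = np.empty((n_permutations, m, K))
    for b in range(n_permutations):
        perm_genes = rng.choice(n_genes, size=m, replace=False)
        Xp = X.copy()
        for g in perm_genes:
            Xp[:, g] = Xp[rng.permutation(n_cells), g]
        load = PCA(n_components=K, svd_solver="full").fit(Xp).components_
        null[b] = load[:, perm_genes].T ** 2
    null = null.reshape(-1, K)  # pooled null per component

    n_sig = 0
    first_failed = False
    for k in range(K):
        nk = np.sort(null[:, k])
        # empirical p per gene: fraction of null >= observed (add-one smoothed)
        p_gene = 1.0 - np.searchsorted(nk, obs[k], side="left") / (len(nk) + 1)
        hits = int((p_gene < alpha).sum())
        P_k = stats.binomtest(hits, n_genes, alpha, alternative="greater").pvalue
        if P_k >= alpha:
            first_failed = k == 0
            break
        n_sig += 1
    if n_sig == 0 and first_failed:
        warnings.warn("first component not significant; falling back to 1")
        return 1
    return n_sig


# ---------------------------------------------------------------------------
# NMF + rank selection
# ---------------------------------------------------------------------------

def fit_nmf(train: CellMatrix, k: int, seed: int = 0,
            genes: Sequence[str] | None = None, max_iter: int = 400
            ) -> FeatureSpace:
    """Non-negative matrix factorization of the normalized layer, rank ``k``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    genes = list(genes) if genes is not None else list(train.gene_ids)
    X = train.lognorm(genes)
    if X.min() < 0:
        raise ValueError("NMF requires a non-negative input layer")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = NMF(n_components=k, init="nndsvda", random_state=seed,
                    max_iter=max_iter).fit(X)
    return FeatureSpace(
        kind="nmf", gene_ids=genes, n_features=k, model=model,
        metadata={"reconstruction_err": float(model.reconstruction_err_),
                  "seed": seed},
    )


def nmf_rank_sweep(train: CellMatrix, k_max: int = 100, seed: int = 0,
                   genes: Sequence[str] | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruction error for k = 1..k_max (same data, same seed schedule)."""
    ks = np.arange(1, k_max + 1)
    errs = np.array([
        fit_nmf(train, int(k), seed=seed, genes=genes).metadata["reconstruction_err"]
        for k in ks
    ])
    return ks, errs


def select_nmf_rank(train: CellMatrix, k_max: int = 100, seed: int = 0,
                    genes: Sequence[str] | None = None) -> int:
    """NMF rank at the Unit Invariant Knee of the error-vs-rank curve."""
    ks, errs = nmf_rank_sweep(train, k_max=k_max, seed=seed, genes=genes)
    return int(uik_elbow(ks, errs))


def uik_elbow(x: Sequence[float], y: Sequence[float]) -> float:
    """Unit-invariant knee: rescale the curve to the unit square and return
    the x-value maximizing perpendicular distance to the first-to-last chord.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired points")
    if not np.all(np.diff(x) > 0):
        raise ValueError("x must be strictly increasing")
    xs = (x - x[0]) / (x[-1] - x[0])
    yr = y[-1] - y[0]
    if yr == 0:
        raise ValueError("degenerate curve: flat y")
    ys = (y - y[0]) / yr
    # chord from (0, 0) to (1, 1) in rescaled space; distance ∝ |ys - xs|
    d = np.abs(ys - xs) / np.sqrt(2.0)
    if np.max(d) < 1e-12:
        raise ValueError("degenerate curve: points are collinear")
    return float(x[int(np.argmax(d))])
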