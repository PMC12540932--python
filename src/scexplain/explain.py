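"""Local-surrogate (LIME-style) explanations and expression-weighted Z-scores.

For each correctly classified case cell in the test split, the classifier's
local decision surface is approximated by a weighted ridge regression fit to
the model's case probabilities on perturbed copies of the cell. Per-gene
importances are then aggregated subject-by-subject,

    F_ij = mean over subject i's explained cells of |importance of gene j|,
    F_j  = mean of F_ij over case subjects (subjects weighted equally),

weighted by normalized percent expression N_j = P_j / sum_l P_l to discourage
sparsely expressed genes,

    W_j = N_j * F_j,      Z_j = (W_j - mean(W)) / sd(W),

giving importance Z-scores comparable across datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge

from .classify import POSITIVE, EvaluationResult
from .core_data import CellMatrix, percent_expression


@dataclass
class LimeConfig:
    """Knobs of the tabular local-surrogate recipe.

    ``n_perturbations`` samples are drawn around the cell; ``kernel_width``
    "auto" resolves to 0.75 * sqrt(n_features); the surrogate is a ridge
    regression with penalty ``surrogate_penalty``. With ``discretize`` on,
    features are quartile-binned and perturbations flip bin membership
    (the canonical interpretable representation); off, perturbations are
    Gaussian in standardized units. ``max_cells_per_subject`` optionally
    caps how many of a subject's cells are explained (a compute budget;
    None explains all).
    """

    n_perturbations: int = 5000
    kernel_width: float | str = "auto"
    surrogate_penalty: float = 1.0
    discretize: bool = True
    seed: int = 0
    max_cells_per_subject: int | None = None

    def __post_init__(self) -> None:
        if self.n_perturbations < 100:
            raise ValueError("n_perturbations must be >= 100")
        if self.kernel_width != "auto" and not self.kernel_width > 0:
            raise ValueError("kernel_width must be positive or 'auto'")

    def resolve_width(self, n_features: int) -> float:
        if self.kernel_width == "auto":
            return 0.75 * np.sqrt(n_features)
        return float(self.kernel_width)


@dataclass
class BackgroundStats:
    """Training-split statistics the perturbation sampler draws from."""

    means: np.ndarray
    stds: np.ndarray
    quartiles: np.ndarray  # (3, F) inner bin edges
    bin_means: np.ndarray  # (4, F) mean training value per quartile bin
    feature_names: list[str]

    @classmethod
    def from_matrix(cls, X_train: np.ndarray, feature_names: Sequence[str]
                    ) -> "BackgroundStats":
        X = np.asarray(X_train, dtype=float)
        q = np.percentile(X, [25, 50, 75], axis=0)
        bins = np.empty((4, X.shape[1]))
        for f in range(X.shape[1]):
            b = np.searchsorted(q[:, f], X[:, f], side="right")
            for k in range(4):
                sel = b == k
                bins[k, f] = X[sel, f].mean() if sel.any() else q[min(k, 2), f]
        return cls(means=X.mean(axis=0), stds=X.std(axis=0),
                   quartiles=q, bin_means=bins,
                   feature_names=list(feature_names))

    def bin_of(self, x: np.ndarray) -> np.ndarray:
        """Quartile bin index (0..3) of each feature value."""
        out = np.empty(x.size, dtype=np.int64)
        for f in range(x.size):
            out[f] = np.searchsorted(self.quartiles[:, f], x[f], side="right")
        return out


@dataclass
class CellExplanation:
    """Signed per-feature importances of one cell under one (or averaged) model."""

    cell_id: str
    model_index: int  # -1 for a model-averaged explanation
    importances: np.ndarray
    feature_names: list[str] = field(default_factory=list)


def explain_cell(model, cell: np.ndarray, background: BackgroundStats,
                 cfg: LimeConfig, rng: np.random.Generator | None = None,
                 ) -> CellExplanation:
    """Fit a weighted ridge surrogate to the model around one cell.

    Perturbed samples are drawn around the cell, the model's case probability
    is computed for each, samples are weighted by exp(-d^2 / w^2) on the
    distance in the interpretable representation, and the ridge coefficients
    are returned as signed importances — one per input feature. If the model's
    output is constant over the sample, a zero explanation is returned with a
    warning.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    x = np.asarray(cell, dtype=float).ravel()
    F = x.size
    n = cfg.n_perturbations
    width = cfg.resolve_width(F)

    const = background.stds == 0  # zero-variance features are never perturbed

    if cfg.discretize:
        x_bins = background.bin_of(x)
        # sample a quartile bin per (sample, feature); equal mass per bin
        samp_bins = rng.integers(0, 4, size=(n, F))
        samp_bins[0] = x_bins  # first sample is the instance itself
        samp_bins[:, const] = x_bins[const]
        Z = (samp_bins == x_bins[None, :]).astype(float)  # interpretable rep
        Xp = background.bin_means[samp_bins, np.arange(F)[None, :]]
        Xp[0] = x
        d = np.sqrt(((Z - 1.0) ** 2).sum(axis=1))
    else:
        noise = rng.standard_normal((n, F))
        noise[0] = 0.0
        noise[:, const] = 0.0
        Xp = x[None, :] + noise * background.stds[None, :]
        Z = noise  # standardized perturbation is the representation
        d = np.sqrt((noise ** 2).sum(axis=1))

    proba = model.predict_proba(Xp)
    case_idx = int(np.where(np.asarray(model.classes_, dtype=object) == POSITIVE)[0][0])
    target = proba[:, case_idx]
    if np.ptp(target) == 0:
        warnings.warn("model output constant over the perturbation sample; "
                      "returning a zero explanation")
        return CellExplanation("", -1, np.zeros(F), background.feature_names)

    w = np.exp(-(d ** 2) / (width ** 2))
    ridge = Ridge(alpha=cfg.surrogate_penalty)
    ridge.fit(Z, target, sample_weight=w)
    return CellExplanation("", -1, ridge.coef_.copy(), background.feature_names)


def select_correct_case_cells(result: EvaluationResult, meta: pd.DataFrame
                              ) -> dict[int, list[str]]:
    """Per model: test cells from case subjects whose prediction was correct."""
    if result.cell_ids is None:
        raise ValueError("evaluation carries no cell ids")
    is_case = (meta.loc[result.cell_ids, "condition"] == POSITIVE).to_numpy()
    out: dict[int, list[str]] = {}
    for i in range(result.predictions.shape[0]):
        mask = result.correct[i] & is_case
        out[i] = [cid for cid, keep in zip(result.cell_ids, mask) if keep]
        if not out[i]:
            warnings.warn(f"model {i}: no correctly classified case cells")
    return out


def explain_correct_case_cells(models: Sequence, result: EvaluationResult,
                               X_test: np.ndarray, meta: pd.DataFrame,
                               background: BackgroundStats, cfg: LimeConfig,
                               ) -> pd.DataFrame:
    """Model-averaged signed importances for every explained case cell.

    Each cell is explained under every CV model that classified it correctly,
    and the per-model explanations are averaged. Rows are cells (indexed by
    cell id), columns features. ``max_cells_per_subject`` caps the explained
    cells per subject (chosen deterministically from ``cfg.seed``).
    """
    per_model = select_correct_case_cells(result, meta)
    cell_models: dict[str, list[int]] = {}
    for i, cells in per_model.items():
        for cid in cells:
            cell_models.setdefault(cid, []).append(i)

    cell_ids = list(cell_models)
    if cfg.max_cells_per_subject is not None and cell_ids:
        rng = np.random.default_rng(cfg.seed)
        subj = meta.loc[cell_ids, "subject_id"]
        kept: list[str] = []
        for _, grp in subj.groupby(subj, sort=True):
            ids = sorted(grp.index)
            if len(ids) > cfg.max_cells_per_subject:
                pick = rng.choice(len(ids), cfg.max_cells_per_subject, replace=False)
                ids = [ids[k] for k in sorted(pick)]
            kept.extend(ids)
        cell_ids = kept

    pos = {cid: k for k, cid in enumerate(result.cell_ids)}
    rng = np.random.default_rng(cfg.seed)
    rows = np.zeros((len(cell_ids), X_test.shape[1]))
    for r, cid in enumerate(cell_ids):
        x = X_test[pos[cid]]
        expls = [
            explain_cell(models[i], x, background, cfg, rng=rng).importances
            for i in cell_models[cid]
        ]
        rows[r] = np.mean(expls, axis=0)
    return pd.DataFrame(rows, index=pd.Index(cell_ids, name="cell_id"),
                        columns=background.feature_names)


# ---------------------------------------------------------------------------
# Aggregation chain
# ---------------------------------------------------------------------------

def aggregate_subject(expls: np.ndarray | pd.DataFrame) -> np.ndarray:
    """F_ij: mean absolute importance per gene over one subject's cells."""
    A = np.asarray(expls, dtype=float)
    if A.ndim == 1:
        A = A[None, :]
    if A.shape[0] == 0:
        raise ValueError("need >= 1 explanation")
    return np.abs(A).mean(axis=0)


def aggregate_condition(F: Mapping[str, np.ndarray] | Sequence[np.ndarray]
                        ) -> np.ndarray:
    """F_j: mean of per-subject F_ij over case subjects, equally weighted."""
    vecs = list(F.values()) if isinstance(F, Mapping) else list(F)
    if not vecs:
        raise ValueError("need >= 1 case subject")
    return np.mean(np.stack(vecs), axis=0)


def weight_and_zscore(F_j: np.ndarray, P_j: np.ndarray,
                      gene_ids: Sequence[str],
                      population_sd: bool = True) -> pd.DataFrame:
    """Expression-weighted importances and their Z-scores (one cell type).

    N_j = P_j / sum_l P_l; W_j = N_j * F_j; Z_j = (W_j - mean W) / sd W with
    a population (n-denominator) standard deviation by default. Genes never
    observed (P_j = 0) get W_j = 0 and are flagged in ``never_expressed``.
    """
    F_j = np.asarray(F_j, dtype=float)
    P_j = np.asarray(P_j, dtype=float)
    if F_j.size != P_j.size or F_j.size != len(gene_ids):
        raise ValueError("F, P and gene_ids must be the same length")
    if F_j.size < 2:
        raise ValueError("need >= 2 genes")
    total = P_j.sum()
    if total <= 0:
        raise ValueError("no gene is expressed; cannot normalize P")
    N_j = P_j / total
    W_j = N_j * F_j
    mu = W_j.mean()
    sigma = W_j.std(ddof=0 if population_sd else 1)
    if sigma == 0:
        raise ValueError("degenerate importance distribution: sd(W) = 0")
    Z_j = (W_j - mu) / sigma
    out = pd.DataFrame({
        "gene_id": list(gene_ids), "F": F_j, "P": P_j, "N": N_j,
        "W": W_j, "Z": Z_j, "never_expressed": P_j == 0,
    }).set_index("gene_id")
    out.attrs.update({"mu": float(mu), "sigma": float(sigma)})
    return out


def importance_table(models: Sequence, result: EvaluationResult,
                     X_test: np.ndarray, meta: pd.DataFrame,
                     background: BackgroundStats, cfg: LimeConfig,
                     expression_matrix: CellMatrix) -> pd.DataFrame:
    """Full chain: explanations -> per-subject -> per-condition -> W, Z.

    ``expression_matrix`` supplies percent expression (raw counts of the cell
    type's cells, all splits). Returns the per-gene table with columns
    F, P, N, W, Z; the number of case subjects M is stored in ``attrs``.
    """
    expl = explain_correct_case_cells(models, result, X_test, meta,
                                      background, cfg)
    if expl.empty:
        raise ValueError("no cells could be explained")
    subj = meta.loc[expl.index, "subject_id"]
    F_by_subject = {
        str(s): aggregate_subject(grp.to_numpy())
        for s, grp in expl.groupby(subj, sort=True)
    }
    F_j = aggregate_condition(F_by_subject)
    P_j = percent_expression(expression_matrix, background.feature_names)
    table = weight_and_zscore(F_j, P_j, background.feature_names)
    table.attrs["M"] = len(F_by_subject)
    table.attrs["n_cells_explained"] = int(expl.shape[0])
    return table


def importance_correlation(a: pd.DataFrame, b: pd.DataFrame
                           ) -> tuple[float, float]:
    """Pearson correlation of two tables' Z-scores over their shared genes."""
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes")
    r, p = stats.pearsonr(a.loc[shared, "Z"], b.loc[shared, "Z"])
    return float(r), float(p)
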