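"""Optimal gene sets by percentile-elimination permutation testing.

Cell type-specific importance Z-scores are averaged across exploratory
datasets; genes with mean Z > 1.00 form the ranked candidate pool. Starting
at the percentile rank of Z = 1.00 and raising the threshold in 0.001 steps,
ever-smaller nested gene sets are used to retrain the classifier, and each
set's balanced accuracy is compared with the mean accuracy of equal-size
random gene sets (the benchmark). The optimal set maximizes the summed
accuracy gap (LIME minus random) across the exploratory datasets, smallest
set on ties. Transfer evaluation repeats the LIME-vs-random comparison on an
independent target dataset with a rank-sum test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassifierSpec, run_pipeline
from .core_data import CellMatrix


def mean_z(tables: Sequence[pd.DataFrame], policy: str = "intersection"
           ) -> pd.Series:
    """Per-gene mean Z over datasets.

    ``intersection`` (default) keeps genes appearing in every table;
    ``union`` averages each gene over the tables that contain it. A single
    table passes through with a warning (the single-exploratory-dataset case,
    e.g. dopaminergic neurons).
    """
    if not tables:
        raise ValueError("need at least one importance table")
    if len(tables) == 1:
        warnings.warn("single importance table: mean Z is a pass-through")
        return tables[0]["Z"].copy()
    zs = [t["Z"] for t in tables]
    if policy == "intersection":
        shared = zs[0].index
        for z in zs[1:]:
            shared = shared.intersection(z.index)
        if len(shared) == 0:
            raise ValueError("no genes shared across all tables")
        return pd.concat([z.loc[shared] for z in zs], axis=1).mean(axis=1)
    if policy == "union":
        return pd.concat(zs, axis=1).mean(axis=1, skipna=True)
    raise ValueError(f"unknown membership policy {policy!r}")


def candidate_pool(meanz: pd.Series, z_min: float = 1.0) -> pd.DataFrame:
    """Ranked candidate genes with percentile ranks over ALL scored genes.

    Percentile rank of a gene is the fraction of scored genes with mean Z at
    or below its own (top gene -> 1.0); ties are broken lexicographically by
    gene id so ranking is deterministic. Only genes with mean Z > ``z_min``
    enter the pool, ordered by descending mean Z.
    """
    s = meanz.sort_index()  # lexicographic tie-break
    order = np.argsort(-s.to_numpy(), kind="stable")
    ranked = s.iloc[order]
    n = len(ranked)
    percentile = (n - np.arange(n)) / n  # descending order -> top gene = 1.0
    df = pd.DataFrame({"mean_z": ranked, "percentile": percentile})
    pool = df[df["mean_z"] > z_min]
    if pool.empty:
        raise ValueError(f"no genes exceed mean Z = {z_min}")
    return pool


@dataclass
class EliminationCurve:
    """(threshold, n_genes, LIME accuracy, random-benchmark accuracy, delta)."""

    records: pd.DataFrame
    dataset_id: str = ""
    cell_type: str = ""
    pool: pd.DataFrame | None = None

    def genes_at(self, n_genes: int) -> list[str]:
        if self.pool is None:
            raise ValueError("curve carries no pool; cannot recover gene sets")
        return list(self.pool.index[:n_genes])


@dataclass
class OptimalGeneSet:
    """The threshold-induced gene set maximizing the summed accuracy gap."""

    cell_type: str
    gene_ids: list[str]
    n_genes: int
    delta_sum: float
    provenance: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        pd.Series(self.gene_ids, name="gene_id").to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"cell_type": self.cell_type, "n_genes": self.n_genes,
                       "delta_sum": self.delta_sum,
                       "provenance": self.provenance}, fh, indent=2)


def elimination_curves(m: CellMatrix, pool: pd.DataFrame, spec: ClassifierSpec,
                       step: float = 0.001, n_random: int = 10, seed: int = 0,
                       test_fraction: float = 0.2, k_folds: int = 5,
                       dataset_id: str = "", cell_type: str = "",
                       ) -> EliminationCurve:
    """Retrain and score the classifier along the percentile-elimination path.

    Thresholds run from the pool's lowest percentile (the Z = 1.00 rank) to
    1.00 in increments of ``step``; thresholds that leave the surviving gene
    count unchanged are evaluated once. At each distinct count the classifier
    is trained on the surviving ranked genes and on ``n_random`` equal-size
    random sets drawn from all detected genes (each with a distinct sub-seed);
    the benchmark accuracy is the mean over random sets.
    """
    if pool.empty:
        raise ValueError("empty candidate pool")
    percentiles = pool["percentile"].to_numpy()
    start = float(percentiles.min())
    thresholds = np.arange(start, 1.0 + step / 2, step)
    rng = np.random.default_rng(seed)
    all_genes = np.array(m.gene_ids)

    rows, seen = [], set()
    for t in thresholds:
        surviving = pool.index[percentiles >= t - 1e-12]
        n = len(surviving)
        if n == 0 or n in seen:
            continue
        seen.add(n)
        _, res, _, _ = run_pipeline(m, list(surviving), spec, seed=seed,
                                    test_fraction=test_fraction, k_folds=k_folds)
        acc_lime = res.mean_balanced_accuracy
        rand_accs = []
        for r in range(n_random):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            rand_rng = np.random.default_rng(sub_seed)
            rand_genes = rand_rng.choice(all_genes, size=n, replace=False)
            _, rres, _, _ = run_pipeline(m, list(rand_genes), spec, seed=seed,
                                         test_fraction=test_fraction,
                                         k_folds=k_folds)
            rand_accs.append(rres.mean_balanced_accuracy)
        acc_rand = float(np.mean(rand_accs))
        rows.append({"threshold": float(t), "n_genes": n,
                     "acc_lime": acc_lime, "acc_random": acc_rand,
                     "delta": acc_lime - acc_rand})
    records = pd.DataFrame(rows).sort_values("n_genes", ascending=False,
                                             ignore_index=True)
    return EliminationCurve(records=records, dataset_id=dataset_id,
                            cell_type=cell_type, pool=pool)


def optimal_gene_set(curves: Sequence[EliminationCurve], cell_type: str = ""
                     ) -> OptimalGeneSet:
    """argmax over nested threshold sets of the summed accuracy gap.

    Curves must share the same ranked pool; the gap sum is taken over all
    supplied curves at each common gene count, ties resolved toward the
    smallest set.
    """
    if not curves:
        raise ValueError("need at least one elimination curve")
    pools = [tuple(c.pool.index) for c in curves if c.pool is not None]
    if len(set(pools)) > 1:
        raise ValueError("curves were built from different ranked pools")
    common = set(curves[0].records["n_genes"])
    for c in curves[1:]:
        common &= set(c.records["n_genes"])
    if not common:
        raise ValueError("curves share no gene counts; threshold grids disagree")
    delta_sum = {}
    for n in common:
        delta_sum[n] = sum(
            float(c.records.loc[c.records["n_genes"] == n, "delta"].iloc[0])
            for c in curves
        )
    best = max(delta_sum.items(), key=lambda kv: (kv[1], -kv[0]))
    n_best, d_best = int(best[0]), float(best[1])
    genes = curves[0].genes_at(n_best)
    return OptimalGeneSet(
        cell_type=cell_type, gene_ids=genes, n_genes=n_best, delta_sum=d_best,
        provenance={"datasets": [c.dataset_id for c in curves]},
    )


def _balance_conditions(m: CellMatrix, seed: int) -> CellMatrix:
    """Down-sample the majority condition to the minority cell count."""
    y = m.labels()
    counts = pd.Series(y).value_counts()
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = np.zeros(m.n_cells, dtype=bool)
    for cond in counts.index:
        idx = np.where(y == cond)[0]
        keep[rng.choice(idx, size=n_min, replace=False)] = True
    return m.subset_cells(keep)


@dataclass
class TransferResult:
    """LIME-set vs random-set accuracies on an independent target dataset."""

    accuracies: pd.DataFrame  # columns: permutation, acc_lime, acc_random
    wins: int
    n_permutations: int
    rank_sum_p: float
    missing_genes: list[str]

    @property
    def mean_difference(self) -> float:
        return float((self.accuracies["acc_lime"]
                      - self.accuracies["acc_random"]).mean())


def transfer_evaluate(target: CellMatrix, gene_set: OptimalGeneSet | Sequence[str],
                      spec: ClassifierSpec, n_random: int = 10, seed: int = 0,
                      balance: bool = False, test_fraction: float = 0.2,
                      k_folds: int = 5,
                      random_genes: Sequence[str] | None = None) -> TransferResult:
    """Does the optimal gene set beat random equal-size sets on new data?

    ``n_random`` permutations each retrain the classifier with the gene set
    (re-seeded) and with a fresh random equal-size set (distinct sub-seed);
    the two accuracy samples are compared with a two-sided rank-sum test.
    ``balance=True`` first down-samples the majority condition so case and
    control cell counts match.
    """
    if n_random < 2:
        raise ValueError("need >= 2 permutations for the rank-sum test")
    genes = list(gene_set.gene_ids) if isinstance(gene_set, OptimalGeneSet) else list(gene_set)
    detected = set(target.gene_ids)
    missing = [g for g in genes if g not in detected]
    if missing:
        warnings.warn(f"{len(missing)} gene(s) of the set absent from target")
    genes = [g for g in genes if g in detected]
    if not genes:
        raise ValueError("no gene of the set is detected in the target")
    if balance:
        target = _balance_conditions(target, seed)
    pool = np.array(sorted(detected)) if random_genes is None else np.array(random_genes)
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_random):
        run_seed = int(rng.integers(0, 2**31 - 1))
        _, res_l, _, _ = run_pipeline(target, genes, spec, seed=run_seed,
                                      test_fraction=test_fraction, k_folds=k_folds)
        rand_genes = np.random.default_rng(int(rng.integers(0, 2**31 - 1))
                                           ).choice(pool, size=len(genes),
                                                    replace=False)
        _, res_r, _, _ = run_pipeline(target, list(rand_genes), spec,
                                      seed=run_seed,
                                      test_fraction=test_fraction, k_folds=k_folds)
        rows.append({"permutation": p,
                     "acc_lime": res_l.mean_balanced_accuracy,
                     "acc_random": res_r.mean_balanced_accuracy})
    acc = pd.DataFrame(rows)
    stat = stats.ranksums(acc["acc_lime"], acc["acc_random"])
    return TransferResult(
        accuracies=acc,
        wins=int((acc["acc_lime"] > acc["acc_random"]).sum()),
        n_permutations=n_random,
        rank_sum_p=float(stat.pvalue),
        missing_genes=missing,
    )
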