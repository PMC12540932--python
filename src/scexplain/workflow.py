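"""File-to-file pipeline stages with a run manifest.

Stages communicate only through files inside the run directory, so any stage
output (for instance a precomputed cell-by-topic matrix) can be substituted
externally. Each stage appends a manifest entry recording its configuration
hash, seed, package versions and input/output checksums, giving a fully
reproducible trail for a run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .burden import burden_report, read_variants
from .classify import ClassifierSpec, run_pipeline
from .core_data import (
    CellMatrix,
    QCThresholds,
    load_matrix,
    normalize_log,
    qc_filter,
    split_train_test,
    write_matrix,
    write_qc_report,
)
from .dge import log2fc, prioritize
from .explain import BackgroundStats, LimeConfig, importance_table
from .features import select_hvg
from .geneset import (
    candidate_pool,
    elimination_curves,
    mean_z,
    optimal_gene_set,
    transfer_evaluate,
)
from .synthetic import SimulationConfig, write_simulation

STAGES = ("simulate", "qc", "features", "train", "explain", "optimal-set",
          "transfer", "prioritize", "burden")


class DependencyError(FileNotFoundError):
    """An upstream stage artifact needed by this stage is missing."""


@dataclass
class RunConfig:
    """Everything a run needs: paths, thresholds, specs, seeds.

    Serialized as YAML; :meth:`from_yaml` / :meth:`to_yaml` round-trip the
    configuration unchanged so the manifest hash is stable.
    """

    out_dir: str = "run"
    seed: int = 0
    cell_type: str | None = None
    input_matrix: str | None = None  # external input; defaults to simulate output
    simulation: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=lambda: {"family": "nn"})
    lime: dict = field(default_factory=dict)
    scale_target: float | None = None
    test_fraction: float = 0.2
    k_folds: int = 5
    elimination_step: float = 0.001
    n_random: int = 10
    z_min: float = 1.0
    lfc_min: float = 0.25
    target_matrix: str | None = None
    annotation_table: str | None = None
    variant_table: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dict(self.__dict__), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _checksums(paths: list[Path]) -> dict[str, str]:
    return {str(p): _sha256(p) for p in paths if p.is_file()}


def _append_manifest(run_dir: Path, stage: str, cfg: RunConfig,
                     inputs: list[Path], outputs: list[Path]) -> None:
    manifest = run_dir / "manifest.json"
    entries = json.loads(manifest.read_text()) if manifest.exists() else []
    entries.append({
        "stage": stage,
        "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "inputs": _checksums(inputs),
        "outputs": _checksums(outputs),
    })
    manifest.write_text(json.dumps(entries, indent=2))


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"missing artifact {path}; run the '{produced_by}' stage first")
    return path


def _load_normalized(run_dir: Path, cfg: RunConfig, which: str = "qc_matrix"
                     ) -> CellMatrix:
    m = load_matrix(_require(run_dir / which / "matrix.mtx", "qc").parent)
    if cfg.cell_type is not None:
        m = m.subset_cell_type(cfg.cell_type)
    return normalize_log(m, cfg.scale_target)


def run_synthetic_study(seed: int = 0,
                        sim: SimulationConfig | None = None,
                        lime_perturbations: int = 1000,
                        max_cells_per_subject: int | None = 15,
                        classifier_family: str = "nn",
                        curve_family: str = "lr",
                        n_random: int = 10,
                        with_randomization: bool = True) -> dict:
    """End-to-end reference study on one synthetic dataset.

    Simulates a case/control cohort (default: the reference conditions of
    :class:`~scexplain.synthetic.SimulationConfig`), runs QC-free
    normalization, HVG selection, five-fold CV classifier training, the
    local-surrogate importance chain, and percentile-elimination optimal
    gene-set selection. The faster ``curve_family`` classifier retrains the
    many elimination/benchmark models; the main classifier is
    ``classifier_family``. Returns a dict with the matrix, ground truth,
    importance table, elimination curve, optimal set and summary numbers.
    """
    from .synthetic import randomize_labels, simulate_counts

    sim = sim if sim is not None else SimulationConfig(seed=seed)
    m, truth = simulate_counts(sim)
    m = normalize_log(m)
    cell_type = str(m.obs["cell_type"].iloc[0])
    planted = truth.genes(cell_type)

    spec = ClassifierSpec(family=classifier_family, seed=seed)
    train, _ = split_train_test(m, 0.2, seed=seed)
    hvg = select_hvg(train)
    models, result, train, test = run_pipeline(m, hvg.gene_ids, spec, seed=seed)

    randomized_acc = None
    if with_randomization:
        mr = randomize_labels(m, 1.0, seed=seed)
        _, res_r, _, _ = run_pipeline(mr, hvg.gene_ids, spec, seed=seed)
        randomized_acc = res_r.mean_balanced_accuracy

    background = BackgroundStats.from_matrix(train.lognorm(hvg.gene_ids),
                                             hvg.gene_ids)
    lime_cfg = LimeConfig(n_perturbations=lime_perturbations, seed=seed,
                          max_cells_per_subject=max_cells_per_subject)
    table = importance_table(models, result, test.lognorm(hvg.gene_ids),
                             test.obs, background, lime_cfg, m)

    planted_in_hvg = [g for g in planted if g in table.index]
    recovery_pct = (100.0 * float((table.loc[planted_in_hvg, "Z"] > 1.0).sum())
                    / len(planted)) if planted else float("nan")

    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        meanz = mean_z([table])
    pool = candidate_pool(meanz)
    curve = elimination_curves(m, pool, ClassifierSpec(family=curve_family,
                                                       seed=seed),
                               n_random=n_random, seed=seed,
                               dataset_id=sim.dataset_id, cell_type=cell_type)
    optimal = optimal_gene_set([curve], cell_type=cell_type)

    return {
        "matrix": m, "truth": truth, "hvg": hvg, "models": models,
        "evaluation": result, "importance_table": table, "pool": pool,
        "curve": curve, "optimal_set": optimal,
        "baseline_accuracy": result.mean_balanced_accuracy,
        "randomized_accuracy": randomized_acc,
        "planted_recovery_pct": recovery_pct,
        "optimal_set_size": optimal.n_genes,
        "n_planted": len(planted),
    }


def run_stage(cfg: RunConfig, stage: str) -> dict:
    """Execute one pipeline stage; returns a small summary dict."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stage": stage}

    if stage == "simulate":
        sim_cfg = SimulationConfig(**{"seed": cfg.seed, **cfg.simulation})
        out = run_dir / "sim_matrix"
        m, truth = write_simulation(sim_cfg, out)
        summary.update(n_cells=m.n_cells, n_genes=m.n_genes)
        _append_manifest(run_dir, stage, cfg, [],
                         sorted(out.glob("*")))

    elif stage == "qc":
        src = Path(cfg.input_matrix) if cfg.input_matrix else run_dir / "sim_matrix"
        _require(src / "matrix.mtx", "simulate")
        m = load_matrix(src)
        filtered = qc_filter(m, QCThresholds(**cfg.qc))
        out = run_dir / "qc_matrix"
        write_matrix(filtered, out)
        write_qc_report(filtered, run_dir / "qc_report.tsv")
        summary.update(cells_in=m.n_cells, cells_out=filtered.n_cells)
        _append_manifest(run_dir, stage, cfg, sorted(src.glob("*")),
                         [*sorted(out.glob("*")), run_dir / "qc_report.tsv"])

    elif stage == "features":
        m = _load_normalized(run_dir, cfg)
        train, _ = split_train_test(m, cfg.test_fraction, seed=cfg.seed)
        space = select_hvg(train)
        out = run_dir / "features"
        space.save(out)
        summary.update(n_hvg=space.n_features)
        _append_manifest(run_dir, stage, cfg,
                         sorted((run_dir / "qc_matrix").glob("*")),
                         sorted(out.glob("*")))

    elif stage == "train":
        genes_f = _require(run_dir / "features" / "genes.tsv", "features")
        genes = pd.read_csv(genes_f, sep="\t")["gene_id"].tolist()
        m = _load_normalized(run_dir, cfg)
        spec = ClassifierSpec(seed=cfg.seed, **cfg.classifier)
        models, result, train, test = run_pipeline(
            m, genes, spec, seed=cfg.seed, test_fraction=cfg.test_fraction,
            k_folds=cfg.k_folds)
        result.to_frame().to_csv(run_dir / "evaluation.tsv", sep="\t", index=False)
        (run_dir / "evaluation.json").write_text(json.dumps({
            "mean_balanced_accuracy": result.mean_balanced_accuracy,
            "std_balanced_accuracy": result.std_balanced_accuracy,
            "family": spec.family, "seed": cfg.seed,
        }, indent=2))
        preds = pd.DataFrame(result.predictions.T, index=result.cell_ids)
        preds.to_csv(run_dir / "predictions.tsv", sep="\t")
        summary.update(mean_balanced_accuracy=result.mean_balanced_accuracy)
        _append_manifest(run_dir, stage, cfg, [genes_f],
                         [run_dir / "evaluation.tsv", run_dir / "evaluation.json",
                          run_dir / "predictions.tsv"])

    elif stage == "explain":
        genes_f = _require(run_dir / "features" / "genes.tsv", "features")
        _require(run_dir / "evaluation.tsv", "train")
        genes = pd.read_csv(genes_f, sep="\t")["gene_id"].tolist()
        m = _load_normalized(run_dir, cfg)
        spec = ClassifierSpec(seed=cfg.seed, **cfg.classifier)
        models, result, train, test = run_pipeline(
            m, genes, spec, seed=cfg.seed, test_fraction=cfg.test_fraction,
            k_folds=cfg.k_folds)
        background = BackgroundStats.from_matrix(train.lognorm(genes), genes)
        lime_cfg = LimeConfig(**{"seed": cfg.seed, **cfg.lime})
        table = importance_table(models, result, test.lognorm(genes),
                                 test.obs, background, lime_cfg, m)
        table.to_csv(run_dir / "importance_table.tsv", sep="\t")
        summary.update(n_genes=len(table),
                       n_cells_explained=table.attrs["n_cells_explained"])
        _append_manifest(run_dir, stage, cfg, [genes_f],
                         [run_dir / "importance_table.tsv"])

    elif stage == "optimal-set":
        tbl_f = _require(run_dir / "importance_table.tsv", "explain")
        table = pd.read_csv(tbl_f, sep="\t", index_col=0)
        meanz = mean_z([table])
        pool = candidate_pool(meanz, z_min=cfg.z_min)
        m = _load_normalized(run_dir, cfg)
        spec = ClassifierSpec(seed=cfg.seed, **cfg.classifier)
        curve = elimination_curves(m, pool, spec, step=cfg.elimination_step,
                                   n_random=cfg.n_random, seed=cfg.seed,
                                   test_fraction=cfg.test_fraction,
                                   k_folds=cfg.k_folds)
        curve.records.to_csv(run_dir / "elimination_curve.tsv", sep="\t",
                             index=False)
        optimal = optimal_gene_set([curve], cell_type=cfg.cell_type or "")
        optimal.to_tsv(run_dir / "optimal_gene_set.tsv")
        optimal.to_json(run_dir / "optimal_gene_set.json")
        summary.update(n_genes=optimal.n_genes, delta_sum=optimal.delta_sum)
        _append_manifest(run_dir, stage, cfg, [tbl_f],
                         [run_dir / "elimination_curve.tsv",
                          run_dir / "optimal_gene_set.tsv",
                          run_dir / "optimal_gene_set.json"])

    elif stage == "transfer":
        set_f = _require(run_dir / "optimal_gene_set.tsv", "optimal-set")
        genes = pd.read_csv(set_f, sep="\t")["gene_id"].tolist()
        if cfg.target_matrix is None:
            raise DependencyError("transfer stage needs cfg.target_matrix")
        target = load_matrix(Path(cfg.target_matrix))
        if cfg.cell_type is not None:
            target = target.subset_cell_type(cfg.cell_type)
        target = normalize_log(target, cfg.scale_target)
        spec = ClassifierSpec(seed=cfg.seed, **cfg.classifier)
        res = transfer_evaluate(target, genes, spec, n_random=cfg.n_random,
                                seed=cfg.seed, test_fraction=cfg.test_fraction,
                                k_folds=cfg.k_folds)
        res.accuracies.to_csv(run_dir / "transfer.tsv", sep="\t", index=False)
        summary.update(wins=res.wins, rank_sum_p=res.rank_sum_p,
                       mean_difference=res.mean_difference)
        _append_manifest(run_dir, stage, cfg, [set_f], [run_dir / "transfer.tsv"])

    elif stage == "prioritize":
        set_f = _require(run_dir / "optimal_gene_set.tsv", "optimal-set")
        tbl_f = _require(run_dir / "importance_table.tsv", "explain")
        genes = pd.read_csv(set_f, sep="\t")["gene_id"].tolist()
        table = pd.read_csv(tbl_f, sep="\t", index_col=0)
        m = _load_normalized(run_dir, cfg)
        ct = cfg.cell_type or str(m.obs["cell_type"].iloc[0])
        ann = (pd.read_csv(cfg.annotation_table, sep="\t")
               if cfg.annotation_table else None)
        out = prioritize({ct: genes}, {ct: table["Z"]},
                         {ct: log2fc(m, ct)}, ann, lfc_min=cfg.lfc_min)
        out.to_csv(run_dir / "prioritized.tsv", sep="\t", index=False)
        summary.update(n_prioritized=len(out))
        _append_manifest(run_dir, stage, cfg, [set_f, tbl_f],
                         [run_dir / "prioritized.tsv"])

    elif stage == "burden":
        if cfg.variant_table is None:
            raise DependencyError("burden stage needs cfg.variant_table")
        variants = read_variants(_require(Path(cfg.variant_table), "burden input"))
        report = burden_report(variants)
        report.to_csv(run_dir / "burden.tsv", sep="\t", index=False)
        summary.update(n_rows=len(report))
        _append_manifest(run_dir, stage, cfg, [Path(cfg.variant_table)],
                         [run_dir / "burden.tsv"])

    (run_dir / "run_config.yaml").exists() or cfg.to_yaml(run_dir / "run_config.yaml")
    return summary
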