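"""Synthetic multi-subject, multi-cell-type count matrices with planted signal.

The generator emulates the statistical features a case/control single-nucleus
study presents to the pipeline: overdispersed (negative-binomial) counts,
log-normal gene baseline means, log-normal library sizes, per-subject random
effects shared by all of a subject's cells, and cell-type-specific
condition-associated genes whose means are multiplied by ``2**log2_effect``
in case cells. Ground truth (which genes carry signal, and how much) is
returned alongside the matrix so recovery can be measured downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from .core_data import CellMatrix, write_matrix


class ConfigError(ValueError):
    """Degenerate or inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic case/control study.

    Defaults describe the reference study conditions used throughout the test
    suite: 6 case + 6 control subjects with 150 cells each, 2000 genes, one
    cell type, and 20 planted genes up-regulated two-fold (log2 effect 1.0)
    in case cells. ``signal_genes`` maps cell type -> [(gene index, log2
    effect)]; when None, ``n_signal_genes`` genes are drawn (per cell type)
    from the upper half of baseline expression, since disease markers must be
    detectably expressed to be discoverable.
    """

    n_case_subjects: int = 6
    n_control_subjects: int = 6
    cells_per_subject: int | Sequence[int] = 150
    n_genes: int = 2000
    cell_types: Sequence[tuple[str, float]] = (("DaNeurons", 1.0),)
    signal_genes: Mapping[str, Sequence[tuple[int, float]]] | None = None
    n_signal_genes: int = 20
    signal_log2_effect: float = 1.0
    baseline_log_mean_mu: float = float(np.log(0.5))
    baseline_log_mean_sd: float = 1.0
    nb_dispersion: float = 2.0
    subject_effect_sd: float = 0.15
    library_size_log_mean: float = 0.0
    library_size_log_sd: float = 0.35
    dataset_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case_subjects < 1 or self.n_control_subjects < 1:
            raise ConfigError("need at least one subject per condition")
        if self.n_genes < 1:
            raise ConfigError("need at least one gene")
        props = [p for _, p in self.cell_types]
        if abs(sum(props) - 1.0) > 1e-8 or min(props) <= 0:
            raise ConfigError("cell type proportions must be positive and sum to 1")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.subject_effect_sd < 0:
            raise ConfigError("subject_effect_sd must be >= 0")
        if self.signal_genes is not None:
            names = {n for n, _ in self.cell_types}
            for ct, pairs in self.signal_genes.items():
                if ct not in names:
                    raise ConfigError(f"signal cell type {ct!r} not simulated")
                for idx, eff in pairs:
                    if not 0 <= idx < self.n_genes:
                        raise ConfigError(f"signal gene index {idx} out of range")
                    if not np.isfinite(eff):
                        raise ConfigError("effect sizes must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cell_types" in raw:
            raw["cell_types"] = [tuple(x) for x in raw["cell_types"]]
        if raw.get("signal_genes"):
            raw["signal_genes"] = {
                ct: [tuple(x) for x in pairs] for ct, pairs in raw["signal_genes"].items()
            }
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dict(self.__dict__)
        d["cell_types"] = [list(x) for x in self.cell_types]
        if d["signal_genes"] is not None:
            d["signal_genes"] = {
                ct: [list(x) for x in pairs] for ct, pairs in d["signal_genes"].items()
            }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Planted signal per cell type: gene identifiers and log2 effect sizes."""

    signal: Mapping[str, Sequence[tuple[str, float]]] = field(default_factory=dict)

    def genes(self, cell_type: str) -> list[str]:
        return [g for g, _ in self.signal.get(cell_type, [])]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cell_type": ct, "gene_id": g, "log2_effect": e}
            for ct, pairs in self.signal.items()
            for g, e in pairs
        ]
        return pd.DataFrame(rows, columns=["cell_type", "gene_id", "log2_effect"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t")
        sig: dict[str, list[tuple[str, float]]] = {}
        for _, row in df.iterrows():
            sig.setdefault(str(row["cell_type"]), []).append(
                (str(row["gene_id"]), float(row["log2_effect"]))
            )
        return cls(sig)


def simulate_counts(cfg: SimulationConfig) -> tuple[CellMatrix, GroundTruth]:
    """Draw a synthetic study from ``cfg``; reproducible given ``cfg.seed``.

    Count model for cell c (subject i, cell type t) and gene g:

        mu[c, g] = base[g] * subj[i, g] * 2**effect(t, cond(i), g) * lib[c]
        count[c, g] ~ NB(mean=mu[c, g], dispersion=theta)

    with ``var = mu + mu**2 / theta``, ``base`` log-normal, ``subj`` a
    log-normal per-(subject, gene) random effect, and ``lib`` a log-normal
    per-cell library-size factor.
    """
    rng = np.random.default_rng(cfg.seed)
    n_subj = cfg.n_case_subjects + cfg.n_control_subjects
    conditions = ["case"] * cfg.n_case_subjects + ["control"] * cfg.n_control_subjects
    subjects = [f"{c.upper()[:4]}_{i:02d}" for i, c in enumerate(conditions)]

    if isinstance(cfg.cells_per_subject, int):
        cells_per = [cfg.cells_per_subject] * n_subj
    else:
        cells_per = list(cfg.cells_per_subject)
        if len(cells_per) != n_subj:
            raise ConfigError("cells_per_subject list length must equal subject count")

    gene_ids = np.array([f"G{j:04d}" for j in range(cfg.n_genes)])
    base = rng.lognormal(cfg.baseline_log_mean_mu, cfg.baseline_log_mean_sd, cfg.n_genes)

    # Planted signal: explicit map, or auto-drawn from the upper half of
    # baseline expression (markers must be expressed to be discoverable).
    if cfg.signal_genes is not None:
        signal = {ct: list(pairs) for ct, pairs in cfg.signal_genes.items()}
    else:
        expressed = np.where(base >= np.median(base))[0]
        signal = {}
        for ct, _ in cfg.cell_types:
            chosen = rng.choice(expressed, size=min(cfg.n_signal_genes, len(expressed)),
                                replace=False)
            signal[ct] = [(int(j), float(cfg.signal_log2_effect)) for j in np.sort(chosen)]
    truth = GroundTruth({
        ct: [(str(gene_ids[j]), e) for j, e in pairs] for ct, pairs in signal.items()
    })

    ct_names = [n for n, _ in cfg.cell_types]
    ct_props = np.array([p for _, p in cfg.cell_types])

    blocks, obs_rows, cell_ids = [], [], []
    theta = cfg.nb_dispersion
    for i, (subj, cond, n_cells) in enumerate(zip(subjects, conditions, cells_per)):
        subj_eff = (
            rng.lognormal(0.0, cfg.subject_effect_sd, cfg.n_genes)
            if cfg.subject_effect_sd > 0 else np.ones(cfg.n_genes)
        )
        # multinomial cell-type assignment within subject
        cts = rng.choice(len(ct_names), size=n_cells, p=ct_props)
        lib = rng.lognormal(cfg.library_size_log_mean, cfg.library_size_log_sd, n_cells)
        mu = np.outer(lib, base * subj_eff)
        if cond == "case":
            for t_idx, ct in enumerate(ct_names):
                pairs = signal.get(ct, [])
                if not pairs:
                    continue
                rows = cts == t_idx
                if rows.any():
                    cols = np.array([j for j, _ in pairs])
                    effs = np.array([e for _, e in pairs])
                    mu[np.ix_(rows, cols)] *= 2.0 ** effs
        p = theta / (theta + mu)
        blocks.append(rng.negative_binomial(theta, p))
        for k in range(n_cells):
            cell_ids.append(f"{subj}_c{k:04d}")
            obs_rows.append((subj, cond, ct_names[cts[k]], cfg.dataset_id))

    X = np.vstack(blocks).astype(np.int64)
    obs = pd.DataFrame(
        obs_rows, columns=["subject_id", "condition", "cell_type", "dataset_id"],
        index=pd.Index(cell_ids, name="cell_id"),
    )
    adata = ad.AnnData(X=X, obs=obs,
                       var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")))
    return CellMatrix(adata), truth


def randomize_labels(m: CellMatrix, fraction: float, seed: int = 0,
                     mode: str = "uniform") -> CellMatrix:
    """Return a copy of ``m`` with a fraction of condition labels randomized.

    ``round(fraction * n)`` cells are chosen without replacement. In
    ``uniform`` mode each chosen cell's condition is redrawn uniformly from
    {case, control} (it may keep its label); ``flip`` mode inverts it.
    Counts and all other metadata are untouched; ``fraction=0`` is identity.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if mode not in ("uniform", "flip"):
        raise ValueError("mode must be 'uniform' or 'flip'")
    out = m.copy()
    n_pick = int(round(fraction * m.n_cells))
    if n_pick == 0:
        return out
    rng = np.random.default_rng(seed)
    picked = rng.choice(m.n_cells, size=n_pick, replace=False)
    cond = out.adata.obs["condition"].to_numpy(dtype=object)
    if mode == "uniform":
        cond[picked] = rng.choice(["case", "control"], size=n_pick)
    else:
        flip = {"case": "control", "control": "case"}
        cond[picked] = [flip[c] for c in cond[picked]]
    out.adata.obs["condition"] = pd.Categorical(cond, categories=["case", "control"])
    out.adata.obs["condition"] = out.adata.obs["condition"].astype(str)
    return out


def write_simulation(cfg: SimulationConfig, out_dir: str | Path
                     ) -> tuple[CellMatrix, GroundTruth]:
    """Simulate and persist matrix (MTX+TSV layout) plus ground truth TSV."""
    out_dir = Path(out_dir)
    m, truth = simulate_counts(cfg)
    write_matrix(m, out_dir)
    truth.to_tsv(out_dir / "ground_truth.tsv")
    cfg.to_yaml(out_dir / "simulation_config.yaml")
    return m, truth
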