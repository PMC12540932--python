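"""Rare-variant gene burden testing: damaging-missense classification,
rare-allele-frequency filtering, per-cohort Fisher exact tests, and the
Cochran–Mantel–Haenszel test across cohorts.

Counting is carrier-based (dominant model): a subject counts once per arm
regardless of how many qualifying variants they carry. Variant tables arrive
pre-annotated (consequence category, AlphaMissense label, CADD score,
population allele frequency, per-cohort carrier counts); annotation itself is
out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable as _SMStratified

CATEGORIES = ("lof", "missense", "synonymous")
AM_LABELS = ("pathogenic", "ambiguous", "benign", "missing")


@dataclass(frozen=True)
class CohortCounts:
    """Carrier counts for one variant (or aggregate) in one cohort arm pair."""

    case_carriers: int
    case_total: int
    control_carriers: int
    control_total: int

    def __post_init__(self) -> None:
        if min(self.case_carriers, self.case_total,
               self.control_carriers, self.control_total) < 0:
            raise ValueError("counts must be non-negative")
        if (self.case_carriers > self.case_total
                or self.control_carriers > self.control_total):
            raise ValueError("carriers cannot exceed totals")


@dataclass
class VariantRecord:
    """One annotated coding variant with per-cohort carrier counts."""

    variant_id: str
    gene: str
    category: str  # lof | missense | synonymous
    amissense_label: str = "missing"  # pathogenic | ambiguous | benign | missing
    cadd: float | None = None
    allele_frequency: float | None = None
    cohorts: Mapping[str, CohortCounts] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")
        if self.amissense_label not in AM_LABELS:
            raise ValueError(f"amissense_label must be one of {AM_LABELS}")
        if self.allele_frequency is not None and not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError("allele_frequency must lie in [0, 1]")


@dataclass
class StratifiedCounts:
    """Per-stratum 2x2 carrier tables: a=case carriers, b=case non-carriers,
    c=control carriers, d=control non-carriers."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.a, self.b = np.atleast_1d(self.a), np.atleast_1d(self.b)
        self.c, self.d = np.atleast_1d(self.c), np.atleast_1d(self.d)
        if not (len(self.a) == len(self.b) == len(self.c) == len(self.d)):
            raise ValueError("stratum arrays must share a length")
        if len(self.a) < 1:
            raise ValueError("need at least one stratum")
        for arr in (self.a, self.b, self.c, self.d):
            if (np.asarray(arr) < 0).any():
                raise ValueError("all entries must be >= 0")
        if not self.labels:
            self.labels = [f"stratum_{i}" for i in range(len(self.a))]


def classify_damaging(v: VariantRecord) -> bool:
    """Damaging-missense rule: AlphaMissense "pathogenic", or "ambiguous"
    with CADD strictly above 20. Missing annotations count as not damaging
    (with a warning). Only missense variants may be classified."""
    if v.category != "missense":
        raise ValueError("classify_damaging applies to missense variants only")
    if v.amissense_label == "pathogenic":
        return True
    if v.amissense_label == "ambiguous":
        if v.cadd is None:
            warnings.warn(f"{v.variant_id}: ambiguous label without CADD; "
                          "treated as not damaging")
            return False
        return v.cadd > 20.0
    if v.amissense_label == "missing":
        warnings.warn(f"{v.variant_id}: missing AlphaMissense label; "
                      "treated as not damaging")
    return False


def rare_filter(variants: Sequence[VariantRecord], af_max: float = 0.01
                ) -> list[VariantRecord]:
    """Keep variants with population allele frequency strictly below
    ``af_max``; a missing frequency (absent from the reference) is kept and
    flagged with a warning."""
    kept = []
    for v in variants:
        if v.allele_frequency is None:
            warnings.warn(f"{v.variant_id}: no reference allele frequency; "
                          "kept as rare")
            kept.append(v)
        elif v.allele_frequency < af_max:
            kept.append(v)
    return kept


def fisher_burden(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of one 2x2 carrier table.

    Returns (odds ratio, P). OR = (a·d)/(b·c); on a zero margin the Haldane
    half-count correction is applied and a warning raised. The two-sided P
    sums hypergeometric probabilities no larger than the observed table's.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0 or a * d == 0:
        if b * c == 0:
            warnings.warn("zero margin: Haldane-corrected odds ratio reported")
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)) \
            if b * c == 0 else (a * d) / (b * c)
    else:
        orr = (a * d) / (b * c)
    return float(orr), float(p)


def cmh_test(t: StratifiedCounts, continuity: bool = False
             ) -> tuple[float, float, float]:
    """Cochran–Mantel–Haenszel test across strata (cohorts).

    Returns (Mantel–Haenszel common odds ratio, 1-df chi-square statistic,
    two-sided P). The statistic is (|Σa − ΣE[a]| − ½·continuity)² / ΣVar(a)
    with hypergeometric expectation and variance per stratum; the common OR
    is Σ(a·d/n) / Σ(b·c/n). All-zero strata are dropped with a warning.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (t.a, t.b, t.c, t.d))
    n = a + b + c + d
    keep = n > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} empty stratum(s)")
        a, b, c, d, n = a[keep], b[keep], c[keep], d[keep], n[keep]
    if len(n) == 0:
        raise ValueError("no informative stratum")
    row1, col1 = a + b, a + c
    expect = row1 * col1 / n
    var = row1 * (n - row1) * col1 * (n - col1) / (n**2 * (n - 1.0))
    total_var = np.nansum(var)
    if total_var <= 0:
        raise ValueError("degenerate table: zero total variance")
    num = abs(a.sum() - expect.sum()) - (0.5 if continuity else 0.0)
    chi2 = max(num, 0.0) ** 2 / total_var
    p = float(stats.chi2.sf(chi2, df=1))
    # cross-check the common OR with the statsmodels implementation
    tables = np.stack([np.stack([a, b], axis=0), np.stack([c, d], axis=0)],
                      axis=0)  # 2 x 2 x k
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        orr = float(_SMStratified(tables).oddsratio_pooled)
    return orr, float(chi2), p


# ---------------------------------------------------------------------------
# Table assembly from variant records
# ---------------------------------------------------------------------------

def aggregate_burden(variants: Sequence[VariantRecord], category: str,
                     damaging_only: bool = False) -> StratifiedCounts:
    """Gene-burden 2x2 tables per cohort from qualifying variants.

    Carrier counts are summed over qualifying variants within each cohort
    (a carrier-count approximation that assumes carriers of distinct variants
    are distinct subjects, as in public variant-browser tables). ``lof``
    categories are typically excluded upstream when represented by a
    singleton variant.
    """
    qual = [v for v in variants if v.category == category]
    if damaging_only:
        qual = [v for v in qual if classify_damaging(v)]
    if not qual:
        raise ValueError(f"no qualifying {category} variants")
    cohorts = sorted({c for v in qual for c in v.cohorts})
    a, b, c_, d = [], [], [], []
    for coh in cohorts:
        carriers_case = sum(v.cohorts[coh].case_carriers
                            for v in qual if coh in v.cohorts)
        carriers_ctrl = sum(v.cohorts[coh].control_carriers
                            for v in qual if coh in v.cohorts)
        case_total = max(v.cohorts[coh].case_total
                         for v in qual if coh in v.cohorts)
        ctrl_total = max(v.cohorts[coh].control_total
                         for v in qual if coh in v.cohorts)
        a.append(carriers_case)
        b.append(max(case_total - carriers_case, 0))
        c_.append(carriers_ctrl)
        d.append(max(ctrl_total - carriers_ctrl, 0))
    return StratifiedCounts(np.array(a), np.array(b), np.array(c_),
                            np.array(d), labels=cohorts)


def burden_report(variants: Sequence[VariantRecord],
                  categories: Sequence[str] = ("missense", "synonymous"),
                  damaging_missense: bool = True, af_max: float = 0.01,
                  continuity: bool = False) -> pd.DataFrame:
    """Per-cohort Fisher and combined CMH burden results per category.

    Variants are rare-filtered first. For missense, a "damaging missense"
    stratum is added when ``damaging_missense`` is set. LoF is excluded by
    default (singleton categories carry no test information).
    """
    rare = rare_filter(variants, af_max=af_max)
    rows = []
    jobs = [(cat, False) for cat in categories]
    if damaging_missense and "missense" in categories:
        jobs.append(("missense", True))
    for cat, dmg in jobs:
        label = "damaging_missense" if dmg else cat
        try:
            table = aggregate_burden(rare, cat, damaging_only=dmg)
        except ValueError:
            warnings.warn(f"no qualifying variants for {label}; skipped")
            continue
        for i, coh in enumerate(table.labels):
            orr, p = fisher_burden(int(table.a[i]), int(table.b[i]),
                                   int(table.c[i]), int(table.d[i]))
            rows.append({"category": label, "cohort": coh, "test": "fisher",
                         "odds_ratio": orr, "statistic": np.nan, "p": p})
        if len(table.labels) > 1:
            orr, chi2, p = cmh_test(table, continuity=continuity)
            rows.append({"category": label, "cohort": "combined",
                         "test": "cmh", "odds_ratio": orr,
                         "statistic": chi2, "p": p})
    return pd.DataFrame(rows)


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV with per-cohort count columns.

    Required columns: variant_id, gene, category, amissense_label, cadd,
    allele_frequency, cohort, case_carriers, case_total, control_carriers,
    control_total — one row per (variant, cohort); cadd / allele_frequency
    may be empty.
    """
    df = pd.read_csv(path, sep="\t")
    out: dict[str, VariantRecord] = {}
    for _, r in df.iterrows():
        vid = str(r["variant_id"])
        if vid not in out:
            cadd = None if pd.isna(r.get("cadd")) else float(r["cadd"])
            af = (None if pd.isna(r.get("allele_frequency"))
                  else float(r["allele_frequency"]))
            out[vid] = VariantRecord(
                variant_id=vid, gene=str(r["gene"]),
                category=str(r["category"]),
                amissense_label=str(r.get("amissense_label", "missing")),
                cadd=cadd, allele_frequency=af, cohorts={},
            )
        out[vid].cohorts[str(r["cohort"])] = CohortCounts(
            case_carriers=int(r["case_carriers"]),
            case_total=int(r["case_total"]),
            control_carriers=int(r["control_carriers"]),
            control_total=int(r["control_total"]),
        )
    return list(out.values())
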