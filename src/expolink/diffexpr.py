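"""Per-study differential expression: unpaired t-tests, log2 fold change,
Benjamini-Hochberg adjustment and up/down gene-set selection.

A gene is called up-regulated when p* <= p_cutoff and logFC >= lfc_cutoff,
down-regulated when p* <= p_cutoff and logFC <= -lfc_cutoff, where p* is the
BH-adjusted p-value by default (raw-p mode retained by flag) and
logFC = mean(case) - mean(control) on the log2 scale.  Test statistics are
computed on the Z-normalized matrix; logFC on the pre-normalization log2
matrix, since Z-scores carry no fold-change units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .studies import CASE, CONTROL, ExpressionStudy, zscore_normalize

T_TEST_VARIANTS = ("student", "welch")

STAT_COLUMNS = ["t", "p", "p_adj", "logFC", "direction"]


@dataclass(frozen=True)
class Thresholds:
    """Significance thresholds for DE gene selection."""

    p_cutoff: float = 0.01
    lfc_cutoff: float = 1.0
    use_adjusted: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.p_cutoff <= 1:
            raise ValueError("p_cutoff must be in (0, 1]")
        if self.lfc_cutoff < 0:
            raise ValueError("lfc_cutoff must be >= 0")


@dataclass(frozen=True)
class DiseaseGeneSet:
    """Significant up/down gene sets for one disease or exposure."""

    disease_id: str
    up: frozenset
    down: frozenset
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError(f"{self.disease_id}: up and down sets overlap")

    @property
    def genes(self) -> frozenset:
        return self.up | self.down

    def for_direction(self, direction: str) -> frozenset:
        if direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
        return self.up if direction == "up" else self.down


def ttest_unpaired(case_values, control_values, variant: str = "welch") -> tuple[float, float]:
    """Two-sided unpaired t-test; t sign follows mean(case) - mean(control)."""
    if variant not in T_TEST_VARIANTS:
        raise ValueError(f"unknown t-test variant {variant!r}")
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(case, ctrl, equal_var=(variant == "student"))
    return float(t), float(p)


def log_fold_change(case_values, control_values) -> float:
    """mean(case) - mean(control); inputs are assumed log2-scale."""
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("empty group")
    return float(case.mean() - ctrl.mean())


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    Shared by DE selection and enrichment so both stages adjust identically.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(study: ExpressionStudy, variant: str = "welch",
             lfc_source: ExpressionStudy | None = None,
             thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Per-gene statistics table (t, p, p_adj, logFC, direction).

    The t-test runs on the Z-normalized matrix; logFC comes from
    ``lfc_source`` (default: the raw input study).  Genes dropped by
    normalization (missing values, zero SD) do not appear.
    """
    if variant not in T_TEST_VARIANTS:
        raise ValueError(f"unknown t-test variant {variant!r}")
    thresholds = thresholds or Thresholds()
    z = zscore_normalize(study)
    if z.n_case < 2 or z.n_control < 2:
        raise ValueError(f"study {study.study_id!r}: need >=2 samples per group")
    case = z.case_matrix()
    ctrl = z.control_matrix()
    t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=(variant == "student"))
    lfc_study = lfc_source if lfc_source is not None else study
    lfc_vals = lfc_study.values.reindex(z.values.index)
    if lfc_vals.isna().any().any():
        raise ValueError("lfc_source is missing genes present in the test matrix")
    lfc = (
        lfc_vals.loc[:, z.group == CASE].mean(axis=1)
        - lfc_vals.loc[:, z.group == CONTROL].mean(axis=1)
    ).to_numpy()
    table = pd.DataFrame(
        {"t": t, "p": p, "p_adj": bh_adjust(p), "logFC": lfc},
        index=pd.Index(z.values.index, name="gene"),
    )
    return annotate_direction(table, thresholds)


def annotate_direction(table: pd.DataFrame, thresholds: Thresholds) -> pd.DataFrame:
    """Add/refresh the ``direction`` column per the selection rule."""
    pstar = table["p_adj"] if thresholds.use_adjusted else table["p"]
    sig = pstar <= thresholds.p_cutoff
    up = sig & (table["logFC"] >= thresholds.lfc_cutoff)
    down = sig & (table["logFC"] <= -thresholds.lfc_cutoff)
    out = table.copy()
    out["direction"] = np.where(up, "up", np.where(down, "down", "none"))
    return out


def select_significant(table: pd.DataFrame, disease_id: str,
                       thresholds: Thresholds | None = None) -> DiseaseGeneSet:
    """Apply the p*/logFC thresholds and return the up/down gene sets."""
    thresholds = thresholds or Thresholds()
    annotated = annotate_direction(table, thresholds)
    return DiseaseGeneSet(
        disease_id=disease_id,
        up=frozenset(annotated.index[annotated["direction"] == "up"]),
        down=frozenset(annotated.index[annotated["direction"] == "down"]),
        thresholds=thresholds,
    )


def write_gene_stats(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.10g", columns=STAT_COLUMNS)


def write_gene_set(gene_set: DiseaseGeneSet, path) -> None:
    """Two-column (gene, direction) text, lexicographic order."""
    rows = [(g, "up") for g in sorted(gene_set.up)] + [(g, "down") for g in sorted(gene_set.down)]
    pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(path, sep="\t", index=False)


def read_gene_set(path, disease_id: str | None = None,
                  thresholds: Thresholds | None = None) -> DiseaseGeneSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene", "direction"]:
        raise ValueError(f"{path}: expected columns (gene, direction)")
    up = frozenset(df.loc[df["direction"] == "up", "gene"].str.upper())
    down = frozenset(df.loc[df["direction"] == "down", "gene"].str.upper())
    return DiseaseGeneSet(disease_id or str(path), up, down, thresholds or Thresholds())
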