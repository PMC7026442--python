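"""Expression study containers, file IO, probe collapsing and Z-score normalization.

An :class:`ExpressionStudy` holds a genes x samples matrix of log2-scale
expression values ``g_ij`` together with a case/control label per sample.
Cross-platform comparability is obtained by the per-gene Z-score transform

    Z_ij = (g_ij - mean(g_i)) / SD(g_i)

computed across all samples of one study (cases and controls together), with
the sample (n-1) standard-deviation convention.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

COLLAPSE_POLICIES = ("max_mean", "max_abs_t", "first")


class ExpressionParseError(ValueError):
    """Malformed expression matrix or label input."""


@dataclass(eq=False)
class ExpressionStudy:
    """One expression study: genes x samples matrix plus sample groups.

    Parameters
    ----------
    study_id : str
        Identifier for the study (e.g. an exposure or a cancer type).
    values : pandas.DataFrame
        Genes (rows, symbols/probe ids) x samples (columns), log2-scale.
        Gene symbols are upper-cased on construction for cross-study matching.
    group : pandas.Series
        Maps each sample id to ``"case"`` or ``"control"``.
    dropped_genes : dict
        Bookkeeping of genes removed by normalization (``"missing"``,
        ``"constant"`` lists); empty for freshly constructed studies.
    """

    study_id: str
    values: pd.DataFrame
    group: pd.Series
    dropped_genes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = self.values.index.astype(str).str.upper()
        self.values.columns = self.values.columns.astype(str)
        group = pd.Series(self.group).astype(str)
        group.index = group.index.astype(str)
        missing = [s for s in self.values.columns if s not in group.index]
        if missing:
            raise ValueError(
                f"study {self.study_id!r}: samples without group label: {missing[:5]}"
            )
        bad = set(group.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"study {self.study_id!r}: unknown group labels {sorted(bad)}")
        self.group = group.reindex(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_case(self) -> int:
        return int((self.group == CASE).sum())

    @property
    def n_control(self) -> int:
        return int((self.group == CONTROL).sum())

    def case_matrix(self) -> np.ndarray:
        return self.values.loc[:, self.group == CASE].to_numpy(float)

    def control_matrix(self) -> np.ndarray:
        return self.values.loc[:, self.group == CONTROL].to_numpy(float)


def write_expression(study: ExpressionStudy, path) -> None:
    """Write the matrix as TSV (first column gene id, header of sample ids)."""
    study.values.to_csv(path, sep="\t", index_label="gene")


def write_labels(study: ExpressionStudy, path) -> None:
    """Write the sample -> group map as two-column TSV."""
    study.group.rename("group").to_csv(path, sep="\t", index_label="sample")


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ExpressionParseError(f"{path}: label file needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_expression(path, label_map: dict, study_id: str | None = None,
                    strict: bool = True) -> ExpressionStudy:
    """Parse a tab-separated expression matrix.

    First column holds gene/probe ids, the header row holds sample ids.
    ``label_map`` assigns each sample to case/control; with ``strict=True``
    unlabeled samples are an error, otherwise they are dropped.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise ExpressionParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ExpressionParseError(f"{path}: line 1: header has no sample columns")
    samples = header[1:]
    dup = pd.Index(samples)[pd.Index(samples).duplicated()].tolist()
    if dup:
        raise ExpressionParseError(f"{path}: line 1: duplicated sample ids {dup}")
    n_fields = len(header)
    for i, ln in enumerate(lines[1:], start=2):
        got = ln.count("\t") + 1
        if got != n_fields:
            raise ExpressionParseError(
                f"{path}: line {i}: expected {n_fields} fields, got {got}"
            )
    if len(lines) == 1:
        raise ExpressionParseError(f"{path}: empty matrix (no gene rows)")
    try:
        df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", index_col=0,
                         float_precision="round_trip")
        df = df.astype(float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ExpressionParseError(f"{path}: {exc}") from exc

    unlabeled = [s for s in df.columns if str(s) not in label_map]
    if unlabeled:
        if strict:
            raise ExpressionParseError(f"{path}: samples missing from label map: {unlabeled[:5]}")
        df = df.drop(columns=unlabeled)
        log.warning("%s: dropped %d unlabeled samples", path, len(unlabeled))
    if df.shape[1] == 0:
        raise ExpressionParseError(f"{path}: no labeled samples remain")
    group = pd.Series({str(s): label_map[str(s)] for s in df.columns})
    return ExpressionStudy(study_id or str(path), df, group)


def collapse_probes(study: ExpressionStudy, probe_to_gene: dict,
                    policy: str = "max_mean") -> ExpressionStudy:
    """Collapse probe-level rows to one row per gene symbol.

    policy:
      - ``max_mean``  keep the probe with the highest mean expression
      - ``max_abs_t`` keep the probe with the largest |Welch t| (case vs control)
      - ``first``     keep the first probe in file order
    Unmapped probes are dropped (count logged).
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    if policy not in COLLAPSE_POLICIES:
        raise ValueError(f"unknown collapse policy {policy!r}")
    mapping = {str(k).upper(): str(v).upper() for k, v in probe_to_gene.items()}
    probes = study.values.index
    mapped = probes.isin(mapping)
    n_unmapped = int((~mapped).sum())
    if n_unmapped:
        log.warning("study %s: dropping %d unmapped probes", study.study_id, n_unmapped)
    vals = study.values.loc[mapped]
    if policy == "max_mean":
        score = vals.mean(axis=1).to_numpy()
    elif policy == "max_abs_t":
        case = vals.loc[:, study.group == CASE].to_numpy(float)
        ctrl = vals.loc[:, study.group == CONTROL].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t, _ = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
        score = np.abs(np.nan_to_num(t, nan=-np.inf))
    else:  # first
        score = -np.arange(len(vals), dtype=float)

    genes = np.array([mapping[p] for p in vals.index])
    keep_pos: dict[str, int] = {}
    for pos, (g, s) in enumerate(zip(genes, score)):
        if g not in keep_pos or s > score[keep_pos[g]]:
            keep_pos[g] = pos
    order = sorted(keep_pos.values())
    out = vals.iloc[order].copy()
    out.index = genes[order]
    return ExpressionStudy(study.study_id, out, study.group.copy())


def zscore_normalize(study: ExpressionStudy, ddof: int = 1) -> ExpressionStudy:
    """Per-gene Z-score transform across all samples of the study.

    Genes with any missing value or zero standard deviation are dropped and
    recorded in ``dropped_genes`` (no imputation, no silent zero rows).
    """
    vals = study.values.astype(float)
    has_na = vals.isna().any(axis=1)
    vals = vals.loc[~has_na]
    sd = vals.std(axis=1, ddof=ddof)
    constant = sd == 0
    missing_genes = list(study.values.index[has_na])
    constant_genes = list(vals.index[constant])
    if missing_genes:
        log.warning("study %s: dropped %d genes with missing values",
                    study.study_id, len(missing_genes))
    if constant_genes:
        log.warning("study %s: dropped %d constant genes",
                    study.study_id, len(constant_genes))
    vals = vals.loc[~constant]
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd.loc[~constant], axis=0)
    return ExpressionStudy(
        study.study_id, z, study.group.copy(),
        dropped_genes={"missing": missing_genes, "constant": constant_genes},
    )


@dataclass(eq=False)
class ClinicalTable:
    """Per-patient survival time (months), event indicator, categorical factors."""

    patients: pd.Index
    time: np.ndarray
    event: np.ndarray
    factors: pd.DataFrame

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if len(self.patients) != len(self.time) or len(self.time) != len(self.event):
            raise ValueError("patients, time and event lengths differ")
        if np.any(self.time < 0):
            raise ValueError("negative survival times")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        self.event = self.event.astype(int)


def read_clinical(path, time_col: str = "time_months", event_col: str = "event",
                  factor_cols: list[str] | None = None,
                  patient_col: str | None = None) -> ClinicalTable:
    """Read a tab-separated clinical table with a declared column schema.

    Patients with missing time/event are excluded listwise (count logged).
    """
    df = pd.read_csv(path, sep="\t")
    pid = patient_col or df.columns[0]
    for col in (pid, time_col, event_col):
        if col not in df.columns:
            raise ExpressionParseError(f"{path}: missing column {col!r}")
    if factor_cols is None:
        factor_cols = [c for c in df.columns if c not in (pid, time_col, event_col)]
    bad = df[time_col].isna() | df[event_col].isna()
    if bad.any():
        log.warning("%s: excluding %d patients with missing time/event", path, int(bad.sum()))
        df = df.loc[~bad]
    return ClinicalTable(
        patients=pd.Index(df[pid].astype(str)),
        time=df[time_col].to_numpy(float),
        event=df[event_col].to_numpy(),
        factors=df[factor_cols].astype(str).set_index(pd.Index(df[pid].astype(str))),
    )
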