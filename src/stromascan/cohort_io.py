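"""Reading, writing and value-level normalization of expression cohorts.

Containers
----------
:class:`ExpressionMatrix`
    A genes x samples table of expression values on a declared scale
    (``log2p1`` after log2(x+1), or ``linear`` for raw RPKM-like values).
:class:`ClinicalTable`
    Per-sample overall survival (time, event) plus the stratification
    covariates used throughout (ER status, node status, age group, stage
    group, tumor size group).
:class:`ProbeMap`
    Many-to-one microarray probe -> gene symbol map.

Normalizations implemented here operate on values only; correlation-based
signature construction lives in :mod:`stromascan.metagene`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

LOG2P1 = "log2p1"
LINEAR = "linear"

#: controlled vocabulary for binary clinical statuses
_STATUS_SYNONYMS = {
    "pos": "pos", "positive": "pos", "+": "pos", "1": "pos", "true": "pos",
    "neg": "neg", "negative": "neg", "-": "neg", "0": "neg", "false": "neg",
    "missing": "missing", "na": "missing", "nan": "missing", "": "missing",
    "unknown": "missing",
}

_SIZE_SYNONYMS = {
    "le2cm": "le2cm", "<2cm": "le2cm", "<=2cm": "le2cm", "small": "le2cm",
    "gt2cm": "gt2cm", ">2cm": "gt2cm", "large": "gt2cm",
    "missing": "missing", "na": "missing", "nan": "missing", "": "missing",
}


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a scale tag.

    Parameters
    ----------
    data
        DataFrame indexed by unique gene symbol, columns are unique sample
        ids, float values.
    scale_tag
        ``"log2p1"`` (values are log2(x+1), hence >= 0) or ``"linear"``.
    """

    data: pd.DataFrame
    scale_tag: str = LOG2P1

    def __post_init__(self) -> None:
        if self.scale_tag not in (LOG2P1, LINEAR):
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if self.scale_tag == LOG2P1 and (values < 0).any():
            raise ValidationError("log2p1 matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def require_genes(self, genes: Iterable[str]) -> None:
        """Raise listing the symbols absent from the matrix, if any."""
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing}")

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        self.require_genes(genes)
        return ExpressionMatrix(self.data.loc[list(genes)].copy(), self.scale_tag)


@dataclass
class ClinicalTable:
    """Per-sample survival and stratification covariates.

    ``data`` is indexed by sample id with columns ``time`` (positive float),
    ``event`` (0/1 int), and the categorical covariates ``er_status``,
    ``node_status``, ``age_group``, ``stage_group``, ``tumor_size_group``.
    The time unit is carried as metadata and never converted implicitly.
    """

    data: pd.DataFrame
    time_unit: str = "days"
    n_rejected: int = 0

    REQUIRED = ("time", "event")
    CATEGORICAL = ("er_status", "node_status", "age_group", "stage_group",
                   "tumor_size_group")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValidationError(f"clinical table lacks required column {col!r}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in clinical table")
        if (self.data["time"] <= 0).any():
            raise ValidationError("clinical table contains non-positive times")
        if not self.data["event"].isin([0, 1]).all():
            raise ValidationError("event column must be 0/1")
        for col in self.CATEGORICAL:
            if col not in self.data.columns:
                self.data[col] = "missing"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ProbeMap:
    """Many-to-one probe id -> gene symbol mapping."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mapping = dict(self.mapping)

    @property
    def genes(self) -> set[str]:
        return set(self.mapping.values())

    def __getitem__(self, probe: str) -> str:
        return self.mapping[probe]

    def __contains__(self, probe: str) -> bool:
        return probe in self.mapping


# ---------------------------------------------------------------------------
# loading / writing


def load_expression_matrix(path, transform: str = "none", sep: str = "\t",
                           transpose: bool = False) -> ExpressionMatrix:
    """Load a delimited genes x samples table.

    The first column holds gene symbols, the header row sample ids.  With
    ``transform="log2p1"`` every value v becomes log2(v + 1) and the result
    is tagged ``log2p1``; with ``"none"`` values are taken as already being
    on log2 scale unless ``transform="keep_linear"`` tags them ``linear``.
    ``transpose=True`` supports samples-in-rows files.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        raw = raw.T
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene symbols in {path}: {dups[:5]}")
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(f"non-numeric cell at gene {row!r}, sample {col!r}")
        if coerced.isna().any():
            row = raw.index[coerced.isna().to_numpy().nonzero()[0][0]]
            raise ParseError(f"empty cell at gene {row!r}, sample {col!r}")
        raw[col] = coerced
    values = raw.astype(float)
    if transform == "log2p1":
        if (values.to_numpy() < 0).any():
            raise ValidationError("negative values incompatible with log2(x+1)")
        values = np.log2(values + 1.0)
        tag = LOG2P1
    elif transform == "none":
        tag = LOG2P1
    elif transform == "keep_linear":
        tag = LINEAR
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    return ExpressionMatrix(values, tag)


def write_expression_matrix(matrix: ExpressionMatrix, path, sep: str = "\t") -> None:
    matrix.data.to_csv(path, sep=sep, index_label="gene")


def load_clinical_table(path, time_unit: str = "days") -> ClinicalTable:
    """Load a CSV clinical table, normalizing categories and rejecting
    non-positive survival times (the rejection count is logged and recorded).
    """
    raw = pd.read_csv(path, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    for col in ClinicalTable.REQUIRED:
        if col not in raw.columns:
            raise ValidationError(f"clinical table lacks required column {col!r}")
    time = pd.to_numeric(raw["time"], errors="coerce")
    event = pd.to_numeric(raw["event"], errors="coerce")
    keep = time.notna() & (time > 0) & event.isin([0, 1])
    n_rejected = int((~keep).sum())
    if n_rejected:
        logger.warning("rejected %d clinical rows (non-positive/missing time or "
                       "invalid event)", n_rejected)
    out = pd.DataFrame(index=raw.index[keep])
    out["time"] = time[keep].astype(float)
    out["event"] = event[keep].astype(int)

    def _norm(col: str, table: Mapping[str, str]) -> pd.Series:
        if col not in raw.columns:
            return pd.Series("missing", index=out.index)
        vals = raw.loc[keep, col].fillna("missing").astype(str).str.strip().str.lower()
        unknown = ~vals.isin(table)
        if unknown.any():
            # free categoricals (age/stage) keep their labels verbatim
            return raw.loc[keep, col].fillna("missing").astype(str)
        return vals.map(table)

    out["er_status"] = _norm("er_status", _STATUS_SYNONYMS)
    out["node_status"] = _norm("node_status", _STATUS_SYNONYMS)
    out["tumor_size_group"] = _norm("tumor_size_group", _SIZE_SYNONYMS)
    for col in ("age_group", "stage_group"):
        if col in raw.columns:
            out[col] = raw.loc[keep, col].fillna("missing").astype(str)
        else:
            out[col] = "missing"
    return ClinicalTable(out, time_unit=time_unit, n_rejected=n_rejected)


def write_clinical_table(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, index_label="sample_id")


def load_probe_map(path, sep: str = "\t") -> ProbeMap:
    """Two-column (probe, gene) delimited file, no header required."""
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if raw.shape[1] < 2:
        raise ValidationError("probe map needs two columns: probe, gene")
    first = str(raw.iloc[0, 0]).lower()
    if first in ("probe", "probe_id"):
        raw = raw.iloc[1:]
    probes = raw.iloc[:, 0].astype(str)
    if probes.duplicated().any():
        raise ValidationError("probe map assigns a probe to more than one gene")
    return ProbeMap(dict(zip(probes, raw.iloc[:, 1].astype(str))))


# ---------------------------------------------------------------------------
# value-level normalizations


def collapse_probes(probe_matrix: ExpressionMatrix, probe_map: ProbeMap
                    ) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    For each gene, the retained row is the single probe with the maximal mean
    signal across all samples of the cohort; ties go to the lexicographically
    smaller probe id.  Unmapped probes are dropped.
    """
    present = [p for p in probe_matrix.gene_ids if p in probe_map]
    if not present:
        raise ValidationError("no probe of the matrix appears in the probe map")
    means = probe_matrix.data.loc[present].mean(axis=1)
    best: dict[str, str] = {}
    for probe in sorted(present):  # lexicographic order makes ties deterministic
        gene = probe_map[probe]
        if gene not in best or means[probe] > means[best[gene]]:
            best[gene] = probe
    genes = sorted(best)
    collapsed = probe_matrix.data.loc[[best[g] for g in genes]].copy()
    collapsed.index = pd.Index(genes, name="gene")
    return ExpressionMatrix(collapsed, probe_matrix.scale_tag)


def normalize_rpkm_matrix(rpkm: ExpressionMatrix, scale: float = 100_000.0
                          ) -> ExpressionMatrix:
    """Within-sample RPKM normalization followed by log2(x+1).

    Each value is divided by its sample's total RPKM and multiplied by
    ``scale`` (100,000), so pre-log per-sample sums equal ``scale`` exactly;
    the result is then log2-transformed after addition of 1.
    """
    if rpkm.scale_tag != LINEAR:
        raise ValidationError("normalize_rpkm_matrix expects a linear-scale matrix")
    values = rpkm.data
    if (values.to_numpy() < 0).any():
        raise ValidationError("RPKM values must be non-negative")
    colsums = values.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValidationError(f"zero total RPKM in sample(s): {list(zero.index)}")
    scaled = values.div(colsums, axis=1) * scale
    return ExpressionMatrix(np.log2(scaled + 1.0), LOG2P1)


def normalize_gene_to_metagene(expr: ExpressionMatrix, gene: str,
                               signature) -> pd.Series:
    """Per-sample log-ratio of a gene to a signature's mean log2 value.

    Subtracts, in each sample, the unstandardized mean log2 expression of
    the signature genes from the gene's log2 value.
    """
    genes = list(signature.genes) if hasattr(signature, "genes") else list(signature)
    expr.require_genes([gene] + genes)
    metagene_mean = expr.data.loc[genes].mean(axis=0)
    return expr.data.loc[gene] - metagene_mean


def compare_groups(values_a, values_b, paired: bool = False):
    """Two-sided t-test between two groups.

    Paired t-test when the observations are matched (e.g. tumor and normal
    tissue from the same patient), Welch two-sample otherwise.  Returns
    ``(statistic, p_value, note)``; a zero-variance degenerate comparison
    yields ``(nan, 1.0, "zero-variance")`` rather than an exception.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired and a.shape != b.shape:
        raise ValidationError("paired comparison requires equal-length vectors")
    if min(a.size, b.size) < 2:
        raise ValidationError("need at least 2 observations per group")
    if paired:
        diff = a - b
        if np.allclose(diff.std(ddof=1), 0.0):
            return float("nan"), 1.0, "zero-variance"
        t, p = stats.ttest_rel(a, b)
    else:
        if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
            return float("nan"), 1.0, "zero-variance"
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), ""
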