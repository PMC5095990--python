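"""Metagene construction: correlation expansion, greedy compaction,
cross-cohort consensus and per-sample scoring.

The pipeline mirrors the stromal-signature workflow: starting from seed
genes (e.g. fibroblast/ECM markers), the candidate set is *expanded* to all
genes whose Pearson correlation with at least one seed exceeds a threshold
(default 0.84); the expanded set is then *compacted* by iteratively removing
the gene with the lowest mean correlation to the others until every survivor
clears a mean-correlation threshold (default 0.85).  Intersecting the
compact clusters of several cohorts yields a consensus signature (the
"metagene"), and tumors are scored by the standardized per-sample mean of
the signature genes' log2 expression.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix
from .errors import ThresholdUnattainableError, ValidationError

logger = logging.getLogger(__name__)

EXPANSION_R = 0.84
COMPACTION_MEAN_R = 0.85


@dataclass
class GeneSignature:
    """A named, ordered gene list with free-text provenance."""

    name: str
    genes: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} has duplicate genes")
        self.genes = list(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "genes": self.genes,
                       "provenance": self.provenance}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GeneSignature":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(payload["name"], payload["genes"], payload.get("provenance", ""))


@dataclass
class CompactionTrace:
    """Removal history of a greedy compaction run.

    ``removed`` lists ``(gene, mean correlation at removal)`` in removal
    order; ``final_means`` maps each survivor to its mean correlation with
    the other survivors.
    """

    removed: list[tuple[str, float]] = field(default_factory=list)
    final_means: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"step": i + 1, "gene": g, "mean_r": r, "action": "removed"}
                for i, (g, r) in enumerate(self.removed)]
        rows += [{"step": len(self.removed) + 1, "gene": g, "mean_r": r,
                  "action": "retained"} for g, r in self.final_means.items()]
        return pd.DataFrame(rows, columns=["step", "gene", "mean_r", "action"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def correlation_matrix(expr: ExpressionMatrix, genes=None) -> pd.DataFrame:
    """Pearson correlation of log2 expression between genes, across samples."""
    genes = list(genes) if genes is not None else expr.gene_ids
    expr.require_genes(genes)
    values = expr.data.loc[genes].to_numpy()
    sd = values.std(axis=1)
    flat = [g for g, s in zip(genes, sd) if s == 0]
    if flat:
        raise ValidationError(f"zero-variance gene(s): {flat}")
    corr = np.corrcoef(values)
    corr = np.atleast_2d(corr)
    return pd.DataFrame(corr, index=genes, columns=genes)


def expand_gene_set(expr: ExpressionMatrix, seeds: GeneSignature,
                    r_threshold: float = EXPANSION_R) -> GeneSignature:
    """All genes correlated above ``r_threshold`` (strict) with >= 1 seed.

    Seeds absent from the matrix are dropped with a warning; seeds present
    are always included (self-correlation is 1).  Output order follows the
    matrix's row order.
    """
    present = [g for g in seeds.genes if g in expr.data.index]
    absent = [g for g in seeds.genes if g not in expr.data.index]
    if absent:
        warnings.warn(f"seed genes absent from matrix, dropped: {absent}")
    if not present:
        raise ValidationError("no seed gene present in the expression matrix")

    values = expr.data.to_numpy()
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    ok = norms > 0
    seed_rows = [expr.data.index.get_loc(g) for g in present]
    seed_centered = centered[seed_rows]
    seed_norms = norms[seed_rows]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered @ seed_centered.T) / np.outer(norms, seed_norms)
    corr[~ok] = -np.inf
    best = corr.max(axis=1)
    selected = set(np.asarray(expr.data.index)[best > r_threshold]) | set(present)
    genes = [g for g in expr.gene_ids if g in selected]
    return GeneSignature(
        name=f"{seeds.name}_expanded",
        genes=genes,
        provenance=f"expanded from {seeds.name} at r>{r_threshold}",
    )


def compact_cluster(expr: ExpressionMatrix, genes,
                    mean_r_threshold: float = COMPACTION_MEAN_R,
                    min_size: int = 2) -> tuple[GeneSignature, CompactionTrace]:
    """Greedy compaction of a gene set to a tight correlation cluster.

    Iteratively removes the gene with the lowest mean Pearson correlation
    to the *other* genes in the current set (self-correlation excluded)
    until every remaining gene's mean exceeds ``mean_r_threshold`` (strict).
    Equal minima are broken toward the lexicographically smallest symbol.

    Raises :class:`ThresholdUnattainableError` (trace attached) if the set
    would shrink below ``min_size`` first.
    """
    name = genes.name if isinstance(genes, GeneSignature) else "cluster"
    gene_list = list(genes.genes) if isinstance(genes, GeneSignature) else list(genes)
    if len(gene_list) < min_size:
        raise ValidationError(f"need at least {min_size} genes, got {len(gene_list)}")
    corr = correlation_matrix(expr, gene_list)
    C = corr.to_numpy()
    active = list(range(len(gene_list)))
    trace = CompactionTrace()
    while True:
        k = len(active)
        if k == 1:  # vacuously compact (only reachable with min_size=1)
            break
        sub = C[np.ix_(active, active)]
        means = (sub.sum(axis=1) - 1.0) / (k - 1)
        if means.min() > mean_r_threshold:
            break
        if k - 1 < min_size:
            trace.final_means = {gene_list[i]: float(m)
                                 for i, m in zip(active, means)}
            raise ThresholdUnattainableError(
                f"threshold {mean_r_threshold} unattainable: set would shrink "
                f"below min_size={min_size}", trace=trace)
        low = means.min()
        candidates = [gene_list[active[j]] for j in range(k)
                      if means[j] <= low + 1e-15]
        victim = min(candidates)
        j = next(j for j in range(k) if gene_list[active[j]] == victim)
        trace.removed.append((victim, float(means[j])))
        del active[j]
    survivors = [gene_list[i] for i in active]
    if len(active) > 1:
        sub = C[np.ix_(active, active)]
        means = (sub.sum(axis=1) - 1.0) / (len(active) - 1)
    else:
        means = np.array([1.0])
    trace.final_means = {g: float(m) for g, m in zip(survivors, means)}
    sig = GeneSignature(
        name=f"{name}_compact",
        genes=survivors,
        provenance=f"greedy compaction at mean r>{mean_r_threshold}",
    )
    return sig, trace


def consensus_signature(signatures: list[GeneSignature],
                        name: str = "consensus") -> GeneSignature:
    """Set intersection of several signatures, ordered as in the first.

    An empty intersection is returned as an empty signature with a warning,
    not an error.
    """
    if len(signatures) < 2:
        raise ValidationError("consensus needs at least two signatures")
    common = set(signatures[0].genes)
    for sig in signatures[1:]:
        common &= set(sig.genes)
    genes = [g for g in signatures[0].genes if g in common]
    if not genes:
        warnings.warn("consensus of signatures is empty")
    return GeneSignature(
        name=name,
        genes=genes,
        provenance="intersection of: " + ", ".join(s.name for s in signatures),
    )


@dataclass
class MetageneScoreVector:
    """Standardized per-sample metagene values (mean 0, SD 1, ddof=1)."""

    scores: pd.Series
    signature_name: str = ""

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def to_numpy(self) -> np.ndarray:
        return self.scores.to_numpy()


def metagene_score(expr: ExpressionMatrix, signature: GeneSignature,
                   per_gene_standardize: bool = False) -> MetageneScoreVector:
    """Standardized mean of the signature genes' log2 expression per sample.

    Default: average the genes' log2 values within each sample, then
    standardize the resulting vector across samples (subtract the cohort
    mean, divide by the sample SD with n-1 denominator).  With
    ``per_gene_standardize=True`` each gene's row is z-scored before
    averaging; the final vector is standardized in both modes.
    """
    if len(signature) == 0:
        raise ValidationError("cannot score an empty signature")
    expr.require_genes(signature.genes)
    if expr.n_samples < 2:
        raise ValidationError("need at least 2 samples to standardize")
    sub = expr.data.loc[signature.genes]
    if per_gene_standardize:
        sd = sub.std(axis=1, ddof=1)
        flat = sd.index[sd == 0].tolist()
        if flat:
            raise ValidationError(f"zero-variance gene(s): {flat}")
        sub = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    raw = sub.mean(axis=0)
    spread = raw.std(ddof=1)
    if spread == 0:
        raise ValidationError("per-sample metagene means have zero variance")
    return MetageneScoreVector((raw - raw.mean()) / spread, signature.name)


def correlate_with_metagene(expr: ExpressionMatrix, gene: str,
                            signature: GeneSignature) -> float:
    """Pearson correlation of one gene with a signature's per-sample mean."""
    expr.require_genes([gene] + signature.genes)
    g = expr.data.loc[gene].to_numpy()
    m = expr.data.loc[signature.genes].mean(axis=0).to_numpy()
    if g.std() == 0 or m.std() == 0:
        raise ValidationError("zero variance on one side of the correlation")
    return float(np.corrcoef(g, m)[0, 1])
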