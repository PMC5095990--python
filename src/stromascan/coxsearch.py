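"""Stratified Cox proportional-hazards fitting and the exhaustive pairwise
prognostic scan.

The fitter maximizes the stratified Cox partial likelihood with Efron tie
handling by Newton-Raphson with step-halving (relative log-likelihood
tolerance 1e-9, at most 100 iterations).  Each stratum contributes its own
risk sets; no baseline hazard is estimated.  The risk-set bookkeeping is
precomputed once per (clinical table, strata) design in :class:`CoxData`, so
the exhaustive all-pairs scan -- C(n, 2) two-covariate fits over a candidate
gene set, ranked by the likelihood-ratio test p-value (df = 2) -- reuses it
and stays fast enough for hundreds of thousands of fits.

Opposing prognostic signatures are derived from the ranked scan: genes
appearing more than ``min_count`` times among the ``top_k`` pairs are kept
and classified by the majority sign of their hazard ratios (HR > 1 -> poor
prognosis set, HR < 1 -> good prognosis set).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import ClinicalTable, ExpressionMatrix
from .errors import ComputationError, ValidationError
from .metagene import GeneSignature

logger = logging.getLogger(__name__)

DEFAULT_STRATA = ("er_status", "node_status")


@dataclass
class SearchConfig:
    """Constants of the pairwise scan and signature derivation."""

    top_k: int = 100
    min_count: int = 5          # strict: kept genes appear > min_count times
    strata: tuple[str, ...] = DEFAULT_STRATA
    standardize_covariates: bool = False
    tol: float = 1e-9
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if self.min_count < 0:
            raise ValidationError("min_count must be >= 0")


@dataclass
class CoxFit:
    """Result of one (possibly multivariate) stratified Cox fit."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    null_loglik: float
    n: int
    n_events: int
    strata: str
    converged: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coef - 1.959963984540054 * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coef + 1.959963984540054 * self.se)

    @property
    def wald_p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    @property
    def lrt_p(self) -> float:
        return likelihood_ratio_test(self.loglik, self.null_loglik,
                                     df=len(self.names))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.names,
            "coef": self.coef,
            "HR": self.hr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.wald_p,
        })


@dataclass
class PairScanResult:
    gene_a: str
    gene_b: str
    hr_a: float
    hr_b: float
    lrt_p: float
    converged: bool


@dataclass
class PrognosticSignaturePair:
    good: GeneSignature
    poor: GeneSignature
    counts: dict[str, int]
    sign_consistency: dict[str, float]
    excluded_ties: list[str] = field(default_factory=list)


class CoxData:
    """Precomputed risk-set structure for a fixed (time, event, strata) design.

    Sorting, tie grouping and the Efron correction fractions depend only on
    the survival outcome and strata, so they are computed once and shared by
    every covariate-matrix fit against the same design.
    """

    def __init__(self, time, event, strata_labels=None):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        n = time.size
        if strata_labels is None:
            strata_labels = np.zeros(n, dtype=int)
        codes, _ = pd.factorize(np.asarray(strata_labels))
        if event.sum() < 2:
            raise ValidationError("need at least 2 observed events")

        order_parts, slices, gfirst, ev_pos, frac, gstart, gsize = \
            [], [], [], [], [], [], []
        offset = 0
        for s in np.unique(codes):
            idx = np.nonzero(codes == s)[0]
            # ascending time; events before censorings at equal times is
            # irrelevant for risk sets (risk set = time >= t), keep stable sort
            o = idx[np.lexsort((event[idx] == 0, time[idx]))]
            t_s, e_s = time[o], event[o]
            order_parts.append(o)
            slices.append((offset, offset + len(o)))
            ev_local = np.nonzero(e_s == 1)[0]
            if ev_local.size:
                ev_times = t_s[ev_local]
                # tie groups among events sharing a time in this stratum
                new_group = np.ones(ev_local.size, dtype=bool)
                new_group[1:] = ev_times[1:] != ev_times[:-1]
                starts = np.nonzero(new_group)[0]
                sizes = np.diff(np.append(starts, ev_local.size))
                for st, d in zip(starts, sizes):
                    t0 = ev_times[st]
                    gfirst.append(offset + int(np.searchsorted(t_s, t0, "left")))
                    gstart.append(len(ev_pos))
                    gsize.append(int(d))
                    for l in range(d):
                        ev_pos.append(offset + int(ev_local[st + l]))
                        frac.append(l / d)
            offset += len(o)

        self.n = n
        self.order = np.concatenate(order_parts)
        self.slices = slices
        self.group_first = np.asarray(gfirst, dtype=int)
        self.group_start = np.asarray(gstart, dtype=int)
        self.group_size = np.asarray(gsize, dtype=int)
        self.ev_pos = np.asarray(ev_pos, dtype=int)
        self.frac = np.asarray(frac, dtype=float)
        self.ev_group = np.repeat(np.arange(len(gsize)), self.group_size)
        self.n_events = int(self.ev_pos.size)
        self.null_loglik = self._loglik_only(np.zeros(self.n))

    # -- partial likelihood machinery ------------------------------------

    def _suffix(self, arr: np.ndarray) -> np.ndarray:
        """Per-stratum suffix sums along axis 0."""
        out = np.empty_like(arr)
        for a, b in self.slices:
            out[a:b] = np.cumsum(arr[a:b][::-1], axis=0)[::-1]
        return out

    def _terms(self, eta_sorted: np.ndarray):
        """Efron denominators phi_e and per-event risk/tie weights."""
        # center within stratum for overflow safety; partial lik is invariant
        eta_c = eta_sorted.copy()
        for a, b in self.slices:
            eta_c[a:b] -= eta_c[a:b].max()
        w = np.exp(eta_c)
        s_suffix = self._suffix(w)
        s_r = s_suffix[self.group_first][self.ev_group]
        w_ev = w[self.ev_pos]
        s_d = np.add.reduceat(w_ev, self.group_start)[self.ev_group]
        phi = s_r - self.frac * s_d
        return eta_c, w, phi

    def _loglik_only(self, eta_sorted: np.ndarray) -> float:
        eta_c, _, phi = self._terms(eta_sorted)
        return float(eta_c[self.ev_pos].sum() - np.log(phi).sum())

    def _loglik_grad_info(self, Xs: np.ndarray, beta: np.ndarray):
        eta_c, w, phi = self._terms(Xs @ beta)
        p = Xs.shape[1]
        wx = w[:, None] * Xs
        z_r = self._suffix(wx)[self.group_first][self.ev_group]
        z_d = np.add.reduceat(wx[self.ev_pos], self.group_start, axis=0)[self.ev_group]
        z = (z_r - self.frac[:, None] * z_d) / phi[:, None]
        grad = Xs[self.ev_pos].sum(axis=0) - z.sum(axis=0)

        wxx = wx[:, :, None] * Xs[:, None, :]           # n x p x p
        q_r = self._suffix(wxx.reshape(-1, p * p)).reshape(-1, p, p)
        q_r = q_r[self.group_first][self.ev_group]
        q_d = np.add.reduceat(wxx[self.ev_pos].reshape(-1, p * p),
                              self.group_start, axis=0).reshape(-1, p, p)
        q_d = q_d[self.ev_group]
        q = (q_r - self.frac[:, None, None] * q_d) / phi[:, None, None]
        info = q.sum(axis=0) - np.einsum("ei,ej->ij", z, z)
        ll = float(eta_c[self.ev_pos].sum() - np.log(phi).sum())
        return ll, grad, info

    # -- Newton-Raphson ---------------------------------------------------

    def fit(self, X: np.ndarray, names=None, tol: float = 1e-9,
            max_iter: int = 100, strata_desc: str = "") -> CoxFit:
        """Fit covariate matrix ``X`` (n x p, original sample order)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != self.n:
            X = X.T
        p = X.shape[1]
        names = list(names) if names is not None else [f"x{i}" for i in range(p)]
        warns: list[str] = []
        if not np.isfinite(X).all():
            raise ValidationError("covariates contain non-finite values")
        Xs = X[self.order]

        beta = np.zeros(p)
        ll, grad, info = self._loglik_grad_info(Xs, beta)
        converged = False
        for _ in range(max_iter):
            try:
                delta = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                warns.append("singular information matrix")
                break
            step = 1.0
            for _ in range(30):  # step-halving on overshoot
                cand = beta + step * delta
                ll_new = self._loglik_only(Xs @ cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                step *= 0.5
            else:
                warns.append("step-halving failed")
                break
            beta = beta + step * delta
            ll_prev = ll
            ll, grad, info = self._loglik_grad_info(Xs, beta)
            if abs(ll - ll_prev) <= tol * (abs(ll) + tol):
                converged = True
                break
        if converged and np.abs(beta).max() > 50:
            converged = False        # likely complete separation
            warns.append("divergent coefficient (possible separation)")
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
            converged = False
            warns.append("singular information matrix at optimum")
        return CoxFit(names=names, coef=beta, se=se, loglik=ll,
                      null_loglik=self.null_loglik, n=self.n,
                      n_events=self.n_events, strata=strata_desc,
                      converged=converged, warnings=warns)


# ---------------------------------------------------------------------------
# public operations


def _design_from_clinical(clinical: ClinicalTable, strata, sample_ids=None):
    """Align clinical rows, drop samples with missing strata, build CoxData."""
    df = clinical.data
    if sample_ids is not None:
        keep_ids = [s for s in sample_ids if s in df.index]
        df = df.loc[keep_ids]
    strata = list(strata) if strata else []
    for s in strata:
        if s not in df.columns:
            raise ValidationError(f"strata field {s!r} not in clinical table")
    if strata:
        ok = ~(df[strata].isin(["missing"]).any(axis=1))
        n_dropped = int((~ok).sum())
        if n_dropped:
            logger.info("excluded %d samples with missing strata values", n_dropped)
        df = df.loc[ok]
        labels = df[strata].astype(str).agg("|".join, axis=1).to_numpy()
        desc = " x ".join(strata)
    else:
        labels = None
        desc = "none"
    data = CoxData(df["time"].to_numpy(), df["event"].to_numpy(), labels)
    return data, list(df.index), desc


def fit_cox_ph(covariates, clinical: ClinicalTable, strata=DEFAULT_STRATA,
               tol: float = 1e-9, max_iter: int = 100,
               drop_constant: bool = False) -> CoxFit:
    """Stratified Cox PH fit of named per-sample covariates.

    ``covariates`` is a DataFrame (or mapping of name -> Series/array)
    indexed/aligned by sample id.  Samples missing strata values are
    excluded (logged).  A constant covariate raises unless
    ``drop_constant=True`` (then it is dropped with a warning).
    """
    cov = pd.DataFrame(covariates)
    if not isinstance(cov.index, pd.Index) or cov.index.inferred_type == "integer":
        cov.index = clinical.data.index[:len(cov)]
    data, ids, desc = _design_from_clinical(clinical, strata, list(cov.index))
    cov = cov.loc[ids]
    dropped = []
    for name in list(cov.columns):
        if cov[name].std() == 0:
            if drop_constant:
                dropped.append(name)
                cov = cov.drop(columns=name)
            else:
                raise ValidationError(f"constant covariate {name!r}")
    if cov.shape[1] == 0:
        raise ValidationError("no usable covariates")
    fit = data.fit(cov.to_numpy(), names=list(cov.columns), tol=tol,
                   max_iter=max_iter, strata_desc=desc)
    for name in dropped:
        fit.warnings.append(f"dropped constant covariate {name!r}")
    return fit


def likelihood_ratio_test(full_loglik: float, null_loglik: float,
                          df: int = 1, tol: float = 1e-6) -> float:
    """Upper chi-square tail of 2 * (LL_full - LL_null) with ``df`` d.o.f."""
    if df < 1:
        raise ValidationError("df must be >= 1")
    statistic = 2.0 * (full_loglik - null_loglik)
    if statistic < -tol:
        raise ComputationError(
            f"negative LRT statistic {statistic:.3g}: full model log-likelihood "
            "below null indicates a broken fit")
    return float(stats.chi2.sf(max(statistic, 0.0), df))


def pairwise_scan(expr: ExpressionMatrix, genes, clinical: ClinicalTable,
                  config: SearchConfig | None = None) -> list[PairScanResult]:
    """Exhaustive two-gene stratified Cox scan over all C(n, 2) pairs.

    Each pair's two log2 expression vectors are the covariates (raw by
    default, standardized if configured).  Results are sorted ascending by
    the df=2 LRT p-value; unconverged pairs sort last, flagged.
    """
    config = config or SearchConfig()
    gene_list = list(genes.genes) if isinstance(genes, GeneSignature) else list(genes)
    if len(gene_list) < 2:
        raise ValidationError("pairwise scan needs at least 2 genes")
    expr.require_genes(gene_list)

    shared = [s for s in expr.sample_ids if s in clinical.data.index]
    data, ids, _ = _design_from_clinical(clinical, config.strata, shared)
    X_all = expr.data.loc[gene_list, ids].to_numpy().T  # samples x genes
    if config.standardize_covariates:
        X_all = (X_all - X_all.mean(axis=0)) / X_all.std(axis=0, ddof=1)
    Xs_all = X_all[data.order]  # presort once; pair fits slice columns

    results: list[PairScanResult] = []
    pairs = list(itertools.combinations(range(len(gene_list)), 2))
    for count, (i, j) in enumerate(pairs, 1):
        fit = _fit_sorted_pair(data, Xs_all[:, [i, j]], config)
        lrt_p = fit.lrt_p if fit.converged else float("nan")
        results.append(PairScanResult(
            gene_a=gene_list[i], gene_b=gene_list[j],
            hr_a=float(fit.hr[0]), hr_b=float(fit.hr[1]),
            lrt_p=float(lrt_p), converged=fit.converged))
        if count % 500 == 0:
            logger.info("pairwise scan: %d/%d pairs", count, len(pairs))
    if not results:
        raise ValidationError("zero usable pairs")
    results.sort(key=lambda r: (not r.converged,
                                r.lrt_p if np.isfinite(r.lrt_p) else np.inf))
    return results


def _fit_sorted_pair(data: CoxData, Xs: np.ndarray, config: SearchConfig) -> CoxFit:
    """Fit a presorted 2-column covariate matrix (scan inner loop)."""
    if Xs[:, 0].std() == 0 or Xs[:, 1].std() == 0:
        return CoxFit(names=["a", "b"], coef=np.zeros(2), se=np.full(2, np.nan),
                      loglik=data.null_loglik, null_loglik=data.null_loglik,
                      n=data.n, n_events=data.n_events, strata="",
                      converged=False, warnings=["constant covariate"])
    beta = np.zeros(2)
    ll, grad, info = data._loglik_grad_info(Xs, beta)
    converged = False
    for _ in range(config.max_iter):
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        for _ in range(30):
            ll_new = data._loglik_only(Xs @ (beta + step * delta))
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            break
        beta = beta + step * delta
        ll_prev = ll
        ll, grad, info = data._loglik_grad_info(Xs, beta)
        if abs(ll - ll_prev) <= config.tol * (abs(ll) + config.tol):
            converged = True
            break
    if converged and np.abs(beta).max() > 50:
        converged = False
    try:
        se = np.sqrt(np.maximum(np.diag(np.linalg.inv(info)), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
        converged = False
    return CoxFit(names=["a", "b"], coef=beta, se=se, loglik=ll,
                  null_loglik=data.null_loglik, n=data.n,
                  n_events=data.n_events, strata="", converged=converged)


def scan_results_frame(results: list[PairScanResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_a": r.gene_a, "gene_b": r.gene_b, "hr_a": r.hr_a,
        "hr_b": r.hr_b, "lrt_p": r.lrt_p, "converged": r.converged,
    } for r in results])


def derive_prognostic_sets(ranked: list[PairScanResult],
                           config: SearchConfig | None = None
                           ) -> PrognosticSignaturePair:
    """Opposing good/poor signatures from a ranked pair scan.

    Takes the first ``top_k`` converged pairs, counts each gene's
    appearances, keeps genes appearing strictly more than ``min_count``
    times, and classifies each by the majority sign of its hazard ratios
    (HR > 1 -> poor, HR < 1 -> good).  Genes with an exact sign tie are
    excluded with a warning and reported.
    """
    config = config or SearchConfig()
    if not ranked:
        raise ValidationError("ranked list is empty")
    top = [r for r in ranked if r.converged][:config.top_k]
    counts: dict[str, int] = {}
    sign_sum: dict[str, int] = {}
    for r in top:
        for gene, hr in ((r.gene_a, r.hr_a), (r.gene_b, r.hr_b)):
            counts[gene] = counts.get(gene, 0) + 1
            sign_sum[gene] = sign_sum.get(gene, 0) + (1 if hr > 1 else
                                                      -1 if hr < 1 else 0)
    kept = sorted(g for g, c in counts.items() if c > config.min_count)
    good, poor, ties = [], [], []
    consistency: dict[str, float] = {}
    for g in kept:
        consistency[g] = abs(sign_sum[g]) / counts[g]
        if sign_sum[g] > 0:
            poor.append(g)
        elif sign_sum[g] < 0:
            good.append(g)
        else:
            ties.append(g)
    if ties:
        warnings.warn(f"genes with tied HR signs excluded: {ties}")
    if not good and not poor:
        warnings.warn("no gene exceeded the appearance threshold; empty signatures")
    return PrognosticSignaturePair(
        good=GeneSignature("good_prognosis", good,
                           provenance=f"top_{config.top_k} scan, count>{config.min_count}"),
        poor=GeneSignature("poor_prognosis", poor,
                           provenance=f"top_{config.top_k} scan, count>{config.min_count}"),
        counts={g: counts[g] for g in kept},
        sign_consistency=consistency,
        excluded_ties=ties)


def signature_aggregate(expr: ExpressionMatrix, signature: GeneSignature,
                        center: bool = True) -> pd.Series:
    """Per-sample mean log2 expression of a signature, cohort-centered."""
    present = [g for g in signature.genes if g in expr.data.index]
    missing = [g for g in signature.genes if g not in expr.data.index]
    if missing:
        warnings.warn(f"signature {signature.name!r}: missing genes dropped: "
                      f"{missing}")
    if not present:
        raise ValidationError(f"no gene of signature {signature.name!r} present")
    agg = expr.data.loc[present].mean(axis=0)
    return agg - agg.mean() if center else agg


def evaluate_signature_pair(good: GeneSignature, poor: GeneSignature,
                            expr: ExpressionMatrix, clinical: ClinicalTable,
                            strata=DEFAULT_STRATA):
    """Univariate and joint Cox fits of two opposing signature scores.

    Signatures are quantified as their centered mean log2 expression.
    Returns ``(fit_good_uni, fit_poor_uni, fit_multivariate)``; a collinear
    pair yields an unconverged multivariate fit flagged in its warnings.
    """
    score_g = signature_aggregate(expr, good)
    score_p = signature_aggregate(expr, poor)
    uni_g = fit_cox_ph({good.name: score_g}, clinical, strata)
    uni_p = fit_cox_ph({poor.name: score_p}, clinical, strata)
    multi = fit_cox_ph(pd.DataFrame({good.name: score_g, poor.name: score_p}),
                       clinical, strata)
    if not multi.converged:
        multi.warnings.append("multivariate fit unconverged (possible "
                              "collinearity of signature scores)")
    return uni_g, uni_p, multi


def evaluate_gene_adjusted(gene: str, opposing: GeneSignature,
                           expr: ExpressionMatrix, clinical: ClinicalTable,
                           strata=DEFAULT_STRATA):
    """Single-gene Cox fit, alone and adjusted for an opposing signature.

    Covariate 1 is the gene's standardized log2 expression; covariate 2 the
    opposing signature's centered mean log2 value.  Returns
    ``(fit_univariate, fit_adjusted)``; an empty or constant opposing score
    reduces the adjusted fit to the univariate one with a warning.
    """
    expr.require_genes([gene])
    g = expr.data.loc[gene]
    if g.std(ddof=1) == 0:
        raise ValidationError(f"gene {gene!r} has zero variance")
    g_std = (g - g.mean()) / g.std(ddof=1)
    uni = fit_cox_ph({gene: g_std}, clinical, strata)
    if len(opposing) == 0:
        adj = fit_cox_ph({gene: g_std}, clinical, strata)
        adj.warnings.append("opposing signature empty; adjusted = univariate")
        return uni, adj
    opp = signature_aggregate(expr, opposing)
    if opp.std(ddof=1) == 0:
        adj = fit_cox_ph({gene: g_std}, clinical, strata)
        adj.warnings.append("opposing score constant; adjusted = univariate")
        return uni, adj
    adj = fit_cox_ph(pd.DataFrame({gene: g_std, opposing.name: opp}),
                     clinical, strata)
    return uni, adj
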