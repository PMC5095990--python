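"""Seeded synthetic cohorts with the statistical structure the stromal
analysis assumes.

The generative model is a latent-factor one.  A per-tumor fibroblast
abundance factor F drives a block of correlated "ECM" genes; an endothelial
factor E, correlated with F at a configurable rho (the observed range across
tumor types is roughly 0.34-0.78), drives an endothelial block.  Two further
latent components G and P, each positively correlated with F, carry opposing
survival effects (G protective, P harmful); planted "good" and "poor" genes
load on them.  Survival times are drawn from a proportional-hazards model
with an exponential baseline (stratum-specific rate multipliers for ER x
node), with independent exponential censoring whose rate is solved
numerically to hit a target censoring fraction.

Expression is generated on log2 scale, converted to a linear scale as
2^y - 1 and stored as log2(linear + 1), an exact round trip that exercises
the same load path as real data.  Everything is a pure function of
(config, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort_io import ClinicalTable, ExpressionMatrix
from .errors import ValidationError

__all__ = [
    "SimulationConfig", "SyntheticTruth", "SyntheticCohort",
    "generate_cohort", "generate_multi_cohort", "generate_paired_normal",
    "generate_compartment_data",
]


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults give a realistic mid-size
    breast-cancer-like cohort in which the planted phenomena are detectable.

    Loadings are on log2-expression scale.  ``block_loading``/``noise_sd``
    of 3.0/1.0 give planted-block inter-gene correlation
    lambda^2/(lambda^2+sigma^2) = 0.9.  Survival coefficients apply to the
    latent components: ``beta_good`` (< 0, protective) to G and
    ``beta_poor`` (> 0, harmful) to P.
    """

    n_samples: int = 300
    # stromal (ECM-like) block
    n_block_genes: int = 4
    block_loading: float = 3.0
    noise_sd: float = 1.0
    block_gene_names: list[str] | None = None
    # endothelial block
    n_endo_genes: int = 3
    endo_loading: float = 3.0
    rho_fib_endo: float = 0.6       # F-E latent correlation (range seen: 0.34-0.78)
    # unstructured noise genes
    n_noise_genes: int = 10
    # stromal candidate genes: load on F with small heterogeneous spillover
    # onto the prognostic components G and P (per-gene tilts ~ N(0, tilt_sd)),
    # emulating the continuum of a correlation-expanded stromal candidate set
    n_candidate_genes: int = 0
    candidate_tilt_sd: float = 0.3
    # prognosis-relevant latents and their genes
    n_good_genes: int = 5
    n_poor_genes: int = 5
    a_good: float = 0.7             # corr(G, F)
    a_poor: float = 0.7             # corr(P, F)
    prog_loading: float = 3.0    # planted prognostic genes form tight clusters,
    prog_noise_sd: float = 1.0   # like the stromal block (inter-gene r = 0.9)
    beta_good: float = -0.5
    beta_poor: float = 0.5
    # survival
    baseline_hazard: float = 0.02   # events per month at covariates 0
    stratum_log_multiplier: float = 0.0   # per-stratum log-rate spread
    censor_frac: float = 0.3
    # clinical covariates
    er_pos_prev: float = 0.7
    node_pos_prev: float = 0.4
    er_effect_on_stroma: float = 0.3      # ER+ shifts F upward
    # expression baseline
    base_mean: float = 8.0
    time_unit: str = "months"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValidationError("n_samples must be >= 10")
        for prob in (self.censor_frac, self.er_pos_prev, self.node_pos_prev):
            if not 0.0 <= prob < 1.0 + 1e-12:
                raise ValidationError(f"probability out of [0, 1]: {prob}")
        if self.censor_frac >= 1.0:
            raise ValidationError("censor_frac must be < 1")
        for sd in (self.noise_sd, self.prog_noise_sd):
            if sd <= 0:
                raise ValidationError("noise SDs must be > 0")
        for a in (abs(self.rho_fib_endo), abs(self.a_good), abs(self.a_poor)):
            if a > 1:
                raise ValidationError("latent correlations must be in [-1, 1]")


@dataclass
class SyntheticTruth:
    """Planted structure for recovery tests."""

    latent: pd.DataFrame                  # per-sample F, E, G, P
    block_genes: list[str]
    endo_genes: list[str]
    good_genes: list[str]
    poor_genes: list[str]
    candidate_genes: list[str]
    noise_genes: list[str]
    beta_good: float
    beta_poor: float

    def to_json(self, path) -> None:
        payload = {
            "block_genes": self.block_genes, "endo_genes": self.endo_genes,
            "good_genes": self.good_genes, "poor_genes": self.poor_genes,
            "candidate_genes": self.candidate_genes,
            "noise_genes": self.noise_genes,
            "beta_good": self.beta_good, "beta_poor": self.beta_poor,
            "latent": self.latent.round(10).to_dict(orient="list"),
            "sample_ids": list(self.latent.index),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix          # stored log2(x+1)
    linear_expression: pd.DataFrame       # same values on linear scale
    clinical: ClinicalTable
    truth: SyntheticTruth
    config: SimulationConfig


def _gene_names(cfg: SimulationConfig):
    block = cfg.block_gene_names or [f"ECM{i+1:03d}" for i in range(cfg.n_block_genes)]
    if len(block) != cfg.n_block_genes:
        raise ValidationError("block_gene_names length must equal n_block_genes")
    endo = [f"END{i+1:02d}" for i in range(cfg.n_endo_genes)]
    good = [f"GOOD{i+1:02d}" for i in range(cfg.n_good_genes)]
    poor = [f"POOR{i+1:02d}" for i in range(cfg.n_poor_genes)]
    cand = [f"CND{i+1:03d}" for i in range(cfg.n_candidate_genes)]
    noise = [f"NSE{i+1:03d}" for i in range(cfg.n_noise_genes)]
    return block, endo, good, poor, cand, noise


def _solve_censor_rate(event_rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean P(C < T) = mean c/(c+r) = target."""
    if target <= 0:
        return 0.0

    def frac(c: float) -> float:
        return float(np.mean(c / (c + event_rates)))

    hi = float(event_rates.max()) * 1e6
    if frac(hi) < target:
        warnings.warn(f"censoring target {target} unattainable; achieved "
                      f"{frac(hi):.3f}")
        return hi
    return float(optimize.brentq(lambda c: frac(c) - target,
                                 1e-12 * event_rates.min(), hi))


def generate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Draw one fully reproducible synthetic cohort."""
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    block, endo, good, poor, cand, noise = _gene_names(cfg)
    samples = [f"S{i+1:04d}" for i in range(n)]

    er_pos = rng.random(n) < cfg.er_pos_prev
    node_pos = rng.random(n) < cfg.node_pos_prev

    F = rng.standard_normal(n) + cfg.er_effect_on_stroma * er_pos
    E = cfg.rho_fib_endo * F + np.sqrt(1 - cfg.rho_fib_endo ** 2) * rng.standard_normal(n)
    G = cfg.a_good * F + np.sqrt(1 - cfg.a_good ** 2) * rng.standard_normal(n)
    P = cfg.a_poor * F + np.sqrt(1 - cfg.a_poor ** 2) * rng.standard_normal(n)

    rows = []
    for _ in block:
        rows.append(cfg.base_mean + cfg.block_loading * F
                    + cfg.noise_sd * rng.standard_normal(n))
    for _ in endo:
        rows.append(cfg.base_mean + cfg.endo_loading * E
                    + cfg.noise_sd * rng.standard_normal(n))
    for _ in good:
        rows.append(cfg.base_mean + cfg.prog_loading * G
                    + cfg.prog_noise_sd * rng.standard_normal(n))
    for _ in poor:
        rows.append(cfg.base_mean + cfg.prog_loading * P
                    + cfg.prog_noise_sd * rng.standard_normal(n))
    for _ in cand:
        g_tilt, p_tilt = rng.normal(0.0, cfg.candidate_tilt_sd, size=2)
        latent = (F + g_tilt * G + p_tilt * P) / np.sqrt(
            1.0 + g_tilt ** 2 + p_tilt ** 2)
        rows.append(cfg.base_mean + cfg.block_loading * latent
                    + cfg.noise_sd * rng.standard_normal(n))
    for _ in noise:
        rows.append(cfg.base_mean + rng.standard_normal(n))
    log2_expr = np.clip(np.vstack(rows), 0.0, None) if rows else np.empty((0, n))
    genes = block + endo + good + poor + cand + noise

    # survival: exponential baseline, PH in the latent components
    lp = cfg.beta_good * G + cfg.beta_poor * P
    stratum = er_pos.astype(int) * 2 + node_pos.astype(int)
    mult = np.exp(cfg.stratum_log_multiplier * (stratum - 1.5))
    rates = cfg.baseline_hazard * mult * np.exp(lp)
    T = rng.exponential(1.0 / rates)
    c_rate = _solve_censor_rate(rates, cfg.censor_frac)
    if c_rate > 0:
        C = rng.exponential(1.0 / c_rate, size=n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        time, event = T, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-6)

    clin = pd.DataFrame({
        "time": time,
        "event": event,
        "er_status": np.where(er_pos, "pos", "neg"),
        "node_status": np.where(node_pos, "pos", "neg"),
        "age_group": np.where(rng.random(n) < 0.5, "le55", "gt55"),
        "stage_group": rng.choice(["I", "II", "III"], size=n, p=[0.3, 0.5, 0.2]),
        "tumor_size_group": np.where(rng.random(n) < 0.5, "le2cm", "gt2cm"),
    }, index=pd.Index(samples, name="sample_id"))

    linear = np.exp2(log2_expr) - 1.0           # exact log2p1 round trip
    stored = np.log2(linear + 1.0)
    expr_df = pd.DataFrame(stored, index=pd.Index(genes, name="gene"),
                           columns=samples)
    truth = SyntheticTruth(
        latent=pd.DataFrame({"F": F, "E": E, "G": G, "P": P}, index=samples),
        block_genes=block, endo_genes=endo, good_genes=good, poor_genes=poor,
        candidate_genes=cand, noise_genes=noise,
        beta_good=cfg.beta_good, beta_poor=cfg.beta_poor)
    return SyntheticCohort(
        expression=ExpressionMatrix(expr_df, "log2p1"),
        linear_expression=pd.DataFrame(linear, index=expr_df.index,
                                       columns=samples),
        clinical=ClinicalTable(clin, time_unit=cfg.time_unit),
        truth=truth, config=cfg)


def generate_multi_cohort(configs: list[SimulationConfig],
                          shared_core: list[str]) -> list[SyntheticCohort]:
    """Independent cohorts whose planted stromal blocks share a gene core.

    Emulates several tumor-type cohorts all containing the same small
    consensus cluster; extra block genes differ per cohort.
    """
    cohorts = []
    for k, cfg in enumerate(configs):
        names = cfg.block_gene_names
        if names is None:
            extra = cfg.n_block_genes - len(shared_core)
            if extra < 0:
                raise ValidationError("shared core larger than block size")
            names = list(shared_core) + [f"C{k+1}BLK{i+1:02d}" for i in range(extra)]
            cfg = replace(cfg, block_gene_names=names)
        if not set(shared_core) <= set(names):
            raise ValidationError(
                f"shared core absent from cohort {k} block genes")
        cohorts.append(generate_cohort(cfg))
    return cohorts


def generate_paired_normal(cohort: SyntheticCohort,
                           shifts: dict[str, float],
                           within_pair_sd: float = 0.3,
                           seed: int | None = None) -> ExpressionMatrix:
    """Matched 'normal tissue' profiles for each tumor sample.

    The normal value of gene g in patient j is the tumor log2 value plus a
    specified mean shift (normal minus tumor; genes absent from ``shifts``
    get 0) plus independent within-pair noise.  Patient-level variation is
    shared with the tumor by construction, so paired t-tests are the
    appropriate comparison.
    """
    cfg_seed = cohort.config.seed + 986243 if seed is None else seed
    rng = np.random.default_rng(cfg_seed)
    tumor = cohort.expression.data
    delta = pd.Series(0.0, index=tumor.index)
    unknown = [g for g in shifts if g not in tumor.index]
    if unknown:
        raise ValidationError(f"shift genes absent from cohort: {unknown}")
    for g, s in shifts.items():
        delta[g] = s
    noise = within_pair_sd * rng.standard_normal(tumor.shape)
    normal = tumor.add(delta, axis=0) + noise
    normal = normal.clip(lower=0.0)
    normal.columns = [f"{s}-N" for s in tumor.columns]
    return ExpressionMatrix(normal, "log2p1")


def generate_compartment_data(stroma_genes: list[str],
                              housekeeping_genes: list[str],
                              n_samples: int = 6,
                              n_background_genes: int = 50,
                              seed: int = 0):
    """Species-separable xenograft-like compartment data on linear scale.

    Returns ``(stroma, cancer)`` linear-scale matrices sharing genes and
    sample ids.  Stroma-specific genes are expressed in the stroma
    compartment and (near) absent from cancer cells; housekeeping genes are
    comparable in both; background genes fill out the library so that the
    within-sample total-count normalization is meaningful.
    """
    rng = np.random.default_rng(seed)
    overlap = set(stroma_genes) & set(housekeeping_genes)
    if overlap:
        raise ValidationError(f"genes in both lists: {sorted(overlap)}")
    background = [f"BG{i+1:03d}" for i in range(n_background_genes)]
    genes = list(stroma_genes) + list(housekeeping_genes) + background
    samples = [f"X{i+1:02d}" for i in range(n_samples)]

    def lognorm(mean, sd, size):
        return np.exp(rng.normal(np.log(mean), sd, size=size))

    n_s, n_h, n_b = len(stroma_genes), len(housekeeping_genes), n_background_genes
    stroma = np.vstack([
        lognorm(100.0, 0.3, (n_s, n_samples)),
        lognorm(50.0, 0.2, (n_h, n_samples)),
        lognorm(10.0, 0.5, (n_b, n_samples)),
    ])
    cancer = np.vstack([
        np.zeros((n_s, n_samples)),                 # stroma-specific: absent
        lognorm(50.0, 0.2, (n_h, n_samples)),
        lognorm(10.0, 0.5, (n_b, n_samples)),
    ])
    idx = pd.Index(genes, name="gene")
    return (ExpressionMatrix(pd.DataFrame(stroma, index=idx, columns=samples), "linear"),
            ExpressionMatrix(pd.DataFrame(cancer, index=idx, columns=samples), "linear"))
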