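"""Synthetic two-sample GWAS data with known causal effects.

The generative model mirrors the structure of a two-sample MR study of a
continuous, SD-scaled exposure and a binary outcome:

* J independent biallelic variants in Hardy-Weinberg equilibrium (the real
  instruments are LD-pruned, so independence is the faithful model);
* exposure X = sum_j a_j g_j + c_x U + e, scaled to unit variance, with a
  shared confounder U ~ N(0,1) that MR must be immune to;
* binary outcome via logit P(D=1) = alpha_0 + theta X + sum_j gamma_j g_j
  + c_y U, where theta is the causal log odds ratio per SD of exposure and
  gamma_j are direct (horizontally pleiotropic) variant effects — zero,
  balanced (zero-mean) or directional (constant);
* two disjoint samples: a continuous-trait GWAS of size n_exposure and a
  case-control outcome GWAS of n_cases/n_controls.

Two generators are provided.  :func:`simulate_individual` simulates
individuals and runs per-variant OLS / logistic regressions, exactly like
the GWAS that produce real summary statistics.  :func:`simulate_summary`
draws the summary statistics directly from their asymptotic sampling
distributions, orders of magnitude faster, for replicate-heavy calibration
studies; the two agree in distribution at matched configurations.

Defaults follow the scale of the motivating study: an exposure GWAS of
8866 individuals and an outcome GWAS of 30,234 cases / 172,122 controls.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy import stats as _stats

from .exceptions import MRError
from .io import InstrumentSpec, SummaryStats, write_summary_stats

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_summary",
    "simulate_individual",
    "perturb_alleles",
]

# non-palindromic allele pairs cycled over variants
_ALLELE_PAIRS = [
    ("A", "G"), ("C", "T"), ("T", "G"), ("G", "A"),
    ("T", "C"), ("G", "T"), ("A", "C"), ("C", "A"),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative-model specification for one synthetic study.

    ``a`` (per-variant exposure effects, SD units) may be given explicitly;
    otherwise effects are sized so the instrument explains ``r2_target`` of
    the exposure variance, split equally over variants.  ``prevalence`` is
    the population disease probability targeted when solving the logistic
    intercept; when None, the sample case fraction is used (cohort-like
    sampling).
    """

    n_exposure: int = 8866
    n_cases: int = 30234
    n_controls: int = 172122
    j_snps: int = 4
    maf_range: tuple[float, float] = (0.1, 0.4)
    maf: tuple[float, ...] | None = None
    a: tuple[float, ...] | None = None
    r2_target: float = 0.05
    theta: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    gamma_scale: float = 0.0
    confounder_exposure: float = 0.3
    confounder_outcome: float = 0.3
    prevalence: float | None = None
    population_multiplier: float = 3.0
    sample_overlap_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.j_snps < 1:
            raise ValueError("j_snps must be at least 1")
        lo, hi = self.maf_range
        if not (0.05 <= lo < hi <= 0.5):
            raise ValueError("maf_range must lie within [0.05, 0.5]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if self.maf is not None and len(self.maf) != self.j_snps:
            raise ValueError("maf must have j_snps entries")
        if self.a is not None and len(self.a) != self.j_snps:
            raise ValueError("a must have j_snps entries")
        if not 0.0 <= self.sample_overlap_fraction <= 1.0:
            raise ValueError("sample_overlap_fraction must lie in [0, 1]")

    @classmethod
    def reduced(cls, **overrides) -> "SimulationConfig":
        """Small-sample preset for fast tests (same model, lighter n)."""
        defaults = dict(n_exposure=2000, n_cases=500, n_controls=2000)
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def case_fraction(self) -> float:
        return self.n_cases / (self.n_cases + self.n_controls)


@dataclass
class SimulatedStudy:
    """Synthetic study: paired summary statistics plus the generating truth."""

    exposure_stats: SummaryStats
    outcome_stats: SummaryStats
    truth: dict = field(default_factory=dict)
    exposure_name: str = "sim_exposure"
    outcome_name: str = "sim_outcome"

    @property
    def instrument(self) -> InstrumentSpec:
        return InstrumentSpec(
            self.exposure_name, tuple(self.exposure_stats.table["variant_id"])
        )

    def write(self, out_dir: str | Path) -> None:
        """Write exposure.tsv / outcome.tsv plus a truth.json side-car."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_summary_stats(self.exposure_stats, out / "exposure.tsv")
        write_summary_stats(self.outcome_stats, out / "outcome.tsv")
        (out / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True) + "\n"
        )


def _draw_parameters(config: SimulationConfig, rng: np.random.Generator):
    """Resolve MAFs, exposure effects and pleiotropic effects for one study."""
    j = config.j_snps
    if config.maf is not None:
        maf = np.asarray(config.maf, dtype=float)
    else:
        maf = rng.uniform(*config.maf_range, size=j)
    het = 2.0 * maf * (1.0 - maf)  # per-variant genotypic variance
    if config.a is not None:
        a = np.asarray(config.a, dtype=float)
    else:
        a = np.sqrt(config.r2_target / (j * het))
    r2 = float(np.sum(het * a**2))
    if r2 >= 1.0:
        raise ValueError(f"instrument explains r2 = {r2:.3f} >= 1")
    if config.pleiotropy_mode == "none":
        gamma = np.zeros(j)
    elif config.pleiotropy_mode == "balanced":
        gamma = rng.normal(0.0, config.gamma_scale, size=j)
    else:  # directional
        gamma = np.full(j, config.gamma_scale)
    return maf, a, gamma, r2


def _variant_frame(
    variant_ids, pairs, eaf, beta, se, n
) -> pd.DataFrame:
    z = beta / se
    return pd.DataFrame(
        {
            "variant_id": variant_ids,
            "effect_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": np.clip(2.0 * _stats.norm.sf(np.abs(z)), 1e-300, 1.0),
            "n": float(n),
        }
    )


def _study_from_tables(exp_df, out_df, truth) -> SimulatedStudy:
    return SimulatedStudy(
        exposure_stats=SummaryStats(exp_df),
        outcome_stats=SummaryStats(out_df),
        truth=truth,
    )


def simulate_summary(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedStudy:
    """Draw summary statistics directly from their sampling distributions.

    beta_Xj ~ N(a_j, se_Xj) with se_Xj = 1/sqrt(n_exposure * 2 maf_j (1-maf_j));
    beta_Yj ~ N(theta a_j + gamma_j, se_Yj) with
    se_Yj = 1/sqrt(n_eff * 2 maf_j (1-maf_j)), where
    n_eff = n_cases n_controls / (n_cases + n_controls) is the effective
    outcome sample size of the logistic score test.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    maf, a, gamma, r2 = _draw_parameters(config, rng)
    j = config.j_snps
    het = 2.0 * maf * (1.0 - maf)
    n_eff = (
        config.n_cases * config.n_controls / (config.n_cases + config.n_controls)
    )
    se_x = 1.0 / np.sqrt(config.n_exposure * het)
    se_y = 1.0 / np.sqrt(n_eff * het)
    beta_x = rng.normal(a, se_x)
    beta_y = rng.normal(config.theta * a + gamma, se_y)

    ids = [f"rs{i + 1:07d}" for i in range(j)]
    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(j)]
    exp_df = _variant_frame(ids, pairs, maf, beta_x, se_x, config.n_exposure)
    out_df = _variant_frame(
        ids, pairs, maf, beta_y, se_y, config.n_cases + config.n_controls
    )
    truth = {
        "theta": config.theta,
        "a": list(map(float, a)),
        "gamma": list(map(float, gamma)),
        "maf": list(map(float, maf)),
        "r2": r2,
        "generator": "summary",
    }
    return _study_from_tables(exp_df, out_df, truth)


def _ols_per_variant(g: np.ndarray, x: np.ndarray):
    """Per-variant simple linear regression of x on each genotype column."""
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    xc = x - x.mean()
    sgg = np.sum(gc**2, axis=0)
    beta = gc.T @ xc / sgg
    rss = np.sum(xc**2) - beta**2 * sgg
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sgg)
    return beta, se


def _logistic_per_variant(g: np.ndarray, y: np.ndarray, max_iter: int = 50):
    """Per-variant logistic regression (intercept + genotype) via Newton."""
    betas = np.empty(g.shape[1])
    ses = np.empty(g.shape[1])
    for jj in range(g.shape[1]):
        X = np.column_stack([np.ones(g.shape[0]), g[:, jj]])
        b = np.zeros(2)
        for _ in range(max_iter):
            p = expit(X @ b)
            w = p * (1.0 - p)
            xtwx = X.T @ (X * w[:, None])
            step = np.linalg.solve(xtwx, X.T @ (y - p))
            b += step
            if np.max(np.abs(step)) < 1e-10:
                break
        cov = np.linalg.inv(xtwx)
        betas[jj] = b[1]
        ses[jj] = math.sqrt(cov[1, 1])
    return betas, ses


def simulate_individual(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedStudy:
    """Simulate individuals and run the per-variant GWAS regressions.

    Sample 1 (exposure GWAS): per-variant OLS of the unit-variance exposure
    on genotype.  Sample 2 (outcome GWAS): a source population of
    ``population_multiplier`` times the target sample is generated, disease
    status drawn from the logistic model with the intercept solved so the
    population prevalence matches the target, and a case-control subsample
    of n_cases/n_controls analysed by per-variant logistic regression.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    maf, a, gamma, r2 = _draw_parameters(config, rng)
    j = config.j_snps
    c_x, c_y = config.confounder_exposure, config.confounder_outcome
    resid_var = 1.0 - r2 - c_x**2
    if resid_var <= 0:
        raise ValueError(
            f"r2 ({r2:.3f}) plus squared confounder loading leaves no "
            "residual exposure variance"
        )
    sd_e = math.sqrt(resid_var)

    # sample 1: continuous-trait GWAS
    n1 = config.n_exposure
    g1 = rng.binomial(2, maf, size=(n1, j)).astype(float)
    u1 = rng.standard_normal(n1)
    x1 = g1 @ a + c_x * u1 + sd_e * rng.standard_normal(n1)
    beta_x, se_x = _ols_per_variant(g1, x1)

    # sample 2: outcome case-control GWAS from a source population
    n_target = config.n_cases + config.n_controls
    m = int(math.ceil(config.population_multiplier * n_target))
    n_overlap = min(int(round(config.sample_overlap_fraction * n_target)), n1, m)
    g2 = rng.binomial(2, maf, size=(m, j)).astype(float)
    u2 = rng.standard_normal(m)
    x2 = g2 @ a + c_x * u2 + sd_e * rng.standard_normal(m)
    if n_overlap > 0:  # reuse sample-1 individuals (documented overlap flag)
        g2[:n_overlap] = g1[:n_overlap]
        u2[:n_overlap] = u1[:n_overlap]
        x2[:n_overlap] = x1[:n_overlap]
    eta = config.theta * x2 + g2 @ gamma + c_y * u2
    k = config.prevalence if config.prevalence is not None else config.case_fraction

    def excess(alpha0: float) -> float:
        return float(np.mean(expit(alpha0 + eta))) - k

    alpha0 = brentq(excess, -40.0, 40.0)
    y = (rng.random(m) < expit(alpha0 + eta)).astype(float)
    case_idx = np.flatnonzero(y == 1.0)
    ctrl_idx = np.flatnonzero(y == 0.0)
    if case_idx.size < config.n_cases or ctrl_idx.size < config.n_controls:
        raise MRError(
            f"source population of {m} yielded {case_idx.size} cases / "
            f"{ctrl_idx.size} controls; increase population_multiplier"
        )
    take = np.concatenate(
        [
            rng.choice(case_idx, config.n_cases, replace=False),
            rng.choice(ctrl_idx, config.n_controls, replace=False),
        ]
    )
    g_cc, y_cc = g2[take], y[take]
    beta_y, se_y = _logistic_per_variant(g_cc, y_cc)

    ids = [f"rs{i + 1:07d}" for i in range(j)]
    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(j)]
    exp_df = _variant_frame(
        ids, pairs, g1.mean(axis=0) / 2.0, beta_x, se_x, n1
    )
    out_df = _variant_frame(
        ids, pairs, g_cc.mean(axis=0) / 2.0, beta_y, se_y, n_target
    )
    truth = {
        "theta": config.theta,
        "a": list(map(float, a)),
        "gamma": list(map(float, gamma)),
        "maf": list(map(float, maf)),
        "r2": r2,
        "alpha0": float(alpha0),
        "generator": "individual",
    }
    return _study_from_tables(exp_df, out_df, truth)


def perturb_alleles(
    study: SimulatedStudy,
    fraction_swapped: float = 0.0,
    fraction_palindromic: float = 0.0,
    seed: int | None = None,
    palindromic_eaf: float = 0.5,
) -> SimulatedStudy:
    """Re-encode a study to exercise the harmonization rules.

    A *swapped* variant's outcome record is re-expressed for the opposite
    effect allele (labels swapped, beta negated, frequency complemented) —
    the same information in the other coding, which harmonization must
    detect and undo.  A *palindromic* variant is re-labelled A/T in both
    tables with its frequency set to ``palindromic_eaf``, so ambiguous ones
    must be excluded downstream.  Palindromic relabelling takes precedence
    when a variant would be picked for both.
    """
    if not 0.0 <= fraction_swapped <= 1.0 or not 0.0 <= fraction_palindromic <= 1.0:
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    exp_df = study.exposure_stats.table.copy()
    out_df = study.outcome_stats.table.copy()
    j = len(exp_df)
    idx = np.arange(j)
    n_pal = int(round(fraction_palindromic * j))
    pal = rng.choice(idx, n_pal, replace=False) if n_pal else np.array([], int)
    rest = np.setdiff1d(idx, pal)
    n_swap = min(int(round(fraction_swapped * j)), rest.size)
    swap = rng.choice(rest, n_swap, replace=False) if n_swap else np.array([], int)

    for i in pal:
        for df in (exp_df, out_df):
            df.loc[df.index[i], ["effect_allele", "other_allele"]] = ["A", "T"]
            df.loc[df.index[i], "eaf"] = palindromic_eaf
    for i in swap:
        row = out_df.index[i]
        ea, oa = out_df.loc[row, "effect_allele"], out_df.loc[row, "other_allele"]
        out_df.loc[row, ["effect_allele", "other_allele"]] = [oa, ea]
        out_df.loc[row, "beta"] = -out_df.loc[row, "beta"]
        if not pd.isna(out_df.loc[row, "eaf"]):
            out_df.loc[row, "eaf"] = 1.0 - out_df.loc[row, "eaf"]

    return replace(
        study,
        exposure_stats=SummaryStats(exp_df),
        outcome_stats=SummaryStats(out_df),
    )
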