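"""Two-sample Mendelian randomization estimators.

The central object is :class:`MendelianRandomization`, a model holding the
harmonized per-variant effects (beta_exposure in SD units, beta_outcome in
log-odds, with standard errors).  ``fit(method=...)`` returns an
:class:`MRResults` (or :class:`EggerResults`) carrying the causal estimate —
a log odds ratio per SD of exposure — its standard error, confidence
interval, p-value and heterogeneity diagnostics.

Methods
-------
``wald``
    Single-variant ratio beta_Y/beta_X with first-order delta-method SE
    |se_Y/beta_X| (a second-order option adds the exposure-side term).
``ivw_fixed`` / ``ivw_random_mult``
    Inverse-variance weighting of the per-variant ratios with weights
    w_j = beta_Xj^2/se_Yj^2, algebraically identical to weighted least
    squares of beta_Y on beta_X through the origin.  The multiplicative
    random-effects variant inflates the fixed SE by
    max(1, sqrt(Q/(J-1))) where Q is Cochran's heterogeneity statistic.
``weighted_median``
    Interpolated weighted median of the ratio estimates; consistent when
    valid instruments carry more than half the weight.  SE by parametric
    bootstrap.
``egger``
    Weighted regression of beta_Y on beta_X with a free intercept; the
    slope is a pleiotropy-robust causal estimate (under InSIDE) and a
    non-zero intercept signals directional pleiotropy.  SEs carry a
    multiplicative overdispersion factor floored at 1; inference uses
    t(J-2).

Instrument strength is summarised by per-variant F = (beta_X/se_X)^2 and,
when frequencies and the exposure sample size are available, by the
variance explained r^2 and the aggregate F statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .exceptions import (
    CollinearityError,
    EmptyInstrumentError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from .harmonize import ExclusionReason, HarmonizedInstrument
from .io import SummaryStats

__all__ = [
    "MendelianRandomization",
    "MRResults",
    "EggerResults",
    "InstrumentStrength",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "weighted_median",
    "mr_egger",
    "instrument_strength",
    "exclude_variants",
]

#: fixed multiplier for 95% intervals, matching forest-plot convention
Z95 = 1.96

METHOD_LABELS = {
    "wald": "Wald ratio",
    "ivw_fixed": "IVW (fixed effects)",
    "ivw_random_mult": "IVW (multiplicative random effects)",
    "weighted_median": "weighted median",
    "egger": "MR-Egger",
}


class MRResults:
    """Causal-effect estimate from one MR method.

    Attributes
    ----------
    beta, se : float
        Log odds ratio per SD of exposure and its standard error.
    pvalue : float
        Two-sided, from the normal distribution (t for MR-Egger).
    q_stat, q_df : float | None
        Cochran heterogeneity statistic and its degrees of freedom, when
        the method defines one and at least two variants were used.
    """

    def __init__(
        self,
        method: str,
        beta: float,
        se: float,
        n_snps: int,
        *,
        exposure: str = "exposure",
        outcome: str = "outcome",
        dist: str = "normal",
        df: int | None = None,
        q_stat: float | None = None,
        q_df: int | None = None,
    ):
        self.method = method
        self.beta = float(beta)
        self.se = float(se)
        self.n_snps = int(n_snps)
        self.exposure = exposure
        self.outcome = outcome
        self.dist = dist
        self.df = df
        self.q_stat = None if q_stat is None else float(q_stat)
        self.q_df = q_df

    @property
    def zvalue(self) -> float:
        return self.beta / self.se

    @property
    def pvalue(self) -> float:
        if self.dist == "t":
            return float(2.0 * _stats.t.sf(abs(self.zvalue), self.df))
        return float(2.0 * _stats.norm.sf(abs(self.zvalue)))

    @property
    def q_pvalue(self) -> float | None:
        if self.q_stat is None or self.q_df is None or self.q_df < 1:
            return None
        return float(_stats.chi2.sf(self.q_stat, self.q_df))

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Confidence bounds on the log-OR scale."""
        z = Z95 if alpha == 0.05 else float(_stats.norm.ppf(1 - alpha / 2))
        return self.beta - z * self.se, self.beta + z * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def or_conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        lo, hi = self.conf_int(alpha)
        return float(np.exp(lo)), float(np.exp(hi))

    def summary(self) -> str:
        lo, hi = self.or_conf_int()
        lines = [
            f"Mendelian randomization: {self.exposure} -> {self.outcome}",
            f"Method: {METHOD_LABELS.get(self.method, self.method)}"
            f"    No. variants: {self.n_snps}",
            "-" * 64,
            f"{'':<16}{'estimate':>12}{'std err':>12}{'z':>10}{'P>|z|':>12}",
            f"{'log OR per SD':<16}{self.beta:>12.4f}{self.se:>12.4f}"
            f"{self.zvalue:>10.3f}{self.pvalue:>12.3g}",
            f"{'OR [95% CI]':<16}{self.odds_ratio:>12.3f}"
            f"   [{lo:.3f}, {hi:.3f}]",
        ]
        if self.q_stat is not None and self.q_df is not None and self.q_df >= 1:
            lines.append(
                f"Cochran Q = {self.q_stat:.3f} (df {self.q_df}, "
                f"p = {self.q_pvalue:.3g})"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<{type(self).__name__} {self.method}: beta={self.beta:.4g} "
            f"se={self.se:.4g} n_snps={self.n_snps}>"
        )


class EggerResults(MRResults):
    """MR-Egger slope with intercept diagnostics (t inference on J-2 df)."""

    def __init__(
        self,
        *args,
        intercept: float,
        intercept_se: float,
        **kwargs,
    ):
        super().__init__(*args, **kwargs)
        self.intercept = float(intercept)
        self.intercept_se = float(intercept_se)

    @property
    def intercept_pvalue(self) -> float:
        t = self.intercept / self.intercept_se
        return float(2.0 * _stats.t.sf(abs(t), self.df))

    def summary(self) -> str:
        base = super().summary()
        return base + (
            f"\nEgger intercept = {self.intercept:.4f} "
            f"(se {self.intercept_se:.4f}, p = {self.intercept_pvalue:.3g})"
        )


@dataclass
class InstrumentStrength:
    """Instrument-strength diagnostics for one exposure.

    F > 10 per variant is the conventional threshold for a non-weak
    instrument.  ``r2_total`` and ``f_aggregate`` are only available when
    effect-allele frequencies (and the exposure sample size) are known.
    """

    per_variant_f: list[tuple[str, float]]
    min_f: float
    r2_total: float | None = None
    f_aggregate: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_variant_f, columns=["variant_id", "F"])


class MendelianRandomization:
    """Two-sample summary-data MR model for one exposure/outcome pair.

    Parameters
    ----------
    beta_exposure, se_exposure
        Per-allele variant-exposure effects in SD units of the exposure.
    beta_outcome, se_outcome
        Variant-outcome effects in log-odds, harmonized to the same effect
        alleles as the exposure effects.
    """

    def __init__(
        self,
        beta_exposure,
        se_exposure,
        beta_outcome,
        se_outcome,
        *,
        variant_ids=None,
        exposure: str = "exposure",
        outcome: str = "outcome",
    ):
        self.beta_exposure = np.atleast_1d(np.asarray(beta_exposure, dtype=float))
        self.se_exposure = np.atleast_1d(np.asarray(se_exposure, dtype=float))
        self.beta_outcome = np.atleast_1d(np.asarray(beta_outcome, dtype=float))
        self.se_outcome = np.atleast_1d(np.asarray(se_outcome, dtype=float))
        lengths = {
            self.beta_exposure.size,
            self.se_exposure.size,
            self.beta_outcome.size,
            self.se_outcome.size,
        }
        if len(lengths) != 1:
            raise ValueError("effect and SE arrays must share one length")
        if self.n_snps == 0:
            raise EmptyInstrumentError("model built with zero variants")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("all standard errors must be positive")
        self.variant_ids = (
            [f"snp{i+1}" for i in range(self.n_snps)]
            if variant_ids is None
            else list(variant_ids)
        )
        self.exposure = exposure
        self.outcome = outcome

    @classmethod
    def from_harmonized(cls, harmonized: HarmonizedInstrument) -> "MendelianRandomization":
        rec = harmonized.records
        return cls(
            rec["beta_exposure"].to_numpy(),
            rec["se_exposure"].to_numpy(),
            rec["beta_outcome"].to_numpy(),
            rec["se_outcome"].to_numpy(),
            variant_ids=list(rec["variant_id"]),
            exposure=harmonized.exposure_name,
            outcome=harmonized.outcome_name,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        beta_exposure: str = "beta_exposure",
        se_exposure: str = "se_exposure",
        beta_outcome: str = "beta_outcome",
        se_outcome: str = "se_outcome",
        variant_id: str = "variant_id",
        exposure: str = "exposure",
        outcome: str = "outcome",
    ) -> "MendelianRandomization":
        ids = list(df[variant_id]) if variant_id in df.columns else None
        return cls(
            df[beta_exposure].to_numpy(),
            df[se_exposure].to_numpy(),
            df[beta_outcome].to_numpy(),
            df[se_outcome].to_numpy(),
            variant_ids=ids,
            exposure=exposure,
            outcome=outcome,
        )

    @property
    def n_snps(self) -> int:
        return self.beta_exposure.size

    def ratio_estimates(self) -> np.ndarray:
        if np.any(self.beta_exposure == 0):
            raise UndefinedRatioError("zero exposure effect: Wald ratio undefined")
        return self.beta_outcome / self.beta_exposure

    def ivw_weights(self) -> np.ndarray:
        """First-order inverse-variance weights of the per-variant ratios."""
        return self.beta_exposure**2 / self.se_outcome**2

    # -- fitting -----------------------------------------------------------

    def fit(self, method: str = "ivw_fixed", **kwargs) -> MRResults:
        if method == "wald":
            return self._fit_wald(**kwargs)
        if method in ("ivw_fixed", "ivw_random_mult"):
            effects = "fixed" if method == "ivw_fixed" else "random_multiplicative"
            return self._fit_ivw(effects=effects, **kwargs)
        if method == "weighted_median":
            return self._fit_weighted_median(**kwargs)
        if method == "egger":
            return self._fit_egger(**kwargs)
        raise ValueError(f"unknown method {method!r}")

    def _fit_wald(self, second_order: bool = False) -> MRResults:
        if self.n_snps != 1:
            raise ValueError("wald requires a single-variant model")
        bx, sx = self.beta_exposure[0], self.se_exposure[0]
        by, sy = self.beta_outcome[0], self.se_outcome[0]
        if bx == 0:
            raise UndefinedRatioError("zero exposure effect: Wald ratio undefined")
        beta = by / bx
        se = abs(sy / bx)
        if second_order:
            se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
        return MRResults(
            "wald", beta, se, 1, exposure=self.exposure, outcome=self.outcome
        )

    def _fit_ivw(self, effects: str = "fixed") -> MRResults:
        j = self.n_snps
        if effects not in ("fixed", "random_multiplicative"):
            raise ValueError(f"unknown effects model {effects!r}")
        if effects == "random_multiplicative" and j < 2:
            raise InsufficientInstrumentsError(
                "multiplicative random effects need at least 2 variants"
            )
        w_reg = 1.0 / self.se_outcome**2  # regression-through-origin weights
        sw = np.sum(w_reg * self.beta_exposure**2)
        if sw == 0:
            raise UndefinedRatioError("all exposure effects are zero")
        beta = np.sum(w_reg * self.beta_exposure * self.beta_outcome) / sw
        se = 1.0 / np.sqrt(sw)
        q_stat = q_df = None
        if j >= 2:
            resid = self.beta_outcome - beta * self.beta_exposure
            q_stat = float(np.sum(w_reg * resid**2))
            q_df = j - 1
        method = "ivw_fixed"
        if effects == "random_multiplicative":
            method = "ivw_random_mult"
            se = se * max(1.0, np.sqrt(q_stat / (j - 1)))
        return MRResults(
            method,
            beta,
            se,
            j,
            exposure=self.exposure,
            outcome=self.outcome,
            q_stat=q_stat,
            q_df=q_df,
        )

    def _fit_weighted_median(
        self, n_boot: int = 1000, seed: int | None = None
    ) -> MRResults:
        if self.n_snps < 3:
            raise InsufficientInstrumentsError(
                "weighted median needs at least 3 variants"
            )
        ratios = self.ratio_estimates()
        weights = self.ivw_weights()
        beta = _weighted_median(ratios, weights)
        rng = np.random.default_rng(seed)
        shape = (n_boot, self.n_snps)
        bx = self.beta_exposure + self.se_exposure * rng.standard_normal(shape)
        by = self.beta_outcome + self.se_outcome * rng.standard_normal(shape)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_boot = by / bx
            w_boot = bx**2 / self.se_outcome**2
        draws = np.array(
            [_weighted_median(r_boot[i], w_boot[i]) for i in range(n_boot)]
        )
        se = float(np.std(draws, ddof=1))
        return MRResults(
            "weighted_median",
            beta,
            se,
            self.n_snps,
            exposure=self.exposure,
            outcome=self.outcome,
        )

    def _fit_egger(self) -> EggerResults:
        j = self.n_snps
        if j < 3:
            raise InsufficientInstrumentsError("MR-Egger needs at least 3 variants")
        # Orient every variant to a positive exposure effect; the Egger model
        # is not invariant to allele recoding otherwise.
        flip = np.where(self.beta_exposure < 0, -1.0, 1.0)
        bx = self.beta_exposure * flip
        by = self.beta_outcome * flip
        if np.ptp(bx) == 0:
            raise CollinearityError("no variation in exposure effects")
        w = 1.0 / self.se_outcome**2
        X = np.column_stack([np.ones(j), bx])
        xtwx = X.T @ (X * w[:, None])
        coef = np.linalg.solve(xtwx, X.T @ (w * by))
        resid = by - X @ coef
        rss = float(np.sum(w * resid**2))
        sigma = max(1.0, np.sqrt(rss / (j - 2)))
        cov = sigma**2 * np.linalg.inv(xtwx)
        return EggerResults(
            "egger",
            coef[1],
            np.sqrt(cov[1, 1]),
            j,
            exposure=self.exposure,
            outcome=self.outcome,
            dist="t",
            df=j - 2,
            q_stat=rss,
            q_df=j - 2,
            intercept=coef[0],
            intercept_se=np.sqrt(cov[0, 0]),
        )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ratio estimates.

    With normalized weights w'_(j) in ratio order, cumulative midpoints
    s_j = sum_{k<=j} w'_k - w'_j/2 define a piecewise-linear quantile
    function; the estimate is its value at probability 0.5.
    """
    order = np.argsort(ratios)
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


# -- functional operation layer -------------------------------------------


def _as_model(data) -> MendelianRandomization:
    if isinstance(data, MendelianRandomization):
        return data
    if isinstance(data, HarmonizedInstrument):
        return MendelianRandomization.from_harmonized(data)
    if isinstance(data, pd.DataFrame):
        return MendelianRandomization.from_dataframe(data)
    raise TypeError(f"cannot build an MR model from {type(data).__name__}")


def wald_ratio(
    beta_exposure: float,
    se_exposure: float,
    beta_outcome: float,
    se_outcome: float,
    second_order: bool = False,
) -> MRResults:
    """Single-variant causal estimate beta_Y/beta_X with delta-method SE."""
    model = MendelianRandomization(
        [beta_exposure], [se_exposure], [beta_outcome], [se_outcome]
    )
    return model.fit("wald", second_order=second_order)


def ivw(data, effects: str = "fixed") -> MRResults:
    """Inverse-variance-weighted estimate (fixed or multiplicative random)."""
    method = "ivw_fixed" if effects == "fixed" else "ivw_random_mult"
    return _as_model(data).fit(method)


def cochran_q(data, beta: float | None = None) -> tuple[float, float]:
    """Cochran's Q around the IVW estimate (or a supplied beta) and its
    chi-square(J-1) p-value.  Requires at least two variants."""
    model = _as_model(data)
    if model.n_snps < 2:
        raise InsufficientInstrumentsError("Q undefined for fewer than 2 variants")
    if beta is None:
        beta = model.fit("ivw_fixed").beta
    w = 1.0 / model.se_outcome**2
    resid = model.beta_outcome - beta * model.beta_exposure
    q = float(np.sum(w * resid**2))
    p = float(_stats.chi2.sf(q, model.n_snps - 1))
    return q, p


def weighted_median(data, n_boot: int = 1000, seed: int | None = None) -> MRResults:
    """Weighted-median estimate with parametric-bootstrap SE."""
    return _as_model(data).fit("weighted_median", n_boot=n_boot, seed=seed)


def mr_egger(data) -> EggerResults:
    """MR-Egger regression (slope + directional-pleiotropy intercept)."""
    return _as_model(data).fit("egger")


def instrument_strength(
    exposure_records, n: float | None = None
) -> InstrumentStrength:
    """Instrument-strength diagnostics from variant-exposure associations.

    Accepts a :class:`~ivmr.io.SummaryStats`, a
    :class:`~ivmr.harmonize.HarmonizedInstrument` or a DataFrame with
    ``beta``/``se`` (or ``beta_exposure``/``se_exposure``) columns.  When
    ``n`` (exposure-GWAS sample size) and frequencies are available the
    summed variance explained and the aggregate F are reported too.
    """
    if isinstance(exposure_records, HarmonizedInstrument):
        df = exposure_records.records.rename(
            columns={
                "beta_exposure": "beta",
                "se_exposure": "se",
                "eaf_exposure": "eaf",
            }
        )
    elif isinstance(exposure_records, SummaryStats):
        df = exposure_records.table
    else:
        df = exposure_records
        if "beta_exposure" in df.columns:
            df = df.rename(
                columns={
                    "beta_exposure": "beta",
                    "se_exposure": "se",
                    "eaf_exposure": "eaf",
                }
            )
    ids = (
        list(df["variant_id"])
        if "variant_id" in df.columns
        else [f"snp{i+1}" for i in range(len(df))]
    )
    beta = df["beta"].to_numpy(dtype=float)
    se = df["se"].to_numpy(dtype=float)
    f = (beta / se) ** 2
    per_variant = list(zip(ids, (float(v) for v in f)))
    r2_total = f_aggregate = None
    if "eaf" in df.columns and not df["eaf"].isna().any():
        eaf = df["eaf"].to_numpy(dtype=float)
        r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
        r2_total = float(np.sum(r2))
        if n is not None and 0.0 < r2_total < 1.0:
            jn = len(beta)
            f_aggregate = float(
                r2_total * (n - jn - 1) / ((1.0 - r2_total) * jn)
            )
    return InstrumentStrength(
        per_variant_f=per_variant,
        min_f=float(np.min(f)),
        r2_total=r2_total,
        f_aggregate=f_aggregate,
    )


def exclude_variants(
    instrument: HarmonizedInstrument, ids
) -> HarmonizedInstrument:
    """Drop named variants from a harmonized instrument (sensitivity path).

    IDs not present are ignored with a warning; the exclusion log gains one
    ``sensitivity_exclusion`` entry per removed variant.  Removing every
    variant raises :class:`~ivmr.exceptions.EmptyInstrumentError`.
    """
    ids = list(ids)
    present = set(instrument.records["variant_id"])
    missing = [v for v in ids if v not in present]
    if missing:
        warnings.warn(
            f"variants not in instrument, ignored: {', '.join(missing)}",
            stacklevel=2,
        )
    drop = [v for v in ids if v in present]
    kept = instrument.records[~instrument.records["variant_id"].isin(drop)]
    if kept.empty:
        raise EmptyInstrumentError(
            f"excluding {ids} empties the instrument for "
            f"{instrument.exposure_name!r} / {instrument.outcome_name!r}"
        )
    exclusions = list(instrument.exclusions) + [
        (v, ExclusionReason.SENSITIVITY) for v in drop
    ]
    return HarmonizedInstrument(
        instrument.exposure_name,
        instrument.outcome_name,
        kept.reset_index(drop=True),
        exclusions,
    )
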