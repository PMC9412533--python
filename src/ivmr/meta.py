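"""Cross-source meta-analysis and multiplicity correction.

Per-source causal estimates (log odds ratios per SD) are combined with a
fixed-effect inverse-variance meta-analysis; between-source heterogeneity is
reported (Cochran's Q and I^2) but never switches the model.  Across
exposures, Benjamini-Hochberg adjustment controls the false discovery rate;
an association is *significant* when its adjusted p (FDR) is below alpha and
*suggestive* when the raw p is below alpha but the FDR is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .models import MRResults, Z95

__all__ = ["MetaEstimate", "meta_fixed", "bh_adjust", "classify_significance"]


@dataclass
class MetaEstimate:
    """Inverse-variance combination of per-source MR estimates."""

    exposure: str
    outcome: str
    method: str
    per_source: list[tuple[str, MRResults]]
    beta: float
    se: float
    q_between: float | None = None
    q_between_df: int | None = None
    q_bh: float | None = None

    @property
    def n_sources(self) -> int:
        return len(self.per_source)

    @property
    def n_snps(self) -> int:
        return max(est.n_snps for _, est in self.per_source)

    @property
    def zvalue(self) -> float:
        return self.beta / self.se

    @property
    def pvalue(self) -> float:
        return float(2.0 * _stats.norm.sf(abs(self.zvalue)))

    @property
    def q_between_pvalue(self) -> float | None:
        if self.q_between is None or not self.q_between_df:
            return None
        return float(_stats.chi2.sf(self.q_between, self.q_between_df))

    @property
    def i2(self) -> float | None:
        """Between-source I^2 = max(0, (Q - df)/Q)."""
        if self.q_between is None or not self.q_between_df:
            return None
        if self.q_between == 0:
            return 0.0
        return max(0.0, (self.q_between - self.q_between_df) / self.q_between)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        z = Z95 if alpha == 0.05 else float(_stats.norm.ppf(1 - alpha / 2))
        return self.beta - z * self.se, self.beta + z * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def or_conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        lo, hi = self.conf_int(alpha)
        return float(np.exp(lo)), float(np.exp(hi))

    @property
    def significant(self) -> bool:
        return self.q_bh is not None and self.q_bh < 0.05

    @property
    def suggestive(self) -> bool:
        return (
            self.q_bh is not None and self.pvalue < 0.05 and self.q_bh >= 0.05
        )

    def summary(self) -> str:
        lo, hi = self.or_conf_int()
        lines = [
            f"Combined estimate: {self.exposure} -> {self.outcome} "
            f"[{self.method}]",
            f"  OR per SD = {self.odds_ratio:.3f} [{lo:.3f}, {hi:.3f}], "
            f"p = {self.pvalue:.3g}"
            + (f", FDR = {self.q_bh:.3g}" if self.q_bh is not None else ""),
        ]
        for label, est in self.per_source:
            slo, shi = est.or_conf_int()
            lines.append(
                f"    {label:<12} OR = {est.odds_ratio:.3f} "
                f"[{slo:.3f}, {shi:.3f}], p = {est.pvalue:.3g} "
                f"({est.n_snps} variants)"
            )
        if self.q_between is not None and self.q_between_df:
            lines.append(
                f"  between-source Q = {self.q_between:.3f} "
                f"(df {self.q_between_df}, p = {self.q_between_pvalue:.3g}), "
                f"I^2 = {100 * self.i2:.0f}%"
            )
        return "\n".join(lines)


def meta_fixed(estimates, *, exposure=None, outcome=None) -> MetaEstimate:
    """Fixed-effect inverse-variance meta-analysis of per-source estimates.

    ``estimates`` is a sequence of :class:`~ivmr.models.MRResults` or of
    ``(source_label, MRResults)`` pairs; a single estimate passes through
    unchanged.  All inputs must be on the log-OR scale.
    """
    items: list[tuple[str, MRResults]] = []
    for i, item in enumerate(estimates):
        if isinstance(item, MRResults):
            items.append((f"source{i + 1}", item))
        else:
            label, est = item
            items.append((str(label), est))
    if not items:
        raise ValueError("meta_fixed requires at least one estimate")
    first = items[0][1]
    exposure = exposure or first.exposure
    outcome = outcome or first.outcome
    method = first.method
    q = q_df = None
    if len(items) == 1:  # single source passes through exactly
        beta, se = first.beta, first.se
    else:
        b = np.array([est.beta for _, est in items])
        v = np.array([1.0 / est.se**2 for _, est in items])
        beta = float(np.sum(v * b) / np.sum(v))
        se = float(1.0 / np.sqrt(np.sum(v)))
        q = float(np.sum(v * (b - beta) ** 2))
        q_df = len(items) - 1
    return MetaEstimate(
        exposure=exposure,
        outcome=outcome,
        method=method,
        per_source=items,
        beta=beta,
        se=se,
        q_between=q,
        q_between_df=q_df,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.  All inputs must lie in
    (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("all p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def classify_significance(meta: MetaEstimate, alpha: float = 0.05) -> str:
    """Label an estimate 'significant' (FDR < alpha), 'suggestive'
    (p < alpha but FDR >= alpha) or 'null'.  Labels are mutually exclusive."""
    if meta.q_bh is None:
        raise ValueError("q_bh not populated; run BH adjustment first")
    if meta.q_bh < alpha:
        return "significant"
    if meta.pvalue < alpha:
        return "suggestive"
    return "null"
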