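"""End-to-end analysis orchestration.

For every exposure x outcome x source the pipeline harmonizes the
instrument, computes instrument strength, fits the requested estimators
(fixed-effect IVW always; the sensitivity estimators — multiplicative
random-effects IVW, weighted median, MR-Egger — only for instruments with
more than ``sensitivity_min_snps`` variants), combines sources with a
fixed-effect meta-analysis, applies Benjamini-Hochberg adjustment across
exposures within the chosen family, and writes auditable TSV outputs plus a
monospace forest-style table.

Given the same configuration and seed the run is fully deterministic,
including the weighted-median bootstrap (per-analysis seeds are derived from
the master seed via ``numpy.random.SeedSequence``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import EmptyInstrumentError
from .harmonize import HarmonizedInstrument, harmonize
from .io import (
    InstrumentSpec,
    SummaryStats,
    read_instrument_spec,
    read_summary_stats,
    write_results_table,
)
from .meta import MetaEstimate, bh_adjust, classify_significance, meta_fixed
from .models import (
    MendelianRandomization,
    MRResults,
    exclude_variants,
    instrument_strength,
)

__all__ = [
    "ExposureInput",
    "SourceInput",
    "OutcomeInput",
    "AnalysisConfig",
    "AnalysisResult",
    "run_analysis",
    "run_sensitivity",
    "render_forest_table",
]

SENSITIVITY_METHODS = ("ivw_random_mult", "weighted_median", "egger")


@dataclass
class ExposureInput:
    name: str
    instrument: InstrumentSpec
    stats: SummaryStats


@dataclass
class SourceInput:
    label: str
    stats: SummaryStats


@dataclass
class OutcomeInput:
    name: str
    sources: list[SourceInput]


@dataclass
class AnalysisConfig:
    """Declarative description of a full study run."""

    exposures: list[ExposureInput]
    outcomes: list[OutcomeInput]
    methods: tuple[str, ...] = (
        "ivw_fixed",
        "ivw_random_mult",
        "weighted_median",
        "egger",
    )
    sensitivity_min_snps: int = 4  # sensitivity methods need n_snps > this
    fdr_family: str = "per_outcome"  # per_outcome | pooled
    fdr_alpha: float = 0.05
    sensitivity_exclusions: dict[str, list[str]] = field(default_factory=dict)
    ambiguity_window: tuple[float, float] = (0.42, 0.58)
    try_strand_flip: bool = True
    n_boot: int = 1000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if "ivw_fixed" not in self.methods:
            raise ValueError("the primary method ivw_fixed must be enabled")
        if self.fdr_family not in ("per_outcome", "pooled"):
            raise ValueError(f"unknown fdr_family {self.fdr_family!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a config file; keyword overrides win over file keys.

        Schema (paths are resolved relative to the config file)::

            exposures:
              - name: ALA
                stats: ala_exposure.tsv
                variants: [rs174547, rs2]     # or instrument_file below
            instrument_file: instruments.tsv  # optional, per exposure_name
            outcomes:
              - name: VTE
                sources:
                  - {label: INVENT, stats: invent_vte.tsv}
            methods: [ivw_fixed, weighted_median, egger]
            fdr_family: per_outcome
            sensitivity_exclusions: {AA_supplemental: [rs174547]}
            seed: 1
            out_dir: results
        """
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent

        spec_map: dict[str, InstrumentSpec] = {}
        if raw.get("instrument_file"):
            spec_map = read_instrument_spec(base / raw["instrument_file"])

        exposures = []
        for entry in raw["exposures"]:
            name = entry["name"]
            if "variants" in entry:
                spec = InstrumentSpec(name, tuple(entry["variants"]))
            elif name in spec_map:
                spec = spec_map[name]
            else:
                raise LookupError(
                    f"no instrument found for exposure {name!r}"
                )
            exposures.append(
                ExposureInput(name, spec, read_summary_stats(base / entry["stats"]))
            )
        outcomes = []
        for entry in raw["outcomes"]:
            sources = [
                SourceInput(s["label"], read_summary_stats(base / s["stats"]))
                for s in entry["sources"]
            ]
            outcomes.append(OutcomeInput(entry["name"], sources))

        kwargs: dict = {"exposures": exposures, "outcomes": outcomes}
        for key in (
            "methods",
            "sensitivity_min_snps",
            "fdr_family",
            "fdr_alpha",
            "sensitivity_exclusions",
            "ambiguity_window",
            "try_strand_flip",
            "n_boot",
            "seed",
            "out_dir",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("methods", "ambiguity_window"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class AnalysisResult:
    """Everything one pipeline run produced."""

    estimates: list[MetaEstimate]
    harmonized: dict[tuple[str, str, str], HarmonizedInstrument]
    strength: pd.DataFrame
    failures: list[tuple[str, str, str, str]] = field(default_factory=list)

    def results_frame(self) -> pd.DataFrame:
        rows = []
        for meta in self.estimates:
            for label, est in meta.per_source:
                lo, hi = est.or_conf_int()
                rows.append(
                    dict(
                        exposure=meta.exposure,
                        outcome=meta.outcome,
                        source=label,
                        n_snps=est.n_snps,
                        OR=est.odds_ratio,
                        CI_low=lo,
                        CI_high=hi,
                        p=est.pvalue,
                        q_BH=np.nan,
                        method=est.method,
                    )
                )
            lo, hi = meta.or_conf_int()
            rows.append(
                dict(
                    exposure=meta.exposure,
                    outcome=meta.outcome,
                    source="combined",
                    n_snps=meta.n_snps,
                    OR=meta.odds_ratio,
                    CI_low=lo,
                    CI_high=hi,
                    p=meta.pvalue,
                    q_BH=np.nan if meta.q_bh is None else meta.q_bh,
                    method=meta.method,
                )
            )
        return pd.DataFrame(rows)

    def harmonization_frame(self) -> pd.DataFrame:
        rows = []
        for (exp, out, src), h in self.harmonized.items():
            for vid, reason in h.exclusions:
                rows.append(
                    dict(
                        exposure=exp, outcome=out, source=src,
                        variant_id=vid, reason=reason,
                    )
                )
        return pd.DataFrame(
            rows, columns=["exposure", "outcome", "source", "variant_id", "reason"]
        )

    def classification(self, alpha: float = 0.05) -> pd.DataFrame:
        rows = [
            dict(
                exposure=m.exposure,
                outcome=m.outcome,
                label=classify_significance(m, alpha),
            )
            for m in self.estimates
            if m.method == "ivw_fixed" and m.q_bh is not None
        ]
        return pd.DataFrame(rows, columns=["exposure", "outcome", "label"])


def _method_seed(master: int, *key: int) -> int:
    """Deterministic per-analysis bootstrap seed below 2^31."""
    state = np.random.SeedSequence(entropy=master, spawn_key=key).generate_state(1)
    return int(state[0] & 0x7FFFFFFF)


def _fit_methods(
    model: MendelianRandomization,
    config: AnalysisConfig,
    seed: int,
) -> dict[str, MRResults]:
    """Fit every applicable method for one harmonized instrument."""
    out: dict[str, MRResults] = {}
    out["ivw_fixed"] = model.fit("ivw_fixed")
    run_sens = model.n_snps > config.sensitivity_min_snps
    for method in SENSITIVITY_METHODS:
        if method not in config.methods or not run_sens:
            continue
        if method == "weighted_median":
            out[method] = model.fit(
                "weighted_median", n_boot=config.n_boot, seed=seed
            )
        else:
            out[method] = model.fit(method)
    return out


def run_analysis(
    config: AnalysisConfig,
    *,
    exclusions: dict[str, list[str]] | None = None,
    label_suffix: str = "",
) -> AnalysisResult:
    """Run the full study described by ``config``.

    ``exclusions`` (exposure name -> variant IDs) applies sensitivity
    exclusions on top of harmonization; excluded-variant analyses are
    labelled ``<exposure><label_suffix>``.  Empty instruments are recorded
    as failures and the run continues.
    """
    exclusions = exclusions or {}
    harmonized: dict[tuple[str, str, str], HarmonizedInstrument] = {}
    failures: list[tuple[str, str, str, str]] = []
    strength_rows: list[dict] = []
    estimates: list[MetaEstimate] = []

    for i_out, outcome in enumerate(config.outcomes):
        outcome_meta: list[MetaEstimate] = []
        for i_exp, exposure in enumerate(config.exposures):
            exp_label = exposure.name + label_suffix
            per_method: dict[str, list[tuple[str, MRResults]]] = {}
            for i_src, source in enumerate(outcome.sources):
                key = (exp_label, outcome.name, source.label)
                try:
                    h = harmonize(
                        exposure.instrument,
                        exposure.stats,
                        source.stats,
                        outcome_name=outcome.name,
                        ambiguity_window=config.ambiguity_window,
                        try_strand_flip=config.try_strand_flip,
                    )
                    if exposure.name in exclusions:
                        h = exclude_variants(h, exclusions[exposure.name])
                except (EmptyInstrumentError, LookupError) as exc:
                    failures.append((*key, str(exc)))
                    continue
                harmonized[key] = h
                n_exp = exposure.stats.table["n"].max()
                strength = instrument_strength(
                    h, n=None if pd.isna(n_exp) else float(n_exp)
                )
                for vid, f in strength.per_variant_f:
                    strength_rows.append(
                        dict(
                            exposure=exp_label,
                            outcome=outcome.name,
                            source=source.label,
                            variant_id=vid,
                            F=f,
                            r2_total=strength.r2_total,
                            f_aggregate=strength.f_aggregate,
                        )
                    )
                model = MendelianRandomization.from_harmonized(h)
                model.exposure = exp_label
                fits = _fit_methods(
                    model, config, _method_seed(config.seed, i_out, i_exp, i_src)
                )
                for method, res in fits.items():
                    per_method.setdefault(method, []).append((source.label, res))
            for method, items in per_method.items():
                outcome_meta.append(
                    meta_fixed(items, exposure=exp_label, outcome=outcome.name)
                )
        estimates.extend(outcome_meta)

    _apply_fdr(estimates, config.fdr_family)
    strength = pd.DataFrame(
        strength_rows,
        columns=[
            "exposure", "outcome", "source", "variant_id",
            "F", "r2_total", "f_aggregate",
        ],
    )
    result = AnalysisResult(estimates, harmonized, strength, failures)
    if config.out_dir:
        _write_outputs(result, config.out_dir)
    return result


def _apply_fdr(estimates: list[MetaEstimate], family: str) -> None:
    """Assign BH-adjusted p-values to the primary (ivw_fixed) estimates."""
    primary = [m for m in estimates if m.method == "ivw_fixed"]
    if not primary:
        return
    if family == "pooled":
        groups = [primary]
    else:
        by_outcome: dict[str, list[MetaEstimate]] = {}
        for m in primary:
            by_outcome.setdefault(m.outcome, []).append(m)
        groups = list(by_outcome.values())
    for group in groups:
        q = bh_adjust([m.pvalue for m in group])
        for m, qv in zip(group, q):
            m.q_bh = float(qv)


def _write_outputs(result: AnalysisResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_results_table(result.estimates, out / "results.tsv")
    result.harmonization_frame().to_csv(
        out / "harmonization_log.tsv", sep="\t", index=False
    )
    result.strength.to_csv(
        out / "strength.tsv", sep="\t", index=False, na_rep="NA",
        float_format="%.6g",
    )
    (out / "forest.txt").write_text(render_forest_table(result.estimates) + "\n")
    if result.failures:
        pd.DataFrame(
            result.failures,
            columns=["exposure", "outcome", "source", "message"],
        ).to_csv(out / "failures.tsv", sep="\t", index=False)


def run_sensitivity(
    config: AnalysisConfig,
    exposure: str,
    excluded_ids: list[str] | None = None,
) -> AnalysisResult:
    """Re-run one exposure with named variants excluded post-harmonization.

    ``excluded_ids`` defaults to ``config.sensitivity_exclusions[exposure]``.
    Outputs are labelled ``<exposure> (excl:rs...)``.
    """
    names = [e.name for e in config.exposures]
    if exposure not in names:
        raise LookupError(f"exposure {exposure!r} not in configuration")
    if excluded_ids is None:
        excluded_ids = config.sensitivity_exclusions.get(exposure, [])
    sub = AnalysisConfig(
        exposures=[e for e in config.exposures if e.name == exposure],
        outcomes=config.outcomes,
        methods=config.methods,
        sensitivity_min_snps=config.sensitivity_min_snps,
        fdr_family=config.fdr_family,
        fdr_alpha=config.fdr_alpha,
        ambiguity_window=config.ambiguity_window,
        try_strand_flip=config.try_strand_flip,
        n_boot=config.n_boot,
        seed=config.seed,
        out_dir=None,
    )
    suffix = (
        f" (excl:{','.join(excluded_ids)})" if excluded_ids else ""
    )
    result = run_analysis(
        sub, exclusions={exposure: excluded_ids} if excluded_ids else {},
        label_suffix=suffix,
    )
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir) / "sensitivity")
    return result


def render_forest_table(estimates: list[MetaEstimate]) -> str:
    """Aligned monospace forest-style table: source rows plus combined row."""
    header = ("exposure", "outcome", "method", "source", "nSNP",
              "OR (95% CI)", "p", "FDR")
    rows: list[tuple[str, ...]] = []
    for meta in sorted(
        estimates, key=lambda m: (m.outcome, m.exposure, m.method)
    ):
        for label, est in meta.per_source:
            lo, hi = est.or_conf_int()
            rows.append(
                (
                    meta.exposure, meta.outcome, meta.method, label,
                    str(est.n_snps),
                    f"{est.odds_ratio:.2f} ({lo:.2f}-{hi:.2f})",
                    f"{est.pvalue:.3g}", "",
                )
            )
        lo, hi = meta.or_conf_int()
        rows.append(
            (
                meta.exposure, meta.outcome, meta.method, "combined",
                str(meta.n_snps),
                f"{meta.odds_ratio:.2f} ({lo:.2f}-{hi:.2f})",
                f"{meta.pvalue:.3g}",
                "" if meta.q_bh is None else f"{meta.q_bh:.3g}",
            )
        )
    widths = [
        max(len(header[c]), *(len(r[c]) for r in rows)) if rows else len(header[c])
        for c in range(len(header))
    ]
    def fmt(row: tuple[str, ...]) -> str:
        return "  ".join(cell.ljust(widths[c]) for c, cell in enumerate(row)).rstrip()
    lines = [fmt(header), fmt(tuple("-" * w for w in widths))]
    lines.extend(fmt(r) for r in rows)
    return "\n".join(lines)
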