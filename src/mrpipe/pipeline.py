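"""Config-driven orchestration of a full two-sample MR study.

One exposure, several binary outcomes.  For each outcome the pipeline
harmonizes the summary tables, computes instrument strength, runs the main
fixed-effect IVW analysis plus the sensitivity battery (IVW after
excluding listed pleiotropic SNPs, MR-Egger, MR-PRESSO raw and
outlier-corrected, weighted median, weighted mode) and the pleiotropy
diagnostics, and applies the study's tiered significance thresholds:
alpha = 0.025 for primary outcomes (Bonferroni over two primaries) and
alpha = 0.05 for secondary outcomes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import mr_core, pleiotropy, summary_io

__all__ = [
    "OutcomeSpec",
    "StudyConfig",
    "OutcomeReport",
    "StudyReport",
    "run_study",
    "render_forest_table",
    "ALL_METHODS",
]

ALL_METHODS = (
    "ivw_fixed",
    "ivw_excl_pleiotropy",
    "egger",
    "presso_raw",
    "presso_outlier_corrected",
    "weighted_median",
    "weighted_mode",
)


@dataclass(frozen=True)
class OutcomeSpec:
    label: str
    path: str
    tier: str = "primary"  # primary | secondary

    def __post_init__(self):
        if self.tier not in {"primary", "secondary"}:
            raise ValueError(f"{self.label}: tier must be primary or secondary")


@dataclass(frozen=True)
class StudyConfig:
    exposure_path: str
    outcomes: tuple[OutcomeSpec, ...]
    exposure_label: str = "exposure"
    exclusion_list_path: str | None = None
    methods: tuple[str, ...] = ALL_METHODS
    se_order: str = mr_core.DEFAULT_SE_ORDER
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int = 0
    palindrome_policy: str = "infer_by_eaf"
    alpha_primary: float = 0.025
    alpha_secondary: float = 0.05
    output_dir: str | None = None

    def __post_init__(self):
        if not self.outcomes:
            raise ValueError("at least one outcome is required")
        for a in (self.alpha_primary, self.alpha_secondary):
            if not 0 < a < 1:
                raise ValueError("alpha thresholds must lie in (0, 1)")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        outcomes = tuple(OutcomeSpec(**o) for o in raw.pop("outcomes"))
        methods = tuple(raw.pop("methods", ALL_METHODS))
        return cls(outcomes=outcomes, methods=methods, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class OutcomeReport:
    label: str
    tier: str
    alpha: float
    n_snps: int
    estimates: dict  # method -> MrEstimate or {"skipped": reason}
    heterogeneity: pleiotropy.HeterogeneityResult | None
    model_selection: pleiotropy.EggerModelSelection | None
    igx: pleiotropy.IGXResult | None
    presso: pleiotropy.PressoResult | None
    strengths: pd.DataFrame | None
    dispositions: dict
    error: str | None = None

    def significant(self, method: str) -> bool | None:
        est = self.estimates.get(method)
        if not isinstance(est, mr_core.MrEstimate):
            return None
        return est.pval < self.alpha


@dataclass
class StudyReport:
    config: StudyConfig
    outcomes: dict  # label -> OutcomeReport
    manifest: list

    def to_json_dict(self) -> dict:
        out = {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "se_order": self.config.se_order,
            "outcomes": {},
        }
        for label, rep in self.outcomes.items():
            entry = {
                "tier": rep.tier,
                "alpha": rep.alpha,
                "n_snps": rep.n_snps,
                "error": rep.error,
                "estimates": {},
                "dispositions": rep.dispositions,
            }
            for method, est in rep.estimates.items():
                if isinstance(est, mr_core.MrEstimate):
                    entry["estimates"][method] = {
                        **est.to_row(),
                        "significant": rep.significant(method),
                    }
                else:
                    entry["estimates"][method] = est
            if rep.heterogeneity:
                h = rep.heterogeneity
                entry["heterogeneity"] = {
                    "q": h.q, "df": h.df, "pval": h.pval,
                    "i2_mr": h.i2_mr, "flag_pleiotropy": h.flag_pleiotropy,
                }
            if rep.model_selection:
                m = rep.model_selection
                entry["model_selection"] = {
                    "q": m.q, "q_prime": m.q_prime, "df_prime": m.df_prime,
                    "p_q_prime": m.p_q_prime, "q_minus_qprime": m.q_minus_qprime,
                    "p_model_test": m.p_model_test, "egger_preferred": m.egger_preferred,
                }
            if rep.igx:
                entry["igx"] = {
                    "q_gx": rep.igx.q_gx, "i2_gx": rep.igx.i2_gx,
                    "low_bias_flag": rep.igx.low_bias_flag,
                }
            if rep.presso:
                p = rep.presso
                entry["presso"] = {
                    "global_rss_obs": p.global_rss_obs,
                    "global_pval": p.global_pval,
                    "outliers": list(p.outliers),
                    "distortion_pval": p.distortion_pval,
                }
            out["outcomes"][label] = entry
        return out


def _exposure_r2(inst: summary_io.HarmonizedInstrument) -> float | None:
    """Variance in the standardized exposure explained by one SNP."""
    if inst.eaf_x is None:
        return None
    return 2 * inst.eaf_x * (1 - inst.eaf_x) * inst.beta_x**2


def _strength_table(instruments: summary_io.InstrumentSet) -> pd.DataFrame | None:
    rows = []
    for inst in instruments:
        r2 = _exposure_r2(inst)
        if r2 is None or inst.n_x is None:
            return None
        r2 = min(r2, 1 - 1e-12)
        f = mr_core.f_statistic(r2, inst.n_x)
        rows.append({"rsid": inst.rsid, "r2": r2, "n": inst.n_x, "f_stat": f, "weak": f <= 10})
    return pd.DataFrame(rows)


def _analyze_outcome(
    cfg: StudyConfig,
    spec: OutcomeSpec,
    exposure: list,
    exclusions: list[str] | None,
    manifest: list,
) -> OutcomeReport:
    alpha = cfg.alpha_primary if spec.tier == "primary" else cfg.alpha_secondary
    outcome = summary_io.read_association_table(spec.path, trait_scale="log_or")
    insts = summary_io.harmonize(
        exposure,
        outcome,
        palindrome_policy=cfg.palindrome_policy,
        exposure_label=cfg.exposure_label,
        outcome_label=spec.label,
    )
    manifest.append({"outcome": spec.label, "dispositions": insts.dispositions})
    ratios = mr_core.wald_ratios(insts, cfg.se_order)
    J = len(ratios)
    estimates: dict = {}
    presso_res = None

    for method in cfg.methods:
        try:
            if method == "ivw_fixed":
                estimates[method] = mr_core.ivw_fixed(ratios)
            elif method == "ivw_excl_pleiotropy":
                if exclusions is None:
                    estimates[method] = {"skipped": "no exclusion list supplied"}
                    continue
                kept = summary_io.apply_exclusions(insts, exclusions)
                if len(kept) == 0:
                    estimates[method] = {"skipped": "all instruments excluded"}
                    continue
                estimates[method] = mr_core.ivw_fixed(
                    mr_core.wald_ratios(kept, cfg.se_order),
                    method_tag="ivw_excl_pleiotropy",
                )
            elif method == "egger":
                estimates[method] = mr_core.egger(insts, cfg.se_order)
            elif method in {"presso_raw", "presso_outlier_corrected"}:
                if presso_res is None:
                    presso_res = pleiotropy.mr_presso(
                        insts,
                        n_sim=cfg.presso_n_sim,
                        seed=cfg.seed,
                        se_order=cfg.se_order,
                    )
                if method == "presso_raw":
                    estimates[method] = presso_res.estimate_raw
                elif presso_res.estimate_corrected is not None:
                    estimates[method] = presso_res.estimate_corrected
                else:
                    estimates[method] = {"skipped": "no outliers detected"}
            elif method == "weighted_median":
                estimates[method] = mr_core.weighted_median(
                    ratios, n_boot=cfg.n_boot, seed=cfg.seed
                )
            elif method == "weighted_mode":
                estimates[method] = mr_core.weighted_mode(
                    ratios, n_boot=cfg.n_boot, seed=cfg.seed
                )
        except (ValueError, ZeroDivisionError) as exc:
            estimates[method] = {"skipped": str(exc)}

    het = model_sel = igx_res = None
    if J >= 2 and isinstance(estimates.get("ivw_fixed"), mr_core.MrEstimate):
        het = pleiotropy.cochran_q(ratios, estimates["ivw_fixed"].beta)
        igx_res = pleiotropy.i2_gx(insts)
    if J >= 3:
        model_sel = pleiotropy.rucker_model_selection(insts, cfg.se_order)

    return OutcomeReport(
        label=spec.label,
        tier=spec.tier,
        alpha=alpha,
        n_snps=J,
        estimates=estimates,
        heterogeneity=het,
        model_selection=model_sel,
        igx=igx_res,
        presso=presso_res,
        strengths=_strength_table(insts),
        dispositions=insts.dispositions,
    )


def run_study(config: StudyConfig) -> StudyReport:
    """Run every outcome through harmonization, estimation and diagnostics.

    A failure in one outcome (e.g. empty harmonized panel) is recorded on
    that outcome's report; remaining outcomes still run.  Deterministic
    given the config's seeds.
    """
    manifest: list = [{"config_hash": config.config_hash(), "seed": config.seed}]
    exposure = summary_io.read_association_table(config.exposure_path, trait_scale="sd")
    exclusions = (
        summary_io.read_exclusion_list(config.exclusion_list_path)
        if config.exclusion_list_path
        else None
    )
    outcomes: dict = {}
    for spec in config.outcomes:
        try:
            outcomes[spec.label] = _analyze_outcome(config, spec, exposure, exclusions, manifest)
        except (summary_io.HarmonizationError, summary_io.ConfigurationError, OSError) as exc:
            manifest.append({"outcome": spec.label, "error": str(exc)})
            outcomes[spec.label] = OutcomeReport(
                label=spec.label,
                tier=spec.tier,
                alpha=config.alpha_primary if spec.tier == "primary" else config.alpha_secondary,
                n_snps=0,
                estimates={m: {"skipped": "outcome failed"} for m in config.methods},
                heterogeneity=None,
                model_selection=None,
                igx=None,
                presso=None,
                strengths=None,
                dispositions={},
                error=str(exc),
            )
    report = StudyReport(config=config, outcomes=outcomes, manifest=manifest)
    if config.output_dir:
        write_report(report, config.output_dir)
    return report


def render_forest_table(report: StudyReport) -> pd.DataFrame:
    """One row per (outcome, method) with OR, CI bounds and p, figure-ordered.

    Skipped methods keep their row with a ``note`` so the layout is stable.
    """
    rows = []
    for label, rep in report.outcomes.items():
        for method in report.config.methods:
            est = rep.estimates.get(method)
            if isinstance(est, mr_core.MrEstimate):
                rows.append(
                    {
                        "outcome": label,
                        "tier": rep.tier,
                        "method": method,
                        "n_snps": est.n_snps,
                        "or": est.or_,
                        "or_ci_low": est.or_ci_low,
                        "or_ci_high": est.or_ci_high,
                        "pval": est.pval,
                        "significant": rep.significant(method),
                        "note": "",
                    }
                )
            else:
                note = est.get("skipped", "unavailable") if isinstance(est, dict) else "unavailable"
                rows.append(
                    {
                        "outcome": label,
                        "tier": rep.tier,
                        "method": method,
                        "n_snps": np.nan,
                        "or": np.nan,
                        "or_ci_low": np.nan,
                        "or_ci_high": np.nan,
                        "pval": np.nan,
                        "significant": None,
                        "note": note,
                    }
                )
    if not rows:
        raise ValueError("report contains no outcomes")
    return pd.DataFrame(rows)


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Write JSON report, forest TSV, diagnostics TSV and run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.to_json_dict(), indent=2, default=str))
    render_forest_table(report).to_csv(out / "forest.tsv", sep="\t", index=False)
    diag_rows = []
    for label, rep in report.outcomes.items():
        row = {"outcome": label, "n_snps": rep.n_snps}
        if rep.heterogeneity:
            row.update(
                q=rep.heterogeneity.q,
                q_df=rep.heterogeneity.df,
                q_pval=rep.heterogeneity.pval,
                i2_mr=rep.heterogeneity.i2_mr,
            )
        if rep.model_selection:
            row.update(
                q_prime=rep.model_selection.q_prime,
                p_model_test=rep.model_selection.p_model_test,
            )
        if rep.igx:
            row.update(i2_gx=rep.igx.i2_gx)
        if rep.presso:
            row.update(
                presso_global_pval=rep.presso.global_pval,
                presso_outliers=",".join(rep.presso.outliers),
                presso_distortion_pval=rep.presso.distortion_pval,
            )
        diag_rows.append(row)
    pd.DataFrame(diag_rows).to_csv(out / "diagnostics.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(report.manifest, indent=2, default=str))
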