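"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates a platelet-count-style instrument panel: ~219
independent SNPs measured in a large continuous-trait GWAS (exposure in SD
units) and looked up in a large binary-trait case-control GWAS (outcome in
log odds ratios).  Per SNP j with minor allele frequency p_j:

* the true standardized effect b_j is drawn normal and the vector rescaled
  so the panel explains ``h2_instruments`` of exposure variance,
  sum 2 p_j (1 - p_j) b_j^2 = h2;
* se_x,j = 1 / sqrt(2 p_j (1 - p_j) n_exposure) and the observed
  beta_x,j ~ N(b_j, se_x,j);
* a direct (pleiotropic) outcome effect alpha_j is zero with probability
  1 - pi and otherwise N(mu_alpha, sd_alpha); planted outliers add
  ``outlier_offset`` times se_y,j on top;
* se_y,j = sqrt((1/n_cases + 1/n_controls) / (2 p_j (1 - p_j))) (the
  standard binary-trait approximation) and the observed
  beta_y,j ~ N(theta_true * b_j + alpha_j, se_y,j).

Instrument selection at the genome-wide threshold is applied to an
*independent* discovery draw of beta_x so the retained panel's observed
exposure effects are free of winner's curse, mirroring a two-sample design
in which instruments were discovered elsewhere.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import mr_core
from .summary_io import HarmonizedInstrument, InstrumentSet

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_two_sample",
    "parameter_recovery_suite",
    "instrument_set_from_tables",
    "make_synthetic_study",
    "STUDY_OUTCOMES",
]


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one synthetic two-sample panel.

    Defaults emulate a strong platelet-count-style panel: 219 instruments
    for a standardized hematological exposure measured in 166,066
    subjects, against an ischemic-stroke-scale outcome GWAS of 60,341
    cases and 454,450 controls, with a causal effect of 0.07 log-OR per SD.
    """

    j_snps: int = 219
    n_exposure: int = 166_066
    n_cases: int = 60_341
    n_controls: int = 454_450
    theta_true: float = 0.07
    h2_instruments: float = 0.15
    maf_range: tuple[float, float] = (0.01, 0.5)
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation: bool = False
    n_outliers: int = 0
    outlier_offset: float = 10.0  # in units of the SNP's outcome SE
    gw_threshold: float | None = 5e-8
    seed: int = 0
    scramble_alleles: bool = False

    def __post_init__(self):
        if min(self.j_snps, self.n_exposure, self.n_cases, self.n_controls) <= 0:
            raise ValueError("all counts must be positive")
        if not 0 <= self.pleiotropy_frac <= 1:
            raise ValueError("pleiotropy_frac must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated panel, for recovery tests."""

    theta_true: float
    rsids: tuple
    b_true: tuple
    alpha: tuple
    outlier_rsids: tuple
    mean_f: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


_BASES = np.array(list("ACGT"))


def _allele_pair(rng: np.random.Generator, scramble: bool, j: int):
    if not scramble:
        return np.full(j, "A"), np.full(j, "G")
    ea = np.empty(j, dtype="<U1")
    oa = np.empty(j, dtype="<U1")
    for i in range(j):
        a, b = rng.choice(4, size=2, replace=False)
        ea[i], oa[i] = _BASES[a], _BASES[b]
    return ea, oa


def simulate_two_sample(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate exposure and outcome summary tables plus their truth record.

    Returns two DataFrames in the dialect ``summary_io`` reads (columns
    rsid, effect_allele, other_allele, eaf, beta, se, pval, n) and a
    :class:`SimTruth`.
    """
    rng = np.random.default_rng(config.seed)
    J = config.j_snps
    maf = rng.uniform(*config.maf_range, size=J)
    var_allele = 2 * maf * (1 - maf)

    # half-normal true effects: instruments are reported on their
    # exposure-increasing allele, so directional pleiotropy (mu_alpha != 0)
    # shifts every Wald ratio the same way
    b = np.abs(rng.normal(0.0, 1.0, size=J))
    b *= math.sqrt(config.h2_instruments / np.sum(var_allele * b**2))

    se_x = 1.0 / np.sqrt(var_allele * config.n_exposure)
    beta_x = rng.normal(b, se_x)
    se_y = np.sqrt((1.0 / config.n_cases + 1.0 / config.n_controls) / var_allele)

    # instrument selection on an independent discovery replicate: the
    # retained SNPs' observed beta_x stay unbiased (no winner's curse)
    if config.gw_threshold is not None:
        beta_disc = rng.normal(b, se_x)
        p_disc = 2 * stats.norm.sf(np.abs(beta_disc / se_x))
        keep = p_disc < config.gw_threshold
        if not np.any(keep):
            raise ValueError(
                "no instruments pass the significance threshold; "
                "increase h2_instruments or j_snps"
            )
    else:
        keep = np.ones(J, dtype=bool)

    alpha = np.zeros(J)
    pleio_mask = rng.random(J) < config.pleiotropy_frac
    if config.pleiotropy_sd > 0 or config.pleiotropy_mean != 0:
        mu = np.full(J, config.pleiotropy_mean)
        if config.inside_violation:
            # direct effects grow with instrument strength, breaking InSIDE
            mu = config.pleiotropy_mean * b / np.mean(b)
        alpha[pleio_mask] = rng.normal(mu[pleio_mask], config.pleiotropy_sd)

    # outliers are planted among the retained SNPs so they appear in the
    # emitted panel
    kept_idx = np.flatnonzero(keep)
    outlier_idx = rng.choice(kept_idx, size=min(config.n_outliers, kept_idx.size), replace=False)
    alpha[outlier_idx] += config.outlier_offset * se_y[outlier_idx]

    beta_y = rng.normal(config.theta_true * b + alpha, se_y)

    rsids = np.array([f"rs{1000000 + i}" for i in range(J)])
    ea, oa = _allele_pair(rng, config.scramble_alleles, J)
    p_x = 2 * stats.norm.sf(np.abs(beta_x / se_x))
    p_y = 2 * stats.norm.sf(np.abs(beta_y / se_y))

    def _table(beta, se, pval, n):
        return pd.DataFrame(
            {
                "rsid": rsids[keep],
                "effect_allele": ea[keep],
                "other_allele": oa[keep],
                "eaf": maf[keep],
                "beta": beta[keep],
                "se": se[keep],
                "pval": np.clip(pval[keep], 1e-300, 1.0),
                "n": n,
            }
        )

    exposure = _table(beta_x, se_x, p_x, config.n_exposure)
    outcome = _table(beta_y, se_y, p_y, config.n_cases + config.n_controls)

    f_real = (beta_x[keep] / se_x[keep]) ** 2
    truth = SimTruth(
        theta_true=config.theta_true,
        rsids=tuple(rsids[keep]),
        b_true=tuple(b[keep]),
        alpha=tuple(alpha[keep]),
        outlier_rsids=tuple(rsids[i] for i in outlier_idx if keep[i]),
        mean_f=float(np.mean(f_real)),
    )
    return exposure, outcome, truth


def instrument_set_from_tables(
    exposure: pd.DataFrame, outcome: pd.DataFrame, **labels
) -> InstrumentSet:
    """Fast path from already-aligned simulated tables to an InstrumentSet."""
    merged = exposure.merge(outcome, on="rsid", suffixes=("_x", "_y"))
    insts = tuple(
        HarmonizedInstrument(
            rsid=r.rsid,
            beta_x=r.beta_x,
            se_x=r.se_x,
            beta_y=r.beta_y,
            se_y=r.se_y,
            aligned_allele=r.effect_allele_x,
            eaf_x=r.eaf_x,
            n_x=int(r.n_x),
        )
        for r in merged.itertuples()
    )
    return InstrumentSet(instruments=insts, **labels)


#: six-outcome study layout emulated by :func:`make_synthetic_study`:
#: (label, tier, n_cases, n_controls, generating OR per SD of exposure)
STUDY_OUTCOMES = (
    ("coronary_artery_disease", "primary", 60_801, 123_504, 1.01),
    ("ischemic_stroke", "primary", 60_341, 454_450, 1.07),
    ("myocardial_infarction", "secondary", 42_561, 123_504, 1.03),
    ("cardioembolic_stroke", "secondary", 9_006, 454_450, 1.12),
    ("large_artery_stroke", "secondary", 6_688, 454_450, 1.09),
    ("small_vessel_stroke", "secondary", 11_710, 454_450, 1.08),
)


def make_synthetic_study(
    out_dir: str | Path,
    seed: int = 0,
    j_snps: int = 219,
    n_exclusions: int = 39,
    outcomes: Sequence[tuple] = STUDY_OUTCOMES,
    n_boot: int = 1000,
    presso_n_sim: int = 1000,
    **sim_overrides,
):
    """Write a complete multi-outcome synthetic study to disk.

    One exposure GWAS is shared by all outcomes (every outcome simulation
    reuses the same seed, hence the same instrument panel and exposure
    draws), each outcome getting its own case/control sizes and generating
    odds ratio.  Also writes a plain-text exclusion list of randomly chosen
    panel rsIDs, standing in for an external pleiotropy-database lookup.

    Returns a :class:`mrpipe.pipeline.StudyConfig` pointing at the files.
    """
    from .pipeline import OutcomeSpec, StudyConfig

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = []
    exposure_path = out_dir / "exposure.tsv"
    truths = {}
    for label, tier, n_cases, n_controls, or_per_sd in outcomes:
        cfg = SimConfig(
            j_snps=j_snps,
            n_cases=n_cases,
            n_controls=n_controls,
            theta_true=math.log(or_per_sd),
            seed=seed,
            **sim_overrides,
        )
        exposure, outcome, truth = simulate_two_sample(cfg)
        if not exposure_path.exists():
            exposure.to_csv(exposure_path, sep="\t", index=False)
            panel_rsids = list(exposure["rsid"])
        path = out_dir / f"{label}.tsv"
        outcome.to_csv(path, sep="\t", index=False)
        truths[label] = truth
        specs.append(OutcomeSpec(label=label, path=str(path), tier=tier))

    rng = np.random.default_rng(seed)
    excl = sorted(rng.choice(panel_rsids, size=min(n_exclusions, len(panel_rsids)), replace=False))
    excl_path = out_dir / "exclusions.txt"
    excl_path.write_text("# synthetic stand-in for a pleiotropy-database lookup\n" + "\n".join(excl) + "\n")

    config = StudyConfig(
        exposure_path=str(exposure_path),
        exposure_label="platelet_count",
        outcomes=tuple(specs),
        exclusion_list_path=str(excl_path),
        n_boot=n_boot,
        presso_n_sim=presso_n_sim,
        seed=seed,
        output_dir=None,
    )
    return config, truths


_POINT_ESTIMATORS = {
    "ivw_fixed": lambda ratios, insts, rng: mr_core.ivw_fixed(ratios),
    "egger": lambda ratios, insts, rng: mr_core.egger(insts),
    "weighted_median": lambda ratios, insts, rng: mr_core.weighted_median(
        ratios, n_boot=200, seed=rng
    ),
    "weighted_mode": lambda ratios, insts, rng: mr_core.weighted_mode(
        ratios, n_boot=200, seed=rng
    ),
}


def parameter_recovery_suite(
    configs: Sequence[SimConfig],
    n_reps: int = 100,
    seed: int = 0,
    methods: Sequence[str] = ("ivw_fixed", "egger", "weighted_median", "weighted_mode"),
) -> pd.DataFrame:
    """Monte-Carlo recovery metrics per (config, method).

    For each configuration, ``n_reps`` panels are generated (seeds derived
    from ``seed``) and each estimator applied; reported per method are mean
    bias, RMSE, empirical 95% CI coverage and the rejection rate of the
    two-sided test at alpha = 0.05 (type-I error when theta_true is 0,
    power otherwise).  Egger rows additionally carry the intercept-test
    rejection rate.
    """
    root = np.random.default_rng(seed)
    rows = []
    for ci, cfg in enumerate(configs):
        ests = {m: [] for m in methods}
        covers = {m: 0 for m in methods}
        rejects = {m: 0 for m in methods}
        intercept_rejects = 0
        for rep in range(n_reps):
            rep_seed = int(root.integers(0, 2**31 - 1))
            rep_cfg = SimConfig(**{**asdict(cfg), "seed": rep_seed})
            exp, out, truth = simulate_two_sample(rep_cfg)
            insts = instrument_set_from_tables(exp, out)
            ratios = mr_core.wald_ratios(insts)
            rng = np.random.default_rng(rep_seed + 1)
            for m in methods:
                est = _POINT_ESTIMATORS[m](ratios, insts, rng)
                ests[m].append(est.beta)
                covers[m] += est.ci_low <= cfg.theta_true <= est.ci_high
                rejects[m] += est.pval < 0.05
                if m == "egger":
                    intercept_rejects += est.extras["intercept_pval"] < 0.05
        for m in methods:
            err = np.array(ests[m]) - cfg.theta_true
            rows.append(
                {
                    "config": ci,
                    "theta_true": cfg.theta_true,
                    "pleiotropy_frac": cfg.pleiotropy_frac,
                    "pleiotropy_mean": cfg.pleiotropy_mean,
                    "method": m,
                    "n_reps": n_reps,
                    "mean_bias": float(np.mean(err)),
                    "rmse": float(np.sqrt(np.mean(err**2))),
                    "coverage": covers[m] / n_reps,
                    "rejection_rate": rejects[m] / n_reps,
                    "egger_intercept_rejection_rate": (
                        intercept_rejects / n_reps if m == "egger" else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
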