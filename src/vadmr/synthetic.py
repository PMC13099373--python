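"""Seeded synthetic gene-region GWAS summary statistics with known truth.

Summary statistics are simulated directly — no individual-level genotypes —
which is exactly what two-sample MR consumes and keeps everything desk-scale.
A gene region carries first-order autoregressive LD, a causal subset of
variants affects the exposure biomarker, and outcome effects follow

    beta_Y,j = theta * beta_X,j(true) + alpha_j + e_j

with alpha_j direct (pleiotropic) effects and e_j outcome sampling noise
correlated according to LD. Effects are generated on the standardized-genotype
scale (marginal effect = R @ causal effects, sampling covariance R/n) and
converted to the per-allele scale via sqrt(2*maf*(1-maf)), so reported
standard errors follow se ~ 1/sqrt(2*maf*(1-maf)*n). Case-control outcomes
are on the log-odds scale with per-variant variance 1/(2*maf*(1-maf)*N*phi*
(1-phi)), phi the case fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz

from .gwas_io import GeneTarget, LDMatrix, zscore_to_pvalue

__all__ = [
    "SimulationConfig",
    "simulate_ld",
    "simulate_region",
    "simulate_region_outcomes",
    "simulate_study",
    "StudyData",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic gene region.

    ``effect_sd`` is the s.d. of causal effects on the standardized-genotype
    scale; with the default exposure_n = 100,000 it yields per-variant
    F-statistics of order 100 at causal variants (strong instruments).
    Set ``n_cases``/``n_controls`` (instead of ``outcome_n``) for a
    case-control outcome on the log-odds scale.
    """

    n_variants: int = 60
    ld_decay: float = 0.5
    n_causal: int = 6
    exposure_n: int = 100_000
    outcome_n: int | None = 50_000
    n_cases: int | None = None
    n_controls: int | None = None
    theta: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    effect_sd: float = 0.03
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    chrom: str = "1"
    region_start: int = 1_000_000
    spacing_bp: int = 2_000

    def __post_init__(self) -> None:
        if not 0 <= self.ld_decay < 1:
            raise ValueError("ld_decay must be in [0, 1)")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        if self.pleiotropy_sd < 0 or self.effect_sd < 0:
            raise ValueError("s.d. parameters must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_cases is None and self.outcome_n is None:
            raise ValueError("need outcome_n or (n_cases, n_controls)")


def simulate_ld(n_variants: int, ld_decay: float, seed: int = 0) -> LDMatrix:
    """AR(1) LD: r[i, j] = ld_decay ** |i - j|, positive definite for decay < 1.

    ``seed`` only names the variants (ids are deterministic in practice);
    the correlation structure itself is a closed form.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    r = toeplitz(np.asarray(ld_decay, dtype=float) ** np.arange(n_variants))
    ids = [f"snp{seed}_{i}" for i in range(n_variants)]
    return LDMatrix(ids, r)


def _region_frame(cfg: SimulationConfig, ids, pos, maf, beta, se, n, cc=None):
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": cfg.chrom,
            "pos": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pvalue": zscore_to_pvalue(beta / se),
            "n": n,
        }
    )
    if cc is not None:
        df["n_cases"], df["n_controls"] = cc
    return df


def _outcome_noise_sd(config: SimulationConfig) -> tuple[float, int, tuple | None]:
    """Standardized-scale sampling s.d., total n, case/control counts."""
    if config.n_cases is not None:
        n_cases, n_controls = int(config.n_cases), int(config.n_controls)
        n_y = n_cases + n_controls
        phi = n_cases / n_y
        return 1.0 / np.sqrt(n_y * phi * (1.0 - phi)), n_y, (n_cases, n_controls)
    n_y = int(config.outcome_n)
    return 1.0 / np.sqrt(n_y), n_y, None


def simulate_region_outcomes(
    config: SimulationConfig, outcome_configs: list[SimulationConfig] | None = None
) -> tuple[pd.DataFrame, list[pd.DataFrame], LDMatrix, dict]:
    """Simulate one gene region with one exposure and several outcomes.

    All outcomes share the region's variants, LD, and true exposure effects;
    each outcome_config contributes its own theta, pleiotropy and sample
    structure, and draws independent sampling noise. The truth record carries
    theta per outcome, the causal indices, the per-variant pleiotropic
    effects, the true (allele-scale) exposure effects, and the seed;
    identical configs give bit-identical output.
    """
    if outcome_configs is None:
        outcome_configs = [config]
    rng = np.random.default_rng(config.seed)
    m = config.n_variants
    ld = simulate_ld(m, config.ld_decay, seed=config.seed)
    chol = np.linalg.cholesky(ld.r + 1e-12 * np.eye(m))

    maf = rng.uniform(*config.maf_range, size=m)
    scale = np.sqrt(2.0 * maf * (1.0 - maf))  # std-genotype <-> per-allele
    pos = config.region_start + config.spacing_bp * np.arange(m)

    causal = np.sort(rng.choice(m, size=config.n_causal, replace=False))
    b = np.zeros(m)
    b[causal] = rng.normal(0.0, config.effect_sd, size=config.n_causal)
    beta_x_true = ld.r @ b  # marginal effects under LD, standardized scale

    se_x_std = 1.0 / np.sqrt(config.exposure_n)
    beta_x_hat = beta_x_true + se_x_std * (chol @ rng.standard_normal(m))
    exposure = _region_frame(
        config, ld.variant_ids, pos, maf, beta_x_hat / scale,
        np.full(m, se_x_std) / scale, config.exposure_n,
    )

    outcome_tables: list[pd.DataFrame] = []
    thetas: list[float] = []
    alphas: list[list[float]] = []
    for ocfg in outcome_configs:
        alpha = (
            rng.normal(ocfg.pleiotropy_mean, ocfg.pleiotropy_sd, size=m)
            if (ocfg.pleiotropy_sd > 0 or ocfg.pleiotropy_mean != 0)
            else np.zeros(m)
        )
        beta_y_true = ocfg.theta * beta_x_true + alpha
        se_y_std, n_y, cc = _outcome_noise_sd(ocfg)
        beta_y_hat = beta_y_true + se_y_std * (chol @ rng.standard_normal(m))
        outcome_tables.append(
            _region_frame(
                config, ld.variant_ids, pos, maf, beta_y_hat / scale,
                np.full(m, se_y_std) / scale, n_y, cc=cc,
            )
        )
        thetas.append(ocfg.theta)
        alphas.append(alpha.tolist())

    truth = {
        "theta": thetas[0] if len(thetas) == 1 else thetas,
        "causal_indices": causal.tolist(),
        "alpha": alphas[0] if len(alphas) == 1 else alphas,
        "beta_x_true": (beta_x_true / scale).tolist(),
        "seed": config.seed,
    }
    return exposure, outcome_tables, ld, truth


def simulate_region(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, LDMatrix, dict]:
    """Simulate one gene region: exposure table, outcome table, LD, truth."""
    exposure, outcome_tables, ld, truth = simulate_region_outcomes(config)
    return exposure, outcome_tables[0], ld, truth


# ---------------------------------------------------------------------------
# Complete toy study: registry + exposure/outcome/control GWAS + LD per region


@dataclass
class StudyData:
    """In-memory bundle of everything the pipeline consumes."""

    registry: list[GeneTarget]
    exposures: dict[str, pd.DataFrame]  # biomarker -> summary table
    outcomes: dict[str, pd.DataFrame]  # outcome -> summary table
    outcome_scales: dict[str, str]  # outcome -> "linear" | "log-odds"
    controls: dict[str, pd.DataFrame]  # positive control -> summary table
    ld: dict[str, LDMatrix]  # chrom -> LD matrix
    truth: dict[str, dict] = field(default_factory=dict)


#: default toy-study layout: (symbol, class, biomarker, theta per outcome)
_DEFAULT_TARGETS = [
    # (symbol, drug_class, biomarker, theta_binary, theta_quant, theta_control)
    ("T1", "lipid-lowering", "LDL", 0.5, 0.5, 0.8),
    ("T2", "lipid-lowering", "LDL", 0.0, 0.0, 0.8),
    ("T3", "antihypertensive", "SBP", 0.5, 0.5, 0.8),
    ("T4", "antihypertensive", "SBP", 0.0, 0.0, 0.8),
    ("T5", "anti-inflammatory", "CRP", 0.0, 0.0, 0.8),
]
_CONTROL_BY_CLASS = {
    "lipid-lowering": "CAD",
    "antihypertensive": "stroke",
    "anti-inflammatory": "RA",
}


def simulate_study(
    seed: int = 0,
    targets: list[tuple] | None = None,
    n_variants: int = 60,
    ld_decay: float = 0.5,
) -> StudyData:
    """Emit a complete toy study: registry, exposures, two outcomes per
    target class, one positive control per class, and per-region LD.

    Each target occupies its own chromosome-like region. Outcomes are a
    case-control trait ("VaD", log-odds scale) and a quantitative
    neuroimaging-like trait ("WMH"); positive-control effects are strong
    (theta 0.8) so well-instrumented targets pass the direction/precision
    gate. Non-null targets carry theta = 0.5 on both outcomes.
    """
    targets = targets if targets is not None else _DEFAULT_TARGETS
    rng = np.random.default_rng(seed)
    registry: list[GeneTarget] = []
    exposures: dict[str, list[pd.DataFrame]] = {}
    outcomes: dict[str, list[pd.DataFrame]] = {"VaD": [], "WMH": []}
    controls: dict[str, list[pd.DataFrame]] = {}
    ld: dict[str, LDMatrix] = {}
    truth: dict[str, dict] = {}

    for i, (symbol, drug_class, biomarker, th_bin, th_quant, th_ctrl) in enumerate(
        targets
    ):
        chrom = str(i + 1)
        region_seed = int(rng.integers(0, 2**31 - 1))
        base = SimulationConfig(
            n_variants=n_variants,
            ld_decay=ld_decay,
            chrom=chrom,
            seed=region_seed,
        )
        exp_df, (vad_df, wmh_df, ctrl_df), region_ld, region_truth = (
            simulate_region_outcomes(
                base,
                [
                    replace(base, theta=th_bin, n_cases=5_000,
                            n_controls=200_000, outcome_n=None),
                    replace(base, theta=th_quant, outcome_n=50_000),
                    replace(base, theta=th_ctrl, n_cases=20_000,
                            n_controls=200_000, outcome_n=None),
                ],
            )
        )
        ld[chrom] = region_ld
        exposures.setdefault(biomarker, []).append(exp_df)
        outcomes["VaD"].append(vad_df)
        outcomes["WMH"].append(wmh_df)
        control_name = _CONTROL_BY_CLASS[drug_class]
        controls.setdefault(control_name, []).append(ctrl_df)

        pos0 = int(exp_df["pos"].iloc[0])
        pos1 = int(exp_df["pos"].iloc[-1])
        registry.append(
            GeneTarget(
                symbol=symbol,
                chrom=chrom,
                start=pos0,
                end=pos1,
                drug_class=drug_class,
                action_sign=-1,
                biomarkers=(biomarker,),
                positive_controls=((control_name, -1),),
            )
        )
        truth[symbol] = {
            "theta_VaD": th_bin,
            "theta_WMH": th_quant,
            "theta_control": th_ctrl,
            **region_truth,
        }

    concat = lambda frames: pd.concat(frames, ignore_index=True)
    return StudyData(
        registry=registry,
        exposures={k: concat(v) for k, v in exposures.items()},
        outcomes={k: concat(v) for k, v in outcomes.items()},
        outcome_scales={"VaD": "log-odds", "WMH": "linear"},
        controls={k: concat(v) for k, v in controls.items()},
        ld=ld,
        truth=truth,
    )
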