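"""Per-target orchestration: instrument selection, harmonization, estimation,
positive-control gating, optional colocalization, and study-level assembly
with the hierarchical multiple-testing correction.

The estimator-choice rule is exactly: one instrument -> Wald ratio; two or
more -> IVW (the primary analysis); three or more additionally MR-Egger and
weighted median. When correlated-instrument mode is on, the generalized IVW
is also computed from the region LD. Positive-control gating follows the
rule that a target passes only if at least one control estimate lies in the
expected (drug-action) direction with p < 0.1.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from .estimators import (
    EstimatorError,
    MREstimate,
    egger,
    f_statistic,
    ivw,
    ivw_correlated,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from .gwas_io import GeneTarget, LDMatrix
from .harmonize import harmonize_tables, instruments_to_arrays, orient_to_drug_action
from .instruments import (
    CLUMP_R2,
    CLUMP_WINDOW_BP,
    P_FALLBACK,
    P_PRIMARY,
    SelectionResult,
    find_proxies,
    select_cis_window,
    threshold_and_clump,
)
from .multiplicity import hierarchical_correction, outcome_correlation
from .synthetic import StudyData


@dataclass
class PipelineOptions:
    flank_bp: int = 500_000
    p_primary: float = P_PRIMARY
    p_fallback: float = P_FALLBACK
    clump_r2: float = CLUMP_R2
    clump_window_bp: int = CLUMP_WINDOW_BP
    gate_p_threshold: float = 0.1
    use_proxies: bool = False
    proxy_r2_min: float = 0.8
    random_effects: bool | str = "auto"
    correlated_ivw: bool = False
    run_coloc: bool = True
    coloc_priors: dict = field(default_factory=dict)
    palindromic_eaf_band: tuple[float, float] = (0.42, 0.58)
    n_boot: int = 1000
    seed: int = 0


@dataclass
class TargetResult:
    target: GeneTarget
    exposure_used: str
    selection: SelectionResult | None
    outcome_estimates: dict[str, dict[str, MREstimate]]  # outcome -> method -> est
    control_estimates: dict[str, dict[str, MREstimate]]
    gate_status: str
    coloc: dict[str, coloc_mod.ColocResult] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def primary_estimate(self, outcome: str) -> MREstimate | None:
        ests = self.outcome_estimates.get(outcome, {})
        return ests.get("primary")


def positive_control_gate(
    controls: list[tuple[MREstimate, int]], p_thresh: float = 0.1
) -> str:
    """Gate a target on its positive controls (drug-action orientation).

    pass: any control with the expected sign and p < p_thresh;
    fail-direction: otherwise, when the most precise (smallest-p) control has
    the wrong sign; fail-precision: right-signed but imprecise;
    no-instruments: no control estimate at all.
    """
    if not controls:
        return "no-instruments"
    for est, expected in controls:
        if np.sign(est.beta) == expected and est.pvalue < p_thresh:
            return "pass"
    best, _ = min(controls, key=lambda ce: ce[0].pvalue)
    best_expected = min(controls, key=lambda ce: ce[0].pvalue)[1]
    if np.sign(best.beta) == best_expected:
        return "fail-precision"
    return "fail-direction"


def _estimate_suite(
    bx, sex, by, sey, scale: str, ld_sub: LDMatrix | None, opts: PipelineOptions
) -> dict[str, MREstimate]:
    """Apply the estimator-choice rule to one harmonized instrument set."""
    n = len(bx)
    ests: dict[str, MREstimate] = {}
    if n == 0:
        return ests
    if n == 1:
        primary = wald_ratio(float(bx[0]), float(sex[0]), float(by[0]), float(sey[0]))
    else:
        primary = ivw(bx, sex, by, sey, random_effects=opts.random_effects)
    _, f_sum, _ = f_statistic(bx, sex)
    primary.f_stat = f_sum
    primary.scale = scale
    ests["primary"] = primary
    ests[primary.method] = primary
    if n >= 3:
        try:
            e = egger(bx, sex, by, sey)
            e.scale = scale
            ests["egger"] = e
        except EstimatorError:
            pass
        wm = weighted_median(bx, sex, by, sey, n_boot=opts.n_boot, seed=opts.seed)
        wm.scale = scale
        ests["weighted_median"] = wm
    if opts.correlated_ivw and ld_sub is not None and n >= 2:
        gi = ivw_correlated(bx, sex, by, sey, ld_sub.r, ridge=1e-6)
        gi.scale = scale
        ests["ivw_correlated"] = gi
    return ests


def _harmonize_with_proxies(
    instruments: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LDMatrix | None,
    opts: PipelineOptions,
):
    present = set(outcome["variant_id"])
    missing = [v for v in instruments["variant_id"] if v not in present]
    if opts.use_proxies and missing and ld is not None:
        mapping, _ = find_proxies(missing, outcome, ld, r2_min=opts.proxy_r2_min)
        if mapping:
            # substitute the proxy's outcome row under the instrument's id;
            # alleles/eaf come from the proxy, so harmonization still applies
            proxied = outcome.set_index("variant_id")
            extra = []
            for mid, pid in mapping.items():
                row = proxied.loc[pid].copy()
                row["variant_id"] = mid
                extra.append(row)
            outcome = pd.concat([outcome, pd.DataFrame(extra)], ignore_index=True)
    return harmonize_tables(instruments, outcome, opts.palindromic_eaf_band)


def run_target(
    target: GeneTarget,
    study: StudyData,
    opts: PipelineOptions | None = None,
) -> TargetResult:
    """Run the full per-target analysis across outcomes and controls."""
    opts = opts or PipelineOptions()
    biomarker = next((b for b in target.biomarkers if b in study.exposures), None)
    empty: dict[str, dict[str, MREstimate]] = {}
    if biomarker is None:
        return TargetResult(
            target, "", None, empty, {}, "no-instruments",
            notes=["biomarker absent from exposure data"],
        )
    exposure = study.exposures[biomarker]
    ld = study.ld.get(str(target.chrom))
    window = select_cis_window(exposure, target, flank_bp=opts.flank_bp)
    selection = threshold_and_clump(
        window, ld, opts.p_primary, opts.p_fallback, opts.clump_r2,
        opts.clump_window_bp, window_bp=opts.flank_bp,
    )
    if selection.status == "no-instruments":
        return TargetResult(
            target, biomarker, selection, empty, {}, "no-instruments",
            notes=["no variant passed even the relaxed threshold"],
        )
    ld_sub = None
    if ld is not None and all(v in ld for v in selection.variant_ids):
        ld_sub = ld.submatrix(selection.variant_ids)

    def _analyze(outcome_df: pd.DataFrame, scale: str):
        instrs, report = _harmonize_with_proxies(
            selection.instruments, outcome_df, ld, opts
        )
        bx, sex, by, sey = instruments_to_arrays(instrs)
        sub = None
        if ld_sub is not None:
            used = [i.variant_id for i in instrs if i.usable]
            if all(v in ld_sub for v in used):
                sub = ld_sub.submatrix(used)
        ests = _estimate_suite(bx, sex, by, sey, scale, sub, opts)
        oriented = {
            name: orient_to_drug_action(est, target) for name, est in ests.items()
        }
        return oriented, report

    outcome_estimates: dict[str, dict[str, MREstimate]] = {}
    coloc_results: dict[str, coloc_mod.ColocResult] = {}
    for name, outcome_df in study.outcomes.items():
        scale = study.outcome_scales.get(name, "linear")
        ests, _ = _analyze(outcome_df, scale)
        if ests:
            outcome_estimates[name] = ests
        if opts.run_coloc:
            shared = window.merge(
                outcome_df[["variant_id"]], on="variant_id", how="inner"
            )
            if len(shared) >= 2:
                sub_out = outcome_df[outcome_df["variant_id"].isin(shared["variant_id"])]
                coloc_results[name] = coloc_mod.coloc_region(
                    shared,
                    sub_out,
                    exposure_type="quantitative",
                    outcome_type="case-control" if scale == "log-odds" else "quantitative",
                    **opts.coloc_priors,
                )

    control_estimates: dict[str, dict[str, MREstimate]] = {}
    gate_inputs: list[tuple[MREstimate, int]] = []
    for ctrl_name, expected in target.positive_controls:
        ctrl_df = study.controls.get(ctrl_name)
        if ctrl_df is None:
            continue
        ests, _ = _analyze(ctrl_df, "log-odds")
        if ests:
            control_estimates[ctrl_name] = ests
            gate_inputs.append((ests["primary"], expected))
    gate_status = positive_control_gate(gate_inputs, opts.gate_p_threshold)

    return TargetResult(
        target=target,
        exposure_used=biomarker,
        selection=selection,
        outcome_estimates=outcome_estimates,
        control_estimates=control_estimates,
        gate_status=gate_status,
        coloc=coloc_results,
    )


def _estimate_row(target, outcome, method, est: MREstimate) -> dict:
    reported = est
    if est.scale == "log-odds":
        reported = to_odds_ratio(est)
    return {
        "target": target.symbol,
        "drug_class": target.drug_class,
        "outcome": outcome,
        "method": method,
        "beta_raw": est.beta,
        "se": est.se,
        "estimate": reported.beta,
        "ci_low": reported.ci_low,
        "ci_high": reported.ci_high,
        "scale": reported.scale,
        "orientation": est.orientation,
        "pvalue": est.pvalue,
        "n_iv": est.n_iv,
        "f_stat": est.f_stat,
        "q_stat": est.q_stat,
        "q_pvalue": est.q_pvalue,
    }


@dataclass
class StudyResult:
    target_results: list[TargetResult]
    estimates: pd.DataFrame
    multiplicity: pd.DataFrame
    coloc: pd.DataFrame
    gates: pd.DataFrame
    manifest: dict


def run_study(
    study: StudyData, opts: PipelineOptions | None = None
) -> StudyResult:
    """Run every registry target, assemble report tables, and apply the
    ACAT + Meff + within-class/global FDR correction."""
    opts = opts or PipelineOptions()
    results = [run_target(t, study, opts) for t in study.registry]
    outcome_names = list(study.outcomes)

    est_rows, gate_rows, coloc_rows = [], [], []
    p_rows, z_rows = [], []
    for res in results:
        t = res.target
        gate_rows.append(
            {
                "target": t.symbol,
                "drug_class": t.drug_class,
                "gate_status": res.gate_status,
                "threshold_used": res.selection.threshold_used if res.selection else None,
                "n_iv": res.selection.n_after_clump if res.selection else 0,
            }
        )
        for outcome, ests in res.outcome_estimates.items():
            for method, est in ests.items():
                if method == "primary":
                    continue
                est_rows.append(_estimate_row(t, outcome, method, est))
        for ctrl, ests in res.control_estimates.items():
            est_rows.append(_estimate_row(t, f"control:{ctrl}", "primary", ests["primary"]))
        for outcome, cres in res.coloc.items():
            coloc_rows.append(
                {
                    "target": t.symbol,
                    "outcome": outcome,
                    "pp_h0": cres.pp_h0,
                    "pp_h1": cres.pp_h1,
                    "pp_h2": cres.pp_h2,
                    "pp_h3": cres.pp_h3,
                    "pp_h4": cres.pp_h4,
                    "n_variants": cres.n_variants,
                }
            )
        pvals, zvals = [], []
        for name in outcome_names:
            primary = res.primary_estimate(name)
            if primary is None:
                pvals.append(np.nan)
                zvals.append(np.nan)
            else:
                pvals.append(primary.pvalue)
                zvals.append(primary.beta / primary.se if primary.se > 0 else np.nan)
        p_rows.append(pvals)
        z_rows.append(zvals)

    estimates = pd.DataFrame(est_rows)
    gates = pd.DataFrame(gate_rows)
    coloc_df = pd.DataFrame(coloc_rows)

    p_matrix = pd.DataFrame(p_rows, columns=outcome_names,
                            index=[r.target.symbol for r in results])
    z_matrix = pd.DataFrame(z_rows, columns=outcome_names, index=p_matrix.index)
    has_any = p_matrix.notna().any(axis=1)
    mult_in = pd.DataFrame(
        {
            "target": p_matrix.index[has_any],
            "drug_class": [r.target.drug_class for r, ok in zip(results, has_any) if ok],
            "p_per_outcome": [
                row.dropna().tolist() for _, row in p_matrix[has_any].iterrows()
            ],
        }
    )
    if len(mult_in):
        corr = (
            outcome_correlation(z_matrix)
            if len(z_matrix) >= 3
            else np.eye(len(outcome_names))
        )
        multiplicity = hierarchical_correction(mult_in, corr)
    else:
        multiplicity = pd.DataFrame(
            columns=["target", "drug_class", "p_acat", "meff",
                     "p_meff_adj", "q_within_class", "q_global"]
        )

    cfg = {
        "seed": opts.seed,
        "flank_bp": opts.flank_bp,
        "p_primary": opts.p_primary,
        "p_fallback": opts.p_fallback,
        "clump_r2": opts.clump_r2,
        "clump_window_bp": opts.clump_window_bp,
        "gate_p_threshold": opts.gate_p_threshold,
        "genome_build": "GRCh37",
    }
    manifest = dict(cfg)
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    return StudyResult(results, estimates, multiplicity, coloc_df, gates, manifest)


def write_study_outputs(result: StudyResult, outdir) -> None:
    """Write the estimates/multiplicity/coloc/gates TSVs and run manifest."""
    from pathlib import Path

    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mult = result.multiplicity.copy()
    if "p_per_outcome" in mult.columns:
        mult["p_per_outcome"] = mult["p_per_outcome"].map(
            lambda ps: ";".join(f"{p:.6g}" for p in ps)
        )
    result.estimates.to_csv(outdir / "estimates.tsv", sep="\t", index=False)
    mult.to_csv(outdir / "multiplicity.tsv", sep="\t", index=False)
    result.coloc.to_csv(outdir / "coloc.tsv", sep="\t", index=False)
    result.gates.to_csv(outdir / "gates.tsv", sep="\t", index=False)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=False)
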