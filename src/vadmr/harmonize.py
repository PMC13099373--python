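"""Allele harmonization between exposure and outcome datasets, and
orientation of final estimates to the drug's direction of action.

Outcome effect alleles are aligned to the exposure's: swapped alleles flip
the outcome beta (and eaf), strand-complement pairs are complemented first,
and palindromic variants (A/T, C/G) are resolved by allele frequency when
both frequencies fall outside an ambiguity band (default 0.42-0.58),
otherwise dropped. Drops are data, not errors; every action is recorded.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import MREstimate
from .gwas_io import GeneTarget

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp_allele(a: str) -> str:
    return a.translate(_COMPLEMENT)


def is_palindromic(a1: str, a2: str) -> bool:
    return _revcomp_allele(a1) == a2


@dataclass
class HarmonizedInstrument:
    """One variant's aligned exposure/outcome effect pair."""

    variant_id: str
    beta_exposure: float = float("nan")
    se_exposure: float = float("nan")
    beta_outcome: float = float("nan")
    se_outcome: float = float("nan")
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    action: str = "kept"  # kept | flipped | dropped
    reason: str = ""

    @property
    def usable(self) -> bool:
        return self.action in ("kept", "flipped")


def _flip(instr: HarmonizedInstrument) -> HarmonizedInstrument:
    instr.beta_outcome = -instr.beta_outcome
    if instr.eaf_outcome is not None and not np.isnan(instr.eaf_outcome):
        instr.eaf_outcome = 1.0 - instr.eaf_outcome
    instr.action = "flipped"
    return instr


def harmonize_pair(
    exp: pd.Series,
    out: pd.Series,
    palindromic_eaf_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedInstrument:
    """Align one outcome record's effect allele to the exposure's.

    ``exp`` and ``out`` are rows of the canonical summary table for the same
    variant id. Idempotent: harmonizing an already-aligned pair is a no-op.
    """
    if exp["variant_id"] != out["variant_id"]:
        raise ValueError("harmonize_pair requires matching variant ids")

    def _eaf(row):
        v = row.get("eaf")
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    instr = HarmonizedInstrument(
        variant_id=str(exp["variant_id"]),
        beta_exposure=float(exp["beta"]),
        se_exposure=float(exp["se"]),
        beta_outcome=float(out["beta"]),
        se_outcome=float(out["se"]),
        eaf_exposure=_eaf(exp),
        eaf_outcome=_eaf(out),
    )
    e1, e2 = exp["effect_allele"], exp["other_allele"]
    o1, o2 = out["effect_allele"], out["other_allele"]

    if is_palindromic(e1, e2):
        # strand is unresolvable from alleles alone; use frequencies
        if {o1, o2} != {e1, e2}:
            instr.action, instr.reason = "dropped", "allele-mismatch"
            return instr
        lo, hi = palindromic_eaf_band
        fe, fo = instr.eaf_exposure, instr.eaf_outcome
        if fe is None or fo is None or lo <= fe <= hi or lo <= fo <= hi:
            instr.action, instr.reason = "dropped", "palindromic-ambiguous"
            return instr
        # frequency identifies the allele: concordant minor/major status
        # means the two effect alleles are physically the same
        if (fe < 0.5) == (fo < 0.5):
            return instr
        return _flip(instr)

    if (o1, o2) == (e1, e2):
        return instr
    if (o1, o2) == (e2, e1):
        return _flip(instr)
    c1, c2 = _revcomp_allele(o1), _revcomp_allele(o2)
    if (c1, c2) == (e1, e2):
        return instr  # strand complement, same orientation
    if (c1, c2) == (e2, e1):
        return _flip(instr)
    instr.action, instr.reason = "dropped", "allele-mismatch"
    return instr


def harmonize_tables(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_eaf_band: tuple[float, float] = (0.42, 0.58),
) -> tuple[list[HarmonizedInstrument], pd.DataFrame]:
    """Harmonize every exposure variant found in the outcome table.

    Returns the usable instruments and a per-variant report (action, reason)
    covering all exposure variants, including those absent from the outcome
    (action "dropped", reason "missing-in-outcome").
    """
    out_by_id = {row["variant_id"]: row for _, row in outcome.iterrows()}
    instruments: list[HarmonizedInstrument] = []
    report_rows = []
    for _, exp_row in exposure.iterrows():
        vid = exp_row["variant_id"]
        out_row = out_by_id.get(vid)
        if out_row is None:
            report_rows.append((vid, "dropped", "missing-in-outcome"))
            continue
        instr = harmonize_pair(exp_row, out_row, palindromic_eaf_band)
        report_rows.append((vid, instr.action, instr.reason))
        if instr.usable:
            instruments.append(instr)
    report = pd.DataFrame(report_rows, columns=["variant_id", "action", "reason"])
    return instruments, report


def instruments_to_arrays(instruments: list[HarmonizedInstrument]):
    """(bx, sex, by, sey) arrays from usable instruments."""
    usable = [i for i in instruments if i.usable]
    return (
        np.array([i.beta_exposure for i in usable]),
        np.array([i.se_exposure for i in usable]),
        np.array([i.beta_outcome for i in usable]),
        np.array([i.se_outcome for i in usable]),
    )


def orient_to_drug_action(estimate: MREstimate, target: GeneTarget) -> MREstimate:
    """Re-express a per-biomarker-unit estimate as the drug-action effect.

    For biomarker-lowering drugs (action_sign -1) the beta is negated and the
    CI bounds swap, so e.g. a log-odds of +0.105 per unit higher SBP reads as
    OR ~ 0.90 per unit pharmacologically lower SBP. Agonists/inducers
    (action_sign +1) are unchanged. Applying twice returns the original.
    """
    out = copy.copy(estimate)
    if estimate.orientation == "drug-action":
        out.orientation = "biomarker-increase"
    else:
        out.orientation = "drug-action"
    if target.action_sign == 1:
        return out
    out.beta = -estimate.beta
    out.ci_low, out.ci_high = -estimate.ci_high, -estimate.ci_low
    return out
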