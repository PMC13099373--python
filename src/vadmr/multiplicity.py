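"""Hierarchical multiple-testing correction across targets and outcomes.

Per-outcome MR p-values for each drug target are first combined with the
Cauchy combination test (ACAT), which is valid under arbitrary dependence
between the outcomes. The combined p is then adjusted for the effective
number of independent outcomes (Li-Ji eigenvalue method) with a Sidak-style
correction, and finally Benjamini-Hochberg FDR is applied both within each
biological drug class and across all targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

#: ACAT input clipping bounds (infinite tangents at exactly 0 or 1)
ACAT_CLIP = 1e-15


def acat(pvals, weights=None) -> float:
    """Cauchy combination test.

    T = sum w_i tan((0.5 - p_i) pi) with weights summing to 1; the combined
    p is 0.5 - arctan(T)/pi. A single p returns itself; equal p values are a
    fixed point under equal weights. Inputs are clipped to
    [1e-15, 1 - 1e-15].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("acat requires at least one p-value")
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    p = np.clip(p, ACAT_CLIP, 1.0 - ACAT_CLIP)
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape or (w < 0).any() or w.sum() <= 0:
            raise ValueError("invalid weights")
        w = w / w.sum()
    t = float(np.sum(w * np.tan((0.5 - p) * np.pi)))
    return float(min(1.0, max(ACAT_CLIP, 0.5 - np.arctan(t) / np.pi)))


def li_ji_meff(corr: np.ndarray) -> float:
    """Effective number of independent tests from a correlation matrix.

    Eigenvalues lambda_i of the entrywise-absolute correlation matrix are
    mapped through f(x) = I(x >= 1) + (x - floor(x)) and summed. Identity of
    size M gives M; perfect correlation gives 1.
    """
    corr = np.abs(np.asarray(corr, dtype=float))
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if np.abs(corr - corr.T).max() > 1e-8:
        raise ValueError("correlation matrix must be symmetric")
    lam = np.linalg.eigvalsh(corr)
    if lam.min() < -1e-6:
        raise ValueError("correlation matrix not PSD within tolerance")
    lam = np.clip(lam, 0.0, None)
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def meff_adjust(p_acat: float, meff: float, style: str = "sidak") -> float:
    """Adjust a combined p for the effective number of outcomes.

    Sidak-style (default): 1 - (1 - p)^meff, bounded by 1 and exact for
    independent tests. "bonferroni" multiplies instead.
    """
    if style == "sidak":
        return float(min(1.0, -np.expm1(meff * np.log1p(-min(p_acat, 1.0 - 1e-16)))))
    if style == "bonferroni":
        return float(min(1.0, p_acat * meff))
    raise ValueError(f"unknown adjustment style {style!r}")


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def outcome_correlation(z_matrix: pd.DataFrame) -> np.ndarray:
    """Pearson correlation of outcome test statistics across targets.

    ``z_matrix`` has one row per target and one column per outcome; pairwise-
    complete observations are used. Undefined entries fall back to 0.
    """
    corr = z_matrix.corr(method="pearson", min_periods=2).to_numpy()
    corr = np.where(np.isnan(corr), 0.0, corr)
    np.fill_diagonal(corr, 1.0)
    # symmetric PSD repair for pairwise-complete artifacts
    lam, vec = np.linalg.eigh((corr + corr.T) / 2.0)
    corr = vec @ np.diag(np.clip(lam, 0.0, None)) @ vec.T
    d = np.sqrt(np.diag(corr))
    corr = corr / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def hierarchical_correction(
    rows: pd.DataFrame,
    corr: np.ndarray,
    meff_style: str = "sidak",
) -> pd.DataFrame:
    """Full correction: ACAT -> Meff adjustment -> within-class FDR -> global FDR.

    ``rows`` needs columns ``target``, ``drug_class`` and ``p_per_outcome``
    (a list/array of available per-outcome p-values; targets missing some
    outcomes contribute only the available ones, equally reweighted).
    Emits one row per target with all intermediate columns.
    """
    out = rows.copy().reset_index(drop=True)
    meff = li_ji_meff(corr)
    out["p_acat"] = [acat(p) for p in out["p_per_outcome"]]
    out["meff"] = meff
    out["p_meff_adj"] = [meff_adjust(p, meff, meff_style) for p in out["p_acat"]]

    out["q_within_class"] = np.nan
    for _, idx in out.groupby("drug_class").groups.items():
        out.loc[idx, "q_within_class"] = bh_fdr(out.loc[idx, "p_meff_adj"])
    out["q_global"] = bh_fdr(out["p_meff_adj"])
    return out
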