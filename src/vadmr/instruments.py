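"""Instrument selection: cis-window extraction, p-value thresholding with
fallback, greedy LD clumping, genome-wide mode, proxy lookup, F-statistics.

Conventions follow the field's standard tooling: candidate variants within
±500 kb of the gene are thresholded at p < 5e-8 (relaxed to 5e-5 when
nothing passes), then clumped greedily by p-value rank — repeatedly take the
most significant remaining variant as an index and discard all others with
r^2 >= 0.001 within 10,000 kb of it. Distances are index-centred. Variant
pairs absent from the LD matrix are conservatively treated as correlated
(r^2 = 1) inside the window unless configured otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import f_statistic  # noqa: F401  (selection-stage surface)
from .gwas_io import LDMatrix

P_PRIMARY = 5e-8
P_FALLBACK = 5e-5
CLUMP_R2 = 0.001
CLUMP_WINDOW_BP = 10_000_000


@dataclass
class SelectionResult:
    """Instruments retained for one target/exposure, with selection metadata."""

    instruments: pd.DataFrame  # rows of the exposure table
    threshold_used: float | None
    mode: str  # "cis" | "genome-wide"
    window_bp: int
    n_before_clump: int
    n_after_clump: int
    status: str = "ok"  # "ok" | "no-instruments"
    fallback_used: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.instruments["variant_id"])


def select_cis_window(
    exposure: pd.DataFrame, target, flank_bp: int = 500_000
) -> pd.DataFrame:
    """Exposure rows within ``flank_bp`` on either side of the gene, inclusive."""
    lo, hi = target.start - flank_bp, target.end + flank_bp
    mask = (
        (exposure["chrom"].astype(str) == str(target.chrom))
        & (exposure["pos"] >= lo)
        & (exposure["pos"] <= hi)
    )
    return exposure.loc[mask].reset_index(drop=True)


def _greedy_clump(
    candidates: pd.DataFrame,
    ld: LDMatrix | None,
    clump_r2: float,
    clump_window_bp: int,
    missing_r2: float,
) -> pd.DataFrame:
    # deterministic order: p, then position, then id — row order irrelevant
    cand = candidates.sort_values(
        ["pvalue", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    kept_idx: list[int] = []
    alive = np.ones(len(cand), dtype=bool)
    pos = cand["pos"].to_numpy()
    ids = cand["variant_id"].to_numpy()
    for i in range(len(cand)):
        if not alive[i]:
            continue
        kept_idx.append(i)
        for j in range(i + 1, len(cand)):
            if not alive[j]:
                continue
            if abs(int(pos[j]) - int(pos[i])) > clump_window_bp:
                continue
            r2 = ld.r2(ids[i], ids[j]) if ld is not None else None
            if r2 is None:
                r2 = missing_r2
            if r2 >= clump_r2:
                alive[j] = False
    return cand.iloc[kept_idx].reset_index(drop=True)


def threshold_and_clump(
    candidates: pd.DataFrame,
    ld: LDMatrix | None,
    p_primary: float = P_PRIMARY,
    p_fallback: float = P_FALLBACK,
    clump_r2: float = CLUMP_R2,
    clump_window_bp: int = CLUMP_WINDOW_BP,
    missing_r2: float = 1.0,
    mode: str = "cis",
    window_bp: int = 500_000,
) -> SelectionResult:
    """Threshold candidates at ``p_primary`` (falling back to ``p_fallback``
    when nothing passes) and clump greedily by p-value rank.

    Returns an empty result with status "no-instruments" when even the
    fallback threshold yields nothing.
    """
    passing = candidates.loc[candidates["pvalue"] <= p_primary]
    threshold, fallback = p_primary, False
    if passing.empty:
        passing = candidates.loc[candidates["pvalue"] <= p_fallback]
        threshold, fallback = p_fallback, True
    if passing.empty:
        return SelectionResult(
            instruments=candidates.iloc[0:0],
            threshold_used=None,
            mode=mode,
            window_bp=window_bp,
            n_before_clump=0,
            n_after_clump=0,
            status="no-instruments",
        )
    clumped = _greedy_clump(passing, ld, clump_r2, clump_window_bp, missing_r2)
    return SelectionResult(
        instruments=clumped,
        threshold_used=threshold,
        mode=mode,
        window_bp=window_bp,
        n_before_clump=len(passing),
        n_after_clump=len(clumped),
        fallback_used=fallback,
    )


def select_genome_wide(
    exposure: pd.DataFrame,
    ld_lookup: dict[str, LDMatrix] | None,
    p_primary: float = P_PRIMARY,
    p_fallback: float = P_FALLBACK,
    clump_r2: float = CLUMP_R2,
    clump_window_bp: int = CLUMP_WINDOW_BP,
    missing_r2: float = 1.0,
) -> SelectionResult:
    """Genome-wide selection: thresholding then per-chromosome clumping.

    ``ld_lookup`` maps chromosome to its LD matrix; variants on different
    chromosomes are unlinked by definition.
    """
    passing = exposure.loc[exposure["pvalue"] <= p_primary]
    threshold, fallback = p_primary, False
    if passing.empty:
        passing = exposure.loc[exposure["pvalue"] <= p_fallback]
        threshold, fallback = p_fallback, True
    if passing.empty:
        return SelectionResult(
            instruments=exposure.iloc[0:0],
            threshold_used=None,
            mode="genome-wide",
            window_bp=0,
            n_before_clump=0,
            n_after_clump=0,
            status="no-instruments",
        )
    pieces = []
    for chrom, group in passing.groupby(passing["chrom"].astype(str), sort=True):
        ld = (ld_lookup or {}).get(str(chrom))
        pieces.append(_greedy_clump(group, ld, clump_r2, clump_window_bp, missing_r2))
    clumped = (
        pd.concat(pieces, ignore_index=True)
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return SelectionResult(
        instruments=clumped,
        threshold_used=threshold,
        mode="genome-wide",
        window_bp=0,
        n_before_clump=len(passing),
        n_after_clump=len(clumped),
        fallback_used=fallback,
    )


def find_proxies(
    missing_ids: list[str],
    outcome: pd.DataFrame,
    ld: LDMatrix,
    r2_min: float = 0.8,
) -> tuple[dict[str, str], list[str]]:
    """For each instrument absent from the outcome data, find the
    outcome-present variant with maximal r^2 >= ``r2_min``.

    Ties break by smaller position, then lexicographic id. Returns the
    mapping and the list of ids left unproxied.
    """
    present = outcome.drop_duplicates("variant_id").set_index("variant_id")
    mapping: dict[str, str] = {}
    unproxied: list[str] = []
    for mid in missing_ids:
        best = None  # (-r2, pos, id)
        for cid in present.index:
            if cid == mid:
                continue
            r2 = ld.r2(mid, cid)
            if r2 is None or r2 < r2_min:
                continue
            key = (-r2, int(present.loc[cid, "pos"]), str(cid))
            if best is None or key < best:
                best = key
        if best is None:
            unproxied.append(mid)
        else:
            mapping[mid] = best[2]
    return mapping, unproxied
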