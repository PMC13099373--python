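"""Input/output and validation for GWAS summary statistics, LD matrices and
the drug-target registry.

Summary statistics travel through the pipeline as pandas DataFrames with a
fixed column vocabulary (see :data:`SUMMARY_COLUMNS`). All positions are
1-based, inclusive, on a single genome build per run (default GRCh37, declared
in config and echoed into outputs — builds are never mixed). Alleles are
upper-cased on read; indels are permitted as multi-character strings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: mandatory columns of a summary-statistics table
SUMMARY_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
]
#: optional columns, carried through when present
OPTIONAL_COLUMNS = ["eaf", "n", "n_cases", "n_controls"]

#: smallest positive double; p-values of exactly 0 are floored to this
P_FLOOR = np.nextafter(0.0, 1.0)


class SummaryStatsError(ValueError):
    """Raised for unrecoverable problems in a summary-statistics file."""


@dataclass
class ReadReport:
    """Bookkeeping from one read/validation pass."""

    n_read: int = 0
    n_valid: int = 0
    n_dropped: int = 0
    n_pvalue_floored: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)

    def count_drop(self, reason: str, n: int = 1) -> None:
        if n:
            self.drop_reasons[reason] = self.drop_reasons.get(reason, 0) + int(n)
            self.n_dropped += int(n)


@dataclass(frozen=True)
class GeneTarget:
    """A druggable gene with its coordinates and analysis metadata.

    ``action_sign`` is -1 for inhibitors/antagonists/binders (the drug lowers
    the biomarker) and +1 for agonists/inducers. ``positive_controls`` maps a
    control trait name to the expected sign of the drug-action effect on it
    (usually -1: biomarker-lowering modulation reduces control-disease risk).
    """

    symbol: str
    chrom: str
    start: int
    end: int
    drug_class: str
    action_sign: int
    biomarkers: tuple[str, ...]
    positive_controls: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.symbol}: start must be < end")
        if self.action_sign not in (-1, 1):
            raise ValueError(f"{self.symbol}: action_sign must be -1 or +1")


class LDMatrix:
    """Pairwise LD correlation (r, signed) over an ordered set of variants.

    The matrix is symmetrized on construction (asymmetries above ``atol``
    are an error), must have a unit diagonal and entries in [-1, 1], and is
    required to be positive semidefinite within tolerance.
    """

    def __init__(self, variant_ids: list[str], r: np.ndarray, atol: float = 1e-8):
        r = np.asarray(r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("LD matrix must be square")
        if len(variant_ids) != r.shape[0]:
            raise ValueError("variant_ids length does not match matrix size")
        if len(set(variant_ids)) != len(variant_ids):
            raise ValueError("duplicate variant ids in LD matrix")
        asym = np.abs(r - r.T).max() if r.size else 0.0
        if asym > atol:
            raise ValueError(f"LD matrix asymmetric beyond tolerance ({asym:.3g})")
        r = (r + r.T) / 2.0
        if r.size and np.abs(np.diag(r) - 1.0).max() > 1e-6:
            raise ValueError("LD matrix diagonal must be 1")
        if r.size and (np.abs(r) > 1.0 + 1e-8).any():
            raise ValueError("LD entries must lie in [-1, 1]")
        if r.size:
            np.fill_diagonal(r, 1.0)
            np.clip(r, -1.0, 1.0, out=r)
            lam_min = np.linalg.eigvalsh(r).min()
            if lam_min < -1e-6:
                raise ValueError(f"LD matrix not PSD (min eigenvalue {lam_min:.3g})")
        self.variant_ids = list(variant_ids)
        self.r = r
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r_value(self, a: str, b: str) -> float | None:
        """Signed r between two variants, or None if either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r[ia, ib])

    def r2(self, a: str, b: str) -> float | None:
        rv = self.r_value(a, b)
        return None if rv is None else rv * rv

    def submatrix(self, ids: list[str]) -> "LDMatrix":
        missing = [v for v in ids if v not in self._index]
        if missing:
            raise KeyError(f"variants absent from LD matrix: {missing[:5]}")
        idx = [self._index[v] for v in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])


def _validate_frame(df: pd.DataFrame, report: ReadReport) -> pd.DataFrame:
    """Apply VariantRecord invariants row-wise; drop and count failures."""
    df = df.copy()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    df["chrom"] = df["chrom"].astype(str)

    for col in ("pos", "beta", "se", "pvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "eaf" in df.columns:
        df["eaf"] = pd.to_numeric(df["eaf"], errors="coerce")

    floored = df["pvalue"] == 0.0
    report.n_pvalue_floored += int(floored.sum())
    df.loc[floored, "pvalue"] = P_FLOOR

    checks = {
        "missing-required": df[["pos", "beta", "se", "pvalue"]].notna().all(axis=1),
        "se-nonpositive": ~(df["se"] > 0),
        "pvalue-out-of-range": ~((df["pvalue"] > 0) & (df["pvalue"] <= 1)),
        "allele-identical": df["effect_allele"] == df["other_allele"],
        "allele-invalid": ~(
            df["effect_allele"].str.fullmatch(r"[ACGT]+")
            & df["other_allele"].str.fullmatch(r"[ACGT]+")
        ),
    }
    bad = ~checks.pop("missing-required")
    report.count_drop("missing-required", int(bad.sum()))
    for reason, mask in checks.items():
        new = mask & ~bad
        report.count_drop(reason, int(new.sum()))
        bad |= new
    if "eaf" in df.columns:
        mask = df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1))
        new = mask & ~bad
        report.count_drop("eaf-out-of-range", int(new.sum()))
        bad |= new

    df = df.loc[~bad].reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    report.n_valid = len(df)
    return df


def read_summary_stats(
    path, column_map: dict[str, str] | None = None
) -> tuple[pd.DataFrame, ReadReport]:
    """Read a tab-delimited summary-statistics file.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    column_map
        Optional mapping from source header names to the canonical names in
        :data:`SUMMARY_COLUMNS` / :data:`OPTIONAL_COLUMNS`.

    Returns the validated table and a :class:`ReadReport` counting dropped
    rows by reason. Missing mandatory columns or zero valid rows raise
    :class:`SummaryStatsError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryStatsError(f"missing mandatory column(s): {', '.join(missing)}")
    keep = SUMMARY_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    report = ReadReport(n_read=len(df))
    df = _validate_frame(df[keep], report)
    if df.empty:
        raise SummaryStatsError(f"no valid rows in {path}")
    for col in ("n", "n_cases", "n_controls"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df, report


def validate_summary(df: pd.DataFrame) -> tuple[pd.DataFrame, ReadReport]:
    """Validate an in-memory summary table against the same invariants."""
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryStatsError(f"missing mandatory column(s): {', '.join(missing)}")
    report = ReadReport(n_read=len(df))
    return _validate_frame(df, report), report


def write_summary_stats(df: pd.DataFrame, path) -> None:
    """Write a summary table in the canonical TSV dialect.

    Floats are written with enough digits that a read round-trips to 1e-12.
    """
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def invert_trait_direction(df: pd.DataFrame) -> pd.DataFrame:
    """Negate every beta, leaving all other fields unchanged.

    Used for traits whose raw direction is "higher = better" (fractional
    anisotropy becomes inversed FA) so that downstream code uniformly sees
    higher values as worse. Involution: applying twice returns the input.
    """
    out = df.copy()
    out["beta"] = -out["beta"]
    return out


def read_ld_matrix(path) -> LDMatrix:
    """Read a TSV LD matrix whose first row and column are variant ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(v) for v in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError("LD matrix row and column ids disagree")
    return LDMatrix(ids, df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def _parse_target(block: dict) -> GeneTarget:
    controls = tuple(
        (str(c["trait"]), int(c.get("expected_sign", -1)))
        for c in block.get("positive_controls", [])
    )
    return GeneTarget(
        symbol=str(block["symbol"]),
        chrom=str(block["chrom"]),
        start=int(block["start"]),
        end=int(block["end"]),
        drug_class=str(block["drug_class"]),
        action_sign=int(block["action_sign"]),
        biomarkers=tuple(str(b) for b in block["biomarkers"]),
        positive_controls=controls,
    )


def load_registry(path) -> list[GeneTarget]:
    """Load the drug-target registry from a YAML file.

    The file holds a ``targets:`` list of blocks with the GeneTarget fields;
    ``positive_controls`` entries are ``{trait, expected_sign}`` mappings.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [_parse_target(b) for b in doc["targets"]]


def dump_registry(targets: list[GeneTarget], path) -> None:
    doc = {
        "targets": [
            {
                "symbol": t.symbol,
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "drug_class": t.drug_class,
                "action_sign": t.action_sign,
                "biomarkers": list(t.biomarkers),
                "positive_controls": [
                    {"trait": trait, "expected_sign": sign}
                    for trait, sign in t.positive_controls
                ],
            }
            for t in targets
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def zscore_to_pvalue(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided normal p-value from a z statistic, floored away from 0."""
    from scipy.stats import norm

    p = 2.0 * norm.sf(np.abs(z))
    return np.maximum(p, P_FLOOR)
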