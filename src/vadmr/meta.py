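"""Fixed-effect inverse-variance meta-analysis of two GWAS.

Used for the clinical vascular-dementia outcome (two case-control GWAS
combined into one) and for pQTL replication datasets. The standard-error
weighting scheme is implemented because the pipeline needs combined betas
and standard errors downstream:

    beta = (b_a/se_a^2 + b_b/se_b^2) / (1/se_a^2 + 1/se_b^2)
    se   = (1/se_a^2 + 1/se_b^2)^(-1/2)

The second dataset's alleles are harmonized to the first's before
combination; variants present in only one input pass through flagged
single-source (configurable). Case/control counts are summed, so combining
cohorts of 3,892/466,606 and 3,116/433,066 cases/controls yields
7,008/899,672. No genomic-control correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gwas_io import zscore_to_pvalue
from .harmonize import harmonize_pair


class MetaError(ValueError):
    pass


def _two_study_i2(b1, se1, b2, se2) -> float:
    """I^2 from the two-study Cochran's Q (df = 1)."""
    w1, w2 = 1.0 / se1**2, 1.0 / se2**2
    pooled = (b1 * w1 + b2 * w2) / (w1 + w2)
    q = w1 * (b1 - pooled) ** 2 + w2 * (b2 - pooled) ** 2
    return float(max(0.0, (q - 1.0) / q)) if q > 0 else 0.0


def fixed_effect_meta(
    a: pd.DataFrame,
    b: pd.DataFrame,
    allow_single_source: bool = True,
) -> pd.DataFrame:
    """Combine two summary-statistics tables per variant.

    Returns a table with beta/se/pvalue columns replaced by the combined
    values, summed sample sizes, a ``source`` flag ("both", "a-only",
    "b-only") and a two-study ``heterogeneity_i2`` for shared variants.
    Input order does not change any value.
    """
    a_idx = a.drop_duplicates("variant_id").set_index("variant_id", drop=False)
    b_idx = b.drop_duplicates("variant_id").set_index("variant_id", drop=False)
    shared = sorted(set(a_idx.index) & set(b_idx.index))
    if not shared and not allow_single_source:
        raise MetaError("no shared variants and single-source pass-through disabled")

    rows = []
    for vid in shared:
        ra, rb = a_idx.loc[vid], b_idx.loc[vid]
        hb = harmonize_pair(ra, rb)
        if not hb.usable:
            continue
        wa, wb = 1.0 / ra["se"] ** 2, 1.0 / hb.se_outcome**2
        beta = (ra["beta"] * wa + hb.beta_outcome * wb) / (wa + wb)
        se = (wa + wb) ** -0.5
        row = dict(ra)
        row.update(
            beta=float(beta),
            se=float(se),
            pvalue=float(zscore_to_pvalue(beta / se)),
            source="both",
            heterogeneity_i2=_two_study_i2(
                float(ra["beta"]), float(ra["se"]), hb.beta_outcome, hb.se_outcome
            ),
        )
        for col in ("n", "n_cases", "n_controls"):
            va, vb = ra.get(col), rb.get(col)
            if pd.notna(va) and pd.notna(vb):
                row[col] = float(va) + float(vb)
        rows.append(row)

    if allow_single_source:
        for vid in sorted(set(a_idx.index) - set(b_idx.index)):
            row = dict(a_idx.loc[vid])
            row.update(source="a-only", heterogeneity_i2=np.nan)
            rows.append(row)
        for vid in sorted(set(b_idx.index) - set(a_idx.index)):
            row = dict(b_idx.loc[vid])
            row.update(source="b-only", heterogeneity_i2=np.nan)
            rows.append(row)

    if not rows:
        raise MetaError("meta-analysis produced no variants")
    out = pd.DataFrame(rows).reset_index(drop=True)
    return out.sort_values(["chrom", "pos", "variant_id"], kind="mergesort").reset_index(
        drop=True
    )
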