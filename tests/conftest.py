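import numpy as np
import pandas as pd
import pytest

from vadmr.gwas_io import GeneTarget
from vadmr.synthetic import SimulationConfig, simulate_region


def make_table(rows):
    """Build a canonical summary table from dicts, filling defaults."""
    defaults = dict(
        chrom="1",
        pos=100,
        effect_allele="A",
        other_allele="G",
        eaf=0.3,
        beta=0.1,
        se=0.05,
        pvalue=0.01,
        n=10_000,
    )
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["variant_id"] = f"rs{i + 1}"
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture
def toy_target():
    return GeneTarget(
        symbol="GENE1",
        chrom="1",
        start=1_000_000,
        end=1_050_000,
        drug_class="antihypertensive",
        action_sign=-1,
        biomarkers=("SBP",),
        positive_controls=(("CAD", -1),),
    )


@pytest.fixture
def strong_region():
    """One simulated region with a true causal effect of 0.5."""
    cfg = SimulationConfig(theta=0.5, seed=11)
    exposure, outcome, ld, truth = simulate_region(cfg)
    return exposure, outcome, ld, truth


def ivw_wls_oracle(bx, by, sey):
    """Independent IVW oracle: no-intercept WLS normal equations by hand."""
    bx, by, sey = map(np.asarray, (bx, by, sey))
    w = 1.0 / sey**2
    beta = np.sum(w * bx * by) / np.sum(w * bx**2)
    se = np.sum(w * bx**2) ** -0.5
    return beta, se


def gls_oracle(bx, by, sey, rho):
    """Independent generalized-least-squares oracle via explicit inverse."""
    omega = np.outer(sey, sey) * rho
    oi = np.linalg.inv(omega)
    prec = bx @ oi @ bx
    return float(bx @ oi @ by / prec), float(prec**-0.5)
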