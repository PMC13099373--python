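"""Emit the seeded synthetic toy study used by every downstream step.

Writes the drug-target registry, per-biomarker exposure GWAS, the two
vascular-dementia outcomes (clinical case-control diagnosis and a
quantitative white-matter phenotype), one positive control per drug class,
and the per-region LD matrices, all as TSV/YAML under results/study/.
"""

import argparse
from pathlib import Path

from vadmr import gwas_io
from vadmr.synthetic import simulate_study


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    study = simulate_study(seed=args.seed)
    args.outdir.mkdir(parents=True, exist_ok=True)
    gwas_io.dump_registry(study.registry, args.outdir / "registry.yaml")
    for name, df in study.exposures.items():
        gwas_io.write_summary_stats(df, args.outdir / f"exposure_{name}.tsv")
    for name, df in study.outcomes.items():
        gwas_io.write_summary_stats(df, args.outdir / f"outcome_{name}.tsv")
    for name, df in study.controls.items():
        gwas_io.write_summary_stats(df, args.outdir / f"control_{name}.tsv")
    for chrom, ld in study.ld.items():
        gwas_io.write_ld_matrix(ld, args.outdir / f"ld_chr{chrom}.tsv")

    n_var = sum(len(df) for df in study.exposures.values())
    print(f"seed {args.seed}: {len(study.registry)} targets, {n_var} exposure "
          f"variants, outcomes {list(study.outcomes)}, controls "
          f"{list(study.controls)} -> {args.outdir}")
    for sym, tr in study.truth.items():
        print(f"  {sym}: true effect on VaD (log-odds per unit) = "
              f"{tr['theta_VaD']}, on WMH = {tr['theta_WMH']}")


if __name__ == "__main__":
    main()
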