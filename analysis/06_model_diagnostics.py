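#!/usr/bin/env python
"""Evaluate a fitted model: pcVPC bands, NPDE, goodness-of-fit tables.

Fits the QSS model to the study-like synthetic dataset produced by
01_simulate_cohort.py (regenerating it if absent), then writes the
prediction-corrected VPC band table and plot, the NPDE summary and the
PRED/IPRED goodness-of-fit table.
"""

import json
from pathlib import Path

import numpy as np

from bevpkpd.cli import _plot_vpc
from bevpkpd.cohort import CohortSpec, generate_cohort, simulate_dataset
from bevpkpd.diagnostics import gof_tables, npde, pc_vpc, vpc_coverage
from bevpkpd.io import read_dataset
from bevpkpd.models import qss_reference
from bevpkpd.saem import SAEMConfig, saem_fit_multistart

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 6


def main() -> None:
    OUT.mkdir(exist_ok=True)
    path = OUT / "study_cohort.csv"
    if path.exists():
        dataset = read_dataset(path)
    else:
        cohort = generate_cohort(CohortSpec(), 1)
        dataset, _ = simulate_dataset(cohort, qss_reference(), 2)
        dataset.write(path)

    fit = saem_fit_multistart(dataset, qss_reference(),
                              SAEMConfig(k1=150, k2=50, seed=SEED), n_runs=2)
    v = pc_vpc(dataset, qss_reference(), fit, n_sim=1000, seed=SEED + 1)
    v.table().to_csv(OUT / "vpc_bands.csv", index=False)
    _plot_vpc(v, OUT / "vpc.pdf")
    print(f"pcVPC (1000 simulated datasets, 90% PI): coverage "
          f"{vpc_coverage(v):.2f} of bin-percentiles inside bands")

    r = npde(dataset, qss_reference(), fit, n_sim=1000, seed=SEED + 2)
    summary = {"mean": float(np.mean(r.npde)),
               "var": float(np.var(r.npde, ddof=1)),
               "global_p": r.global_p, "mean_p": r.mean_p,
               "var_p": r.var_p, "normality_p": r.normality_p}
    (OUT / "npde_summary.json").write_text(json.dumps(summary, indent=1))
    print("NPDE:", json.dumps(summary))

    gof = gof_tables(dataset, qss_reference(), fit)
    gof.to_csv(OUT / "gof_table.csv", index=False)
    print(f"GOF table: {len(gof)} observations; "
          f"IWRES mean {gof.IWRES.mean():+.3f}, sd {gof.IWRES.std():.3f}")


if __name__ == "__main__":
    main()
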