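"""Aggregate each cohort's CpG calls into the promoter feature matrix.

Reads the bedMethyl files written by 01 back through the parsers, applies
the coverage filter (>= 5 reads in >= 95% of samples), expands 2 kb TSS
windows, and averages methylation over promoters with >= 10 qualifying CpGs.
Writes per-cohort stage counts to results/aggregation_counts.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import COHORTS, RESULTS, cohort_dir, load_cohort

import promclock as pc


def main() -> None:
    rows = []
    for name in COHORTS:
        d = cohort_dir(name)
        per_sample = {
            p.name.split(".")[0]: pc.read_bedmethyl(p)
            for p in sorted(d.glob("*.bedmethyl.tsv"))
        }
        m0 = pc.build_site_matrix(per_sample)
        m, dropped = pc.filter_cpgs_by_coverage(m0)
        promoters = pc.read_promoters(d / "promoters.tsv")
        windows = pc.assign_sites_to_windows(m, pc.expand_windows(promoters))
        pm = pc.aggregate(m, windows)
        pm.to_frame().to_csv(d / "promoter_matrix.tsv", sep="\t")
        rows.append(
            {
                "cohort": name,
                "sites_read": m0.n_sites,
                "sites_dropped_low_coverage": len(dropped),
                "sites_kept": m.n_sites,
                "promoters_annotated": len(promoters),
                "promoters_with_10plus_cpgs": pm.n_promoters,
                "imputed_cells": int(pm.imputed.sum()),
            }
        )
        print(f"{name}: {m.n_sites} sites -> {pm.n_promoters} promoter features")
    RESULTS.mkdir(exist_ok=True)
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "aggregation_counts.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
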