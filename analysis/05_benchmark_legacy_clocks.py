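"""Benchmark synthetic legacy-clock CpG sets: single CpGs vs nearest promoters.

Builds three synthetic published-clock CpG lists (335 / 816 / 760 sites,
mirroring the three legacy sets), maps each list onto the cohort's CpG sites
(nearest-site substitution) and onto nearest promoters (deduplicated), and
trains one clock per list per representation with a shared split and seed.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import COHORTS, RESULTS, cohort_dir, load_cohort

import promclock as pc
from promclock.simulate import make_clock_lists

SEED = 42


def main() -> None:
    rows = []
    for name in COHORTS:
        m, windows, pm, cov = load_cohort(name)
        catalogue = m.sites.rename(columns={"start": "pos"})
        lists = make_clock_lists(
            catalogue.assign(promoter_id=""), sizes=(335, 816, 760), seed=SEED
        )
        for clock, grp in lists.groupby("clock"):
            cpgs = list(zip(grp["chrom"], grp["pos"]))
            smap = pc.map_to_sites(cpgs, m, clock)
            _, sev = pc.benchmark_clock(smap, m, cov, seed=SEED)
            pmap = pc.map_to_promoters(cpgs, windows, clock)
            _, pev = pc.benchmark_clock(pmap, pm, cov, seed=SEED)
            rows.append(
                {
                    "cohort": name,
                    "clock": clock,
                    "n_cpgs": smap.n_requested,
                    "n_substituted": smap.n_substituted,
                    "n_promoters": len([
                        f for f in pmap.feature_ids() if f in pm.promoter_ids
                    ]),
                    "cpg_r2": round(sev.r2_pearson_sq, 3),
                    "promoter_r2": round(pev.r2_pearson_sq, 3),
                }
            )
            print(f"{name}/{clock}: CpG R^2 = {sev.r2_pearson_sq:.3f}, "
                  f"promoter R^2 = {pev.r2_pearson_sq:.3f}")
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "legacy_benchmarks.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
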