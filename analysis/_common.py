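"""Shared helpers for the analysis drivers: cohort locations and loading."""

from pathlib import Path

import promclock as pc
from promclock.simulate import SimulationConfig, hbcc_like, nabec_like

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"

# two cohorts mirroring the study's designs: one bimodal-age, one unimodal,
# at desk scale (200 promoters, 40 with planted age effects)
COHORTS: dict[str, SimulationConfig] = {
    "bimodal": nabec_like(
        n_promoters=200, n_causal=40, cpgs_per_promoter=(10, 25), seed=101
    ),
    "unimodal": hbcc_like(
        n_promoters=200, n_causal=40, cpgs_per_promoter=(10, 25), seed=202
    ),
}


def cohort_dir(name: str) -> Path:
    return SCRATCH / name


def load_cohort(name: str):
    """Read a simulated cohort back from its on-disk external formats and
    build the promoter feature matrix the way the pipeline would."""
    d = cohort_dir(name)
    per_sample = {
        p.name.split(".")[0]: pc.read_bedmethyl(p)
        for p in sorted(d.glob("*.bedmethyl.tsv"))
    }
    m = pc.build_site_matrix(per_sample)
    cov = pc.read_covariates(d / "covariates.tsv").subset(m.sample_ids)
    promoters = pc.read_promoters(d / "promoters.tsv")
    m, _ = pc.filter_cpgs_by_coverage(m)
    windows = pc.assign_sites_to_windows(m, pc.expand_windows(promoters))
    pm = pc.aggregate(m, windows)
    return m, windows, pm, cov
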