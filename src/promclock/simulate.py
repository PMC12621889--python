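"""Synthetic cohorts with the statistical structure the pipeline assumes.

The real data behind this kind of analysis (postmortem brain cohorts with
nanopore methylation calls) are controlled-access, so the generator emulates
their structure: per-sample bedMethyl files with negative-binomial read
coverage, promoter-level age effects on the logit-methylation scale, sex and
PMI nuisance effects, blocks of correlated promoters (for pruning tests) and
either bimodal or unimodal age distributions, mirroring the two cohorts'
shapes. A GroundTruth manifest records the planted effects for recovery
tests.

The generative model, per sample s and promoter p:

    logit m_sp = b_p + beta_p (age_s - mean age) + g_p sex_s + h_p pmi_z_s + u_sp

with u_sp sharing a block component (correlation ``block_r`` within a block)
and an independent remainder of total SD ``promoter_noise_sd``. Each member
CpG adds site noise of SD ``site_noise_sd``; read coverage is negative
binomial and the modified-read count binomial at the inverse-logit of the
site latent. Only the ``n_causal`` causal promoters have beta_p != 0; they
are drawn N(0, effect_sd^2), in logit units per year.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from promclock.io import (
    CovariateTable,
    CpGRecord,
    CpGSiteMatrix,
    PromoterAnnotation,
    write_bedmethyl,
    write_promoters,
)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class AgeModel:
    """Cohort age distribution: unimodal normal or two-component bimodal mixture,
    truncated to (lo, hi) years."""

    kind: str = "normal"  # "normal" | "bimodal"
    mu: float = 65.0
    sigma: float = 15.0
    mu1: float = 30.0
    mu2: float = 80.0
    sigma_bimodal: float = 5.0
    mix: float = 0.5
    lo: float = 18.0
    hi: float = 100.0


@dataclass
class SimulationConfig:
    n_samples: int = 130
    age_model: AgeModel = field(default_factory=AgeModel)
    n_promoters: int = 500
    cpgs_per_promoter: tuple[int, int] = (10, 40)
    n_causal: int = 25
    effect_sd: float = 0.03  # logit-methylation per year, scale of causal slopes
    promoter_noise_sd: float = 0.5  # per-sample promoter latent noise (logit)
    site_noise_sd: float = 1.5  # per-CpG deviation around the promoter latent
    n_corr_blocks: int = 0
    block_size: int = 5
    block_r: float = 0.95  # latent correlation within a redundancy block
    coverage_mean: float = 30.0
    coverage_dispersion: float = 10.0
    sex_effect_sd: float = 0.1
    pmi_effect_sd: float = 0.05
    # global nuisance factors (cell composition / technical variation): the
    # structure the screen's PC adjustment exists to remove. Eigenvalues are
    # log-spaced over factor_strength (in promoter-variance units x promoters).
    n_factors: int = 25
    factor_strength: tuple[float, float] = (80.0, 15.0)
    pmi_meanlog: float = 3.0  # lognormal PMI, median ~20 h
    pmi_sdlog: float = 0.4
    promoter_spacing: int = 10_000
    seed: int = 42

    def validate(self) -> None:
        if self.n_causal > self.n_promoters:
            raise ValueError("n_causal exceeds n_promoters")
        if not 0 < self.age_model.lo < self.age_model.hi:
            raise ValueError("invalid age truncation bounds")
        if self.age_model.kind == "bimodal" and not 0 < self.age_model.mix < 1:
            raise ValueError("mixture weight must be in (0, 1)")
        for name in ("effect_sd", "promoter_noise_sd", "site_noise_sd",
                     "sex_effect_sd", "pmi_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def nabec_like(**overrides) -> SimulationConfig:
    """Preset mirroring the bimodal-age cohort (n = 187)."""
    cfg = SimulationConfig(
        n_samples=187,
        age_model=AgeModel(kind="bimodal", mu1=30.0, mu2=80.0, sigma_bimodal=5.0, mix=0.5),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def hbcc_like(**overrides) -> SimulationConfig:
    """Preset mirroring the unimodal-age cohort (n = 130)."""
    cfg = SimulationConfig(n_samples=130, age_model=AgeModel(kind="normal", mu=55.0, sigma=18.0))
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort, for recovery tests."""

    causal_effects: dict[str, float]  # promoter_id -> logit slope per year
    block_membership: dict[str, int]  # promoter_id -> block index
    latent: pd.DataFrame  # samples x promoters latent methylation (frequency scale)

    @property
    def causal_ids(self) -> list[str]:
        return list(self.causal_effects)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "causal_effects": self.causal_effects,
            "block_membership": self.block_membership,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def simulate_cohort(config: SimulationConfig, rng: np.random.Generator | None = None) -> CovariateTable:
    """Draw ages, sex and PMI for a cohort.

    Ages come from the configured (truncated) normal or bimodal mixture; sex
    is Bernoulli(0.5); PMI is lognormal in hours.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    am = config.age_model
    ages = np.empty(config.n_samples)
    filled = 0
    while filled < config.n_samples:
        m = config.n_samples - filled
        if am.kind == "bimodal":
            comp = rng.random(m) < am.mix
            draw = np.where(
                comp,
                rng.normal(am.mu1, am.sigma_bimodal, m),
                rng.normal(am.mu2, am.sigma_bimodal, m),
            )
        else:
            draw = rng.normal(am.mu, am.sigma, m)
        keep = draw[(draw > am.lo) & (draw < am.hi)]
        ages[filled : filled + len(keep)] = keep
        filled += len(keep)
    sex = rng.integers(0, 2, config.n_samples)
    pmi = rng.lognormal(config.pmi_meanlog, config.pmi_sdlog, config.n_samples)
    ids = [f"S{i:04d}" for i in range(config.n_samples)]
    data = pd.DataFrame(
        {
            "age": np.round(ages, 1),
            "sex": sex,
            "pmi": np.round(pmi, 1),
            "pmi_imputed": False,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return CovariateTable(data=data, sex_mapping={"F": 0, "M": 1})


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[PromoterAnnotation], pd.DataFrame]:
    """Promoter annotations plus a CpG site catalogue.

    Promoters are spaced ``promoter_spacing`` bp apart on a synthetic
    chromosome so their 2 kb windows are disjoint by default; each promoter's
    CpG count is drawn from ``cpgs_per_promoter`` and its sites placed
    uniformly (without replacement) inside the window.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 1)
    promoters: list[PromoterAnnotation] = []
    rows = []
    lo, hi = config.cpgs_per_promoter
    for i in range(config.n_promoters):
        tss = 5000 + i * config.promoter_spacing
        pid = f"P{i:05d}"
        promoters.append(
            PromoterAnnotation(
                promoter_id=pid,
                gene=f"GENE{i:05d}",
                chrom="chrS",
                tss=tss,
                strand="+" if i % 2 == 0 else "-",
                core_start=tss - 10,
                core_end=tss + 50,
            )
        )
        n_cpg = int(rng.integers(lo, hi + 1))
        positions = np.sort(rng.choice(np.arange(tss - 1000, tss + 1000), n_cpg, replace=False))
        for pos in positions:
            rows.append((pid, "chrS", int(pos)))
    catalogue = pd.DataFrame(rows, columns=["promoter_id", "chrom", "pos"])
    return promoters, catalogue


def _plant_truth(
    config: SimulationConfig,
    promoters: list[PromoterAnnotation],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, dict[str, float], dict[str, int]]:
    """Per-promoter baselines, age/sex/PMI slopes and block membership."""
    n_p = len(promoters)
    baseline = rng.uniform(-2.0, 2.0, n_p)
    # redundancy-block members share one baseline: without it the inverse
    # logit maps the shared latent through different nonlinear regions and
    # the planted correlation attenuates on the frequency scale
    for b in range(config.n_corr_blocks):
        cols = slice(b * config.block_size, (b + 1) * config.block_size)
        baseline[cols] = baseline[b * config.block_size]
    beta = np.zeros(n_p)
    # causal promoters chosen among those outside redundancy blocks
    n_block = config.n_corr_blocks * config.block_size
    eligible = np.arange(n_block, n_p)
    causal_idx = np.sort(rng.choice(eligible, config.n_causal, replace=False))
    # random sign, magnitude banded around effect_sd so every causal promoter
    # has comparable screen power
    sign = rng.choice([-1.0, 1.0], config.n_causal)
    mag = rng.uniform(0.75, 1.25, config.n_causal) * config.effect_sd
    beta[causal_idx] = sign * mag
    g = rng.normal(0.0, config.sex_effect_sd, n_p)
    h = rng.normal(0.0, config.pmi_effect_sd, n_p)
    causal = {promoters[i].promoter_id: float(beta[i]) for i in causal_idx}
    blocks = {
        promoters[b * config.block_size + j].promoter_id: b
        for b in range(config.n_corr_blocks)
        for j in range(config.block_size)
    }
    return baseline, beta, g, h, causal, blocks


def simulate_site_matrix(
    cohort: CovariateTable,
    promoters: list[PromoterAnnotation],
    catalogue: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CpGSiteMatrix, GroundTruth]:
    """Generate read-sampled CpG methylation for a cohort, in memory.

    The returned frequencies carry the bedMethyl format's printed precision
    (percent rounded to 2 decimals), so writing the matrix as bedMethyl and
    reading it back is lossless.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 2)
    ages = cohort.data["age"].to_numpy(dtype=float)
    sex = cohort.data["sex"].to_numpy(dtype=float)
    pmi = cohort.data["pmi"].to_numpy(dtype=float)
    pmi_z = (pmi - pmi.mean()) / (pmi.std() if pmi.std() > 0 else 1.0)
    n_s, n_p = len(ages), len(promoters)
    baseline, beta, g, h, causal, blocks = _plant_truth(config, promoters, rng)

    # promoter latent noise: block-shared component + independent remainder
    noise = rng.normal(0.0, 1.0, (n_s, n_p))
    if config.n_corr_blocks > 0:
        shared = rng.normal(0.0, 1.0, (n_s, config.n_corr_blocks))
        r = np.sqrt(config.block_r)
        for b in range(config.n_corr_blocks):
            cols = slice(b * config.block_size, (b + 1) * config.block_size)
            noise[:, cols] = r * shared[:, [b]] + np.sqrt(1 - config.block_r) * noise[:, cols]
    latent_logit = (
        baseline
        + np.outer(ages - ages.mean(), beta)
        + np.outer(sex, g)
        + np.outer(pmi_z, h)
        + config.promoter_noise_sd * noise
    )
    if config.n_factors > 0:
        eig = np.logspace(
            np.log10(config.factor_strength[0]),
            np.log10(config.factor_strength[1]),
            config.n_factors,
        )
        loadings = rng.normal(0.0, 1.0, (config.n_factors, n_p)) * np.sqrt(
            eig / n_p
        )[:, None]
        factors = rng.normal(0.0, 1.0, (n_s, config.n_factors))
        latent_logit = latent_logit + factors @ loadings

    cat = catalogue.sort_values(["chrom", "pos"]).reset_index(drop=True)
    pid_to_col = {p.promoter_id: j for j, p in enumerate(promoters)}
    site_prom = cat["promoter_id"].map(pid_to_col).to_numpy()
    n_sites = len(cat)
    site_latent = latent_logit[:, site_prom] + rng.normal(
        0.0, config.site_noise_sd, (n_s, n_sites)
    )
    p_mod = _expit(site_latent)
    disp = config.coverage_dispersion
    cov = rng.negative_binomial(
        disp, disp / (disp + config.coverage_mean), (n_s, n_sites)
    )
    n_mod = rng.binomial(cov, p_mod)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.round(100.0 * n_mod / cov, 2)
    freq = np.where(cov > 0, pct / 100.0, np.nan)
    sites = pd.DataFrame(
        {"chrom": cat["chrom"], "start": cat["pos"], "strand": "."}
    )
    m = CpGSiteMatrix(
        sites=sites,
        sample_ids=cohort.sample_ids,
        freq=freq,
        cov=cov.astype(np.int64),
    )
    truth = GroundTruth(
        causal_effects=causal,
        block_membership=blocks,
        latent=pd.DataFrame(
            _expit(latent_logit),
            index=cohort.sample_ids,
            columns=[p.promoter_id for p in promoters],
        ),
    )
    return m, truth


def matrix_to_records(m: CpGSiteMatrix, sample_id: str) -> list[CpGRecord]:
    """One sample's covered sites as bedMethyl-style records."""
    i = m.sample_ids.index(sample_id)
    records = []
    for j in range(m.n_sites):
        c = int(m.cov[i, j])
        if c == 0:
            continue
        pct = float(np.round(m.freq[i, j] * 100.0, 2))
        records.append(
            CpGRecord(
                chrom=str(m.sites["chrom"].iloc[j]),
                start=int(m.sites["start"].iloc[j]),
                strand=str(m.sites["strand"].iloc[j]),
                valid_coverage=c,
                percent_modified=pct,
                n_modified=int(round(pct * c / 100.0)),
            )
        )
    return records


def simulate_methylation(
    cohort: CovariateTable,
    promoters: list[PromoterAnnotation],
    catalogue: pd.DataFrame,
    config: SimulationConfig,
    outdir: str | Path,
    rng: np.random.Generator | None = None,
) -> tuple[list[Path], GroundTruth]:
    """Write one bedMethyl file per sample plus a ground-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m, truth = simulate_site_matrix(cohort, promoters, catalogue, config, rng)
    paths = []
    for sample_id in cohort.sample_ids:
        path = outdir / f"{sample_id}.bedmethyl.tsv"
        write_bedmethyl(matrix_to_records(m, sample_id), path)
        paths.append(path)
    truth.to_json(outdir / "truth.json")
    return paths, truth


def write_cohort_files(
    cohort: CovariateTable,
    promoters: list[PromoterAnnotation],
    outdir: str | Path,
) -> None:
    """Write covariates.tsv and promoters.tsv alongside the bedMethyl files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = cohort.data.reset_index()[["sample_id", "age", "sex", "pmi"]].copy()
    inv = {v: k for k, v in cohort.sex_mapping.items()}
    df["sex"] = df["sex"].map(inv)
    df.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    write_promoters(promoters, outdir / "promoters.tsv")


def make_clock_lists(
    catalogue: pd.DataFrame,
    sizes: tuple[int, ...] = (335, 816, 760),
    seed: int = 42,
    jitter: int = 3,
) -> pd.DataFrame:
    """Synthetic published-clock CpG lists (sizes default to three legacy sets).

    Roughly half of each list's positions are actual catalogued sites and the
    rest fall elsewhere in the simulated genomic span, so some requests
    require nearest-site substitution, as happens when array-designed clocks
    meet long-read data.
    """
    rng = np.random.default_rng(seed)
    chrom = str(catalogue["chrom"].iloc[0])
    span_lo = int(catalogue["pos"].min())
    span_hi = int(catalogue["pos"].max()) + jitter + 1
    rows = []
    for k, size in enumerate(sizes, start=1):
        n_exact = min(size // 2, len(catalogue))
        exact = rng.choice(catalogue["pos"].to_numpy(), n_exact, replace=False)
        off_catalogue = rng.choice(
            np.arange(span_lo, span_hi), size - n_exact, replace=False
        )
        positions = sorted(set(exact.tolist()) | set(off_catalogue.tolist()))
        while len(positions) < size:  # collisions between the two draws
            extra = int(rng.integers(span_lo, span_hi))
            if extra not in positions:
                positions.append(extra)
        for pos in sorted(positions[:size]):
            rows.append((f"clock{k}", chrom, int(pos)))
    return pd.DataFrame(rows, columns=["clock", "chrom", "pos"])


def make_fixture_suite(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Emit the canonical small test fixtures into ``outdir``.

    Contents: a 20-sample / 50-promoter cohort written in every external
    format; a boundary-coverage site matrix (sites covered in 19/20 vs 18/20
    samples at the 5-read minimum); a duplicated-promoter fixture for the
    pruning stage; promoters with exactly 10 vs 9 catalogued CpGs; and three
    synthetic clock CpG lists of sizes 335 / 816 / 760. Regeneration with the
    same seed is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(
        n_samples=20,
        n_promoters=50,
        n_causal=5,
        cpgs_per_promoter=(9, 15),
        n_corr_blocks=2,
        block_size=3,
        block_r=0.99,
        seed=seed,
    )
    cohort = simulate_cohort(cfg)
    promoters, catalogue = simulate_annotation(cfg)
    paths, truth = simulate_methylation(cohort, promoters, catalogue, cfg, outdir / "cohort")
    write_cohort_files(cohort, promoters, outdir / "cohort")
    clocks = make_clock_lists(catalogue, sizes=(335, 816, 760), seed=seed)
    clock_path = outdir / "clock_cpgs.tsv"
    clocks.to_csv(clock_path, sep="\t", index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=1, default=str)
    return {
        "cohort_dir": outdir / "cohort",
        "clock_cpgs": clock_path,
        "truth": outdir / "cohort" / "truth.json",
        "config": outdir / "config.json",
    }
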