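"""End-to-end orchestration: one config, one seed, one run manifest.

``run_all`` executes read -> aggregate -> cascade -> split -> fit ->
evaluate -> attribute -> export and records per-stage input/output counts in
a JSON manifest, so a run can be audited and reproduced bit-for-bit from its
config and seed.
"""

from __future__ import annotations

import glob
import hashlib
import json
import sys
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from promclock.clock import (
    TuningConfig,
    attribute,
    evaluate,
    export_coefficients,
    fit_clock,
    predict,
    save_model,
    split_samples,
)
from promclock.features import (
    aggregate,
    assign_sites_to_windows,
    expand_windows,
    filter_cpgs_by_coverage,
)
from promclock.io import (
    build_site_matrix,
    merge_strands,
    read_bedmethyl,
    read_covariates,
    read_promoters,
)
from promclock.selection import CascadeConfig, run_cascade


def stage_seed(seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed from the run seed."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """All paths and thresholds of a pipeline run (flat YAML on disk)."""

    bedmethyl_glob: str = ""
    promoters: str = ""
    covariates: str = ""
    outdir: str = "promclock_run"
    min_cov: int = 5
    min_frac: float = 0.95
    window: int = 2000
    min_cpgs: int = 10
    batch_size: int = 1000
    r_max: float = 0.9
    alpha: float = 0.05
    k_pcs: int = 20
    train_frac: float = 0.7
    cv_folds: int = 5
    gene_p_max: float = 0.05
    seed: int = 42
    merge_strand_records: bool = True
    leakage_safe: bool = False
    mod_code: str = "m"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys (typo?): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Report configuration problems; 'error:'-prefixed entries block a run."""
    problems: list[str] = []
    if not 0 < config.min_frac <= 1:
        problems.append("error: min_frac proportion out of range (0, 1]")
    if config.min_cov < 1:
        problems.append("error: min_cov must be >= 1")
    if config.window % 2 != 0 or config.window <= 0:
        problems.append("error: window must be a positive even width")
    if config.min_cpgs < 1:
        problems.append("error: min_cpgs must be >= 1")
    if not 0 <= config.r_max:
        problems.append("error: r_max must be >= 0")
    if not 0 < config.alpha <= 1:
        problems.append("error: alpha out of range (0, 1]")
    if not 0 < config.train_frac < 1:
        problems.append("error: train_frac out of range (0, 1)")
    if config.cv_folds < 2:
        problems.append("error: cv_folds must be >= 2")
    if config.k_pcs < 1:
        problems.append("error: k_pcs must be >= 1")
    if config.bedmethyl_glob:
        n = len(glob.glob(config.bedmethyl_glob))
        if n == 0:
            problems.append(f"error: no files match {config.bedmethyl_glob}")
        elif config.k_pcs >= n:
            problems.append(
                f"warning: k_pcs={config.k_pcs} >= {n} samples; k will be reduced"
            )
    for name in ("promoters", "covariates"):
        path = getattr(config, name)
        if path and not Path(path).exists():
            problems.append(f"error: {name} file not found: {path}")
    return problems


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and return (and write) the run manifest."""
    problems = [p for p in validate_config(config) if p.startswith("error")]
    if problems:
        raise ValueError("; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": {},
        "outputs": {},
    }
    t0 = time.time()

    # timings go to the log, not the manifest, so reruns are bit-identical
    def tick(stage: str) -> None:
        _log(f"[{stage}] done at {time.time() - t0:.1f}s")

    try:
        stage = "read"
        per_sample = {}
        for path in sorted(glob.glob(config.bedmethyl_glob)):
            sample_id = Path(path).name.split(".")[0]
            records = read_bedmethyl(path, config.mod_code)
            if config.merge_strand_records:
                records = merge_strands(records)
            per_sample[sample_id] = records
        m = build_site_matrix(per_sample)
        manifest["counts"]["samples"] = m.n_samples
        manifest["counts"]["sites_read"] = m.n_sites
        cov_table = read_covariates(config.covariates)
        missing = set(m.sample_ids) - set(cov_table.sample_ids)
        if missing:
            raise ValueError(f"samples without covariates: {sorted(missing)}")
        cov_table = cov_table.subset(m.sample_ids)
        tick(stage)

        stage = "aggregate"
        m, dropped = filter_cpgs_by_coverage(m, config.min_cov, config.min_frac)
        manifest["counts"]["sites_kept"] = m.n_sites
        promoters = read_promoters(config.promoters)
        windows = expand_windows(promoters, config.window)
        windows = assign_sites_to_windows(m, windows)
        pm = aggregate(m, windows, config.min_cpgs)
        manifest["counts"]["promoters_annotated"] = len(promoters)
        manifest["counts"]["promoters_aggregated"] = pm.n_promoters
        tick(stage)

        stage = "cascade"
        train_ids, test_ids = split_samples(
            pm.sample_ids, config.train_frac, stage_seed(config.seed, "split")
        )
        cascade_cfg = CascadeConfig(
            r_max=config.r_max,
            batch_size=config.batch_size,
            alpha=config.alpha,
            k_pcs=config.k_pcs,
        )
        selected, report = run_cascade(
            pm,
            cov_table,
            cascade_cfg,
            fit_sample_ids=train_ids if config.leakage_safe else None,
        )
        pruned = report.table[(report.table["stage"] == "prune") & (~report.table["kept"])]
        manifest["counts"]["promoters_after_prune"] = pm.n_promoters - len(pruned)
        manifest["counts"]["promoters_after_screen"] = selected.n_promoters
        report_path = outdir / "selection_report.tsv"
        report.table.to_csv(report_path, sep="\t", index=False)
        manifest["outputs"]["selection_report"] = str(report_path)
        tick(stage)

        stage = "fit"
        sel_train = selected.subset_samples(train_ids)
        tuning = TuningConfig(cv_folds=config.cv_folds)
        model = fit_clock(
            sel_train,
            cov_table.subset(train_ids),
            tuning=tuning,
            seed=stage_seed(config.seed, "cv"),
            train_frac=config.train_frac,
        )
        manifest["counts"]["features_contributing"] = len(model.contributing_features())
        model_path = outdir / "clock_model.json"
        save_model(model, model_path)
        manifest["outputs"]["model"] = str(model_path)
        tick(stage)

        stage = "evaluate"
        sel_test = selected.subset_samples(test_ids)
        preds = predict(model, sel_test, cov_table.subset(test_ids))
        ev = evaluate(preds, cov_table.data.loc[test_ids, "age"])
        manifest["metrics"] = {
            "r2_pearson_sq": ev.r2_pearson_sq,
            "r2_cod": ev.r2_cod,
            "mae_years": ev.mae,
        }
        scatter_path = outdir / "predictions.tsv"
        ev.predictions.to_csv(scatter_path, sep="\t")
        manifest["outputs"]["predictions"] = str(scatter_path)
        tick(stage)

        stage = "attribute"
        imp = attribute(model, sel_test, cov_table.subset(test_ids))
        imp_path = outdir / "importance.tsv"
        imp.mean_abs.rename("mean_abs_attribution_years").to_csv(imp_path, sep="\t")
        manifest["outputs"]["importance"] = str(imp_path)
        tick(stage)

        stage = "export"
        coef_path = outdir / "coefficients.tsv"
        export_coefficients(model, coef_path)
        manifest["outputs"]["coefficients"] = str(coef_path)
        tick(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    _log(
        "run complete: "
        + ", ".join(f"{k}={v}" for k, v in manifest["counts"].items())
    )
    return manifest
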