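"""Legacy-clock benchmarks on long-read data.

Published clock CpG sets rarely coincide exactly with the CpGs captured by a
long-read dataset. Two mappings make them usable:

* **site-level** — each requested CpG is matched to itself when present,
  otherwise to the nearest CpG on the same chromosome (lower coordinate wins
  ties); duplicate matches collapse to one feature.
* **promoter-level** — each requested CpG is assigned the promoter whose TSS
  is nearest (distance 0 when the CpG lies inside the window); promoters
  shared by several clock CpGs enter the model once.

``benchmark_clock`` then restricts the feature matrix to the mapped features
and delegates to the ordinary clock-fitting path with the same split and
seed, so site-level and promoter-level benchmarks are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from promclock.clock import (
    ClockModel,
    EvaluationReport,
    TuningConfig,
    design_frame,
    evaluate,
    fit_clock,
    predict,
    split_samples,
)
from promclock.features import PromoterMatrix, PromoterWindow
from promclock.io import CovariateTable, CpGSiteMatrix


@dataclass
class MappingEntry:
    chrom: str
    pos: int
    matched: str | None  # feature id, or None if unmappable
    distance: int = 0
    substituted: bool = False


@dataclass
class ClockMapping:
    """Resolution of a published clock's CpG list onto available features."""

    clock_name: str
    entries: list[MappingEntry] = field(default_factory=list)

    @property
    def n_requested(self) -> int:
        return len(self.entries)

    @property
    def n_exact(self) -> int:
        return sum(1 for e in self.entries if e.matched is not None and not e.substituted)

    @property
    def n_substituted(self) -> int:
        return sum(1 for e in self.entries if e.matched is not None and e.substituted)

    @property
    def n_unmappable(self) -> int:
        return sum(1 for e in self.entries if e.matched is None)

    def feature_ids(self) -> list[str]:
        """Deduplicated mapped feature ids in first-seen order."""
        seen: set[str] = set()
        out: list[str] = []
        for e in self.entries:
            if e.matched is not None and e.matched not in seen:
                seen.add(e.matched)
                out.append(e.matched)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [e.chrom for e in self.entries],
                "pos": [e.pos for e in self.entries],
                "matched": [e.matched for e in self.entries],
                "distance": [e.distance for e in self.entries],
                "substituted": [e.substituted for e in self.entries],
            }
        )


def _nearest(pos: int, candidates: np.ndarray) -> tuple[int, int]:
    """Index and distance of the nearest candidate; lower coordinate wins ties."""
    d = np.abs(candidates - pos)
    best = int(np.argmin(d))  # argmin returns the first (lowest-coordinate) tie
    return best, int(d[best])


def map_to_sites(
    clock_cpgs: Sequence[tuple[str, int]], m: CpGSiteMatrix, clock_name: str = "clock"
) -> ClockMapping:
    """Match clock CpG positions to dataset CpG sites, nearest-site substitution.

    Exact positions match themselves (distance 0); absent positions take the
    nearest same-chromosome site (absolute distance, lower coordinate on
    ties). Requests on chromosomes absent from the dataset are unmappable.
    """
    chroms = m.sites["chrom"].to_numpy()
    starts = m.sites["start"].to_numpy()
    by_chrom = {c: starts[chroms == c] for c in np.unique(chroms)}
    mapping = ClockMapping(clock_name=clock_name)
    for chrom, pos in clock_cpgs:
        sites = by_chrom.get(chrom)
        if sites is None or len(sites) == 0:
            mapping.entries.append(MappingEntry(chrom, pos, None))
            continue
        i, dist = _nearest(pos, sites)
        mapping.entries.append(
            MappingEntry(
                chrom,
                pos,
                matched=f"{chrom}:{sites[i]}",
                distance=dist,
                substituted=dist > 0,
            )
        )
    return mapping


def map_to_promoters(
    clock_cpgs: Sequence[tuple[str, int]],
    windows: Sequence[PromoterWindow],
    clock_name: str = "clock",
) -> ClockMapping:
    """Assign each clock CpG its nearest promoter (by distance to the TSS).

    Distance is recorded as 0 when the CpG lies inside the promoter's window.
    Promoters shared by several clock CpGs appear once in ``feature_ids()``.
    """
    by_chrom: dict[str, list[PromoterWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    tss_arrays = {
        c: np.array([w.tss for w in ws]) for c, ws in by_chrom.items()
    }
    mapping = ClockMapping(clock_name=clock_name)
    for chrom, pos in clock_cpgs:
        ws = by_chrom.get(chrom)
        if not ws:
            mapping.entries.append(MappingEntry(chrom, pos, None))
            continue
        i, dist = _nearest(pos, tss_arrays[chrom])
        w = ws[i]
        inside = w.window_start <= pos < w.window_end
        mapping.entries.append(
            MappingEntry(
                chrom,
                pos,
                matched=w.promoter_id,
                distance=0 if inside else dist,
                substituted=not inside,
            )
        )
    return mapping


def site_matrix_features(m: CpGSiteMatrix, feature_ids: Sequence[str]) -> PromoterMatrix:
    """View selected CpG sites as a feature matrix usable by the clock.

    Feature ids are "chrom:start" strings; uncovered cells are imputed with
    the site's cohort mean so the penalized fit sees a complete matrix.
    """
    key = [f"{c}:{s}" for c, s in zip(m.sites["chrom"], m.sites["start"])]
    index = {k: j for j, k in enumerate(key)}
    cols = [index[f] for f in feature_ids]
    values = m.freq[:, cols].copy()
    imputed = np.isnan(values)
    if imputed.any():
        col_means = np.nanmean(values, axis=0)
        values[imputed] = np.take(col_means, np.where(imputed)[1])
    return PromoterMatrix(
        promoter_ids=list(feature_ids),
        sample_ids=list(m.sample_ids),
        values=values,
        n_cpgs=np.ones(len(cols), dtype=int),
        genes=[""] * len(cols),
        imputed=imputed,
    )


def benchmark_clock(
    mapping: ClockMapping,
    features: PromoterMatrix | CpGSiteMatrix,
    cov: CovariateTable,
    seed: int = 42,
    train_frac: float = 0.7,
    tuning: TuningConfig | None = None,
) -> tuple[ClockModel, EvaluationReport]:
    """Train and evaluate a clock restricted to a mapping's features.

    Uses the same seeded split and tuning path as the unrestricted clock so
    site-level and promoter-level benchmarks are directly comparable.
    """
    ids = mapping.feature_ids()
    if not ids:
        raise ValueError(f"mapping {mapping.clock_name} resolved no features")
    if isinstance(features, CpGSiteMatrix):
        pm = site_matrix_features(features, ids)
    else:
        present = [f for f in ids if f in features.promoter_ids]
        if not present:
            raise ValueError(
                f"mapping {mapping.clock_name}: no mapped promoter in the matrix"
            )
        pm = features.subset_promoters(present)
    train_ids, test_ids = split_samples(pm.sample_ids, train_frac, seed)
    idx_tr = [pm.sample_ids.index(s) for s in train_ids]
    idx_te = [pm.sample_ids.index(s) for s in test_ids]
    pm_tr = PromoterMatrix(
        promoter_ids=list(pm.promoter_ids),
        sample_ids=train_ids,
        values=pm.values[idx_tr],
        n_cpgs=pm.n_cpgs,
        genes=list(pm.genes),
    )
    pm_te = PromoterMatrix(
        promoter_ids=list(pm.promoter_ids),
        sample_ids=test_ids,
        values=pm.values[idx_te],
        n_cpgs=pm.n_cpgs,
        genes=list(pm.genes),
    )
    model = fit_clock(pm_tr, cov.subset(train_ids), tuning=tuning, seed=seed,
                      train_frac=train_frac)
    preds = predict(model, pm_te, cov.subset(test_ids))
    report = evaluate(preds, cov.data.loc[test_ids, "age"])
    return model, report
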