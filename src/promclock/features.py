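"""CpG-level data to the promoter-level feature matrix.

The feature space of the clock is the mean methylation frequency over the
CpGs inside a 2 kb window centered on each promoter's TSS. Sites must be
covered by at least ``min_cov`` reads in at least ``min_frac`` of samples to
count, and a promoter must retain at least ``min_cpgs`` qualifying CpGs to
become a feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from promclock.io import CpGSiteMatrix, PromoterAnnotation


@dataclass
class PromoterWindow:
    """A promoter with its expanded window and member CpG site indices."""

    promoter_id: str
    gene: str
    chrom: str
    tss: int
    strand: str
    window_start: int
    window_end: int
    clipped: bool = False
    member_sites: list[int] = field(default_factory=list)


@dataclass
class PromoterMatrix:
    """Samples x promoters mean-methylation matrix (the clock's feature space).

    ``values`` lie in [0, 1]; cells where a sample covered no member CpG are
    imputed with the promoter's cohort mean and flagged in ``imputed``.
    ``n_cpgs`` counts member CpGs per retained promoter.
    """

    promoter_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    n_cpgs: np.ndarray
    genes: list[str] = field(default_factory=list)
    imputed: np.ndarray | None = None
    order: pd.DataFrame | None = None  # chrom/window_start per promoter, genomic order

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_promoters(self) -> int:
        return len(self.promoter_ids)

    def subset_promoters(self, keep: list[str]) -> "PromoterMatrix":
        idx = [self.promoter_ids.index(p) for p in keep]
        return PromoterMatrix(
            promoter_ids=list(keep),
            sample_ids=list(self.sample_ids),
            values=self.values[:, idx].copy(),
            n_cpgs=self.n_cpgs[idx].copy(),
            genes=[self.genes[i] for i in idx] if self.genes else [],
            imputed=self.imputed[:, idx].copy() if self.imputed is not None else None,
            order=self.order.iloc[idx].reset_index(drop=True) if self.order is not None else None,
        )

    def subset_samples(self, sample_ids: list[str]) -> "PromoterMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return PromoterMatrix(
            promoter_ids=list(self.promoter_ids),
            sample_ids=list(sample_ids),
            values=self.values[idx].copy(),
            n_cpgs=self.n_cpgs.copy(),
            genes=list(self.genes),
            imputed=self.imputed[idx].copy() if self.imputed is not None else None,
            order=self.order,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.promoter_ids)


def expand_windows(
    promoters: list[PromoterAnnotation], width: int = 2000
) -> list[PromoterWindow]:
    """Expand each promoter to a ``width`` bp window centered on its TSS.

    The window is [tss - width/2, tss + width/2), clipped at coordinate 0
    (``clipped`` flag set). Strand does not alter the interval: the window is
    symmetric about the TSS.
    """
    if width % 2 != 0:
        raise ValueError("window width must be even")
    half = width // 2
    out = []
    for p in promoters:
        start = p.tss - half
        clipped = start < 0
        out.append(
            PromoterWindow(
                promoter_id=p.promoter_id,
                gene=p.gene,
                chrom=p.chrom,
                tss=p.tss,
                strand=p.strand,
                window_start=max(start, 0),
                window_end=p.tss + half,
                clipped=clipped,
            )
        )
    out.sort(key=lambda w: (w.chrom, w.window_start))
    return out


def filter_cpgs_by_coverage(
    m: CpGSiteMatrix, min_cov: int = 5, min_frac: float = 0.95
) -> tuple[CpGSiteMatrix, pd.DataFrame]:
    """Drop CpG sites not covered by >= ``min_cov`` reads in >= ``min_frac`` of samples.

    The comparison is inclusive on the exact fraction: a site covered in
    exactly ``min_frac`` of samples is kept. Returns the filtered matrix and
    a report of dropped sites with their passing fractions.
    """
    if m.n_samples == 0:
        raise ValueError("matrix has zero samples")
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    frac = (m.cov >= min_cov).mean(axis=0)
    keep = frac >= min_frac
    dropped = m.sites.loc[~keep].assign(passing_fraction=frac[~keep]).reset_index(drop=True)
    return m.subset_sites(np.flatnonzero(keep)), dropped


def assign_sites_to_windows(
    m: CpGSiteMatrix, windows: list[PromoterWindow]
) -> list[PromoterWindow]:
    """Record which site indices fall inside each window (half-open intervals).

    A site belongs to a window iff it is on the same chromosome and
    window_start <= start < window_end. A site inside two overlapping windows
    belongs to both. The site matrix is not mutated.
    """
    starts = m.sites["start"].to_numpy()
    chroms = m.sites["chrom"].to_numpy()
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in np.unique(chroms):
        by_chrom[chrom] = np.flatnonzero(chroms == chrom)
    for w in windows:
        idx = by_chrom.get(w.chrom)
        if idx is None:
            w.member_sites = []
            continue
        pos = starts[idx]
        lo = np.searchsorted(pos, w.window_start, side="left")
        hi = np.searchsorted(pos, w.window_end, side="left")
        w.member_sites = idx[lo:hi].tolist()
    return windows


def aggregate(
    m: CpGSiteMatrix, windows: list[PromoterWindow], min_cpgs: int = 10
) -> PromoterMatrix:
    """Average methylation over each window's member CpGs.

    A promoter is retained iff it has >= ``min_cpgs`` member sites (counted
    after coverage filtering, i.e. among sites present in ``m``). Each cell is
    the unweighted mean of the sample's frequencies over member sites with
    cov > 0; a sample covering no member site receives the promoter's cohort
    mean, flagged imputed.
    """
    if min_cpgs < 1:
        raise ValueError("min_cpgs must be >= 1")
    kept = [w for w in windows if len(w.member_sites) >= min_cpgs]
    if not kept:
        raise ValueError(
            "no promoter has enough CpG sites after filtering; "
            "review min_cpgs / coverage thresholds"
        )
    n = m.n_samples
    values = np.empty((n, len(kept)))
    imputed = np.zeros((n, len(kept)), dtype=bool)
    for j, w in enumerate(kept):
        sub = m.freq[:, w.member_sites]
        with np.errstate(invalid="ignore"):
            col = np.nanmean(sub, axis=1)
        missing = np.isnan(col)
        if missing.any():
            if missing.all():
                raise ValueError(
                    f"promoter {w.promoter_id}: no sample covers any member site"
                )
            col[missing] = col[~missing].mean()
            imputed[missing, j] = True
        values[:, j] = col
    return PromoterMatrix(
        promoter_ids=[w.promoter_id for w in kept],
        sample_ids=list(m.sample_ids),
        values=values,
        n_cpgs=np.array([len(w.member_sites) for w in kept]),
        genes=[w.gene for w in kept],
        imputed=imputed,
        order=pd.DataFrame(
            {
                "chrom": [w.chrom for w in kept],
                "window_start": [w.window_start for w in kept],
            }
        ),
    )
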