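"""Readers and writers for every external format the pipeline touches.

Formats handled here:

* **bedMethyl** (modkit ``pileup`` tab-separated dialect) — per-CpG modified
  base calls with valid coverage, percent modified and modified-read count.
* **Promoter annotations** — EPD-style TSV (promoter id, gene symbol,
  chromosome, TSS, strand, optional 60 bp core interval).
* **Covariate tables** — sample id, age (years), sex, PMI (hours).
* **Clock CpG lists** — published-clock CpG coordinates, one row per CpG.
* **Site-matrix persistence** — TSV matrices plus a JSON metadata sidecar.

All genomic coordinates are 0-based, half-open (BED convention).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclass(frozen=True)
class CpGRecord:
    """One CpG site in one sample, as reported by modkit pileup.

    ``percent_modified`` is on the 0–100 scale as printed in the file;
    downstream matrices convert to a [0, 1] frequency.
    """

    chrom: str
    start: int
    strand: str  # "+", "-" or "." (strand-combined)
    valid_coverage: int
    percent_modified: float
    n_modified: int

    @property
    def end(self) -> int:
        return self.start + 1

    def validate(self) -> None:
        if not (0.0 <= self.percent_modified <= 100.0):
            raise ValueError(
                f"percent_modified {self.percent_modified} out of [0, 100] "
                f"at {self.chrom}:{self.start}"
            )
        if self.n_modified > self.valid_coverage:
            raise ValueError(
                f"n_modified {self.n_modified} exceeds coverage "
                f"{self.valid_coverage} at {self.chrom}:{self.start}"
            )
        if self.valid_coverage > 0:
            implied = 100.0 * self.n_modified / self.valid_coverage
            if abs(self.percent_modified - implied) >= 0.5:
                raise ValueError(
                    f"percent_modified {self.percent_modified} inconsistent with "
                    f"{self.n_modified}/{self.valid_coverage} at "
                    f"{self.chrom}:{self.start}"
                )


@dataclass
class CpGSiteMatrix:
    """Samples x CpG-sites methylation frequencies with a parallel coverage matrix.

    ``freq`` holds methylation frequency in [0, 1]; a cell is NaN exactly where
    the corresponding ``cov`` cell is 0 (site not observed in that sample).
    ``sites`` has columns ``chrom``, ``start``, ``strand`` and is sorted by
    (chrom, start).
    """

    sites: pd.DataFrame
    sample_ids: list[str]
    freq: np.ndarray
    cov: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def validate(self) -> None:
        if self.freq.shape != self.cov.shape:
            raise ValueError("freq and cov shapes differ")
        if self.freq.shape != (self.n_samples, self.n_sites):
            raise ValueError("matrix shape does not match sample/site lists")
        uncovered = self.cov == 0
        if not np.all(np.isnan(self.freq[uncovered])):
            raise ValueError("freq must be NaN wherever cov == 0")
        if np.any(np.isnan(self.freq[~uncovered])):
            raise ValueError("freq must be present wherever cov > 0")
        key = self.sites[["chrom", "start"]].apply(tuple, axis=1).tolist()
        if key != sorted(key):
            raise ValueError("sites must be sorted by (chrom, start)")

    def subset_sites(self, index: np.ndarray) -> "CpGSiteMatrix":
        return CpGSiteMatrix(
            sites=self.sites.iloc[index].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
            freq=self.freq[:, index].copy(),
            cov=self.cov[:, index].copy(),
        )


@dataclass
class CovariateTable:
    """Per-sample covariates: age (years), sex (0/1) and PMI (hours).

    ``sex_mapping`` records how the original labels map onto {0, 1};
    ``pmi_imputed`` flags samples whose missing PMI was replaced by the
    cohort median.
    """

    data: pd.DataFrame  # index sample_id; columns age, sex, pmi, pmi_imputed
    sex_mapping: dict[str, int] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def validate(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if not np.isfinite(self.data["age"]).all():
            raise ValueError("ages must be finite")

    def subset(self, sample_ids: Sequence[str]) -> "CovariateTable":
        return CovariateTable(self.data.loc[list(sample_ids)].copy(), dict(self.sex_mapping))


@dataclass(frozen=True)
class PromoterAnnotation:
    """An EPD-style promoter: id, gene symbol, TSS position and strand."""

    promoter_id: str
    gene: str
    chrom: str
    tss: int
    strand: str
    core_start: int | None = None
    core_end: int | None = None

    def validate(self) -> None:
        if self.core_start is not None and self.core_end is not None:
            if self.core_end - self.core_start != 60:
                raise ValueError(
                    f"core interval of {self.promoter_id} is not 60 bp"
                )


# Column indices of the modkit pileup tab-separated block (0-based).
_BM_CHROM, _BM_START, _BM_END, _BM_CODE, _BM_SCORE, _BM_STRAND = range(6)
_BM_VALID_COV, _BM_PCT_MOD, _BM_N_MOD = 9, 10, 11
_BM_MIN_COLS = 12


def read_bedmethyl(path: str | Path, mod_code_filter: str = "m") -> list[CpGRecord]:
    """Read a modkit-pileup bedMethyl file, keeping one modification code.

    Parameters
    ----------
    path
        Tab-separated bedMethyl file (>= 12 columns in the modkit layout:
        chrom, start, end, mod code, score, strand, thickStart, thickEnd,
        color, valid coverage, percent modified, count modified, ...).
    mod_code_filter
        Modification code to retain; ``"m"`` (5mC) by default.

    Returns
    -------
    Records matching the code, sorted by (chrom, start). Malformed lines
    raise :class:`FormatError` naming the line number.
    """
    records: list[CpGRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _BM_MIN_COLS:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {_BM_MIN_COLS} tab-separated "
                    f"columns (modkit pileup layout), found {len(fields)}; "
                    "missing valid-coverage / percent-modified / count-modified block"
                )
            if fields[_BM_CODE] != mod_code_filter:
                continue
            try:
                start = int(fields[_BM_START])
                cov = int(fields[_BM_VALID_COV])
                pct = float(fields[_BM_PCT_MOD])
                n_mod = int(fields[_BM_N_MOD])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            rec = CpGRecord(
                chrom=fields[_BM_CHROM],
                start=start,
                strand=fields[_BM_STRAND],
                valid_coverage=cov,
                percent_modified=pct,
                n_modified=n_mod,
            )
            try:
                rec.validate()
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    records.sort(key=lambda r: (r.chrom, r.start))
    return records


def write_bedmethyl(records: Iterable[CpGRecord], path: str | Path) -> None:
    """Write records in the modkit pileup dialect that :func:`read_bedmethyl` reads."""
    with open(path, "w") as fh:
        for r in records:
            n_unmod = r.valid_coverage - r.n_modified
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.start),
                        str(r.start + 1),
                        "m",
                        str(min(r.valid_coverage, 1000)),
                        r.strand,
                        str(r.start),
                        str(r.start + 1),
                        "255,0,0",
                        str(r.valid_coverage),
                        f"{r.percent_modified:.2f}",
                        str(r.n_modified),
                        str(n_unmod),
                        "0", "0", "0", "0", "0",
                    ]
                )
                + "\n"
            )


def merge_strands(records: Sequence[CpGRecord]) -> list[CpGRecord]:
    """Combine per-strand records at a CpG dinucleotide into one record.

    A ``+`` record at position p paired with a ``-`` record at p+1 (same
    chromosome) is replaced by a single strand-``.`` record at p with summed
    coverage and modified counts and a recomputed percentage. Unpaired
    records pass through unchanged. Total coverage and total modified count
    are conserved.
    """
    out: list[CpGRecord] = []
    i = 0
    n = len(records)
    while i < n:
        r = records[i]
        if (
            r.strand == "+"
            and i + 1 < n
            and records[i + 1].strand == "-"
            and records[i + 1].chrom == r.chrom
            and records[i + 1].start == r.start + 1
        ):
            mate = records[i + 1]
            cov = r.valid_coverage + mate.valid_coverage
            n_mod = r.n_modified + mate.n_modified
            pct = 100.0 * n_mod / cov if cov > 0 else 0.0
            out.append(
                CpGRecord(
                    chrom=r.chrom,
                    start=r.start,
                    strand=".",
                    valid_coverage=cov,
                    percent_modified=pct,
                    n_modified=n_mod,
                )
            )
            i += 2
        else:
            out.append(r)
            i += 1
    return out


def build_site_matrix(
    per_sample_records: Mapping[str, Sequence[CpGRecord]]
) -> CpGSiteMatrix:
    """Assemble per-sample CpG records into a samples x sites matrix.

    The site universe is the union over samples of (chrom, start). Cells are
    methylation frequency (percent / 100) where the sample covers the site and
    NaN (with cov 0) where it does not.
    """
    if not per_sample_records:
        raise ValueError("at least one sample required")
    site_set: dict[tuple[str, int], str] = {}
    for sample_id, records in per_sample_records.items():
        seen: set[tuple[str, int]] = set()
        for r in records:
            key = (r.chrom, r.start)
            if key in seen:
                raise ValueError(
                    f"duplicate site {r.chrom}:{r.start} in sample {sample_id}"
                )
            seen.add(key)
            site_set.setdefault(key, r.strand)
    ordered = sorted(site_set)
    index = {key: j for j, key in enumerate(ordered)}
    sample_ids = list(per_sample_records)
    freq = np.full((len(sample_ids), len(ordered)), np.nan)
    cov = np.zeros((len(sample_ids), len(ordered)), dtype=np.int64)
    for i, sample_id in enumerate(sample_ids):
        for r in per_sample_records[sample_id]:
            j = index[(r.chrom, r.start)]
            cov[i, j] = r.valid_coverage
            freq[i, j] = r.percent_modified / 100.0 if r.valid_coverage > 0 else np.nan
    sites = pd.DataFrame(
        {
            "chrom": [c for c, _ in ordered],
            "start": [s for _, s in ordered],
            "strand": [site_set[key] for key in ordered],
        }
    )
    m = CpGSiteMatrix(sites=sites, sample_ids=sample_ids, freq=freq, cov=cov)
    m.validate()
    return m


def read_promoters(path: str | Path) -> list[PromoterAnnotation]:
    """Read an EPD-style promoter annotation TSV.

    Required columns: ``promoter_id``, ``gene``, ``chrom``, ``tss``,
    ``strand``; optional ``core_start`` / ``core_end`` (60 bp core).
    Output is sorted by (chrom, tss); duplicate promoter ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"promoter_id", "gene", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"promoter file missing columns: {sorted(missing)}")
    if df["promoter_id"].duplicated().any():
        dups = df.loc[df["promoter_id"].duplicated(), "promoter_id"].tolist()
        raise ValueError(f"duplicate promoter ids: {dups}")
    has_core = {"core_start", "core_end"} <= set(df.columns)
    out: list[PromoterAnnotation] = []
    for row in df.itertuples(index=False):
        tss = int(row.tss)
        if tss < 1000:
            warnings.warn(
                f"promoter {row.promoter_id} TSS {tss} < 1000; 2 kb window will "
                "be clipped at 0",
                stacklevel=2,
            )
        ann = PromoterAnnotation(
            promoter_id=str(row.promoter_id),
            gene=str(row.gene),
            chrom=str(row.chrom),
            tss=tss,
            strand=str(row.strand),
            core_start=int(row.core_start) if has_core and pd.notna(row.core_start) else None,
            core_end=int(row.core_end) if has_core and pd.notna(row.core_end) else None,
        )
        ann.validate()
        out.append(ann)
    out.sort(key=lambda a: (a.chrom, a.tss))
    return out


def write_promoters(promoters: Sequence[PromoterAnnotation], path: str | Path) -> None:
    rows = [
        {
            "promoter_id": p.promoter_id,
            "gene": p.gene,
            "chrom": p.chrom,
            "tss": p.tss,
            "strand": p.strand,
            "core_start": p.core_start if p.core_start is not None else "",
            "core_end": p.core_end if p.core_end is not None else "",
        }
        for p in promoters
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> CovariateTable:
    """Read a covariate table (sample_id, age, sex, pmi).

    Sex labels are mapped to {0, 1} in sorted label order and the mapping is
    recorded. Missing PMI is imputed with the cohort median and flagged;
    missing age is a hard error (age is the outcome).
    """
    sep = "\t" if str(path).endswith((".tsv", ".bed")) else None
    df = pd.read_csv(path, sep=sep, engine="python")
    required = {"sample_id", "age", "sex", "pmi"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"covariate file missing columns: {sorted(missing)}")
    if df["age"].isna().any():
        bad = df.loc[df["age"].isna(), "sample_id"].tolist()
        raise ValueError(f"missing age for samples: {bad}")
    labels = sorted(df["sex"].astype(str).unique())
    if len(labels) > 2:
        raise ValueError(f"more than two sex labels: {labels}")
    mapping = {label: code for code, label in enumerate(labels)}
    sex = df["sex"].astype(str).map(mapping)
    pmi = pd.to_numeric(df["pmi"], errors="coerce")
    pmi_imputed = pmi.isna()
    if pmi_imputed.any():
        if pmi_imputed.all():
            raise ValueError("all PMI values missing; cannot impute median")
        pmi = pmi.fillna(pmi.median())
    data = pd.DataFrame(
        {
            "age": df["age"].astype(float).values,
            "sex": sex.values,
            "pmi": pmi.values,
            "pmi_imputed": pmi_imputed.values,
        },
        index=pd.Index(df["sample_id"].astype(str), name="sample_id"),
    )
    table = CovariateTable(data=data, sex_mapping=mapping)
    table.validate()
    return table


def read_clock_cpgs(path: str | Path) -> dict[str, list[tuple[str, int]]]:
    """Read a clock-CpG list TSV with columns ``clock``, ``chrom``, ``pos``.

    Returns positions grouped by clock label, deduplicated and sorted.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"clock", "chrom", "pos"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"clock CpG file missing columns: {sorted(missing)}")
    if len(df) == 0:
        warnings.warn(f"clock CpG file {path} is empty", stacklevel=2)
        return {}
    try:
        positions = df["pos"].astype(int)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-integer position in {path}: {exc}") from exc
    df = df.assign(pos=positions)
    out: dict[str, list[tuple[str, int]]] = {}
    for clock, grp in df.groupby("clock", sort=True):
        pairs = sorted(set(zip(grp["chrom"], grp["pos"])))
        out[str(clock)] = pairs
    return out


def write_site_matrix(m: CpGSiteMatrix, prefix: str | Path) -> None:
    """Persist a site matrix as ``<prefix>.freq.tsv``, ``<prefix>.cov.tsv`` and
    a ``<prefix>.json`` sidecar with site and sample metadata."""
    prefix = Path(prefix)
    cols = [f"{c}:{s}" for c, s in zip(m.sites["chrom"], m.sites["start"])]
    pd.DataFrame(m.freq, index=m.sample_ids, columns=cols).to_csv(
        str(prefix) + ".freq.tsv", sep="\t", float_format="%.17g"
    )
    pd.DataFrame(m.cov, index=m.sample_ids, columns=cols).to_csv(
        str(prefix) + ".cov.tsv", sep="\t"
    )
    meta = {
        "sample_ids": m.sample_ids,
        "sites": [
            {"chrom": c, "start": int(s), "strand": st}
            for c, s, st in zip(m.sites["chrom"], m.sites["start"], m.sites["strand"])
        ],
    }
    with open(str(prefix) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_site_matrix(prefix: str | Path) -> CpGSiteMatrix:
    """Read a site matrix written by :func:`write_site_matrix` (lossless)."""
    prefix = Path(prefix)
    with open(str(prefix) + ".json") as fh:
        meta = json.load(fh)
    freq = pd.read_csv(
        str(prefix) + ".freq.tsv", sep="\t", index_col=0,
        float_precision="round_trip",
    )
    cov = pd.read_csv(str(prefix) + ".cov.tsv", sep="\t", index_col=0)
    sites = pd.DataFrame(meta["sites"])
    m = CpGSiteMatrix(
        sites=sites,
        sample_ids=[str(s) for s in meta["sample_ids"]],
        freq=freq.to_numpy(dtype=float),
        cov=cov.to_numpy(dtype=np.int64),
    )
    m.validate()
    return m
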