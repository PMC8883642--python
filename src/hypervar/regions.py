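"""Genomic region handling and tabular matrix I/O.

Regions use the BED convention throughout: 0-based, half-open
``[start, end)`` coordinates.  A :class:`RegionSet` is an ordered,
de-duplicated list of intervals, optionally stratified into promoter-proximal
and distal regions by distance to the nearest transcription start site (TSS).
Count and occupancy matrices are plain region x sample tables whose row ids
are ``"chrom:start-end"`` strings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROXIMAL = "proximal"
DISTAL = "distal"
UNASSIGNED = "unassigned"

_SEX_CHROMS = {"x", "y"}


class BedParseError(ValueError):
    """Raised for malformed BED input (names the offending line)."""


class MatrixFormatError(ValueError):
    """Raised for malformed count/occupancy tables."""


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class RegionSet:
    """Sorted, de-duplicated collection of regions with stratum labels."""

    regions: list[GenomicRegion]
    stratum: list[str] = field(default_factory=list)

    def __post_init__(self):
        order = sorted(
            range(len(self.regions)),
            key=lambda i: (
                self.regions[i].chrom,
                self.regions[i].start,
                self.regions[i].end,
            ),
        )
        if not self.stratum:
            self.stratum = [UNASSIGNED] * len(self.regions)
        seen: set[tuple] = set()
        regs, strat = [], []
        for i in order:
            r = self.regions[i]
            key = (r.chrom, r.start, r.end)
            if key in seen:
                continue
            seen.add(key)
            regs.append(r)
            strat.append(self.stratum[i])
        self.regions = regs
        self.stratum = strat

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.regions]

    def by_chrom(self) -> dict[str, list[GenomicRegion]]:
        out: dict[str, list[GenomicRegion]] = {}
        for r in self.regions:
            out.setdefault(r.chrom, []).append(r)
        return out


@dataclass
class TSSCatalog:
    """Single-bp transcription start sites."""

    sites: list[tuple[str, int]]

    def __post_init__(self):
        for chrom, pos in self.sites:
            if pos < 0:
                raise ValueError(f"negative TSS position {chrom}:{pos}")

    def by_chrom(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for chrom, pos in self.sites:
            out.setdefault(chrom, []).append(pos)
        return {c: np.sort(np.asarray(p)) for c, p in out.items()}


def read_bed(path) -> RegionSet:
    """Read a BED3+ file into a sorted, de-duplicated :class:`RegionSet`."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinates"
                ) from None
            if end <= start or start < 0:
                raise BedParseError(
                    f"line {lineno}: invalid interval {chrom}:{start}-{end}"
                )
            regions.append(GenomicRegion(chrom, start, end))
    return RegionSet(regions)


def read_tss(path) -> TSSCatalog:
    """Read a TSS catalog from BED; each interval's start is the site."""
    rs = read_bed(path)
    return TSSCatalog([(r.chrom, r.start) for r in rs])


def merge_peaks(peak_sets: Sequence[RegionSet]) -> RegionSet:
    """Union of all peak sets with overlapping-or-bookended intervals merged.

    Bookended intervals (``[0,10)`` and ``[10,20)``) coalesce: merging happens
    once at the raw-peak stage so that the consecutive bins produced later by
    :func:`split_broad_peaks` never re-merge.
    """
    if not peak_sets:
        raise ValueError("at least one peak set is required")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for ps in peak_sets:
        for r in ps:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    merged = []
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_e:  # overlap or touch
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicRegion(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicRegion(chrom, cur_s, cur_e))
    return RegionSet(merged)


def subtract_regions(regions: RegionSet, exclude: RegionSet) -> RegionSet:
    """Remove the parts of ``regions`` covered by ``exclude`` (e.g. a
    user-supplied blacklist); regions may be split or dropped entirely."""
    excl = {c: ivals for c, ivals in merge_peaks([exclude]).by_chrom().items()}
    out = []
    for r in regions:
        pieces = [(r.start, r.end)]
        for b in excl.get(r.chrom, []):
            nxt = []
            for s, e in pieces:
                if b.end <= s or b.start >= e:
                    nxt.append((s, e))
                    continue
                if b.start > s:
                    nxt.append((s, b.start))
                if b.end < e:
                    nxt.append((b.end, e))
            pieces = nxt
        out.extend(GenomicRegion(r.chrom, s, e) for s, e in pieces)
    return RegionSet(out)


def split_broad_peaks(regions: RegionSet, bin_size: int) -> RegionSet:
    """Divide broad regions into consecutive near-equal bins.

    Regions of width <= 1.5 * ``bin_size`` are kept as they are.  A wider
    region is replaced by ``n = max(1, floor(width/bin_size + 0.5))``
    consecutive bins that exactly tile it, with widths differing by at most
    1 bp.  Every resulting bin width lies in ``(2B/3, 1.5B]``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    out = []
    for r in regions:
        w = r.width
        if w <= 1.5 * bin_size:
            out.append(r)
            continue
        n = max(1, int(np.floor(w / bin_size + 0.5)))
        # distribute the remainder over the first (w % n) bins
        base, rem = divmod(w, n)
        pos = r.start
        for k in range(n):
            bw = base + (1 if k < rem else 0)
            out.append(GenomicRegion(r.chrom, pos, pos + bw))
            pos += bw
    return RegionSet(out)


def classify_proximal_distal(
    regions: RegionSet, tss: TSSCatalog, cutoff: int = 5000
) -> RegionSet:
    """Label regions proximal iff the nearest same-chromosome TSS is < cutoff
    bp away (distance 0 if a TSS lies inside ``[start, end)``; otherwise the
    distance to the closer of ``start`` and ``end - 1``)."""
    tss_by_chrom = tss.by_chrom()
    if not tss.sites:
        warnings.warn("empty TSS catalog: all regions labeled distal")
    strat = []
    for r in regions:
        sites = tss_by_chrom.get(r.chrom)
        if sites is None or len(sites) == 0:
            strat.append(DISTAL)
            continue
        j = np.searchsorted(sites, r.start)
        d = np.inf
        for cand in sites[max(0, j - 1): j + 2]:
            if r.start <= cand < r.end:
                d = 0
                break
            d = min(d, abs(cand - r.start), abs(cand - (r.end - 1)))
        # searchsorted window may miss an inside TSS for wide regions; check
        inside = np.searchsorted(sites, r.start) < np.searchsorted(sites, r.end)
        if inside:
            d = 0
        strat.append(PROXIMAL if d < cutoff else DISTAL)
    return RegionSet(list(regions.regions), strat)


def _is_sex_chrom(chrom: str) -> bool:
    name = chrom.lower()
    if name.startswith("chr"):
        name = name[3:]
    return name in _SEX_CHROMS


def drop_sex_chromosomes(regions: RegionSet) -> RegionSet:
    """Remove chrX/chrY regions (case-insensitive, 'chr'-prefix tolerant)."""
    keep = [i for i, r in enumerate(regions) if not _is_sex_chrom(r.chrom)]
    return RegionSet(
        [regions.regions[i] for i in keep],
        [regions.stratum[i] for i in keep],
    )


def occupancy_from_counts(counts: pd.DataFrame, threshold: int = 50) -> pd.DataFrame:
    """Binary occupancy by a strict count threshold: O_ij = 1 iff K_ij > t."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return (counts > threshold).astype(np.int64)


def occupancy_from_peaks(
    reference: RegionSet,
    per_sample_peaks: Sequence[RegionSet],
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """O_ij = 1 iff reference region i overlaps (>= 1 bp, half-open) any peak
    of sample j."""
    if len(reference) == 0:
        raise ValueError("reference region set is empty")
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(len(per_sample_peaks))]
    occ = np.zeros((len(reference), len(per_sample_peaks)), dtype=np.int64)
    ref_ids = reference.ids
    for j, peaks in enumerate(per_sample_peaks):
        by_chrom = {
            c: (np.array([p.start for p in ps]), np.array([p.end for p in ps]))
            for c, ps in peaks.by_chrom().items()
        }
        for i, r in enumerate(reference):
            if r.chrom not in by_chrom:
                continue
            starts, ends = by_chrom[r.chrom]
            # overlap iff peak.start < r.end and peak.end > r.start
            if np.any((starts < r.end) & (ends > r.start)):
                occ[i, j] = 1
    return pd.DataFrame(occ, index=ref_ids, columns=list(sample_ids))


def read_matrix(path, binary: bool = False) -> pd.DataFrame:
    """Read a region x sample TSV (header = sample ids, column 1 = region id).

    With ``binary=True`` the table is validated as an occupancy matrix.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise MatrixFormatError("duplicate region ids")
    if df.columns.has_duplicates:
        raise MatrixFormatError("duplicate sample ids")
    if df.isna().any().any():
        raise MatrixFormatError("missing or ragged cells")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise MatrixFormatError(f"non-numeric cells in column {col!r}")
    if binary:
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise MatrixFormatError("occupancy matrix must be binary")
        df = df.astype(np.int64)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table in the TSV dialect read back by :func:`read_matrix`."""
    df.to_csv(path, sep="\t", index=True)


def region_set_to_frame(regions: RegionSet) -> pd.DataFrame:
    """Tabular view (chrom, start, end, stratum) indexed by region id."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "stratum": regions.stratum,
        },
        index=regions.ids,
    )


def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
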