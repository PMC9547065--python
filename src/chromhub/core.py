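"""Core genomic entities and interval algebra.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
Variant tables that arrive 1-based are converted at the reader boundary
(:mod:`chromhub.io`) so every operation in the package sees a single
convention.

The interval engine here (overlap join, closest feature, containment) is
deliberately self-contained and simple enough to verify against brute-force
all-pairs scans; the test suite does exactly that on randomized inputs.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomeBuild",
    "GenomicInterval",
    "Loop",
    "GeneRecord",
    "PromoterRegion",
    "SignalTrack",
    "overlaps",
    "overlaps_any",
    "join_overlaps",
    "closest_feature",
    "coverage_in_window",
    "interval_signal",
    "promoter_window",
    "merge_intervals",
]


class GenomeBuild:
    """Ordered chromosome name -> length (bp) mapping.

    A synthetic stand-in for a reference assembly: every interval in the
    package can be validated against it.
    """

    def __init__(self, chrom_sizes: dict[str, int] | Sequence[tuple[str, int]]):
        items = list(chrom_sizes.items()) if isinstance(chrom_sizes, dict) else list(chrom_sizes)
        names = [c for c, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in build")
        for name, length in items:
            if not isinstance(length, (int, np.integer)) or length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length!r}")
        self._sizes: dict[str, int] = {c: int(n) for c, n in items}

    @property
    def chromosomes(self) -> list[str]:
        return list(self._sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self):
        return iter(self._sizes)

    def items(self):
        return self._sizes.items()

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeBuild) and self._sizes == other._sizes

    def total_length(self) -> int:
        return sum(self._sizes.values())

    def validate(self, interval: "GenomicInterval") -> None:
        if interval.chrom not in self._sizes:
            raise ValueError(f"chromosome {interval.chrom!r} not in build")
        if interval.end > self._sizes[interval.chrom]:
            raise ValueError(
                f"interval {interval} exceeds {interval.chrom} length "
                f"{self._sizes[interval.chrom]}"
            )

    def __repr__(self) -> str:
        return f"GenomeBuild({self._sizes!r})"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)

    def contains(self, other: "GenomicInterval") -> bool:
        """True when `other` lies fully within self (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Loop:
    """Cis chromatin loop between two anchor intervals ("feet").

    Feet are stored in canonical order (footA.start <= footB.start); the
    constructor reorders if needed so loop identity is independent of input
    foot order. Loop size is the distance between foot midpoints, which is
    insensitive to foot width.
    """

    footA: GenomicInterval
    footB: GenomicInterval
    qvalue: float | None = None
    contact_count: int | None = None

    def __post_init__(self):
        if self.footA.chrom != self.footB.chrom:
            raise ValueError(f"trans loop: {self.footA} / {self.footB}")
        if (self.footA.start, self.footA.end) == (self.footB.start, self.footB.end):
            raise ValueError(f"degenerate loop with identical feet: {self.footA}")
        if self.footA.start > self.footB.start or (
            self.footA.start == self.footB.start and self.footA.end > self.footB.end
        ):
            a, b = self.footA, self.footB
            object.__setattr__(self, "footA", b)
            object.__setattr__(self, "footB", a)
        if self.qvalue is not None and not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"q-value outside [0,1]: {self.qvalue}")
        if self.contact_count is not None and self.contact_count < 0:
            raise ValueError("negative contact count")

    @property
    def chrom(self) -> str:
        return self.footA.chrom

    @property
    def size(self) -> float:
        """Genomic span: footB midpoint - footA midpoint (bp)."""
        return self.footB.midpoint - self.footA.midpoint


@dataclass
class GeneRecord:
    """Gene with body coordinates, single annotated TSS and optional expression."""

    gene_id: str
    symbol: str
    strand: str
    body: GenomicInterval
    tss: int | None = None
    expression: float | None = None
    set_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -: {self.strand!r}")
        if self.tss is None:
            self.tss = self.body.start if self.strand == "+" else self.body.end - 1
        if not (self.body.start <= self.tss < self.body.end):
            raise ValueError(
                f"TSS {self.tss} outside gene body {self.body} for {self.gene_id}"
            )
        if self.expression is not None and self.expression < 0:
            raise ValueError("negative expression")

    @property
    def chrom(self) -> str:
        return self.body.chrom


def promoter_window(
    gene: GeneRecord, halfwidth: int = 2500, build: GenomeBuild | None = None
) -> GenomicInterval:
    """Promoter region [tss - h, tss + h), clipped to chromosome bounds."""
    if halfwidth <= 0:
        raise ValueError("promoter halfwidth must be positive")
    start = max(0, gene.tss - halfwidth)
    end = gene.tss + halfwidth
    if build is not None:
        end = min(end, build[gene.chrom])
    return GenomicInterval(gene.chrom, start, end, name=gene.gene_id)


@dataclass(frozen=True)
class PromoterRegion:
    gene_id: str
    interval: GenomicInterval


class SignalTrack:
    """Binned per-chromosome signal (per-bp rate in each bin).

    Values are stored per bin but interpreted as an average per-bp rate, so
    coverage over an interval is ``sum(value * overlapped bp)``.
    """

    def __init__(self, build: GenomeBuild, bin_size: int, values: dict[str, np.ndarray] | None = None):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.build = build
        self.bin_size = int(bin_size)
        self.values: dict[str, np.ndarray] = {}
        for chrom, length in build.items():
            n = math.ceil(length / bin_size)
            if values is not None and chrom in values:
                arr = np.asarray(values[chrom], dtype=float)
                if arr.shape != (n,):
                    raise ValueError(
                        f"{chrom}: expected {n} bins, got {arr.shape}"
                    )
                if (arr < 0).any():
                    raise ValueError(f"{chrom}: negative signal values")
                self.values[chrom] = arr
            else:
                self.values[chrom] = np.zeros(n)


def coverage_in_window(track: SignalTrack, chrom: str, center: int, halfwidth: int) -> float:
    """Total signal in the inclusive window center +/- halfwidth.

    The window covers ``2*halfwidth + 1`` bp ([center-h, center+h] inclusive);
    partial bins contribute proportionally to the overlapped fraction.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    if chrom not in track.build:
        raise ValueError(f"chromosome {chrom!r} not in build")
    chrom_len = track.build[chrom]
    if not (0 <= center < chrom_len):
        raise ValueError(f"center {center} outside {chrom} (length {chrom_len})")
    lo = max(0, center - halfwidth)
    hi = min(chrom_len, center + halfwidth + 1)  # half-open upper bound
    return interval_signal(track, GenomicInterval(chrom, lo, hi))


def interval_signal(track: SignalTrack, interval: GenomicInterval) -> float:
    """Summed per-bp signal over a half-open interval, partial bins prorated."""
    arr = track.values[interval.chrom]
    bs = track.bin_size
    lo, hi = interval.start, min(interval.end, track.build[interval.chrom])
    if lo >= hi:
        return 0.0
    first, last = lo // bs, (hi - 1) // bs
    if first == last:
        return float(arr[first] * (hi - lo))
    total = arr[first] * ((first + 1) * bs - lo)
    total += arr[last] * (hi - last * bs)
    if last - first > 1:
        total += float(arr[first + 1 : last].sum()) * bs
    return float(total)


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap predicate: same chrom and a.start < b.end and b.start < a.end."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


class IntervalIndex:
    """Per-chromosome sorted index supporting overlap and nearest queries.

    Query cost is O(log n + k) per interval via a sorted-start array plus a
    running maximum of ends, which is exact for arbitrary (possibly nested)
    interval sets.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.intervals = list(intervals)
        self._by_chrom: dict[str, tuple[list[int], list[int], list[int], list[int]]] = {}
        per_chrom: dict[str, list[int]] = {}
        for idx, iv in enumerate(self.intervals):
            per_chrom.setdefault(iv.chrom, []).append(idx)
        for chrom, idxs in per_chrom.items():
            idxs.sort(key=lambda i: (self.intervals[i].start, self.intervals[i].end, i))
            starts = [self.intervals[i].start for i in idxs]
            ends = [self.intervals[i].end for i in idxs]
            maxend = []
            running = 0
            for e in ends:
                running = max(running, e)
                maxend.append(running)
            self._by_chrom[chrom] = (idxs, starts, ends, maxend)

    def overlapping(self, query: GenomicInterval) -> list[int]:
        """Indices (into the original list) of intervals overlapping `query`."""
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return []
        idxs, starts, ends, maxend = entry
        hi = bisect_left(starts, query.end)  # starts[i] < query.end
        out = []
        # scan left while any interval to the left may still reach query.start
        i = hi - 1
        while i >= 0 and maxend[i] > query.start:
            if ends[i] > query.start:
                out.append(idxs[i])
            i -= 1
        out.reverse()
        return out

    def any_overlap(self, query: GenomicInterval) -> bool:
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return False
        idxs, starts, ends, maxend = entry
        hi = bisect_left(starts, query.end)
        i = hi - 1
        while i >= 0 and maxend[i] > query.start:
            if ends[i] > query.start:
                return True
            i -= 1
        return False

    def closest(self, query: GenomicInterval) -> tuple[int, int] | None:
        """(index, signed distance) of the closest interval on query's chromosome.

        Distance is 0 for any overlap; otherwise the half-open gap, positive
        when the feature lies downstream (right) of the query, negative
        upstream. Ties (equal |distance|) break to the smaller start, then to
        input order. Returns None when the chromosome has no features.
        """
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return None
        hits = self.overlapping(query)
        if hits:
            best = min(hits, key=lambda i: (self.intervals[i].start, i))
            return best, 0
        idxs, starts, ends, maxend = entry
        best: tuple[int, int, int, int] | None = None  # (|d|, start, idx, signed)
        for i, iv_idx in enumerate(idxs):
            iv = self.intervals[iv_idx]
            if iv.end <= query.start:
                d = query.start - iv.end
                cand = (d, iv.start, iv_idx, -d)
            elif iv.start >= query.end:
                d = iv.start - query.end
                cand = (d, iv.start, iv_idx, d)
            else:  # pragma: no cover - overlaps handled above
                continue
            if best is None or (cand[0], cand[1], cand[2]) < (best[0], best[1], best[2]):
                best = cand
        assert best is not None
        return best[2], best[3]


def overlaps_any(query: GenomicInterval, features: Sequence[GenomicInterval] | IntervalIndex) -> bool:
    index = features if isinstance(features, IntervalIndex) else IntervalIndex(features)
    return index.any_overlap(query)


def join_overlaps(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (i, j) index pairs with a[i] overlapping b[j], sorted by (i, j)."""
    index = IntervalIndex(b)
    out: list[tuple[int, int]] = []
    for i, query in enumerate(a):
        for j in index.overlapping(query):
            out.append((i, j))
    out.sort()
    return out


def closest_feature(
    query: GenomicInterval, features: Sequence[GenomicInterval] | IntervalIndex
) -> tuple[GenomicInterval, int] | None:
    """Closest feature to `query` on its chromosome with signed distance.

    Returns None when no feature shares the query's chromosome (a
    distinguished "no neighbor" outcome rather than an exception).
    """
    index = features if isinstance(features, IntervalIndex) else IntervalIndex(features)
    hit = index.closest(query)
    if hit is None:
        return None
    idx, dist = hit
    return index.intervals[idx], dist


def merge_intervals(intervals: Iterable[GenomicInterval], gap: int = 0) -> list[GenomicInterval]:
    """Union of intervals, merging any pair closer than `gap` (0 = touching).

    Output is sorted by (chrom, start); chromosome order follows first
    appearance in the input.
    """
    per_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        per_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom, ivs in per_chrom.items():
        ivs.sort(key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out
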