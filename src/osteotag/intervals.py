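"""Interval arithmetic on 0-based, half-open genomic coordinates.

Everything downstream -- peak filtering, promoter/enhancer annotation,
target-gene assignment -- reduces to a handful of bedtools-like primitives
on sorted interval collections.  They are implemented here directly so that
the coordinate conventions are explicit and testable:

* coordinates are BED-dialect 0-based half-open ``[start, end)``;
* abutting intervals (``a.end == b.start``) do NOT overlap;
* distances are unsigned gaps to the gene *body*, 0 when overlapping;
* ties in ``closest_distance`` break on the smaller ``(start, gene_id)``.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    id: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Unsigned gap in bp; 0 when overlapping; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        return max(0, self.start - other.end, other.start - self.end)


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Always sorted by ``(chrom, start, end)``; duplicates are allowed unless
    merged.  Construct with ``presorted=True`` to assert (and verify) that
    the input is already in sort order -- violated order raises, which is how
    the set operations surface unsorted input.
    """

    __slots__ = ("_ivs",)

    def __init__(
        self, intervals: Iterable[GenomicInterval] = (), presorted: bool = False
    ) -> None:
        ivs = list(intervals)
        if presorted:
            for a, b in itertools.pairwise(ivs):
                if a.sort_key() > b.sort_key():
                    raise ValueError(
                        f"intervals not sorted: {a.chrom}:{a.start}-{a.end} "
                        f"precedes {b.chrom}:{b.start}-{b.end}"
                    )
        else:
            ivs.sort(key=GenomicInterval.sort_key)
        self._ivs = ivs

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple]) -> "IntervalSet":
        return cls(GenomicInterval(*t) for t in tuples)

    def __len__(self) -> int:
        return len(self._ivs)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._ivs)

    def __getitem__(self, i):
        return self._ivs[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self._ivs == other._ivs

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self._ivs:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_length(self) -> int:
        return sum(iv.length for iv in self._ivs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self._ivs],
                "start": [iv.start for iv in self._ivs],
                "end": [iv.end for iv in self._ivs],
                "id": [iv.id for iv in self._ivs],
                "strand": [iv.strand for iv in self._ivs],
            }
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene body with a strand-dependent transcription start site.

    The TSS is the first transcribed base: ``start`` on the plus strand and
    ``end - 1`` on the minus strand, so it always lies within ``[start, end)``.
    """

    interval: GenomicInterval
    gene_id: str
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be '+' or '-'")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def _as_sorted_set(x) -> IntervalSet:
    if isinstance(x, IntervalSet):
        return x
    return IntervalSet(x, presorted=True)


def intersect(a, b) -> IntervalSet:
    """Members of ``a`` overlapping >= 1 bp of any member of ``b``.

    Follows ``bedtools intersect -u`` semantics: each qualifying interval of
    ``a`` is reported once, in order.  Half-open abutment does not count.
    """
    a = _as_sorted_set(a)
    b = _as_sorted_set(b)
    out: list[GenomicInterval] = []
    bb = b.by_chrom()
    for chrom, ivs in a.by_chrom().items():
        others = bb.get(chrom)
        if not others:
            continue
        starts = [o.start for o in others]
        # prefix max of end coordinates: others[:k] can reach this far right
        maxend = list(itertools.accumulate((o.end for o in others), func=max))
        for iv in ivs:
            k = bisect_left(starts, iv.end)
            if k > 0 and maxend[k - 1] > iv.start:
                out.append(iv)
    return IntervalSet(out, presorted=False)


def subtract_overlapping(a, b) -> IntervalSet:
    """Members of ``a`` overlapping no member of ``b`` (bedtools -v)."""
    a = _as_sorted_set(a)
    hits = set(id(iv) for iv in intersect(a, b))
    return IntervalSet([iv for iv in a if id(iv) not in hits], presorted=True)


def merge(a, max_gap: int = 0) -> IntervalSet:
    """Fuse intervals on the same chromosome that overlap or lie within
    ``max_gap`` bp of each other; the output is disjoint and unnamed."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    a = _as_sorted_set(a)
    out: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    for iv in a:
        if cur is not None and iv.chrom == cur.chrom and iv.start - cur.end <= max_gap:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end)
            continue
        if cur is not None:
            out.append(cur)
        cur = GenomicInterval(iv.chrom, iv.start, iv.end)
    if cur is not None:
        out.append(cur)
    return IntervalSet(out, presorted=True)


def _gene_index(genes: Sequence[GeneModel]):
    """Per-chromosome arrays for closest-gene queries.

    Genes sorted by (start, gene_id); prefix-max of ends carries, for each
    prefix, the gene reaching furthest right (ties resolved to the smaller
    (start, gene_id), which implements the deterministic tie-break).
    """
    index: dict[str, dict] = {}
    for chrom, glist in itertools.groupby(
        sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)),
        key=lambda g: g.chrom,
    ):
        glist = list(glist)
        starts = [g.start for g in glist]
        best: list[int] = []
        for i, g in enumerate(glist):
            if not best:
                best.append(i)
                continue
            j = best[-1]
            prev = glist[j]
            if g.end > prev.end:
                best.append(i)
            else:
                best.append(j)
        index[chrom] = {"genes": glist, "starts": starts, "reach": best}
    return index


def closest_distance(
    peaks, genes: Sequence[GeneModel]
) -> list[tuple[GenomicInterval, str | None, int | None]]:
    """For each peak, the gene whose body minimises the unsigned gap.

    Returns ``(peak, gene_id, distance)`` triples; distance is 0 for any
    overlap and ``None`` (with gene ``None``) when the peak's chromosome has
    no genes.  Ties break on the smaller ``(start, gene_id)``.
    """
    peaks = _as_sorted_set(peaks)
    index = _gene_index(genes)
    out = []
    for p in peaks:
        idx = index.get(p.chrom)
        if idx is None:
            out.append((p, None, None))
            continue
        glist, starts, reach = idx["genes"], idx["starts"], idx["reach"]
        candidates: list[GeneModel] = []
        # gap-0 genes (overlap or half-open abutment): start <= p.end and
        # end >= p.start; the smallest (start, gene_id) such gene wins
        k2 = bisect_right(starts, p.end)
        zero = None
        for g in glist[:k2]:
            if g.end >= p.start:
                if zero is None:
                    zero = g
                elif g.start > zero.start:
                    break
                elif (g.start, g.gene_id) < (zero.start, zero.gene_id):
                    zero = g
        if zero is not None:
            candidates.append(zero)
        else:
            k = bisect_left(starts, p.end)
            # nearest gene ending left of the peak
            if k > 0:
                candidates.append(glist[reach[k - 1]])
            # nearest gene starting right of the peak end
            j = bisect_left(starts, p.end)
            if j < len(glist):
                first_start = glist[j].start
                while j < len(glist) and glist[j].start == first_start:
                    candidates.append(glist[j])
                    j += 1
        best_gene = None
        best = None
        for g in candidates:
            d = max(0, g.start - p.end, p.start - g.end)
            key = (d, g.start, g.gene_id)
            if best is None or key < best:
                best = key
                best_gene = g
        out.append((p, best_gene.gene_id, best[0]))
    return out


def tss_windows(genes: Sequence[GeneModel], halfwidth: int) -> IntervalSet:
    """One window ``[tss - halfwidth, tss + halfwidth + 1)`` per gene.

    The strand picks the TSS; windows are clipped at coordinate 0 and carry
    the gene id and strand.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    out = []
    for g in genes:
        start = max(0, g.tss - halfwidth)
        out.append(
            GenomicInterval(g.chrom, start, g.tss + halfwidth + 1, id=g.gene_id,
                            strand=g.strand)
        )
    return IntervalSet(out)


# ---------------------------------------------------------------------------
# BED / gene-table I/O

def read_bed(path) -> IntervalSet:
    """Read a BED3/BED6 file (tab-separated, no header)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), name, strand))
    return IntervalSet(out)


def write_bed(intervals, path) -> None:
    """Write BED3 when no interval carries a name/strand, else BED6."""
    ivs = list(intervals)
    six = any(iv.id is not None or iv.strand != "." for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if six:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t0\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gene_table(path) -> list[GeneModel]:
    """Read a gene table TSV with header chrom/start/end/strand/gene_id."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    required = {"chrom", "start", "end", "strand", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return [
        GeneModel(
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.gene_id, r.strand),
            r.gene_id,
            r.strand,
        )
        for r in df.itertuples()
    ]


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "gene_id": [g.gene_id for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)
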