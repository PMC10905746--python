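"""Fragment-count signal processing for CUT&Tag / CUT&RUN style data.

Covers the quantitative plumbing between aligned-fragment surrogates
(binned count tracks) and the statistics modules: counting fragments in
regions, RPKM/CPM normalisation, exogenous-genome (spike-in) scaling
factors, a transparent Poisson local-background broad-peak caller, and
coverage metaprofiles around region centres.

The spike-in scaling factor follows the calibration convention for
CUT&Tag with a fixed ratio of foreign-genome chromatin added per cell:

    factor = ((primary_mapped_reads / primary_genome_bp) / spike_reads) * 10000

Because the spike material is constant per cell, the factor tracks the
amount of genuine on-target material in the library; dividing or
offsetting by it exposes global occupancy changes that per-library (CPM)
normalisation is blind to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage, stats

from . import intervals as gi
from .intervals import GenomicInterval, IntervalSet

import pandas as pd

ASSAYS = ("BRD4", "H3K27ac", "H3K4me2", "H3K27me3", "RUNX2", "RNA")
GENOTYPES = ("WT", "KO1", "KO2")
TIMEPOINTS = ("D0", "D3", "D6")

#: mappable mouse genome size used when none is supplied (configurable).
DEFAULT_PRIMARY_GENOME_BP = 2_654_895_218


@dataclass(frozen=True)
class SampleDesign:
    """Metadata for one sequenced sample."""

    sample_id: str
    assay: str
    genotype: str
    timepoint: str
    replicate: int
    primary_mapped_reads: int
    spike_mapped_reads: int = 0

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.primary_mapped_reads <= 0:
            raise ValueError("primary_mapped_reads must be > 0")
        if self.spike_mapped_reads < 0:
            raise ValueError("spike_mapped_reads must be >= 0")


@dataclass
class BinnedTrack:
    """Integer fragment counts in fixed-width bins, one array per chromosome."""

    bin_size: int
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        for chrom, arr in self.data.items():
            arr = np.asarray(arr)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"counts on {chrom} must be finite and >= 0")
            self.data[chrom] = arr

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom]) * self.bin_size

    def total_count(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(self.bin_size, {c: a.copy() for c, a in self.data.items()})


def pool_tracks(tracks: Sequence[BinnedTrack]) -> BinnedTrack:
    """Sum bin counts across replicate tracks (replicate pooling)."""
    if not tracks:
        raise ValueError("no tracks to pool")
    first = tracks[0]
    out = {c: a.astype(float).copy() for c, a in first.data.items()}
    for t in tracks[1:]:
        if t.bin_size != first.bin_size or set(t.data) != set(out):
            raise ValueError("tracks to pool must share bin size and chromosomes")
        for c in out:
            out[c] = out[c] + t.data[c]
    return BinnedTrack(first.bin_size, out)


# ---------------------------------------------------------------------------
# spike-in calibration

def spike_scaling_factor(
    primary_reads: int,
    spike_reads: int,
    primary_genome_bp: int = DEFAULT_PRIMARY_GENOME_BP,
) -> float:
    """Per-sample spike-in scaling factor.

    ``((primary_reads / primary_genome_bp) / spike_reads) * 10000``.
    Raises when calibration is impossible (no spike reads).
    """
    if primary_reads <= 0:
        raise ValueError("primary_reads must be > 0")
    if primary_genome_bp <= 0:
        raise ValueError("primary_genome_bp must be > 0")
    if spike_reads <= 0:
        raise ValueError(
            "spike_reads must be > 0: spike-in calibration impossible without "
            "exogenous-genome reads"
        )
    return (primary_reads / primary_genome_bp) / spike_reads * 10_000


def scaling_factors(
    samples: Iterable[SampleDesign],
    primary_genome_bp: int = DEFAULT_PRIMARY_GENOME_BP,
) -> dict[str, float]:
    """Spike scaling factor per sample id (samples must carry spike reads)."""
    return {
        s.sample_id: spike_scaling_factor(
            s.primary_mapped_reads, s.spike_mapped_reads, primary_genome_bp
        )
        for s in samples
    }


# ---------------------------------------------------------------------------
# counting and normalisation

@dataclass
class CountMatrix:
    """Fragment counts per feature per sample.

    ``features`` may be an :class:`IntervalSet` (occupancy counts at peaks)
    or plain string ids (gene-level expression counts).
    """

    feature_ids: list[str]
    samples: list[SampleDesign]
    counts: np.ndarray
    features: IntervalSet | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.feature_ids), len(self.samples)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.features is not None and len(self.features) != len(self.feature_ids):
            raise ValueError("features and feature_ids disagree in length")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def feature_lengths(self) -> np.ndarray:
        if self.features is None:
            raise ValueError("no interval features attached; lengths unavailable")
        return np.array([iv.length for iv in self.features], dtype=float)

    def columns(self, predicate) -> np.ndarray:
        """Boolean sample mask from a predicate over SampleDesign."""
        return np.array([bool(predicate(s)) for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, "feature_id", self.feature_ids)
        if self.features is not None:
            df.insert(0, "end", [iv.end for iv in self.features])
            df.insert(0, "start", [iv.start for iv in self.features])
            df.insert(0, "chrom", [iv.chrom for iv in self.features])
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, samples: Sequence[SampleDesign]) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t")
        ids = [s.sample_id for s in samples]
        features = None
        if {"chrom", "start", "end"} <= set(df.columns):
            features = IntervalSet(
                GenomicInterval(r.chrom, int(r.start), int(r.end), str(r.feature_id))
                for r in df.itertuples()
            )
        return cls(
            feature_ids=[str(x) for x in df["feature_id"]],
            samples=list(samples),
            counts=df[ids].to_numpy(float),
            features=features,
        )


def count_in_intervals(track: BinnedTrack, regions) -> np.ndarray:
    """Fragment counts per region with fractional-overlap bin weighting.

    A region covering half of one bin receives half that bin's count.
    Regions beyond the track extent contribute 0 there (with a warning).
    """
    regions = gi._as_sorted_set(regions) if not isinstance(regions, IntervalSet) else regions
    bs = track.bin_size
    out = np.zeros(len(regions), dtype=float)
    warned = False
    # cumulative mass per chromosome makes each region an O(1) difference
    cum = {c: np.concatenate([[0.0], np.cumsum(a)]) for c, a in track.data.items()}

    def mass_upto(chrom: str, pos: float) -> float:
        arr = track.data[chrom]
        c = cum[chrom]
        x = pos / bs
        k = int(np.floor(x))
        if k <= 0:
            return 0.0
        if k >= len(arr):
            return float(c[-1])
        return float(c[k] + (x - k) * arr[k])

    for i, iv in enumerate(regions):
        if iv.chrom not in track.data:
            if not warned:
                warnings.warn(f"region on {iv.chrom} beyond track extent; counted as 0")
                warned = True
            continue
        if iv.end > track.chrom_length(iv.chrom) and not warned:
            warnings.warn(
                f"region {iv.chrom}:{iv.start}-{iv.end} extends beyond track; "
                "missing bins counted as 0"
            )
            warned = True
        out[i] = mass_upto(iv.chrom, iv.end) - mass_upto(iv.chrom, iv.start)
    return out


def count_matrix_from_tracks(
    tracks: Mapping[str, BinnedTrack],
    regions: IntervalSet,
    samples: Sequence[SampleDesign],
) -> CountMatrix:
    """Counts at ``regions`` for each sample's track, in sample order."""
    cols = []
    for s in samples:
        cols.append(count_in_intervals(tracks[s.sample_id], regions))
    ids = [iv.id or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in regions]
    return CountMatrix(ids, list(samples), np.column_stack(cols), features=regions)


def rpkm(
    counts: np.ndarray, lengths_bp: np.ndarray, mapped_reads: np.ndarray
) -> np.ndarray:
    """Reads per kilobase per million mapped reads, elementwise."""
    counts = np.asarray(counts, dtype=float)
    lengths_kb = np.asarray(lengths_bp, dtype=float) / 1_000.0
    mapped_m = np.asarray(mapped_reads, dtype=float) / 1_000_000.0
    if np.any(mapped_m <= 0):
        raise ValueError("library sizes must be > 0 for RPKM")
    if counts.ndim == 1:
        return counts / (lengths_kb * float(mapped_m))
    return counts / (lengths_kb[:, None] * mapped_m[None, :])


def rpkm_matrix(cm: CountMatrix, mask: np.ndarray | None = None) -> np.ndarray:
    """RPKM for (a sample subset of) a CountMatrix with interval features."""
    cols = np.arange(len(cm.samples)) if mask is None else np.flatnonzero(mask)
    mapped = np.array([cm.samples[j].primary_mapped_reads for j in cols], dtype=float)
    return rpkm(cm.counts[:, cols], cm.feature_lengths(), mapped)


def cpm(counts: np.ndarray) -> np.ndarray:
    """Counts per million: each column rescaled to sum to 1e6."""
    counts = np.asarray(counts, dtype=float)
    colsum = counts.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("cannot CPM-normalise an all-zero sample")
    return counts * 1e6 / colsum


# ---------------------------------------------------------------------------
# peak calling

def call_broad_peaks(
    track: BinnedTrack,
    qvalue_cutoff: float = 0.1,
    merge_gap: int = 500,
    min_len: int = 200,
    local_window: int = 10_000,
) -> IntervalSet:
    """Simplified broad-peak caller with a Poisson local background.

    Each bin is tested against lambda_local = max(genome-wide mean,
    ``local_window`` centred rolling mean) with a Poisson upper tail;
    Benjamini-Hochberg across all bins at ``qvalue_cutoff`` selects
    significant bins, whose maximal runs are merged within ``merge_gap``
    and filtered to ``min_len``.  Transparent stand-in for an external
    broad caller; externally called BED peaks can be used instead.
    """
    from .differential import bh_fdr  # local import avoids cycle at import time

    chroms = sorted(track.data)
    if not chroms:
        return IntervalSet()
    all_counts = np.concatenate([track.data[c] for c in chroms])
    total = all_counts.sum()
    if total == 0:
        return IntervalSet()
    lam_genome = total / len(all_counts)
    w = max(1, int(round(local_window / track.bin_size)))
    pvals = []
    for c in chroms:
        arr = track.data[c].astype(float)
        rolling = ndimage.uniform_filter1d(arr, size=w, mode="nearest")
        lam = np.maximum(lam_genome, rolling)
        pvals.append(stats.poisson.sf(np.round(arr) - 1, lam))
    q = bh_fdr(np.concatenate(pvals))
    sig = q <= qvalue_cutoff
    out = []
    offset = 0
    bs = track.bin_size
    for c in chroms:
        n = len(track.data[c])
        mask = sig[offset : offset + n]
        offset += n
        if not mask.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append(GenomicInterval(c, int(s) * bs, int(e) * bs))
    peaks = gi.merge(IntervalSet(out), max_gap=merge_gap)
    return IntervalSet([p for p in peaks if p.length >= min_len], presorted=True)


# ---------------------------------------------------------------------------
# coverage metaprofiles

def coverage_profile(
    track: BinnedTrack,
    regions,
    flank: int,
    nbins: int,
    scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled coverage in ``nbins`` equal windows centred on region midpoints.

    Returns ``(matrix, mean_profile)`` where ``matrix[i, j]`` is the scaled
    fragment mass of region ``i`` in profile bin ``j`` over the window
    ``midpoint +/- flank``.  Windows beyond a chromosome edge are
    zero-padded, so the matrix row sum equals the scaled read mass actually
    present in the window.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    regions = list(regions)
    bs = track.bin_size
    mat = np.zeros((len(regions), nbins), dtype=float)
    cum = {c: np.concatenate([[0.0], np.cumsum(a)]) for c, a in track.data.items()}

    def mass_upto(chrom: str, pos: float) -> float:
        arr = track.data[chrom]
        c = cum[chrom]
        x = pos / bs
        if x <= 0:
            return 0.0
        k = int(np.floor(x))
        if k >= len(arr):
            return float(c[-1])
        return float(c[k] + (x - k) * arr[k])

    for i, iv in enumerate(regions):
        if iv.chrom not in track.data:
            continue
        centre = iv.midpoint
        edges = np.linspace(centre - flank, centre + flank, nbins + 1)
        masses = np.array([mass_upto(iv.chrom, e) for e in edges])
        mat[i] = np.diff(masses) * scale
    return mat, mat.mean(axis=0) if len(regions) else np.zeros(nbins)


# ---------------------------------------------------------------------------
# bedGraph and sample-sheet I/O

def write_bedgraph(track: BinnedTrack, path) -> None:
    with open(path, "w") as fh:
        bs = track.bin_size
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            for i, v in enumerate(arr):
                if v != 0:
                    v = int(v) if float(v).is_integer() else float(v)
                    fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t{v}\n")


def read_bedgraph(path, bin_size: int, chrom_lengths: Mapping[str, int]) -> BinnedTrack:
    """Read a bin-aligned bedGraph back into a track (zeros implicit)."""
    data = {
        c: np.zeros(int(np.ceil(L / bin_size))) for c, L in chrom_lengths.items()
    }
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")
            start, end = int(start), int(end)
            if start % bin_size or (end - start) != bin_size:
                raise ValueError(f"bedGraph line not aligned to {bin_size}-bp bins")
            data[chrom][start // bin_size] = float(value)
    return BinnedTrack(bin_size, data)


def write_sample_sheet(samples: Sequence[SampleDesign], path) -> None:
    pd.DataFrame([s.__dict__ for s in samples]).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleDesign(
            sample_id=str(r.sample_id),
            assay=r.assay,
            genotype=r.genotype,
            timepoint=r.timepoint,
            replicate=int(r.replicate),
            primary_mapped_reads=int(r.primary_mapped_reads),
            spike_mapped_reads=int(r.spike_mapped_reads),
        )
        for r in df.itertuples()
    ]
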