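"""The enhancer classification ladder.

Validated occupancy peaks -> promoter vs enhancer -> super-enhancer ->
target genes within 50 kb -> stem vs early/late osteogenic classes.

Peak validation mirrors the analysis conventions of spike-in calibrated
occupancy studies: a pooled-sample peak is retained when its wild-type
RPKM exceeds 1 and it is either absent from the knockout peak set
("wild-type only") or shows significant (FDR < 0.05) loss of signal in the
knockout by the spike-calibrated NB exact test.

Enhancers are acetylation (H3K27ac) peaks away from transcription start
sites; a peak overlapping both a TSS window and an H3K27ac peak is a
promoter (TSS precedence).  Super-enhancers are called on the classic
rank-ordered signal-density curve with the tangent (slope = 1) rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import differential as diff
from . import intervals as gi
from .intervals import GeneModel, GenomicInterval, IntervalSet
from .signal import CountMatrix, rpkm_matrix

TEMPORAL_TIMEPOINT_CLASS = {
    "D0": "stem",
    "D3": "early_osteogenic",
    "D6": "late_osteogenic",
}


def _peak_ids(peaks: IntervalSet) -> list[str]:
    return [iv.id or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in peaks]


def _overlap_flags(peaks: IntervalSet, other: IntervalSet) -> np.ndarray:
    hit_ids = set(id(iv) for iv in gi.intersect(peaks, other))
    return np.array([id(iv) in hit_ids for iv in peaks])


def validate_peaks(
    pooled_peaks: IntervalSet,
    replicate_peak_sets: list[IntervalSet],
    ko_peaks: IntervalSet,
    counts: CountMatrix,
    effective_lib_sizes: np.ndarray,
    rpkm_min: float = 1.0,
    fdr_cut: float = 0.05,
    phi: float | None = None,
) -> pd.DataFrame:
    """Validate pooled peaks against replicates and the knockout.

    ``counts`` holds fragment counts at ``pooled_peaks`` for all WT and KO
    samples of the assay; ``effective_lib_sizes`` aligns with its samples
    (reciprocal spike factors for calibrated assays, total mapped reads
    otherwise).  Returns one row per pooled peak with ``rpkm_wt``,
    ``replicate_support``, ``wt_only``, ``ko_loss_logFC``, ``ko_loss_fdr``
    and the ``retained`` verdict:

        retained = rpkm_wt > rpkm_min and (wt_only or
                   (ko_loss_fdr < fdr_cut and ko_loss_logFC < 0))
    """
    if counts.features is None or list(counts.features) != list(pooled_peaks):
        raise ValueError("count matrix does not cover the pooled peaks")
    wt = counts.columns(lambda s: s.genotype == "WT")
    ko = counts.columns(lambda s: s.genotype != "WT")
    if not wt.any() or not ko.any():
        raise ValueError("need both WT and KO samples to validate peaks")
    rpkm_wt = rpkm_matrix(counts, wt).mean(axis=1)
    support = np.zeros(len(pooled_peaks), dtype=int)
    for rep_set in replicate_peak_sets:
        support += _overlap_flags(pooled_peaks, rep_set)
    wt_only = ~_overlap_flags(pooled_peaks, ko_peaks)
    de = diff.exact_test_table(
        counts.counts, _peak_ids(pooled_peaks), wt, ko,
        np.asarray(effective_lib_sizes, dtype=float), phi=phi,
    )
    out = pooled_peaks.to_frame().drop(columns=["id", "strand"])
    out["peak_id"] = _peak_ids(pooled_peaks)
    out["rpkm_wt"] = rpkm_wt
    out["replicate_support"] = support
    out["wt_only"] = wt_only
    out["ko_loss_logFC"] = de["logFC"].to_numpy()
    out["ko_loss_fdr"] = de["fdr"].to_numpy()
    out["retained"] = (rpkm_wt > rpkm_min) & (
        wt_only | ((out["ko_loss_fdr"] < fdr_cut) & (out["ko_loss_logFC"] < 0))
    )
    return out.set_index("peak_id")


def annotate_cis_class(
    validated: pd.DataFrame,
    k27ac_peaks: IntervalSet,
    tss_windows: IntervalSet,
) -> pd.DataFrame:
    """Attach the promoter/enhancer class to validated peaks.

    A peak overlapping any TSS window is a promoter regardless of
    acetylation (TSS precedence); otherwise an overlap with an H3K27ac
    peak makes it an enhancer; otherwise the class is missing and the peak
    is excluded from enhancer-level analyses.
    """
    peaks = IntervalSet(
        GenomicInterval(r.chrom, int(r.start), int(r.end), str(i))
        for i, r in validated.iterrows()
    )
    at_tss = _overlap_flags(peaks, tss_windows)
    at_k27 = _overlap_flags(peaks, k27ac_peaks)
    order = {iv.id: j for j, iv in enumerate(peaks)}
    idx = np.array([order[str(i)] for i in validated.index])
    out = validated.copy()
    cls = np.where(at_tss[idx], "promoter", np.where(at_k27[idx], "enhancer", None))
    out["cis_class"] = cls
    return out


@dataclass
class SuperEnhancerCall:
    """Result of the rank-curve super-enhancer call."""

    flags: np.ndarray        # aligned with the input enhancers
    curve: pd.DataFrame      # ascending-rank curve with scaled coordinates
    cutoff_rank: int | None  # rank index of the tangent crossing (or None)


def call_super_enhancers(
    enhancers: IntervalSet,
    k27ac_signal: np.ndarray,
    min_enhancers: int = 10,
) -> SuperEnhancerCall:
    """Tangent-rule super-enhancer call on signal density.

    Density is normalised H3K27ac signal per bp of enhancer.  Enhancers are
    ranked ascending; rank and density are rescaled to the unit square; the
    slope of the curve (central differences) is examined and every enhancer
    strictly above the first rank where the slope exceeds 1 is flagged.
    A flat (all-equal) density curve yields zero super-enhancers.
    """
    sig = np.asarray(k27ac_signal, dtype=float)
    n = len(sig)
    if n != len(enhancers):
        raise ValueError("signal vector does not align with enhancers")
    if n < min_enhancers:
        raise ValueError(f"need >= {min_enhancers} enhancers to rank")
    lengths = np.array([iv.length for iv in enhancers], dtype=float)
    density = sig / lengths
    order = np.argsort(density, kind="stable")
    y = density[order]
    flags = np.zeros(n, dtype=bool)
    span = y[-1] - y[0]
    curve = pd.DataFrame({"rank": np.arange(n), "density": y})
    curve["scaled_rank"] = np.arange(n) / (n - 1)
    if span <= 0:
        curve["scaled_density"] = 0.0
        return SuperEnhancerCall(flags, curve, None)
    ys = (y - y[0]) / span
    curve["scaled_density"] = ys
    x = curve["scaled_rank"].to_numpy()
    slope = np.gradient(ys, x)
    crossing = np.flatnonzero(slope > 1.0)
    if crossing.size == 0:
        return SuperEnhancerCall(flags, curve, None)
    cut = int(crossing[0])
    flags[order[cut + 1 :]] = True
    return SuperEnhancerCall(flags, curve, cut)


def assign_target_genes(
    peaks: pd.DataFrame,
    genes: list[GeneModel],
    expression_flags: pd.DataFrame,
    max_dist: int = 50_000,
) -> pd.DataFrame:
    """Link peaks to genes that lose expression in both knockouts.

    One row per (peak, gene) pair whose unsigned gap to the gene body is at
    most ``max_dist`` and whose gene carries ``down_in_both``.  Peaks may
    link several genes and vice versa.
    """
    down = expression_flags.index[expression_flags["down_in_both"]]
    gene_by_id = {g.gene_id: g for g in genes}
    down_genes = [gene_by_id[g] for g in down if g in gene_by_id]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in down_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.start, g.gene_id))
    rows = []
    for peak_id, r in peaks.iterrows():
        for g in by_chrom.get(r.chrom, []):
            d = max(0, g.start - int(r.end), int(r.start) - g.end)
            if d <= max_dist:
                flags = expression_flags.loc[g.gene_id]
                rows.append(
                    {
                        "peak_id": peak_id,
                        "gene_id": g.gene_id,
                        "distance": d,
                        "gene_down_in_both_ko": True,
                        "gene_osteogenic": bool(flags["osteogenic"]),
                    }
                )
    return pd.DataFrame(
        rows, columns=["peak_id", "gene_id", "distance",
                       "gene_down_in_both_ko", "gene_osteogenic"]
    )


def temporal_classify(
    annotated: pd.DataFrame,
    targets: pd.DataFrame,
    expression_flags: pd.DataFrame,
    timepoint: str,
) -> pd.DataFrame:
    """Temporal class per enhancer-gene link for one binding timepoint.

    For enhancers bound at D0: links whose gene shows no significant WT
    increase over any of D0-D3 / D0-D6 / D3-D6 are stem-cell enhancers.
    For enhancers bound at D3 (D6): links whose gene increases during WT
    differentiation are early (late) osteogenic enhancers.  Links failing
    the timepoint's rule, and enhancers with no link at all, are
    ``unclassified``.  Classification is per link; conflicting links are
    reported, not resolved.
    """
    if timepoint not in TEMPORAL_TIMEPOINT_CLASS:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    target_class = TEMPORAL_TIMEPOINT_CLASS[timepoint]
    enhancer_ids = annotated.index[annotated["cis_class"] == "enhancer"]
    links = targets[targets["peak_id"].isin(enhancer_ids)]
    rows = []
    linked = set()
    for r in links.itertuples():
        osteo = bool(expression_flags.loc[r.gene_id, "osteogenic"])
        if timepoint == "D0":
            cls = "stem" if not osteo else "unclassified"
        else:
            cls = target_class if osteo else "unclassified"
        linked.add(r.peak_id)
        rows.append(
            {"peak_id": r.peak_id, "gene_id": r.gene_id,
             "distance": r.distance, "temporal_class": cls}
        )
    for pid in enhancer_ids:
        if pid not in linked:
            rows.append(
                {"peak_id": pid, "gene_id": None, "distance": None,
                 "temporal_class": "unclassified"}
            )
    return pd.DataFrame(
        rows, columns=["peak_id", "gene_id", "distance", "temporal_class"]
    )
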