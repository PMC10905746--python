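"""Transcription-factor co-occupancy statistics.

Quantifies whether RUNX2 binding concentrates on BRD4-bound enhancers
(Fisher's exact test over an enhancer universe), which RUNX2 peaks lose
occupancy when BRD4 is knocked out (the same NB exact machinery used for
peak validation), and how per-class enhancer RUNX2 signal differs between
genotypes (unpaired two-tailed Student's t-test with pooled variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import differential as diff
from . import intervals as gi
from .classify import _overlap_flags, _peak_ids
from .intervals import IntervalSet
from .signal import CountMatrix, rpkm_matrix


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for (in set A) x (in set B) over a common universe."""

    a: int  # A and B
    b: int  # A only
    c: int  # B only
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact p and odds ratio (Haldane-corrected on zeros).

    The p-value sums hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed the observed one.
    """
    arr = table.as_array()
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    if (arr == 0).any():
        a, b, c, d = (x + 0.5 for x in (table.a, table.b, table.c, table.d))
    else:
        a, b, c, d = table.a, table.b, table.c, table.d
    odds = (a * d) / (b * c)
    return float(odds), float(p)


def fisher_cooccupancy(
    brd4_bound: IntervalSet,
    runx2_peaks: IntervalSet,
    universe: IntervalSet,
) -> tuple[float, float, ContingencyTable2x2]:
    """Fisher exact test of BRD4 x RUNX2 co-occupancy over a region universe.

    Each universe member is classified by overlap with the BRD4-bound set
    and with the RUNX2 peak set; returns (odds ratio, two-sided p, table).
    """
    if len(universe) == 0:
        raise ValueError("co-occupancy universe is empty")
    in_brd4 = _overlap_flags(universe, brd4_bound)
    in_runx2 = _overlap_flags(universe, runx2_peaks)
    table = ContingencyTable2x2(
        int(np.sum(in_brd4 & in_runx2)),
        int(np.sum(in_brd4 & ~in_runx2)),
        int(np.sum(~in_brd4 & in_runx2)),
        int(np.sum(~in_brd4 & ~in_runx2)),
    )
    odds, p = fisher_exact_2x2(table)
    return odds, p, table


def classify_runx2_loss(
    runx2_peaks_wt: IntervalSet,
    runx2_peaks_ko: IntervalSet,
    counts: CountMatrix,
    lib_sizes: np.ndarray | None = None,
    fdr_cut: float = 0.05,
    phi: float | None = None,
    misexpressed_links: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Flag RUNX2 peaks losing occupancy in the BRD4 knockout.

    Per WT RUNX2 peak: ``sig_loss`` (NB exact FDR < cutoff with WT > KO,
    total-mapped-read offsets by default) or ``wt_specific`` (no overlap
    with any KO-called peak); ``lost`` is their union.  When a peak-to-gene
    link table for misexpressed genes is given, ``near_misexpressed_gene``
    marks peaks with at least one link (<= 50 kb convention upstream).
    """
    if counts.features is None or list(counts.features) != list(runx2_peaks_wt):
        raise ValueError("count matrix does not cover the WT RUNX2 peaks")
    wt = counts.columns(lambda s: s.genotype == "WT")
    ko = counts.columns(lambda s: s.genotype != "WT")
    if lib_sizes is None:
        lib_sizes = np.array([s.primary_mapped_reads for s in counts.samples], float)
    de = diff.exact_test_table(
        counts.counts, _peak_ids(runx2_peaks_wt), wt, ko,
        np.asarray(lib_sizes, dtype=float), phi=phi,
    )
    out = runx2_peaks_wt.to_frame().drop(columns=["id", "strand"])
    out["peak_id"] = _peak_ids(runx2_peaks_wt)
    out = out.set_index("peak_id")
    out["avg_wt_rpkm"] = rpkm_matrix(counts, wt).mean(axis=1)
    out["avg_ko_rpkm"] = rpkm_matrix(counts, ko).mean(axis=1)
    out["runx2_logFC"] = de["logFC"].to_numpy()
    out["runx2_fdr"] = de["fdr"].to_numpy()
    out["sig_loss"] = (out["runx2_fdr"] <= fdr_cut) & (out["runx2_logFC"] < 0)
    out["wt_specific"] = ~_overlap_flags(runx2_peaks_wt, runx2_peaks_ko)
    out["lost"] = out["sig_loss"] | out["wt_specific"]
    if misexpressed_links is not None:
        near = set(misexpressed_links["peak_id"])
        out["near_misexpressed_gene"] = [pid in near for pid in out.index]
    return out


def class_signal_ttest(
    signal_by_condition: pd.DataFrame,
    classes: pd.Series,
) -> pd.DataFrame:
    """Per-class unpaired two-tailed Student's t on enhancer signal.

    ``signal_by_condition`` has one row per enhancer and two columns (e.g.
    WT and KO mean RPKM); ``classes`` assigns each enhancer a class label.
    Enhancers are treated as independent observations, as is conventional
    for this comparison.  Classes with < 2 members are skipped; degenerate
    (zero pooled variance) classes report a missing p-value.
    """
    if signal_by_condition.shape[1] != 2:
        raise ValueError("expected exactly two condition columns")
    cond_a, cond_b = signal_by_condition.columns
    rows = []
    for cls, idx in classes.groupby(classes).groups.items():
        sub = signal_by_condition.loc[idx]
        if len(sub) < 2:
            continue
        x, y = sub[cond_a].to_numpy(float), sub[cond_b].to_numpy(float)
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
            t, p = (0.0, np.nan) if np.mean(x) == np.mean(y) else (np.inf, np.nan)
        else:
            t, p = stats.ttest_ind(x, y, equal_var=True)
        rows.append(
            {
                "class": cls,
                "n": len(sub),
                f"mean_{cond_a}": float(np.mean(x)),
                f"mean_{cond_b}": float(np.mean(y)),
                "t": float(t),
                "pvalue": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("class")
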