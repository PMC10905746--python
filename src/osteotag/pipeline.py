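"""Configuration-driven orchestration of the full analysis.

Stage order mirrors the analysis narrative: signal (spike factors, peak
calling, counting) -> differential (NB exact tests with spike offsets for
occupancy, library-size offsets for expression) -> classification ladder
(validation, promoter/enhancer, super-enhancers, 50-kb targets, temporal
classes) -> co-occupancy -> motif enrichment.  Everything here is a thin
shell over the library modules; no computation lives only in the CLI.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd
import yaml

from . import classify as cl
from . import cooccupancy as co
from . import differential as diff
from . import intervals as gi
from . import motif as mo
from . import signal as sig
from .intervals import GeneModel, GenomicInterval, IntervalSet
from .motif import MotifEnrichment, PositionWeightMatrix, RUNX_EXAMPLE_PWM
from .signal import BinnedTrack, CountMatrix, SampleDesign

log = logging.getLogger("osteotag")

TIMEPOINTS = ("D0", "D3", "D6")


@dataclass
class PipelineConfig:
    """Thresholds and knobs for one pipeline run.

    Defaults are the analysis constants of the study design: RPKM > 1 peak
    filter, FDR < 0.05, TSS +/- 500 bp promoter window (1 kb is the
    documented alternative), 50-kb target distance.
    """

    rpkm_min: float = 1.0
    fdr: float = 0.05
    logfc_cut: float = 0.0
    tss_halfwidth: int = 500
    target_max_dist: int = 50_000
    peak_qvalue: float = 0.1
    peak_merge_gap: int = 500
    peak_min_len: int = 200
    peak_local_window: int = 10_000
    se_min_enhancers: int = 10
    primary_genome_bp: int | None = None  # None -> sum of track chromosomes

    def __post_init__(self) -> None:
        for name in ("rpkm_min", "fdr", "tss_halfwidth", "target_max_dist",
                     "peak_qvalue", "peak_merge_gap", "peak_min_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(
                f"unknown configuration keys: {sorted(unknown)}; "
                f"known keys: {sorted(known)}"
            )
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("pipeline config must be a flat key/value document")
        return cls.from_mapping(data)


@dataclass
class PipelineResult:
    """All per-stage tables of one run plus the JSON summary."""

    validated: dict[str, pd.DataFrame]
    annotated: dict[str, pd.DataFrame]
    enhancer_universe: dict[str, IntervalSet]
    se_calls: dict[str, tuple[IntervalSet, np.ndarray]]
    expression: dict[str, pd.DataFrame]
    targets: dict[str, pd.DataFrame]
    temporal: dict[str, pd.DataFrame]
    runx2: pd.DataFrame
    runx2_classes: pd.DataFrame
    fisher: dict
    motif: MotifEnrichment
    summary: dict


def _samples(bundle, **kw) -> list[SampleDesign]:
    out = []
    for s in bundle.samples:
        if all(getattr(s, k) == v for k, v in kw.items()):
            out.append(s)
    return out


def _pool(bundle, samples) -> BinnedTrack:
    return sig.pool_tracks([bundle.tracks[s.sample_id] for s in samples])


def _call(track, cfg: PipelineConfig) -> IntervalSet:
    return sig.call_broad_peaks(
        track, qvalue_cutoff=cfg.peak_qvalue, merge_gap=cfg.peak_merge_gap,
        min_len=cfg.peak_min_len, local_window=cfg.peak_local_window,
    )


def _named(peaks: IntervalSet, prefix: str) -> IntervalSet:
    return IntervalSet(
        [GenomicInterval(p.chrom, p.start, p.end, f"{prefix}_{k:04d}")
         for k, p in enumerate(peaks)],
        presorted=True,
    )


def run(bundle, config: PipelineConfig | None = None,
        pwm: PositionWeightMatrix = RUNX_EXAMPLE_PWM) -> PipelineResult:
    """Execute the full analysis on an input bundle.

    ``bundle`` provides ``tracks`` (sample_id -> BinnedTrack), ``samples``
    (SampleDesign list covering occupancy and RNA), ``rna`` (gene-level
    CountMatrix), ``genes`` (GeneModel list) and ``sequences`` (region ->
    sequence).  Stage failures abort with the stage name in the message.
    """
    cfg = config or PipelineConfig()
    genes = bundle.genes
    gene_lengths = np.array([g.end - g.start for g in genes], dtype=float)
    gene_ids = [g.gene_id for g in genes]
    genome_bp = cfg.primary_genome_bp or sum(
        next(iter(bundle.tracks.values())).chrom_length(c)
        for c in next(iter(bundle.tracks.values())).data
    )
    tssw = gi.tss_windows(genes, cfg.tss_halfwidth)

    # ----- expression stage (shared across timepoints)
    stage = "differential-expression"
    try:
        rna = bundle.rna
        if set(rna.feature_ids) != set(gene_ids):
            raise ValueError("RNA matrix and gene table cover different genes")
        row = [rna.feature_ids.index(g) for g in gene_ids]
        counts = rna.counts[row, :]
        rna_groups = [f"{s_.genotype}_{s_.timepoint}" for s_ in rna.samples]
        libs = diff.expression_lib_sizes(counts, rna_groups)
        raw_libs = np.array([s.primary_mapped_reads for s in rna.samples], float)
        masks = {
            (gt, tp): np.array([s.genotype == gt and s.timepoint == tp
                                for s in rna.samples])
            for gt in ("WT", "KO1", "KO2") for tp in TIMEPOINTS
        }
        def tested(mask_a, mask_b):
            de = diff.exact_test_table(counts, gene_ids, mask_a, mask_b, libs)
            # independent filtering: pick the mean-count cutoff maximising
            # BH rejections, then re-adjust on the surviving set
            mean_counts = (de["mean_a"] + de["mean_b"]) / 2
            grid = np.unique(np.concatenate(
                [[0.0], np.quantile(mean_counts, [0.1, 0.2, 0.3, 0.4, 0.5])]))
            _, fdr, _ = diff.independent_filter(
                mean_counts.to_numpy(), de["pvalue"].to_numpy(), grid, alpha=cfg.fdr)
            de["fdr"] = np.where(np.isnan(fdr), 1.0, fdr)
            return de

        trajectory = {}
        for key, (t0, t1) in {"d0_d3": ("D0", "D3"), "d0_d6": ("D0", "D6"),
                              "d3_d6": ("D3", "D6")}.items():
            trajectory[key] = tested(masks[("WT", t0)], masks[("WT", t1)])
        expression = {}
        for tp in TIMEPOINTS:
            de1 = tested(masks[("WT", tp)], masks[("KO1", tp)])
            de2 = tested(masks[("WT", tp)], masks[("KO2", tp)])
            wt = masks[("WT", tp)]
            wt_rpkm = pd.Series(
                sig.rpkm(counts[:, wt], gene_lengths, raw_libs[wt]).mean(axis=1),
                index=gene_ids,
            )
            expression[tp] = diff.classify_expression_changes(
                de1, de2, wt_rpkm, trajectory,
                rpkm_min=cfg.rpkm_min, logfc_cut=cfg.logfc_cut, fdr_cut=cfg.fdr,
            )
            log.info("expression %s: %d genes down in both knockouts",
                     tp, int(expression[tp]["down_in_both"].sum()))
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # ----- occupancy stages, per timepoint
    validated, annotated, universe, se_calls = {}, {}, {}, {}
    targets, temporal = {}, {}
    for tp in TIMEPOINTS:
        stage = f"occupancy-{tp}"
        try:
            wt = _samples(bundle, assay="BRD4", genotype="WT", timepoint=tp)
            ko = [s for s in _samples(bundle, assay="BRD4", timepoint=tp)
                  if s.genotype != "WT"]
            pooled = _named(_call(_pool(bundle, wt), cfg), f"brd4_{tp.lower()}")
            rep_peaks = [_call(bundle.tracks[s.sample_id], cfg) for s in wt]
            ko_peaks = _call(_pool(bundle, ko), cfg)
            occ_samples = wt + ko
            counts = sig.count_matrix_from_tracks(bundle.tracks, pooled, occ_samples)
            factors = sig.scaling_factors(occ_samples, genome_bp)
            efflib = np.array([1.0 / factors[s.sample_id] for s in occ_samples])
            validated[tp] = cl.validate_peaks(
                pooled, rep_peaks, ko_peaks, counts, efflib,
                rpkm_min=cfg.rpkm_min, fdr_cut=cfg.fdr,
            )
            log.info("%s: %d pooled peaks, %d retained", tp, len(pooled),
                     int(validated[tp]["retained"].sum()))

            k27 = _samples(bundle, assay="H3K27ac", genotype="WT", timepoint=tp)
            k27_peaks = _named(_call(_pool(bundle, k27), cfg), f"k27_{tp.lower()}")
            annotated[tp] = cl.annotate_cis_class(validated[tp], k27_peaks, tssw)
            universe[tp] = gi.subtract_overlapping(k27_peaks, tssw)

            k27_counts = sig.count_matrix_from_tracks(
                bundle.tracks, universe[tp], k27)
            k27_cpm = sig.cpm(k27_counts.counts).mean(axis=1)
            se = cl.call_super_enhancers(
                universe[tp], k27_cpm, min_enhancers=cfg.se_min_enhancers)
            se_calls[tp] = (universe[tp], se.flags)

            retained = annotated[tp][annotated[tp]["retained"]]
            targets[tp] = cl.assign_target_genes(
                retained, genes, expression[tp], max_dist=cfg.target_max_dist)
            temporal[tp] = cl.temporal_classify(
                retained, targets[tp], expression[tp], tp)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # ----- RUNX2 co-occupancy (D0 assay)
    stage = "cooccupancy"
    try:
        rx_wt = _samples(bundle, assay="RUNX2", genotype="WT")
        rx_ko = [s for s in _samples(bundle, assay="RUNX2") if s.genotype != "WT"]
        rx_peaks = _named(_call(_pool(bundle, rx_wt), cfg), "runx2")
        rx_ko_peaks = _call(_pool(bundle, rx_ko), cfg)
        rx_samples = rx_wt + rx_ko
        rx_counts = sig.count_matrix_from_tracks(bundle.tracks, rx_peaks, rx_samples)
        rx_links = cl.assign_target_genes(
            rx_counts.to_frame().set_index("feature_id").rename_axis("peak_id"),
            genes, expression["D0"], max_dist=cfg.target_max_dist)
        runx2 = co.classify_runx2_loss(
            rx_peaks, rx_ko_peaks, rx_counts, fdr_cut=cfg.fdr,
            misexpressed_links=rx_links)
        log.info("RUNX2: %d WT peaks, %d lost in knockout", len(rx_peaks),
                 int(runx2["lost"].sum()))

        brd4_union = gi.merge(IntervalSet(
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for tp in TIMEPOINTS
            for _, r in validated[tp][validated[tp]["retained"]].iterrows()
        ))
        uni = universe["D0"]
        odds, p, table = co.fisher_cooccupancy(brd4_union, rx_peaks, uni)
        fisher = {"odds_ratio": odds, "pvalue": p,
                  "table": [table.a, table.b, table.c, table.d]}

        # class per universe enhancer: first matching temporal class, else unbound
        classes = pd.Series("unbound", index=[iv.id for iv in uni])
        for tp in TIMEPOINTS:
            cls_name = cl.TEMPORAL_TIMEPOINT_CLASS[tp]
            ids = set(temporal[tp].loc[
                temporal[tp]["temporal_class"] == cls_name, "peak_id"])
            rows = annotated[tp].loc[annotated[tp].index.isin(ids)]
            cls_peaks = IntervalSet(
                GenomicInterval(r.chrom, int(r.start), int(r.end))
                for _, r in rows.iterrows())
            hit = cl._overlap_flags(uni, cls_peaks)
            for iv, h in zip(uni, hit):
                if h and classes[iv.id] == "unbound":
                    classes[iv.id] = cls_name
        uni_counts = sig.count_matrix_from_tracks(bundle.tracks, uni, rx_samples)
        wt_mask = uni_counts.columns(lambda s: s.genotype == "WT")
        rx_rpkm = pd.DataFrame(
            {
                "wt": sig.rpkm_matrix(uni_counts, wt_mask).mean(axis=1),
                "ko": sig.rpkm_matrix(uni_counts, ~wt_mask).mean(axis=1),
            },
            index=[iv.id for iv in uni],
        )
        runx2_classes = co.class_signal_ttest(rx_rpkm, classes)
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # ----- motif enrichment at bound osteogenic enhancers
    stage = "motif"
    try:
        seq_regions = IntervalSet(
            GenomicInterval(k.split(":")[0], *map(int, k.split(":")[1].split("-")))
            for k in bundle.sequences
        )

        def region_seqs(peaks: IntervalSet) -> list[str]:
            out = []
            hit = gi.intersect(seq_regions, peaks)
            for iv in hit:
                out.append(bundle.sequences[f"{iv.chrom}:{iv.start}-{iv.end}"])
            return out

        osteo_peaks = []
        for tp in ("D3", "D6"):
            cls_name = cl.TEMPORAL_TIMEPOINT_CLASS[tp]
            ids = set(temporal[tp].loc[
                temporal[tp]["temporal_class"] == cls_name, "peak_id"])
            for _, r in annotated[tp].loc[annotated[tp].index.isin(ids)].iterrows():
                osteo_peaks.append(GenomicInterval(r.chrom, int(r.start), int(r.end)))
        osteo_set = gi.merge(IntervalSet(osteo_peaks)) if osteo_peaks else IntervalSet()
        unbound = gi.subtract_overlapping(universe["D0"], brd4_union)
        bound_seqs = region_seqs(osteo_set)
        unbound_seqs = region_seqs(unbound)
        if bound_seqs and unbound_seqs:
            motif = mo.motif_enrichment(bound_seqs, unbound_seqs, pwm)
        else:
            motif = None  # degenerate run (e.g. no osteogenic enhancers)
            log.warning("motif stage skipped: empty bound or background set")
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    summary = {
        "config": asdict(cfg),
        "timepoints": {},
        "fisher_cooccupancy": fisher,
        "motif": None if motif is None else {
            "fraction_bound": motif.fraction_bound,
            "fraction_background": motif.fraction_background,
            "odds_ratio": motif.odds_ratio,
            "pvalue": motif.pvalue,
        },
    }
    for tp in TIMEPOINTS:
        ann = annotated[tp]
        ret = ann[ann["retained"]]
        uni_iv = universe[tp]
        flags = se_calls[tp][1]
        bound_mask = cl._overlap_flags(uni_iv, brd4_union)
        n_b = int(bound_mask.sum())
        n_u = int((~bound_mask).sum())
        summary["timepoints"][tp] = {
            "n_pooled_peaks": int(len(ann)),
            "n_retained": int(len(ret)),
            "n_promoters": int((ret["cis_class"] == "promoter").sum()),
            "n_enhancers": int((ret["cis_class"] == "enhancer").sum()),
            "n_enhancer_universe": int(len(uni_iv)),
            "n_super_enhancers": int(flags.sum()),
            "se_frequency_brd4_bound": float(flags[bound_mask].mean()) if n_b else float("nan"),
            "se_frequency_unbound": float(flags[~bound_mask].mean()) if n_u else float("nan"),
            "n_target_links": int(len(targets[tp])),
            "n_down_in_both": int(expression[tp]["down_in_both"].sum()),
        }

    return PipelineResult(
        validated=validated, annotated=annotated, enhancer_universe=universe,
        se_calls=se_calls, expression=expression, targets=targets,
        temporal=temporal, runx2=runx2, runx2_classes=runx2_classes,
        fisher=fisher, motif=motif, summary=summary,
    )


def write_result(result: PipelineResult, outdir) -> None:
    """Write master tables (TSV), BED exports and the JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tp in TIMEPOINTS:
        ann = result.annotated[tp]
        master = ann.merge(
            result.targets[tp].set_index("peak_id"),
            left_index=True, right_index=True, how="left",
        )
        master.to_csv(outdir / f"brd4_peaks_{tp}.tsv", sep="\t")
        result.temporal[tp].to_csv(
            outdir / f"temporal_enhancers_{tp}.tsv", sep="\t", index=False)
        retained = ann[ann["retained"]]
        for cls in ("promoter", "enhancer"):
            rows = retained[retained["cis_class"] == cls]
            gi.write_bed(
                IntervalSet(
                    GenomicInterval(r.chrom, int(r.start), int(r.end), str(i))
                    for i, r in rows.iterrows()),
                outdir / f"brd4_{cls}s_{tp}.bed",
            )
        uni, flags = result.se_calls[tp]
        gi.write_bed(
            IntervalSet([iv for iv, f in zip(uni, flags) if f], presorted=True),
            outdir / f"super_enhancers_{tp}.bed",
        )
    result.runx2.to_csv(outdir / "runx2_peaks.tsv", sep="\t")
    result.runx2_classes.to_csv(outdir / "runx2_class_ttest.tsv", sep="\t")
    (outdir / "summary.json").write_text(json.dumps(result.summary, indent=1))


def load_bundle(indir):
    """Load a written bundle (sample sheet, tracks, genes, RNA, FASTA)."""
    indir = Path(indir)
    meta = json.loads((indir / "bundle.json").read_text())
    samples = sig.read_sample_sheet(indir / "samples.tsv")
    genes = gi.read_gene_table(indir / "genes.tsv")
    rna_samples = [s for s in samples if s.assay == "RNA"]
    rna = CountMatrix.from_tsv(indir / "rna_counts.tsv", rna_samples)
    tracks = {}
    tdir = indir / "tracks"
    for s in samples:
        if s.assay == "RNA":
            continue
        tracks[s.sample_id] = sig.read_bedgraph(
            tdir / f"{s.sample_id}.bedgraph", meta["bin_size"],
            meta["chrom_lengths"],
        )
    sequences = mo.read_fasta(indir / "element_sequences.fa")
    return SimpleNamespace(
        samples=samples, genes=genes, rna=rna, tracks=tracks,
        sequences=sequences, chrom_lengths=meta["chrom_lengths"],
    )


#: floors used by the demo's self-check (and the CLI exit status)
DEMO_FLOORS = {
    "validated_peaks": 0.9, "target_links": 0.9, "temporal_classes": 0.9,
    "super_enhancer_jaccard": 0.8,
}


def check_metrics(metrics: dict, floors: dict = DEMO_FLOORS) -> list[str]:
    """Return a list of floor violations (empty means all good)."""
    bad = []
    for key in ("validated_peaks", "target_links", "temporal_classes"):
        for tp, st in metrics[key].items():
            for m in ("precision", "recall"):
                if st[m] < floors[key]:
                    bad.append(f"{key}/{tp}/{m}={st[m]:.3f} < {floors[key]}")
    if metrics["super_enhancers"]["jaccard"] < floors["super_enhancer_jaccard"]:
        bad.append(
            f"super_enhancers/jaccard={metrics['super_enhancers']['jaccard']:.3f}"
            f" < {floors['super_enhancer_jaccard']}"
        )
    return bad


def demo(seed: int = 0, outdir=None, generator_config=None, config=None):
    """One-command end-to-end run: simulate, analyse, evaluate.

    Returns ``(bundle, result, metrics)``; writes tables and the metrics
    report when ``outdir`` is given.
    """
    from . import simulate as sim

    gcfg = generator_config or sim.GeneratorConfig(seed=seed)
    bundle = sim.generate(gcfg)
    result = run(bundle, config)
    metrics = sim.evaluate(result, bundle)
    if outdir is not None:
        outdir = Path(outdir)
        write_result(result, outdir)
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1))
    return bundle, result, metrics
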