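"""Seeded synthetic data with planted ground truth for the whole pipeline.

The generator lays out a toy two-chromosome genome on a 45-kb block
lattice.  Alternating "target" and "spacer" blocks carry, respectively, a
downregulated gene plus its bound enhancer (gap 2-20 kb) and an optional
unaffected gene; decoy (unbound) enhancers live in a separate tail region
of each chromosome behind a buffer block.  The lattice guarantees, by
construction, that every bound enhancer is within 50 kb of exactly its own
downregulated gene and that every decoy is more than 50 kb from any
downregulated gene, with margins far larger than peak-boundary noise.

Occupancy counts are drawn at bin resolution.  Replicate noise is a
per-(element, sample) gamma multiplier shared across the element's bins,
so that peak-level counts are exactly NB(mu, phi); background bins are
Poisson.  Knockout samples lose element signal by a global factor while
spike-in mass per cell stays constant, and every library is re-sequenced
to the wild-type depth -- so the loss is (nearly) invisible to per-library
normalisation and only the spike channel reveals it, mirroring the
experimental rationale for spike-in calibration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import intervals as gi
from . import signal as sig
from .intervals import GeneModel, GenomicInterval, IntervalSet
from .motif import PositionWeightMatrix, RUNX_EXAMPLE_PWM, write_fasta
from .signal import BinnedTrack, CountMatrix, SampleDesign

TIMEPOINTS = ("D0", "D3", "D6")
CLASS_BY_TIMEPOINT = {"D0": "stem", "D3": "early_osteogenic", "D6": "late_osteogenic"}
BOUND_FLAG = {"D0": "bound_d0", "D3": "bound_d3", "D6": "bound_d6"}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic genome and assays.

    Defaults emulate a high signal-to-noise CUT&Tag experiment (most
    fragments in peaks), a 4x global occupancy collapse in the knockout,
    4 occupancy and 4 expression replicates, NB dispersion 0.1, and a
    heavy-tailed acetylation subset defining super-enhancers.
    """

    seed: int = 0
    chrom_names: tuple[str, ...] = ("chr1", "chr2")
    chrom_length: int = 10_500_000
    block_size: int = 45_000
    bin_size: int = 100

    # element/gene layout
    n_stem: int = 40
    n_early: int = 40
    n_late: int = 40
    n_flat_genes: int = 480
    n_silent_genes: int = 20
    n_promoter_elements: int = 20
    n_unbound_enhancers: int = 180
    decoys_per_block: int = 2
    gene_offset: tuple[int, int] = (2_000, 6_000)
    gene_length: tuple[int, int] = (6_000, 10_000)
    enhancer_gap: tuple[int, int] = (2_000, 20_000)
    enhancer_length: tuple[int, int] = (1_000, 2_000)
    promoter_halfwidth: int = 300

    # occupancy counts
    phi: float = 0.1
    mu_background: float = 0.1
    brd4_mu_element: float = 300.0
    k27_mu_element: float = 12.0
    runx2_mu_element: float = 8.0
    ko_loss_factor: float = 0.25
    runx2_ko_loss_factor: float = 0.25
    spike_ratio: float = 0.1
    brd4_reps: int = 4
    k27_reps: int = 2
    runx2_reps: int = 2

    # acetylation tail / super-enhancers
    k27_sigma: float = 0.6
    k27_floor: float = 0.5
    k27_bound_meanlog: float = 0.8
    se_fraction: float = 0.1
    se_boost: float = 10.0

    # co-occupancy and motifs
    runx2_rate_bound: float = 0.6
    runx2_rate_unbound: float = 0.1
    motif_rate_bound_osteo: float = 0.6
    motif_rate_background: float = 0.1

    # expression
    rna_reps: int = 4
    rna_base_meanlog: float = math.log(150.0)
    rna_base_sigma: float = 1.0
    rna_min_mu: float = 5.0
    silent_mu: float = 0.2
    ko_logfc: float = -1.5
    osteo_logfc: float = 2.0

    target_max_dist: int = 50_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("phi", "mu_background", "ko_loss_factor", "spike_ratio"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    @property
    def genome_bp(self) -> int:
        return self.chrom_length * len(self.chrom_names)


@dataclass
class SimulatedBundle:
    """Everything the pipeline consumes, plus the planted truth."""

    config: GeneratorConfig
    genes: list[GeneModel]
    elements: IntervalSet
    truth: pd.DataFrame            # one row per planted element
    gene_truth: pd.DataFrame       # one row per gene (program)
    truth_links: dict[str, pd.DataFrame]
    samples: list[SampleDesign]
    tracks: dict[str, BinnedTrack]
    rna: CountMatrix
    sequences: dict[str, str]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return self.config.chrom_lengths


def _uniform_int(rng, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def generate_genome(config: GeneratorConfig):
    """Place genes and regulatory elements; return (genes, elements, truth).

    Raises when the requested element counts cannot be packed on the block
    lattice, naming the violated capacity.
    """
    rng = np.random.default_rng([config.seed, 1])
    nb = config.chrom_length // config.block_size
    n_chrom = len(config.chrom_names)
    n_targets = config.n_stem + config.n_early + config.n_late
    t_per_chrom = [n_targets // n_chrom + (i < n_targets % n_chrom) for i in range(n_chrom)]
    decoy_blocks_needed = math.ceil(config.n_unbound_enhancers / config.decoys_per_block) if config.n_unbound_enhancers else 0

    d_per_chrom = [
        decoy_blocks_needed // n_chrom + (i < decoy_blocks_needed % n_chrom)
        for i in range(n_chrom)
    ]
    t_blocks: list[tuple[str, int]] = []
    f_blocks: list[tuple[str, int]] = []
    d_blocks: list[tuple[str, int]] = []
    for ci, chrom in enumerate(config.chrom_names):
        tc, dc = t_per_chrom[ci], d_per_chrom[ci]
        # body: alternating target/spacer; one buffer; decoy region;
        # any remaining tail blocks become extra spacers for null genes
        if 2 * tc + 1 + dc > nb:
            raise ValueError(
                f"capacity: {tc} target + {dc} decoy blocks need "
                f"{2 * tc + 1 + dc} blocks but {chrom} has {nb}"
            )
        t_blocks += [(chrom, 2 * i) for i in range(tc)]
        f_blocks += [(chrom, 2 * i + 1) for i in range(tc)]
        d_blocks += [(chrom, 2 * tc + 1 + j) for j in range(dc)]
        f_blocks += [(chrom, j) for j in range(2 * tc + 1 + dc, nb)]
    flat_slots = [(chrom, block, slot) for chrom, block in f_blocks for slot in (0, 1)]
    if len(flat_slots) < config.n_flat_genes:
        raise ValueError(
            f"capacity: {config.n_flat_genes} unaffected genes need as many "
            f"spacer-block slots, only {len(flat_slots)} available"
        )
    if len(d_blocks) < decoy_blocks_needed:
        raise ValueError(
            f"capacity: {decoy_blocks_needed} decoy blocks needed, only "
            f"{len(d_blocks)} available in the tail regions"
        )

    genes: list[GeneModel] = []
    gene_rows = []
    elements: list[GenomicInterval] = []
    el_rows = []

    def place_gene(chrom, block, program, gid, slot=0):
        # slot 1 parks a second gene in the back half of a spacer block
        base = block * config.block_size + slot * 18_000
        off = _uniform_int(rng, config.gene_offset)
        length = _uniform_int(rng, config.gene_length)
        strand = "+" if rng.random() < 0.5 else "-"
        g = GeneModel(
            GenomicInterval(chrom, base + off, base + off + length, gid, strand),
            gid, strand,
        )
        genes.append(g)
        gene_rows.append({"gene_id": gid, "program": program, "chrom": chrom,
                          "start": g.start, "end": g.end, "strand": strand})
        return g

    def add_element(chrom, start, end, kind, **flags):
        eid = f"el_{len(elements):04d}"
        elements.append(GenomicInterval(chrom, start, end, eid))
        row = {
            "element_id": eid, "chrom": chrom, "start": start, "end": end,
            "kind": kind, "temporal_class": "none",
            "bound_d0": False, "bound_d3": False, "bound_d6": False,
            "runx2_bound": False, "super_enhancer": False,
            "linked_gene": None, "motif_planted": False, "k27_multiplier": 1.0,
        }
        row.update(flags)
        el_rows.append(row)
        return row

    # --- target blocks: downregulated gene + its bound enhancer
    classes = (
        ["stem"] * config.n_stem + ["early_osteogenic"] * config.n_early
        + ["late_osteogenic"] * config.n_late
    )
    order = rng.permutation(len(classes))
    program_of = {
        "stem": "down_flat",
        "early_osteogenic": "down_osteo_d3",
        "late_osteogenic": "down_osteo_d6",
    }
    bound_of = {
        "stem": {"bound_d0": True},
        "early_osteogenic": {"bound_d3": True},
        "late_osteogenic": {"bound_d6": True},
    }
    for k, (chrom, block) in enumerate(t_blocks):
        cls = classes[order[k]]
        gid = f"g_{cls.split('_')[0]}_{k:03d}"
        g = place_gene(chrom, block, program_of[cls], gid)
        gap = _uniform_int(rng, config.enhancer_gap)
        length = _uniform_int(rng, config.enhancer_length)
        start = g.end + gap
        add_element(chrom, start, start + length, "enhancer",
                    temporal_class=cls, linked_gene=gid, **bound_of[cls])

    # --- spacer blocks: unaffected genes (a few silent), some with a
    #     constitutively bound promoter element at the TSS
    flat_idx = rng.choice(len(flat_slots), size=config.n_flat_genes, replace=False)
    silent = set(rng.choice(config.n_flat_genes, size=config.n_silent_genes, replace=False).tolist())
    flat_genes = []
    for k, si in enumerate(sorted(flat_idx.tolist())):
        chrom, block, slot = flat_slots[si]
        program = "silent" if k in silent else "flat"
        g = place_gene(chrom, block, program, f"g_flat_{k:03d}", slot=slot)
        if program == "flat":
            flat_genes.append(g)
    promo_idx = rng.choice(len(flat_genes), size=config.n_promoter_elements, replace=False)
    for k in sorted(promo_idx.tolist()):
        g = flat_genes[k]
        hw = config.promoter_halfwidth
        add_element(g.chrom, max(0, g.tss - hw), g.tss + hw, "promoter",
                    linked_gene=g.gene_id,
                    bound_d0=True, bound_d3=True, bound_d6=True)

    # --- decoy blocks: unbound enhancers, far from any downregulated gene
    remaining = config.n_unbound_enhancers
    for chrom, block in d_blocks:
        if remaining <= 0:
            break
        base = block * config.block_size
        slots = min(config.decoys_per_block, remaining)
        for s in range(slots):
            lo = base + 4_000 + s * 20_000
            start = lo + int(rng.integers(0, 8_000))
            length = _uniform_int(rng, config.enhancer_length)
            add_element(chrom, start, start + length, "enhancer")
            remaining -= 1

    truth_columns = [
        "element_id", "chrom", "start", "end", "kind", "temporal_class",
        "bound_d0", "bound_d3", "bound_d6", "runx2_bound", "super_enhancer",
        "linked_gene", "motif_planted", "k27_multiplier",
    ]
    truth = pd.DataFrame(el_rows, columns=truth_columns).set_index("element_id")
    gene_truth = pd.DataFrame(
        gene_rows, columns=["gene_id", "program", "chrom", "start", "end", "strand"]
    ).set_index("gene_id")

    # --- acetylation multipliers, super-enhancers, RUNX2, motifs
    enh = truth.index[truth["kind"] == "enhancer"]
    bound_any = truth.loc[enh, ["bound_d0", "bound_d3", "bound_d6"]].any(axis=1)
    meanlog = np.where(bound_any, config.k27_bound_meanlog, 0.0)
    mult = config.k27_floor + np.exp(rng.normal(meanlog, config.k27_sigma))
    n_se = int(round(config.se_fraction * len(enh)))
    se_pos = np.argsort(mult)[-n_se:] if n_se else np.array([], dtype=int)
    boosted = mult.copy()
    boosted[se_pos] *= config.se_boost
    truth.loc[enh, "k27_multiplier"] = boosted
    truth.loc[enh[se_pos], "super_enhancer"] = True

    brd4_bound = truth[["bound_d0", "bound_d3", "bound_d6"]].any(axis=1)
    p_runx2 = np.where(brd4_bound, config.runx2_rate_bound, config.runx2_rate_unbound)
    truth["runx2_bound"] = rng.random(len(truth)) < p_runx2

    osteo_bound = truth["temporal_class"].isin(["early_osteogenic", "late_osteogenic"])
    p_motif = np.where(osteo_bound, config.motif_rate_bound_osteo,
                       config.motif_rate_background)
    truth["motif_planted"] = rng.random(len(truth)) < p_motif

    element_set = IntervalSet(elements)
    return genes, element_set, truth, gene_truth


def compute_truth_links(
    genes: list[GeneModel],
    truth: pd.DataFrame,
    gene_truth: pd.DataFrame,
    max_dist: int = 50_000,
) -> dict[str, pd.DataFrame]:
    """Brute-force (element, downregulated gene) pairs within ``max_dist``."""
    down = gene_truth[gene_truth["program"].str.startswith("down")]
    out = {}
    for tp in TIMEPOINTS:
        rows = []
        bound = truth[truth[BOUND_FLAG[tp]]]
        for eid, e in bound.iterrows():
            for gid, g in down.iterrows():
                if g.chrom != e.chrom:
                    continue
                d = max(0, g.start - e.end, e.start - g.end)
                if d <= max_dist:
                    rows.append({"element_id": eid, "gene_id": gid, "distance": d})
        out[tp] = pd.DataFrame(rows, columns=["element_id", "gene_id", "distance"])
    return out


# ---------------------------------------------------------------------------
# occupancy simulation

def _element_mu(row, assay: str, genotype: str, timepoint: str, cfg: GeneratorConfig) -> float:
    """Expected fragment count per fully covered bin for one element."""
    if assay == "BRD4":
        if not row[BOUND_FLAG[timepoint]]:
            return 0.0
        mu = cfg.brd4_mu_element
        if genotype != "WT":
            mu *= cfg.ko_loss_factor
        return mu
    if assay == "H3K27ac":
        if row["kind"] == "promoter":
            return cfg.k27_mu_element
        return cfg.k27_mu_element * row["k27_multiplier"]
    if assay == "RUNX2":
        if not row["runx2_bound"]:
            return 0.0
        mu = cfg.runx2_mu_element
        brd4_bound = row["bound_d0"] or row["bound_d3"] or row["bound_d6"]
        if genotype != "WT" and brd4_bound:
            mu *= cfg.runx2_ko_loss_factor
        return mu
    raise ValueError(f"no occupancy model for assay {assay!r}")


def _expected_mass(truth, assay, genotype, tp, cfg) -> float:
    el = sum(
        _element_mu(row, assay, genotype, tp, cfg) * (row["end"] - row["start"]) / cfg.bin_size
        for _, row in truth.iterrows()
    )
    nbins = sum(L // cfg.bin_size for L in cfg.chrom_lengths.values())
    return el + nbins * cfg.mu_background


def simulate_occupancy_counts(
    truth: pd.DataFrame, config: GeneratorConfig
) -> tuple[dict[str, BinnedTrack], list[SampleDesign]]:
    """Binned occupancy tracks plus sample metadata with spike read counts."""
    rng = np.random.default_rng([config.seed, 2])
    cfg = config
    designs = []  # (assay, genotype, tp, reps, has_spike)
    for tp in TIMEPOINTS:
        designs.append(("BRD4", "WT", tp, cfg.brd4_reps, True))
        designs.append(("BRD4", "KO2", tp, cfg.brd4_reps, True))
        designs.append(("H3K27ac", "WT", tp, cfg.k27_reps, False))
    designs.append(("RUNX2", "WT", "D0", cfg.runx2_reps, False))
    designs.append(("RUNX2", "KO2", "D0", cfg.runx2_reps, False))

    tracks: dict[str, BinnedTrack] = {}
    samples: list[SampleDesign] = []
    by_chrom = {c: truth[truth["chrom"] == c] for c in cfg.chrom_names}
    wt_mass: dict[tuple[str, str], float] = {}

    for assay, genotype, tp, reps, has_spike in designs:
        key = (assay, tp)
        if key not in wt_mass:
            wt_mass[key] = _expected_mass(truth, assay, "WT", tp, cfg)
        m_wt = wt_mass[key]
        m_s = m_wt if genotype == "WT" else _expected_mass(truth, assay, genotype, tp, cfg)
        s0 = cfg.spike_ratio * m_wt if has_spike else 0.0
        d = (m_wt + s0) / (m_s + s0)
        for rep in range(1, reps + 1):
            data = {}
            for chrom, sub in by_chrom.items():
                nbins = cfg.chrom_lengths[chrom] // cfg.bin_size
                lam = np.full(nbins, cfg.mu_background * d)
                for _, row in sub.iterrows():
                    mu = _element_mu(row, assay, genotype, tp, cfg)
                    if mu == 0.0:
                        continue
                    g = rng.gamma(1.0 / cfg.phi, cfg.phi) if cfg.phi > 0 else 1.0
                    b0 = row["start"] // cfg.bin_size
                    b1 = (row["end"] - 1) // cfg.bin_size
                    for b in range(b0, min(b1 + 1, nbins)):
                        ov = min(row["end"], (b + 1) * cfg.bin_size) - max(row["start"], b * cfg.bin_size)
                        lam[b] += mu * g * d * ov / cfg.bin_size
                data[chrom] = rng.poisson(lam).astype(np.int64)
            track = BinnedTrack(cfg.bin_size, data)
            spike = int(rng.poisson(s0 * d)) if has_spike else 0
            sample_id = f"{assay}_{genotype}_{tp}_r{rep}"
            tracks[sample_id] = track
            samples.append(
                SampleDesign(
                    sample_id=sample_id, assay=assay, genotype=genotype,
                    timepoint=tp, replicate=rep,
                    primary_mapped_reads=max(1, int(track.total_count())),
                    spike_mapped_reads=spike,
                )
            )
    return tracks, samples


# ---------------------------------------------------------------------------
# expression simulation

def simulate_expression_counts(
    gene_truth: pd.DataFrame, config: GeneratorConfig
) -> CountMatrix:
    """Gene x sample NB expression counts for WT/KO1/KO2 at D0/D3/D6."""
    rng = np.random.default_rng([config.seed, 3])
    cfg = config
    gene_ids = list(gene_truth.index)
    base = np.maximum(
        cfg.rna_min_mu,
        np.exp(rng.normal(cfg.rna_base_meanlog, cfg.rna_base_sigma, len(gene_ids))),
    )
    base = np.where(gene_truth["program"].eq("silent"), cfg.silent_mu, base)

    def wt_mu(program: str, mu0: float, tp: str) -> float:
        fold = 2.0 ** cfg.osteo_logfc
        if program == "down_osteo_d3" and tp in ("D3", "D6"):
            return mu0 * fold
        if program == "down_osteo_d6" and tp == "D6":
            return mu0 * fold
        return mu0

    samples = []
    cols = []
    ko_fold = 2.0 ** cfg.ko_logfc
    for genotype in ("WT", "KO1", "KO2"):
        for tp in TIMEPOINTS:
            for rep in range(1, cfg.rna_reps + 1):
                mu = np.array(
                    [wt_mu(p, m, tp) for p, m in zip(gene_truth["program"], base)]
                )
                if genotype != "WT":
                    down = gene_truth["program"].str.startswith("down").to_numpy()
                    mu = np.where(down, mu * ko_fold, mu)
                if cfg.phi > 0:
                    lam = mu * rng.gamma(1.0 / cfg.phi, cfg.phi, size=len(mu))
                else:
                    lam = mu
                counts = rng.poisson(lam)
                cols.append(counts)
                samples.append(
                    SampleDesign(
                        sample_id=f"RNA_{genotype}_{tp}_r{rep}", assay="RNA",
                        genotype=genotype, timepoint=tp, replicate=rep,
                        primary_mapped_reads=max(1, int(counts.sum())),
                    )
                )
    counts = np.column_stack(cols)
    return CountMatrix(gene_ids, samples, counts)


# ---------------------------------------------------------------------------
# sequence simulation

def simulate_sequences(
    elements: IntervalSet,
    truth: pd.DataFrame,
    config: GeneratorConfig,
    pwm: PositionWeightMatrix = RUNX_EXAMPLE_PWM,
) -> dict[str, str]:
    """Random element sequences with motif instances planted per the truth.

    Keys are ``chrom:start-end`` region strings, the lookup convention the
    pipeline uses to match called peaks to provided sequences.
    """
    rng = np.random.default_rng([config.seed, 4])
    bases = np.array(list("ACGT"))
    lo = pwm.probs
    out = {}
    for iv in elements:
        row = truth.loc[iv.id]
        seq = rng.choice(bases, size=iv.length, p=[0.25] * 4)
        if row["motif_planted"] and iv.length >= pwm.width:
            inst = [
                bases[rng.choice(4, p=lo[i] / lo[i].sum())] for i in range(pwm.width)
            ]
            inst = "".join(inst)
            if rng.random() < 0.5:
                from .motif import reverse_complement

                inst = reverse_complement(inst)
            off = int(rng.integers(0, iv.length - pwm.width + 1))
            seq[off : off + pwm.width] = list(inst)
        out[f"{iv.chrom}:{iv.start}-{iv.end}"] = "".join(seq)
    return out


def generate(config: GeneratorConfig) -> SimulatedBundle:
    """Run the full generator: genome, occupancy, expression, sequences."""
    genes, elements, truth, gene_truth = generate_genome(config)
    links = compute_truth_links(genes, truth, gene_truth, config.target_max_dist)
    tracks, occ_samples = simulate_occupancy_counts(truth, config)
    rna = simulate_expression_counts(gene_truth, config)
    seqs = simulate_sequences(elements, truth, config)
    return SimulatedBundle(
        config=config, genes=genes, elements=elements, truth=truth,
        gene_truth=gene_truth, truth_links=links,
        samples=occ_samples + rna.samples, tracks=tracks, rna=rna,
        sequences=seqs,
    )


def write_bundle(bundle: SimulatedBundle, outdir, write_tracks: bool = False) -> None:
    """Write the bundle in the plain-text formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gi.write_gene_table(bundle.genes, outdir / "genes.tsv")
    gi.write_bed(bundle.elements, outdir / "elements.bed")
    sig.write_sample_sheet(bundle.samples, outdir / "samples.tsv")
    bundle.rna.to_tsv(outdir / "rna_counts.tsv")
    write_fasta(bundle.sequences, outdir / "element_sequences.fa")
    meta = {
        "chrom_lengths": bundle.chrom_lengths,
        "bin_size": bundle.config.bin_size,
        "seed": bundle.config.seed,
    }
    (outdir / "bundle.json").write_text(json.dumps(meta, indent=1))
    truth = bundle.truth.reset_index().to_dict(orient="records")
    links = {tp: df.to_dict(orient="records") for tp, df in bundle.truth_links.items()}
    gene_truth = bundle.gene_truth.reset_index().to_dict(orient="records")
    (outdir / "truth.json").write_text(
        json.dumps({"elements": truth, "genes": gene_truth, "links": links}, indent=1)
    )
    if write_tracks:
        tdir = outdir / "tracks"
        tdir.mkdir(exist_ok=True)
        for sid, track in bundle.tracks.items():
            sig.write_bedgraph(track, tdir / f"{sid}.bedgraph")


# ---------------------------------------------------------------------------
# evaluation against the planted truth

def _match_peaks(called: IntervalSet, elements: IntervalSet) -> dict[str, str]:
    """Map called peak id -> planted element id by largest overlap."""
    out: dict[str, tuple[int, str]] = {}
    by_chrom = elements.by_chrom()
    for p in called:
        best = None
        for e in by_chrom.get(p.chrom, []):
            ov = min(p.end, e.end) - max(p.start, e.start)
            if ov > 0 and (best is None or ov > best[0]):
                best = (ov, e.id)
        if best:
            out[p.id or f"{p.chrom}:{p.start}-{p.end}"] = best[1]
    return out


def _prf(called: set, truth: set) -> dict:
    tp = len(called & truth)
    return {
        "n_called": len(called),
        "n_truth": len(truth),
        "precision": tp / len(called) if called else float("nan"),
        "recall": tp / len(truth) if truth else float("nan"),
        "jaccard": tp / len(called | truth) if called | truth else float("nan"),
    }


def evaluate(result, bundle: SimulatedBundle) -> dict:
    """Score pipeline outputs against the planted truth.

    ``result`` is a :class:`osteotag.pipeline.PipelineResult`.  Returns a
    JSON-serialisable nested dict of per-stage precision/recall/Jaccard.
    """
    truth = bundle.truth
    metrics: dict = {}

    retention = {}
    cis_truth_all, cis_called_all = {}, {}
    for tp in TIMEPOINTS:
        validated = result.validated[tp]
        peaks = IntervalSet(
            GenomicInterval(r.chrom, int(r.start), int(r.end), str(i))
            for i, r in validated.iterrows()
        )
        match = _match_peaks(peaks, bundle.elements)
        retained_ids = validated.index[validated["retained"]]
        called = {match[i] for i in retained_ids if i in match}
        truth_set = set(truth.index[truth[BOUND_FLAG[tp]]])
        stats = _prf(called, truth_set)
        n_unmatched = sum(1 for i in retained_ids if i not in match)
        if called or n_unmatched:
            stats["precision"] = len(called & truth_set) / (len(called) + n_unmatched)
        retention[tp] = stats

        annotated = result.annotated[tp]
        for cls in ("promoter", "enhancer"):
            ids = annotated.index[
                annotated["retained"] & (annotated["cis_class"] == cls)
            ]
            cis_called_all.setdefault(cls, set()).update(
                (tp, match[i]) for i in ids if i in match
            )
            kind_set = truth.index[(truth["kind"] == cls) & truth[BOUND_FLAG[tp]]]
            cis_truth_all.setdefault(cls, set()).update((tp, e) for e in kind_set)
    metrics["validated_peaks"] = retention
    metrics["cis_class"] = {
        cls: _prf(cis_called_all[cls], cis_truth_all[cls]) for cls in cis_called_all
    }

    # super-enhancers (acetylation universe is shared across timepoints; D0)
    se_universe, se_flags = result.se_calls["D0"]
    match = _match_peaks(se_universe, bundle.elements)
    called_se = {
        match[iv.id or f"{iv.chrom}:{iv.start}-{iv.end}"]
        for iv, f in zip(se_universe, se_flags)
        if f and (iv.id or f"{iv.chrom}:{iv.start}-{iv.end}") in match
    }
    truth_se = set(truth.index[truth["super_enhancer"]])
    metrics["super_enhancers"] = _prf(called_se, truth_se)

    # target links and temporal classes
    link_stats, temporal_stats = {}, {}
    for tp in TIMEPOINTS:
        validated = result.validated[tp]
        peaks = IntervalSet(
            GenomicInterval(r.chrom, int(r.start), int(r.end), str(i))
            for i, r in validated.iterrows()
        )
        match = _match_peaks(peaks, bundle.elements)
        called_links = {
            (match[r.peak_id], r.gene_id)
            for r in result.targets[tp].itertuples()
            if r.peak_id in match
        }
        truth_links = {
            (r.element_id, r.gene_id) for r in bundle.truth_links[tp].itertuples()
        }
        link_stats[tp] = _prf(called_links, truth_links)

        cls = CLASS_BY_TIMEPOINT[tp]
        tdf = result.temporal[tp]
        called_cls = {
            match[r.peak_id]
            for r in tdf.itertuples()
            if r.temporal_class == cls and r.peak_id in match
        }
        truth_cls = set(truth.index[truth["temporal_class"] == cls])
        temporal_stats[tp] = _prf(called_cls, truth_cls)
    metrics["target_links"] = link_stats
    metrics["temporal_classes"] = temporal_stats

    # co-occupancy / RUNX2 loss / motif statistics
    metrics["fisher_cooccupancy"] = {
        "odds_ratio": result.fisher["odds_ratio"], "pvalue": result.fisher["pvalue"]
    }
    runx2_truth_lost = set(
        truth.index[
            truth["runx2_bound"]
            & truth[["bound_d0", "bound_d3", "bound_d6"]].any(axis=1)
        ]
    )
    match = _match_peaks(
        IntervalSet(
            GenomicInterval(r.chrom, int(r.start), int(r.end), str(i))
            for i, r in result.runx2.iterrows()
        ),
        bundle.elements,
    )
    called_lost = {
        match[i] for i in result.runx2.index[result.runx2["lost"]] if i in match
    }
    metrics["runx2_loss"] = _prf(called_lost, runx2_truth_lost)
    if result.motif is None:
        metrics["motif_enrichment"] = None
    else:
        metrics["motif_enrichment"] = {
            "fraction_bound": result.motif.fraction_bound,
            "fraction_background": result.motif.fraction_background,
            "odds_ratio": result.motif.odds_ratio,
            "pvalue": result.motif.pvalue,
        }
    return metrics
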