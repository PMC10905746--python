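"""Classification ladder: validation, cis class, super-enhancers, targets."""

import numpy as np
import pandas as pd
import pytest

from osteotag import classify as cl
from osteotag import differential as diff
from osteotag.intervals import GeneModel, GenomicInterval, IntervalSet
from osteotag.signal import CountMatrix, SampleDesign


def make_counts(peaks, wt_counts, ko_counts, reads=10**6):
    n_wt, n_ko = wt_counts.shape[1], ko_counts.shape[1]
    samples = [
        SampleDesign(f"wt{i}", "BRD4", "WT", "D0", i + 1, reads, 100)
        for i in range(n_wt)
    ] + [
        SampleDesign(f"ko{i}", "BRD4", "KO2", "D0", i + 1, reads, 100)
        for i in range(n_ko)
    ]
    ids = [iv.id for iv in peaks]
    return CountMatrix(ids, samples, np.hstack([wt_counts, ko_counts]), peaks)


class TestValidatePeaks:
    def peak(self, i, chrom="chr1"):
        return GenomicInterval(chrom, i * 10_000, i * 10_000 + 1_000, f"p{i}")

    def test_low_rpkm_never_retained(self):
        peaks = IntervalSet([self.peak(0)])
        # 0.8 RPKM at 1 kb and 1e6 reads -> 0.8 counts
        wt = np.full((1, 2), 0.8)
        ko = np.zeros((1, 2))
        cm = make_counts(peaks, wt, ko)
        out = cl.validate_peaks(peaks, [peaks], IntervalSet(), cm, np.ones(4), phi=0.1)
        assert not out["retained"].any()
        assert out["rpkm_wt"].iloc[0] == pytest.approx(0.8)

    def test_wt_only_branch_retains_despite_underpowered_test(self):
        peaks = IntervalSet([self.peak(0)])
        wt = np.full((1, 2), 5_000.0)
        ko = np.full((1, 2), 4_000.0)  # not significant at n=2, phi large
        cm = make_counts(peaks, wt, ko)
        out = cl.validate_peaks(peaks, [peaks, peaks], IntervalSet(), cm,
                                np.ones(4), phi=5.0)
        assert out["wt_only"].iloc[0]
        assert out["retained"].iloc[0]
        assert out["replicate_support"].iloc[0] == 2

    def test_retained_invariant_holds(self, rng):
        peaks = IntervalSet([self.peak(i) for i in range(30)])
        wt = rng.poisson(3_000, (30, 4)).astype(float)
        ko = rng.poisson(1_000, (30, 4)).astype(float)
        cm = make_counts(peaks, wt, ko)
        out = cl.validate_peaks(peaks, [peaks], peaks, cm, np.ones(8), phi=0.1)
        ok = (out["rpkm_wt"] > 1.0) & (
            out["wt_only"] | ((out["ko_loss_fdr"] < 0.05) & (out["ko_loss_logFC"] < 0))
        )
        assert (out["retained"] == ok).all()

    def test_planted_true_vs_decoy_recovery(self, rng):
        # 500 peaks with a genuine 4x knockout loss, 500 decoys without
        n = 500
        peaks = IntervalSet(
            [GenomicInterval("chr1", i * 5_000, i * 5_000 + 1_000, f"p{i:04d}")
             for i in range(2 * n)]
        )
        true_mask = np.arange(2 * n) < n
        base = 4_000.0
        wt = rng.poisson(base * rng.gamma(10, 0.1, (2 * n, 4)))
        ko_mu = np.where(true_mask, base * 0.25, base)
        ko = rng.poisson(ko_mu[:, None] * rng.gamma(10, 0.1, (2 * n, 4)))
        cm = make_counts(peaks, wt.astype(float), ko.astype(float))
        out = cl.validate_peaks(peaks, [peaks], peaks, cm, np.ones(8))
        sens = out["retained"].to_numpy()[true_mask].mean()
        tnr = 1 - out["retained"].to_numpy()[~true_mask].mean()
        assert sens >= 0.9
        assert tnr >= 0.9

    def test_mismatched_counts_raise(self):
        peaks = IntervalSet([self.peak(0), self.peak(1)])
        cm = make_counts(IntervalSet([self.peak(0)]), np.ones((1, 2)), np.ones((1, 2)))
        with pytest.raises(ValueError, match="cover"):
            cl.validate_peaks(peaks, [], IntervalSet(), cm, np.ones(4))


class TestCisClass:
    def validated(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["peak_id"] = [f"p{i}" for i in range(len(df))]
        df["retained"] = True
        return df.set_index("peak_id")

    def test_tss_precedence_and_cases(self):
        peaks = self.validated(
            [("chr1", 900, 1_200),    # overlaps TSS window and K27ac -> promoter
             ("chr1", 5_000, 6_000),  # K27ac only -> enhancer
             ("chr1", 9_000, 9_500)]  # neither -> unannotated
        )
        tssw = IntervalSet([GenomicInterval("chr1", 500, 1_501)])
        k27 = IntervalSet([GenomicInterval("chr1", 800, 6_500)])
        out = cl.annotate_cis_class(peaks, k27, tssw)
        assert list(out["cis_class"]) == ["promoter", "enhancer", None]

    def test_exhaustive_overlap_cases_are_mutually_exclusive(self, rng):
        rows = [("chr1", int(s := rng.integers(0, 50_000)), int(s) + 500)
                for _ in range(200)]
        peaks = self.validated(rows)
        tssw = IntervalSet(
            [GenomicInterval("chr1", i * 7_000, i * 7_000 + 1_001) for i in range(7)]
        )
        k27 = IntervalSet(
            [GenomicInterval("chr1", i * 3_000 + 1_500, i * 3_000 + 2_500)
             for i in range(16)]
        )
        out = cl.annotate_cis_class(peaks, k27, tssw)
        for pid, r in out.iterrows():
            iv = GenomicInterval(r.chrom, r.start, r.end)
            at_tss = any(iv.overlaps(w) for w in tssw)
            at_k27 = any(iv.overlaps(w) for w in k27)
            want = "promoter" if at_tss else ("enhancer" if at_k27 else None)
            assert r["cis_class"] == want


class TestSuperEnhancers:
    def enhancers(self, n):
        return IntervalSet(
            [GenomicInterval("chr1", i * 3_000, i * 3_000 + 1_000) for i in range(n)]
        )

    def test_single_extreme_outlier_is_the_only_call(self):
        sig = np.full(100, 10.0)
        sig[37] = 1_000.0
        call = cl.call_super_enhancers(self.enhancers(100), sig)
        assert call.flags.sum() == 1 and call.flags[37]

    def test_uniform_density_yields_no_calls(self):
        call = cl.call_super_enhancers(self.enhancers(50), np.full(50, 7.0))
        assert call.flags.sum() == 0 and call.cutoff_rank is None

    def test_planted_heavy_tail_recovery(self):
        rng = np.random.default_rng(3)
        m = np.exp(rng.normal(0, 1.5, 300))
        se_true = np.argsort(m)[-30:]
        m[se_true] *= 10.0
        call = cl.call_super_enhancers(self.enhancers(300), m * 1_000)
        called = set(np.flatnonzero(call.flags))
        truth = set(se_true.tolist())
        jaccard = len(called & truth) / len(called | truth)
        assert jaccard >= 0.8

    def test_too_few_enhancers_raise(self):
        with pytest.raises(ValueError, match=">= 10"):
            cl.call_super_enhancers(self.enhancers(5), np.arange(5.0))


def flags_frame(genes, down, osteo=()):
    df = pd.DataFrame(index=pd.Index([g.gene_id for g in genes], name="gene"))
    df["down_in_both"] = [g.gene_id in down for g in genes]
    df["osteogenic"] = [g.gene_id in osteo for g in genes]
    for c in ("increase_d0_d3", "increase_d0_d6", "increase_d3_d6"):
        df[c] = df["osteogenic"]
    return df


class TestTargets:
    def gene(self, chrom, start, end, gid):
        return GeneModel(GenomicInterval(chrom, start, end, gid, "+"), gid, "+")

    def peaks_frame(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["peak_id"] = [f"p{i}" for i in range(len(df))]
        return df.set_index("peak_id")

    def test_50kb_boundary(self):
        genes = [self.gene("chr1", 100_000, 110_000, "g1")]
        flags = flags_frame(genes, down={"g1"})
        near = self.peaks_frame([("chr1", 50_000, 51_000)])   # gap 49 kb
        far = self.peaks_frame([("chr1", 48_000, 49_000)])    # gap 51 kb
        assert len(cl.assign_target_genes(near, genes, flags)) == 1
        assert len(cl.assign_target_genes(far, genes, flags)) == 0

    def test_matches_all_pairs_oracle(self, rng):
        genes = [
            self.gene("chr1", s := int(rng.integers(0, 400_000)),
                      s + int(rng.integers(2_000, 10_000)), f"g{i}")
            for i in range(40)
        ]
        down = {f"g{i}" for i in range(40) if rng.random() < 0.5}
        flags = flags_frame(genes, down)
        rows = [("chr1", int(s := rng.integers(0, 400_000)), int(s) + 1_000)
                for _ in range(60)]
        peaks = self.peaks_frame(rows)
        got = set(
            map(tuple, cl.assign_target_genes(peaks, genes, flags,
                                              max_dist=50_000)[
                ["peak_id", "gene_id"]].itertuples(index=False))
        )
        want = set()
        for pid, r in peaks.iterrows():
            for g in genes:
                if g.gene_id in down and max(
                    0, g.start - r.end, r.start - g.end
                ) <= 50_000:
                    want.add((pid, g.gene_id))
        assert got == want

    def test_expanding_max_dist_is_monotone(self, rng):
        genes = [self.gene("chr1", 10_000 * i, 10_000 * i + 3_000, f"g{i}")
                 for i in range(20)]
        flags = flags_frame(genes, down={g.gene_id for g in genes})
        peaks = self.peaks_frame(
            [("chr1", int(s := rng.integers(0, 200_000)), int(s) + 500)
             for _ in range(20)]
        )
        small = cl.assign_target_genes(peaks, genes, flags, max_dist=10_000)
        large = cl.assign_target_genes(peaks, genes, flags, max_dist=60_000)
        small_set = set(map(tuple, small[["peak_id", "gene_id"]].itertuples(index=False)))
        large_set = set(map(tuple, large[["peak_id", "gene_id"]].itertuples(index=False)))
        assert small_set <= large_set


class TestTemporal:
    def setup_tables(self, osteo):
        ann = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1_000],
             "retained": [True], "cis_class": ["enhancer"]},
            index=pd.Index(["p0"], name="peak_id"),
        )
        genes = [GeneModel(GenomicInterval("chr1", 5_000, 9_000, "g1", "+"), "g1", "+")]
        flags = flags_frame(genes, down={"g1"}, osteo={"g1"} if osteo else set())
        targets = cl.assign_target_genes(ann, genes, flags)
        return ann, targets, flags

    def test_flat_gene_at_d0_is_stem(self):
        ann, targets, flags = self.setup_tables(osteo=False)
        out = cl.temporal_classify(ann, targets, flags, "D0")
        assert list(out["temporal_class"]) == ["stem"]

    def test_induced_gene_at_d3_is_early_osteogenic(self):
        ann, targets, flags = self.setup_tables(osteo=True)
        out = cl.temporal_classify(ann, targets, flags, "D3")
        assert list(out["temporal_class"]) == ["early_osteogenic"]
        out6 = cl.temporal_classify(ann, targets, flags, "D6")
        assert list(out6["temporal_class"]) == ["late_osteogenic"]

    def test_unlinked_enhancer_is_unclassified(self):
        ann, _, flags = self.setup_tables(osteo=False)
        empty = cl.assign_target_genes(ann.iloc[:0], [], flags.iloc[:0])
        out = cl.temporal_classify(ann, empty, flags, "D0")
        assert list(out["temporal_class"]) == ["unclassified"]
        assert out["gene_id"].isna().all()
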