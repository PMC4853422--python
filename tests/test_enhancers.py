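import numpy as np
import pandas as pd
import pytest

from primkit.enhancers import (
    EnhancerCatalog,
    annotate_enhancer_genes,
    assign_activity,
    call_enhancers,
    class_association_summary,
    count_tf_peaks,
    partition_activity,
)
from primkit.intervals import GenomicInterval, PeakSet, TranscriptAnnotation
from oracles import brute_call_enhancers


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


def k27ac(spans, ct):
    return PeakSet(f"{ct}_ac", ct, "K27ac", [iv(s, e) for s, e in spans])


def k4(spans, ct):
    return PeakSet(f"{ct}_k4", ct, "K4me3", [iv(s, e) for s, e in spans])


def tx(gene, start, end, strand="+", chrom="chr1"):
    return TranscriptAnnotation(f"t_{gene}", gene, chrom, strand, start, end)


def empty_marks(cts=("SSC", "MASC", "ESC")):
    return {ct: k27ac([], ct) for ct in cts}, {ct: k4([], ct) for ct in cts}


def call(ac_spans, k4_spans, annotation=(), **kw):
    """Single-cell-type helper: everything planted in SSC."""
    ac, km = empty_marks()
    ac["SSC"] = k27ac(ac_spans, "SSC")
    km["SSC"] = k4(k4_spans, "SSC")
    return call_enhancers(ac, km, list(annotation), **kw)


class TestCallEnhancers:
    def test_extended_k4_zone_rejects_k27ac(self):
        cat = call([(6100, 6300)], [(5000, 5200)])
        assert len(cat) == 0
        # outside the [4000, 6200) zone: survives
        cat = call([(6200, 6400)], [(5000, 5200)])
        assert len(cat) == 1

    def test_merge_within_500(self):
        cat = call([(8000, 8400), (8700, 8900)], [])
        assert len(cat) == 1
        row = cat.table.iloc[0]
        assert (row.start, row.end) == (8000, 8900)

    def test_gene_body_and_tss_tes_rejection(self):
        ann = [tx("g1", 20_000, 30_000)]
        assert len(call([(22_000, 22_500)], [], ann)) == 0  # inside body
        assert len(call([(29_500, 30_200)], [], ann)) == 0  # spans TES point
        assert len(call([(30_001, 30_400)], [], ann)) == 1  # clear of both

    def test_missing_cell_type_errors(self):
        ac, km = empty_marks()
        del km["ESC"]
        with pytest.raises(ValueError):
            call_enhancers(ac, km, [])

    def test_cross_cell_type_union_merging(self):
        ac, km = empty_marks()
        ac["SSC"] = k27ac([(1000, 1400)], "SSC")
        ac["ESC"] = k27ac([(1600, 2000)], "ESC")
        cat = call_enhancers(ac, km, [])
        assert len(cat) == 1
        assert cat.table.iloc[0].contributors == "SSC,ESC"


class TestActivityPartition:
    def make_catalog(self):
        ac, km = empty_marks()
        ac["SSC"] = k27ac([(1000, 1500), (5000, 5400)], "SSC")
        ac["ESC"] = k27ac([(1200, 1600)], "ESC")
        return call_enhancers(ac, km, []), ac

    def test_flags_from_overlap(self):
        cat, ac = self.make_catalog()
        cat = assign_activity(cat, ac)
        flags = cat.table.set_index("start")
        assert bool(flags.loc[1000, "active_SSC"]) and bool(
            flags.loc[1000, "active_ESC"]
        )
        assert not flags.loc[1000, "active_MASC"]

    def test_touching_peak_gives_no_activity(self):
        ac, km = empty_marks()
        ac["SSC"] = k27ac([(1000, 1500)], "SSC")
        cat = call_enhancers(ac, km, [])
        ac["MASC"] = k27ac([(1500, 1800)], "MASC")  # touches end-to-start
        cat = assign_activity(cat, ac)
        assert not cat.table.iloc[0]["active_MASC"]

    def test_inactive_everywhere_dropped(self):
        cat, ac = self.make_catalog()
        none = {ct: k27ac([], ct) for ct in ("SSC", "MASC", "ESC")}
        assert len(assign_activity(cat, none)) == 0

    @pytest.mark.parametrize(
        "active, label",
        [(("SSC", "MASC", "ESC"), "SME"), (("ESC",), "E"), (("SSC", "ESC"), "SE")],
    )
    def test_subset_labels(self, active, label):
        table = pd.DataFrame(
            {
                "chrom": ["chr1"], "start": [100], "end": [200],
                "enhancer_id": ["e1"], "contributors": [""],
                **{f"active_{ct}": [ct in active] for ct in ("SSC", "MASC", "ESC")},
            }
        )
        cat = partition_activity(EnhancerCatalog(table=table))
        assert cat.table.iloc[0]["subset"] == label

    def test_subsets_partition_catalog(self, noise_free_study):
        study = noise_free_study
        km = {
            ct: PeakSet(
                ct, ct, "K4me3",
                [p for r in range(1, reps + 1)
                 for p in study.chip_peaks[(ct, r, "K4me3")].intervals],
            )
            for ct, reps in study.config.chip_replicates.items()
        }
        cat = call_enhancers(study.k27ac_peaks, km, study.annotation,
                             study.layout)
        cat = partition_activity(assign_activity(cat, study.k27ac_peaks))
        counts = cat.table["subset"].value_counts()
        assert counts.sum() == len(cat)
        assert set(counts.index) <= {"S", "M", "E", "SM", "SE", "ME", "SME"}


class TestAnnotateGenes:
    def test_distance_window(self):
        cat = call([(9000, 10_000)], [])
        near = tx("g_near", 60_000, 70_000)
        far = tx("g_far", 160_000, 170_000)
        cat = annotate_enhancer_genes(cat, [near, far], window=100_000)
        hits = cat.table.iloc[0]["transcripts"]
        assert [h[1] for h in hits] == ["g_near"]
        assert hits[0][2] == 50_000

    def test_zero_window_touching_only(self):
        cat = call([(9000, 10_000)], [])
        touching = tx("g_touch", 10_000, 12_000)
        apart = tx("g_apart", 10_001, 12_001)
        cat = annotate_enhancer_genes(cat, [touching, apart], window=0)
        assert [h[1] for h in cat.table.iloc[0]["transcripts"]] == ["g_touch"]

    def test_enhancer_between_boundaries_distance_zero(self):
        cat = call([(9000, 10_000)], [])
        spanning = tx("g_span", 8000, 20_000)
        cat = annotate_enhancer_genes(cat, [spanning], window=0)
        assert cat.table.iloc[0]["transcripts"][0][2] == 0


class TestClassAssociation:
    def make(self):
        table = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [100, 300, 500, 700],
                "end": [200, 400, 600, 800],
                "enhancer_id": [f"e{i}" for i in range(4)],
                "subset": ["S", "S", "S", "S"],
                "transcripts": [
                    [("t1", "gI", 0)],
                    [("t2", "gI2", 10)],
                    [("t3", "gI3", 10), ("t4", "gII", 5)],
                    [("t5", "gnone", 0)],
                ],
            }
        )
        classes = pd.Series({"gI": "I", "gI2": "I", "gI3": "I", "gII": "II"})
        return EnhancerCatalog(table=table), classes

    def test_fractions_and_double_counting(self):
        cat, classes = self.make()
        out = class_association_summary(cat, classes)
        assert out.loc["S", "frac_class_I"] == pytest.approx(0.75)
        assert out.loc["S", "frac_class_II"] == pytest.approx(0.25)

    def test_empty_subset_undefined(self):
        cat, classes = self.make()
        out = class_association_summary(cat, classes)
        assert np.isnan(out.loc["ME", "frac_class_I"])
        assert out.loc["ME", "n"] == 0


class TestCountTfPeaks:
    def test_counts_and_half_open_boundary(self):
        regions = [iv(1000, 2000)]
        tfs = {
            "Pou5f1": [iv(900, 1100), iv(1500, 1600), iv(1999, 2100)],
            "Sox2": [iv(2000, 2200)],  # abuts region end: no shared base
            "Nanog": [],
        }
        out = count_tf_peaks(regions, tfs, region_ids=["e1"])
        assert out.loc["e1", "Pou5f1"] == 3
        assert out.loc["e1", "Sox2"] == 0
        assert out.loc["e1", "Nanog"] == 0


class TestOracleAndMonotonicity:
    def random_instance(self, rng):
        def spans(n, lo=0, hi=40_000, max_len=800):
            starts = rng.integers(lo, hi, n)
            return [(int(s), int(s + rng.integers(50, max_len))) for s in starts]

        ac = {ct: k27ac(spans(rng.integers(0, 20)), ct) for ct in ("SSC", "MASC", "ESC")}
        km = {ct: k4(spans(rng.integers(0, 10)), ct) for ct in ("SSC", "MASC", "ESC")}
        ann = [
            tx(f"g{i}", int(s), int(s + rng.integers(500, 3000)))
            for i, s in enumerate(rng.integers(0, 40_000, rng.integers(0, 5)))
        ]
        return ac, km, ann

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(101)
        for _ in range(150):
            ac, km, ann = self.random_instance(rng)
            cat = call_enhancers(ac, km, ann)
            got = [(r.chrom, r.start, r.end) for r in cat.table.itertuples()]
            want = brute_call_enhancers(
                {ct: ac[ct].intervals for ct in ac},
                {ct: km[ct].intervals for ct in km},
                ann, 1000, 500,
            )
            assert got == want

    def test_wider_gap_never_increases_count(self):
        rng = np.random.default_rng(55)
        for _ in range(25):
            ac, km, ann = self.random_instance(rng)
            sizes = [
                len(call_enhancers(ac, km, ann, merge_gap=g))
                for g in (0, 250, 500, 2000)
            ]
            assert sizes == sorted(sizes, reverse=True)

    def test_wider_extension_never_increases_survivors(self):
        rng = np.random.default_rng(56)
        for _ in range(25):
            ac, km, ann = self.random_instance(rng)
            sizes = [
                len(call_enhancers(ac, km, ann, k4_extension=f))
                for f in (0, 500, 1000, 5000)
            ]
            # survivors can merge differently, so compare total covered bases
            covered = []
            for f in (0, 500, 1000, 5000):
                cat = call_enhancers(ac, km, ann, k4_extension=f)
                covered.append(int((cat.table.end - cat.table.start).sum()))
            assert covered == sorted(covered, reverse=True)
            assert sizes[0] >= sizes[-1] or covered[0] >= covered[-1]

    def test_catalog_disjoint_and_sorted(self):
        rng = np.random.default_rng(57)
        for _ in range(25):
            ac, km, ann = self.random_instance(rng)
            cat = call_enhancers(ac, km, ann)
            t = cat.table
            for chrom, grp in t.groupby("chrom"):
                starts = grp.start.to_numpy()
                ends = grp.end.to_numpy()
                assert (starts[1:] >= ends[:-1]).all()
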