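import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from primkit.intervals import (
    CoverageTrack,
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    TranscriptAnnotation,
)
from primkit.promoters import (
    build_prim_table,
    call_promoter_state,
    compute_prim,
    consensus_bivalent_genes,
    consensus_state,
    define_promoters,
    mean_promoter_signal,
    promoter_signal_column,
)


def tx(gene, t, chrom, strand, start, end):
    return TranscriptAnnotation(t, gene, chrom, strand, start, end)


def peakset(mark, spans, sample="s1", ct="SSC"):
    return PeakSet(
        sample, ct, mark, [GenomicInterval("chr1", s, e) for s, e in spans]
    )


def states_series(codes):
    return pd.Series(codes, dtype="Int8")


class TestDefinePromoters:
    def test_plus_strand_window(self):
        proms = define_promoters([tx("g1", "t1", "chr1", "+", 10_000, 15_000)])
        p = proms["g1"]
        assert (p.interval.start, p.interval.end, p.tss) == (8000, 12_000, 10_000)

    def test_minus_strand_tss_at_txend(self):
        proms = define_promoters([tx("g1", "t1", "chr1", "-", 5000, 9000)])
        p = proms["g1"]
        assert (p.interval.start, p.interval.end, p.tss) == (7000, 11_000, 9000)

    def test_clamped_at_chromosome_start(self):
        proms = define_promoters([tx("g1", "t1", "chr1", "+", 1000, 5000)])
        assert (proms["g1"].interval.start, proms["g1"].interval.end) == (0, 3000)

    def test_canonical_transcript_longest_then_lowest_start(self):
        proms = define_promoters(
            [
                tx("g1", "t_short", "chr1", "+", 10_000, 12_000),
                tx("g1", "t_long", "chr1", "+", 20_000, 30_000),
            ]
        )
        assert proms["g1"].tss == 20_000
        proms = define_promoters(
            [
                tx("g1", "tb", "chr1", "+", 30_000, 40_000),
                tx("g1", "ta", "chr1", "+", 10_000, 20_000),
            ]
        )
        assert proms["g1"].tss == 10_000  # tie on length -> lowest txStart


class TestPromoterState:
    @pytest.fixture
    def promoters(self):
        return define_promoters([tx("g1", "t1", "chr1", "+", 10_000, 15_000)])

    @pytest.mark.parametrize(
        "k4_spans, k27_spans, expected",
        [
            ([(9000, 9100)], [], 1),
            ([(9000, 9100)], [(11_000, 11_200)], 0),
            ([], [(11_000, 11_200)], -1),
            ([], [], None),
            ([(11_999, 12_100)], [], 1),  # one shared base suffices
            ([(12_000, 12_100)], [], None),  # touching only, half-open
        ],
    )
    def test_state_coding(self, promoters, k4_spans, k27_spans, expected):
        col = call_promoter_state(
            promoters, peakset("K4me3", k4_spans), peakset("K27me3", k27_spans)
        )
        if expected is None:
            assert pd.isna(col["g1"])
        else:
            assert col["g1"] == expected

    def test_states_partition_every_gene(self, noise_free_tables):
        states = noise_free_tables["states"]
        valid = states.isin([1, 0, -1]) | states.isna()
        assert valid.all().all()


class TestConsensus:
    def test_two_of_three_bivalent_included(self):
        cols = [states_series({"g": v}) for v in (0, 0, 1)]
        assert consensus_bivalent_genes(cols, 2) == {"g"}

    def test_single_bivalent_excluded(self):
        cols = [
            states_series({"g": 0}),
            states_series({"g": 1}),
            states_series({"g": pd.NA}),
        ]
        assert consensus_bivalent_genes(cols, 2) == set()

    def test_min_support_one(self):
        cols = [states_series({"g": 0}), states_series({"g": pd.NA})]
        assert consensus_bivalent_genes(cols, 1) == {"g"}

    def test_too_few_replicates_error(self):
        with pytest.raises(ValueError):
            consensus_bivalent_genes([states_series({"g": 0})], 2)

    def test_monotone_in_min_support(self):
        rng = np.random.default_rng(5)
        cols = [
            pd.Series(rng.choice([1, 0, -1], size=50), dtype="Int8")
            for _ in range(4)
        ]
        sets = [consensus_bivalent_genes(cols, k) for k in (1, 2, 3, 4)]
        for a, b in zip(sets, sets[1:]):
            assert b <= a

    def test_consensus_state_recodes_mark_votes(self):
        # K4 in 2 reps, K27 in only 1 -> consensus K4-only
        cols = [
            states_series({"g": 0}),
            states_series({"g": 1}),
            states_series({"g": pd.NA}),
        ]
        assert consensus_state(cols, 2)["g"] == 1


class TestSignals:
    def uniform_track(self, depth, lib):
        return CoverageTrack(
            "s", "K4me3",
            {"chr1": (np.array([0]), np.array([100_000]), np.array([depth]))},
            lib,
        )

    def test_rpm_normalization(self):
        proms = define_promoters([tx("g1", "t1", "chr1", "+", 10_000, 15_000)])
        p = proms["g1"]
        assert mean_promoter_signal(self.uniform_track(2.0, 10**6), p) == 2.0
        assert mean_promoter_signal(self.uniform_track(2.0, 2 * 10**6), p) == 1.0

    def test_zero_track(self):
        proms = define_promoters([tx("g1", "t1", "chr1", "+", 10_000, 15_000)])
        assert mean_promoter_signal(self.uniform_track(0.0, 10**6), proms["g1"]) == 0.0

    def test_missing_chromosome_errors(self):
        proms = define_promoters([tx("g1", "t1", "chr2", "+", 10_000, 15_000)])
        with pytest.raises(KeyError):
            mean_promoter_signal(self.uniform_track(1.0, 10**6), proms["g1"])


class TestPrim:
    def test_equal_signals_zero(self):
        assert compute_prim(10.0, 10.0) == 0.0

    def test_direct_evaluation(self):
        assert compute_prim(8.0, 2.0) == pytest.approx(1.9995, abs=1e-3)
        assert compute_prim(0.0, 4.0) == pytest.approx(-11.967, abs=1e-2)

    def test_negative_signal_errors(self):
        with pytest.raises(ValueError):
            compute_prim(-1.0, 2.0)

    @settings(max_examples=200, deadline=None)
    @given(
        st.floats(0, 1e6, allow_nan=False),
        st.floats(0, 1e6, allow_nan=False),
    )
    def test_antisymmetry(self, x, y):
        assert compute_prim(x, y) == pytest.approx(-compute_prim(y, x), abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(
        st.floats(0, 1e4, allow_nan=False),
        st.floats(0, 1e4, allow_nan=False),
        st.floats(1e-3, 1e3, allow_nan=False),
    )
    def test_strictly_monotone(self, x, y, delta):
        assert compute_prim(x + delta, y) > compute_prim(x, y)
        assert compute_prim(x, y + delta) < compute_prim(x, y)


class TestPrimTable:
    def make_grid(self, state, k4a, k4b, k27a, k27b):
        idx = pd.Index(["g"], name="gene")
        states = pd.DataFrame(
            {"s1": pd.array([state], dtype="Int8"),
             "s2": pd.array([state], dtype="Int8")}, index=idx
        )
        k4 = pd.DataFrame({"s1": [k4a], "s2": [k4b]}, index=idx)
        k27 = pd.DataFrame({"s1": [k27a], "s2": [k27b]}, index=idx)
        return states, k4, k27

    def test_undefined_where_state_na(self):
        states, k4, k27 = self.make_grid(pd.NA, 1, 1, 1, 1)
        out = build_prim_table(states, k4, k27)
        assert out.isna().all().all()

    def test_equal_signals_give_zero(self):
        states, k4, k27 = self.make_grid(0, 4.0, 4.0, 4.0, 4.0)
        out = build_prim_table(states, k4, k27)
        assert (out == 0).all().all()

    def test_replicate_mean_before_ratio(self):
        states, k4, k27 = self.make_grid(0, 2.0, 6.0, 4.0, 4.0)
        out = build_prim_table(
            states, k4, k27, sample_groups={"s1": "SSC", "s2": "SSC"}
        )
        assert out.loc["g", "SSC"] == pytest.approx(0.0)

    def test_grid_mismatch_errors(self):
        states, k4, k27 = self.make_grid(0, 1, 1, 1, 1)
        with pytest.raises(ValueError):
            build_prim_table(states, k4.rename(columns={"s2": "x"}), k27)
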