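"""Peak-weighted document vote, complexity correction, and thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from squigbin.classify import (
    UNCLASSIFIED,
    calibrate_threshold,
    classify_binary,
    classify_multiclass,
    classify_stream,
    document_scores,
    peak_indicator,
    shred_complexity,
    split_into_chunks,
)
from squigbin.index import MatchProfile, compute_pml
from squigbin.pore_model import make_bins, synthetic_pore_model
from squigbin.reference import ReferenceText, ShredTable, StrandBinSeq
from squigbin.signal import signal_to_binseq
from squigbin.simulate import SimParams, simulate_read


def make_table(docs, classes=None, names=None, strands=None, lengths=None):
    """Hand-built shred table; lengths default to 10 symbols per row."""
    n = len(docs)
    classes = classes or ["classA"] * n
    names = names or [f"ref{d}" for d in docs]
    strands = strands or ["+"] * n
    lengths = lengths or [10] * n
    starts = np.cumsum([0] + [L + 1 for L in lengths[:-1]])
    return ShredTable(
        doc_id=np.array(docs), ref_name=names, class_label=classes,
        start=starts, end=starts + np.array(lengths), strand=strands,
        shred_size=max(lengths),
    )


class TestPeaks:
    def test_worked_example(self):
        peaks = peak_indicator(np.array([3, 2, 1, 2, 1, 0]))
        assert list(np.nonzero(peaks)[0]) == [0, 3]

    def test_strictly_decreasing_single_peak(self):
        peaks = peak_indicator(np.array([5, 4, 3, 2, 1]))
        assert list(np.nonzero(peaks)[0]) == [0]

    def test_constant_all_peaks(self):
        assert peak_indicator(np.array([2, 2, 2])).all()


class TestComplexity:
    def _ref_with_symbols(self, symbols_per_doc, n_bins=6):
        strands, rows = [], []
        starts, pos, docs = [], 0, []
        lengths = []
        for d, symbols in enumerate(symbols_per_doc):
            strands.append(StrandBinSeq(f"ref{d}", "classA", "+",
                                        np.array(symbols, dtype=np.int16)))
            docs.append(d)
            starts.append(pos)
            lengths.append(len(symbols))
            pos += len(symbols) + 1
        table = ShredTable(
            doc_id=np.array(docs), ref_name=[f"ref{d}" for d in docs],
            class_label=["classA"] * len(docs),
            start=np.array(starts), end=np.array(starts) + np.array(lengths),
            strand=["+"] * len(docs), shred_size=max(lengths),
        )
        return ReferenceText(strands=strands, shred_table=table,
                             class_map={"classA": "plain"}, n_bins=n_bins)

    def test_zero_maximal_and_intermediate_entropy(self):
        ref = self._ref_with_symbols([
            [4] * 12,                      # single symbol -> 0
            [0, 1, 2, 3, 4, 5] * 2,        # all six equally frequent -> 1
            [0, 0, 1, 1, 2, 2],            # three symbols -> log2(3)/log2(6)
        ])
        c = shred_complexity(ref)
        assert c[0] == 0.0
        assert c[1] == pytest.approx(1.0)
        assert c[2] == pytest.approx(math.log2(3) / math.log2(6), abs=1e-4)


class TestDocumentScores:
    def test_worked_eq2_example(self):
        profile = MatchProfile(P=np.array([3, 2, 1, 2, 1, 0]),
                               D=np.array([1, 1, 1, 2, 2, 2]))
        table = make_table([1, 2])
        scores = document_scores(profile, {1: 1.0, 2: 1.0}, table)
        assert scores.scores == {1: 3.0, 2: 2.0}

    def test_zero_profile_scores_zero(self):
        profile = MatchProfile(P=np.zeros(4, int), D=np.full(4, -1))
        scores = document_scores(profile, {}, make_table([1, 2]))
        assert scores.scores == {1: 0.0, 2: 0.0}

    def test_complexity_scales_linearly(self):
        profile = MatchProfile(P=np.array([3, 2, 1, 2, 1, 0]),
                               D=np.array([1, 1, 1, 2, 2, 2]))
        table = make_table([1, 2])
        half = document_scores(profile, {1: 1.0, 2: 0.5}, table)
        assert half.scores == {1: 3.0, 2: 1.0}

    def test_unknown_document_rejected(self):
        profile = MatchProfile(P=np.array([1]), D=np.array([9]))
        with pytest.raises(ValueError, match="shred table"):
            document_scores(profile, {}, make_table([1, 2]))


class TestMulticlass:
    def test_argmax_class(self):
        profile = MatchProfile(P=np.array([3, 2, 1, 2, 1, 0]),
                               D=np.array([1, 1, 1, 2, 2, 2]))
        table = make_table([1, 2], classes=["classA", "classB"])
        scores = document_scores(profile, {}, table)
        call = classify_multiclass(scores, {"classA": "plain", "classB": "plain"})
        assert call.predicted_class == "classA"
        assert call.top_doc == 1
        assert call.score == 3.0

    def test_all_zero_is_unclassified(self):
        scores = document_scores(
            MatchProfile(P=np.zeros(3, int), D=np.full(3, -1)), {},
            make_table([1, 2]),
        )
        assert classify_multiclass(scores, {}).predicted_class == UNCLASSIFIED

    def test_same_class_tie_still_resolves_to_class(self):
        profile = MatchProfile(P=np.array([2, 0, 2, 0]),
                               D=np.array([1, 1, 2, 2]))
        table = make_table([1, 2], classes=["classA", "classA"])
        scores = document_scores(profile, {}, table)
        assert classify_multiclass(scores, {}).predicted_class == "classA"

    def test_class_relabeling_permutes_output(self):
        profile = MatchProfile(P=np.array([5, 1, 3, 1]),
                               D=np.array([1, 1, 2, 2]))
        t1 = make_table([1, 2], classes=["x", "y"])
        t2 = make_table([1, 2], classes=["y", "x"])
        c1 = classify_multiclass(document_scores(profile, {}, t1), {})
        c2 = classify_multiclass(document_scores(profile, {}, t2), {})
        assert c1.predicted_class == "x" and c2.predicted_class == "y"
        assert c1.top_doc == c2.top_doc


class TestBinary:
    CLASS_MAP = {"pos": "positive", "null": "null"}

    def _scores(self, pos, null):
        profile = MatchProfile(P=np.array([pos, 0, null, 0]),
                               D=np.array([1, 1, 2, 2]))
        table = make_table([1, 2], classes=["pos", "null"])
        return document_scores(profile, {}, table)

    def test_ratio_rule(self):
        call = classify_binary(self._scores(6, 4), self.CLASS_MAP, tau=1.2)
        assert call.ratio == pytest.approx(1.5)
        assert call.predicted_class == "pos"

    def test_tie_at_tau_goes_null(self):
        call = classify_binary(self._scores(4, 4), self.CLASS_MAP, tau=1.0)
        assert call.ratio == pytest.approx(1.0)
        assert call.predicted_class == "null"

    def test_zero_null_is_positive_infinity(self):
        call = classify_binary(self._scores(3, 0), self.CLASS_MAP, tau=1.0)
        assert math.isinf(call.ratio)
        assert call.predicted_class == "pos"

    def test_all_zero_unclassified(self):
        call = classify_binary(self._scores(0, 0), self.CLASS_MAP, tau=1.0)
        assert call.predicted_class == UNCLASSIFIED

    def test_missing_role_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            classify_binary(self._scores(1, 1), {"pos": "plain", "null": "null"})
        with pytest.raises(ValueError, match="tau"):
            classify_binary(self._scores(1, 1), self.CLASS_MAP, tau=0.0)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)),
                    min_size=1, max_size=30),
           st.floats(0.1, 5.0), st.floats(0.0, 5.0))
    def test_raising_tau_never_adds_positives(self, reads, tau, delta):
        def count(t):
            n = 0
            for pos, null in reads:
                call = classify_binary(self._scores(pos, null),
                                       self.CLASS_MAP, tau=t)
                n += call.predicted_class == "pos"
            return n

        assert count(tau + delta) <= count(tau)


class TestCalibration:
    def test_quantile_example(self):
        tau = calibrate_threshold([0.5, 1.0, 2.0, 4.0], 0.25)
        assert tau == pytest.approx(2.5)

    def test_limits_and_degenerate(self):
        ratios = [0.5, 1.0, 2.0, 4.0]
        assert calibrate_threshold(ratios, 0.999) == pytest.approx(0.5, abs=0.02)
        assert calibrate_threshold([3.0] * 10, 0.4) == 3.0
        with pytest.raises(ValueError, match="empty"):
            calibrate_threshold([], 0.5)
        with pytest.raises(ValueError):
            calibrate_threshold(ratios, 1.5)

    def test_calibrated_rate_tracks_expected_fraction(self):
        rng = np.random.default_rng(11)
        ratios = rng.lognormal(0.0, 1.0, 500)
        for f in (0.1, 0.25, 0.5, 0.9):
            tau = calibrate_threshold(ratios, f)
            rate = float((ratios > tau).mean())
            assert abs(rate - f) <= 0.05


class TestStreaming:
    def test_single_chunk_equals_batch(self, two_class_setup, model, cfg):
        rng = np.random.default_rng(12)
        seq = two_class_setup.seqs["refA"]
        samples, _ = simulate_read(seq, 1000, 4000, model, SimParams(), rng)
        calls = classify_stream([samples], two_class_setup.index,
                                two_class_setup.ref, model, cfg,
                                complexity=two_class_setup.complexity)
        bins = signal_to_binseq(samples, model, cfg)
        profile = compute_pml(two_class_setup.index, bins)
        scores = document_scores(profile, two_class_setup.complexity,
                                 two_class_setup.index.shred_table)
        batch = classify_multiclass(scores, two_class_setup.ref.class_map)
        assert calls[-1].predicted_class == batch.predicted_class
        assert calls[-1].score == pytest.approx(batch.score)

    def test_true_class_score_nondecreasing_noise_free(self, two_class_setup,
                                                       model, cfg):
        rng = np.random.default_rng(13)
        seq = two_class_setup.seqs["refA"]
        params = SimParams(amplitude_noise_factor=0.0, dwell_sd=0.0)
        samples, _ = simulate_read(seq, 5000, 6000, model, params, rng)
        calls = classify_stream(split_into_chunks(samples, 4000),
                                two_class_setup.index, two_class_setup.ref,
                                model, cfg,
                                complexity=two_class_setup.complexity,
                                normalize=False)
        scores = [c.score for c in calls]
        assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))
        assert calls[-1].predicted_class == "classA"

    def test_chunk_splitting(self):
        chunks = split_into_chunks(np.arange(10_500), 4_000)
        assert [len(c) for c in chunks] == [4000, 4000, 2500]
        with pytest.raises(ValueError):
            split_into_chunks(np.arange(10), 0)
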