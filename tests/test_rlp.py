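"""Prediction-residual mapping and the gated run-length cascade."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qscodec.qsd_io import CorruptionError, QualityRecord
from qscodec.rlp import (DEFAULT_THETA, ContextTable, GateFeatures, START,
                         apply_prpm, build_context_table, gate_score,
                         invert_prpm, prediction_map, prediction_unmap,
                         run_length_pass, run_length_unpass)
from qscodec.synthetic import PROFILES, generate_qsd


def recs(*symbol_lists):
    return [QualityRecord(symbols=list(s), index=i)
            for i, s in enumerate(symbol_lists)]


fixed_records = st.integers(1, 12).flatmap(
    lambda L: st.lists(
        st.lists(st.integers(0, 9), min_size=L, max_size=L),
        min_size=1, max_size=6))


class TestContextTable:
    def test_hand_counted_orderings(self):
        # pairs: start->0, 0->0, 0->1, 1->1
        table = build_context_table(recs([0, 0, 1, 1]))
        assert table.alphabet == [0, 1]
        assert table.orders[START] == [0, 1]
        assert table.orders[0] == [0, 1]  # counts tie, ascending code
        assert table.orders[1] == [1, 0]

    def test_single_symbol_record(self):
        table = build_context_table(recs([5], [3]))
        assert table.orders[START][:2] == [3, 5]  # counts tie -> ascending
        assert table.orders[3] == [3, 5]  # unseen context: ascending

    def test_ranking_invariant_to_duplication(self):
        one = build_context_table(recs([2, 2, 7, 2]))
        two = build_context_table(recs([2, 2, 7, 2], [2, 2, 7, 2]))
        assert one.orders == two.orders

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_context_table(recs([]))

    def test_index_stream_roundtrip(self):
        table = build_context_table(recs([0, 0, 1, 1, 4, 4, 0]))
        alphabet, perms = table.to_index_streams()
        rebuilt = ContextTable.from_index_streams(alphabet, perms)
        assert rebuilt == table

    def test_non_permutation_rejected(self):
        with pytest.raises(CorruptionError):
            ContextTable.from_index_streams([3, 5], [0, 0] * 3)


class TestPredictionMap:
    def test_hand_ranked_example(self):
        records = recs([0, 0, 1, 1])
        table = build_context_table(records)
        assert prediction_map(records, table) == [0, 0, 1, 0]

    def test_constant_record_maps_to_zeros(self):
        records = recs([7, 7, 7, 7])
        table = build_context_table(records)
        assert prediction_map(records, table) == [0, 0, 0, 0]

    def test_unmap_inverts_example(self):
        records = recs([0, 0, 1, 1])
        table = build_context_table(records)
        assert prediction_unmap([0, 0, 1, 0], table, [4]) == records

    def test_foreign_symbol_rejected(self):
        table = build_context_table(recs([1, 1]))
        with pytest.raises(ValueError):
            prediction_map(recs([2]), table)

    def test_rank_out_of_range_is_corruption(self):
        table = build_context_table(recs([1, 1]))
        with pytest.raises(CorruptionError):
            prediction_unmap([1], table, [1])

    @settings(deadline=None, max_examples=100)
    @given(symbol_lists=fixed_records)
    def test_roundtrip(self, symbol_lists):
        records = recs(*symbol_lists)
        table = build_context_table(records)
        residuals = prediction_map(records, table)
        lengths = [len(r.symbols) for r in records]
        assert prediction_unmap(residuals, table, lengths) == records

    def test_rank_zero_concentration_on_sticky_markov(self):
        """With stay-probability p, at least ~p of residuals are rank 0."""
        profile = PROFILES["binned-short"].with_(m=1000, seed=11)
        block = generate_qsd(profile)  # 1e5 symbols, p = 0.9
        table = build_context_table(block.records)
        residuals = prediction_map(block.records, table)
        frac_zero = residuals.count(0) / len(residuals)
        assert frac_zero >= profile.stay_probability - 0.05


class TestRunLength:
    @pytest.mark.parametrize("stream, symbols, lengths", [
        ([5, 5, 5, 2, 2, 7], [5, 2, 7], [3, 2, 1]),
        ([], [], []),
        ([1, 2, 3], [1, 2, 3], [1, 1, 1]),
    ])
    def test_pass_examples(self, stream, symbols, lengths):
        assert run_length_pass(stream) == (symbols, lengths)
        assert run_length_unpass(symbols, lengths) == stream

    def test_zero_length_is_corruption(self):
        with pytest.raises(CorruptionError):
            run_length_unpass([1], [0])

    @settings(deadline=None, max_examples=100)
    @given(stream=st.lists(st.integers(0, 3), max_size=60))
    def test_roundtrip(self, stream):
        symbols, lengths = run_length_pass(stream)
        assert run_length_unpass(symbols, lengths) == stream
        assert sum(lengths) == len(stream)


class TestGate:
    def test_long_run_fires(self):
        assert gate_score(GateFeatures.from_stream([5, 5, 5, 5])) is True

    def test_run_free_stream_skips(self):
        assert gate_score(GateFeatures.from_stream([1, 2, 3])) is False

    def test_zero_theta_skips_on_tie(self):
        feats = GateFeatures.from_stream([5, 5, 5, 5])
        assert gate_score(feats, theta=(0, 0, 0, 0)) is False

    def test_default_theta_is_break_even_rule(self, rng):
        for _ in range(30):
            stream = rng.integers(0, 3, int(rng.integers(1, 40))).tolist()
            feats = GateFeatures.from_stream(stream)
            assert gate_score(feats) == (2 * feats.n_runs < feats.n)


class TestCascade:
    def test_constant_input_collapses_to_one_token_pair(self):
        mapped = apply_prpm(recs([7] * 6))
        assert mapped.level_flags == [True, True, False, False]
        assert mapped.symbols == [0]
        assert mapped.level_lengths == {1: [6]}

    def test_unpredictable_input_skips_all_rle(self):
        # transitions from 0 are split between 1 and 2 (tie-broken table),
        # so the residual stream [0, 0, 0, 1] has mean run length 2 and
        # every run-length gate declines
        mapped = apply_prpm(recs([0, 1, 0, 2]))
        assert mapped.symbols == [0, 0, 0, 1]
        assert mapped.level_flags == [True, False, False, False]
        assert mapped.level_lengths == {}

    def test_perfect_alternation_is_fully_predictable(self):
        # a strictly alternating record maps to all-zero residuals, which
        # the first run-length level then collapses
        mapped = apply_prpm(recs([0, 1, 0, 1]))
        assert mapped.level_flags == [True, True, False, False]
        assert mapped.symbols == [0]
        assert mapped.level_lengths == {1: [4]}

    def test_fired_gates_strictly_reduce_tokens(self, rng):
        for seed in range(20):
            profile = PROFILES["binned-short"].with_(m=10, fixed_length=50,
                                                     seed=seed)
            mapped = apply_prpm(generate_qsd(profile).records)
            for lvl, lengths in mapped.level_lengths.items():
                n_before = sum(lengths)
                assert 2 * len(lengths) < n_before

    def test_inverse_of_constant_example(self):
        records = recs([7] * 6)
        assert invert_prpm(apply_prpm(records), [6]) == records

    def test_flag_stream_mismatch_is_corruption(self):
        mapped = apply_prpm(recs([7] * 6))
        mapped.level_flags[2] = True  # claims a level with no stream
        with pytest.raises(CorruptionError):
            invert_prpm(mapped, [6])

    @settings(deadline=None, max_examples=100)
    @given(symbol_lists=fixed_records)
    def test_roundtrip_random(self, symbol_lists):
        records = recs(*symbol_lists)
        L = len(records[0].symbols)
        mapped = apply_prpm(records)
        assert invert_prpm(mapped, [L] * len(records)) == records

    @pytest.mark.parametrize("profile_name", sorted(PROFILES))
    def test_roundtrip_all_profiles(self, profile_name):
        profile = PROFILES[profile_name].with_(m=8, seed=3)
        if profile.fixed_length is None:
            profile = profile.with_(length_range=None, fixed_length=120)
        records = generate_qsd(profile).records
        mapped = apply_prpm(records)
        L = profile.fixed_length
        assert invert_prpm(mapped, [L] * len(records)) == records
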