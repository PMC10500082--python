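"""Clustering, routing, alignment, vote counting, LLRs and re-decoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligocodec import construct_code
from oligocodec.channel import ChannelParams, Read, sample_reads
from oligocodec.decoder import (
    Cluster,
    ReDecodeSchedule,
    ScheduleExhausted,
    accumulate_counts,
    compute_llr,
    decode_reads,
    ed_filter,
    finalize,
    index_cluster,
    iterative_redecode,
    levenshtein,
    llr_matrix,
    msa_align,
    route_cluster,
    singleton_vl_counts,
)
from oligocodec.encoder import IntegrityError, encode_file, seq_to_codes


def _read(seq, q=38, last_q=None, source=-1):
    quals = np.full(len(seq), q, dtype=np.int16)
    if last_q is not None:
        quals[-1] = last_q
    return Read(seq, quals, source)


def _brute_levenshtein(a, b):
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        _brute_levenshtein(a[1:], b[1:]) + (a[0] != b[0]),
        _brute_levenshtein(a[1:], b) + 1,
        _brute_levenshtein(a, b[1:]) + 1,
    )


class TestLevenshtein:
    def test_examples(self):
        assert levenshtein("GATTACA", "GATTACA") == 0
        assert levenshtein("GATTACA", "GACTACA") == 1
        assert levenshtein("ACGT", "") == 4

    @settings(max_examples=60, derandomize=True)
    @given(
        st.text(alphabet="ACGT", max_size=7),
        st.text(alphabet="ACGT", max_size=7),
    )
    def test_matches_brute_force_recursion(self, a, b):
        assert levenshtein(a, b) == _brute_levenshtein(a, b)


class TestIndexClustering:
    def test_clean_reads_land_on_their_ordinal(self, small_pool, small_cfg):
        _, records, _ = small_pool
        reads = [_read(r.sequence, source=r.ordinal) for r in records[:10]]
        clusters, stats = index_cluster(reads, small_cfg)
        assert sorted(clusters) == list(range(10))
        assert stats["corrected_index"] == 0 and stats["rs_failed"] == 0

    def test_two_symbol_index_corruption_still_clusters(self, small_pool,
                                                        small_cfg):
        _, records, _ = small_pool
        seq = records[5].sequence
        # corrupt bases 0 and 4: two distinct RS symbols of the index region
        corrupted = list(seq)
        corrupted[0] = "A" if seq[0] != "A" else "C"
        corrupted[4] = "A" if seq[4] != "A" else "C"
        clusters, stats = index_cluster(
            [_read("".join(corrupted))], small_cfg
        )
        assert list(clusters) == [5]
        assert stats["corrected_index"] == 1

    def test_unknown_index_discarded(self, small_cfg):
        # a valid RS codeword whose index is outside the canonical list:
        # encode an index ordinal beyond total_oligos
        from oligocodec.encoder import index_with_parity_codes, codes_to_seq

        far = index_with_parity_codes(small_cfg.total_oligos + 200)[-1]
        seq = codes_to_seq(far) + "A" * small_cfg.payload_nt
        clusters, stats = index_cluster([_read(seq)], small_cfg)
        assert not clusters
        assert stats["unknown_index"] == 1

    def test_garbage_index_fails_rs(self, small_cfg):
        seq = "ACGT" * (small_cfg.oligo_nt // 4)
        seq = seq[: small_cfg.oligo_nt]
        clusters, stats = index_cluster([_read(seq)], small_cfg)
        assert stats["rs_failed"] + stats["unknown_index"] == 1


class TestEdFilter:
    def test_outlier_removed(self):
        base = "ACGTACGTACGTACGTACGT"
        outlier = "TTTCTTTCTTTCTTTCTTTC"  # ED 15 from base
        c = Cluster(0, [_read(base)] * 3 + [_read(outlier)])
        removed = ed_filter(c, d_th=10)
        assert removed == 1 and len(c.members) == 3

    def test_close_pair_kept(self):
        a = "ACGTACGTACGTACGT"
        b = "ACGAACGTACGTACGA"  # ED 2
        c = Cluster(0, [_read(a), _read(b)])
        assert ed_filter(c, d_th=10) == 0
        assert len(c.members) == 2

    def test_distant_pair_both_removed(self):
        a = "AAAAAAAAAAAAAAAA"
        b = "GGGGGGGGGGGGCCCC"  # ED 16 > 10
        c = Cluster(0, [_read(a), _read(b)])
        assert ed_filter(c, d_th=10) == 2
        assert c.members == []

    def test_singleton_passes(self):
        c = Cluster(0, [_read("ACGT")])
        assert ed_filter(c, d_th=10) == 0
        assert len(c.members) == 1


class TestRouting:
    def test_conditions(self):
        L = 20
        full = _read("A" * L)
        short = _read("A" * (L - 1))
        assert route_cluster(Cluster(0, [full, full, full]), L) == "direct"
        assert route_cluster(Cluster(0, [short]), L) == "singleton_vl"
        assert route_cluster(Cluster(0, [full, short]), L) == "msa"
        assert route_cluster(Cluster(0, []), L) is None


class TestSingletonRescue:
    def test_high_quality_last_base_votes(self, small_cfg):
        L = small_cfg.oligo_nt
        B = small_cfg.payload_bits
        read = _read("A" * (L - 2) + "T", last_q=35)  # length L-1, last base T
        votes = singleton_vl_counts(read, small_cfg)
        assert votes[B - 2] == 1 and votes[B - 1] == 1  # T = 11
        assert (votes[: B - 2] == -1).all()

    def test_q30_boundary_is_strict(self, small_cfg):
        L = small_cfg.oligo_nt
        read = _read("A" * (L - 1), last_q=30)
        assert (singleton_vl_counts(read, small_cfg) == -1).all()

    def test_l_minus_2_read_votes_a(self, small_cfg):
        L = small_cfg.oligo_nt
        B = small_cfg.payload_bits
        read = _read("C" * (L - 3) + "A", last_q=40)
        votes = singleton_vl_counts(read, small_cfg)
        assert votes[B - 2] == 0 and votes[B - 1] == 0  # A = 00


class TestMsaAlign:
    def test_identical_full_length(self):
        s = "ACGTACGTACGTACGTACGTACGT"
        c = Cluster(0, [_read(s), _read(s)])
        rows, qrows, L = msa_align(c, len(s))
        assert L == len(s)
        assert all(np.array_equal(r, seq_to_codes(s)) for r in rows)

    def test_interior_deletion_becomes_gap(self):
        s = "ACGTTGCAACGTTGCAACGT"
        short = s[:7] + s[8:]  # drop base 7
        c = Cluster(0, [_read(s), _read(short)])
        rows, qrows, L = msa_align(c, len(s))
        assert L == len(s)
        gaps = [int((r == 4).sum()) for r in rows]
        assert sorted(gaps) == [0, 1]
        assert (qrows[gaps.index(1)] == -1).sum() == 1

    def test_center_prefers_full_length(self):
        s = "ACGTACGTACGTACGTACGTACAG"
        c = Cluster(0, [_read(s[:-1]), _read(s), _read(s[:-2])])
        rows, _, L = msa_align(c, len(s))
        assert L == len(s)

    def test_needs_two_members(self):
        with pytest.raises(ValueError):
            msa_align(Cluster(0, [_read("ACGT")]), 4)


class TestCounting:
    def test_four_clean_reads(self, small_pool, small_cfg):
        _, records, _ = small_pool
        B = small_cfg.payload_bits
        clusters = {3: Cluster(3, [_read(records[3].sequence)] * 4)}
        counts, stats = accumulate_counts(clusters, small_cfg)
        total = counts.k0[3] + counts.k1[3]
        assert (total == 4).all()
        assert (counts.ke[3] == 0).all()
        assert stats["used_reads"] == 4

    def test_low_last_base_q_erases_last_two_bits_only(self, small_pool,
                                                       small_cfg):
        _, records, _ = small_pool
        B = small_cfg.payload_bits
        clusters = {
            0: Cluster(0, [_read(records[0].sequence, last_q=18)])
        }
        counts, _ = accumulate_counts(clusters, small_cfg)
        assert (counts.ke[0][: B - 2] == 0).all()
        assert (counts.ke[0][B - 2 :] == 1).all()

    def test_gap_positions_vote_erasure(self, small_pool, small_cfg):
        _, records, _ = small_pool
        seq = records[7].sequence
        mid = 16 + small_cfg.payload_nt // 2  # interior payload base
        short = seq[:mid] + seq[mid + 1 :]
        clusters = {7: Cluster(7, [_read(seq), _read(short)])}
        counts, _ = accumulate_counts(clusters, small_cfg)
        ke = counts.ke[7]
        assert ke.sum() == 2  # exactly one gapped payload base
        pos = np.nonzero(ke)[0]
        assert len(pos) == 2 and pos[0] % 2 == 0 and pos[1] == pos[0] + 1

    def test_bookkeeping_identity(self, small_pool, small_cfg):
        """k0 + k1 + ke equals the number of contributing reads everywhere."""
        data, records, _ = small_pool
        params = ChannelParams(seed=21)
        reads = sample_reads(records, 300, params, seed=21)
        from oligocodec.channel import length_filter

        kept, _ = length_filter(reads, small_cfg.oligo_nt)
        clusters, _ = index_cluster(kept, small_cfg)
        for c in clusters.values():
            ed_filter(c, small_cfg.d_th)
        counts, _ = accumulate_counts(clusters, small_cfg)
        total = counts.k0 + counts.k1 + counts.ke
        assert (total == counts.contributors[:, None]).all()
        assert (counts.ke >= 0).all()


class TestLLR:
    def test_balanced_votes_are_uninformative(self):
        sch = ReDecodeSchedule()
        assert compute_llr(2, 2, 5, 0, sch) == 0.0

    def test_closed_form_values(self):
        sch = ReDecodeSchedule()
        assert compute_llr(3, 0, 0, 0, sch) == pytest.approx(
            3 * np.log(0.98 / 0.02), rel=1e-12
        )
        assert compute_llr(3, 0, 0, 1, sch) == pytest.approx(
            3 * np.log(0.985 / 0.015), rel=1e-12
        )

    def test_magnitude_strictly_increases_with_iteration(self):
        sch = ReDecodeSchedule()
        mags = [abs(compute_llr(2, 1, 0, i, sch)) for i in range(4)]
        assert all(b > a for a, b in zip(mags, mags[1:]))

    def test_schedule_bounds(self):
        sch = ReDecodeSchedule(0.02, 0.005, 0.005)
        assert [i for i in range(10) if sch.valid(i)] == [0, 1, 2, 3]
        with pytest.raises(ScheduleExhausted):
            compute_llr(1, 0, 0, 4, sch)

    def test_erasure_rows_give_zero_llr(self, small_cfg):
        from oligocodec.decoder import PositionCounts

        n, B = small_cfg.total_oligos, small_cfg.payload_bits
        counts = PositionCounts(
            np.zeros((n, B), np.int32),
            np.zeros((n, B), np.int32),
            np.zeros(n, np.int32),
        )
        assert not llr_matrix(counts, ReDecodeSchedule()).any()


class TestIterativeRedecode:
    def test_noiseless_converges_in_one_round(self, toy_code):
        rng = np.random.default_rng(1)
        cols = toy_code.encode(
            rng.integers(0, 2, (8, 6), dtype=np.uint8)
        ).astype(float)
        llr0 = (1 - 2 * cols) * 10.0
        bits, ok, info = iterative_redecode(
            llr0, toy_code, ReDecodeSchedule()
        )
        assert ok and info["redecode_rounds"] == 1
        assert np.array_equal(bits, cols.astype(np.uint8))

    def test_failed_column_rescued_at_next_iteration(self, toy_code):
        """A vote pattern that defeats BP at eps_0 but converges once the
        LLR magnitudes grow at eps_1 (pattern found by seeded search)."""
        diff = np.array(
            [2, 3, 0, 2, 2, 1, 1, 3, -1, 1, 1, 2, -2, 0, 2, 2], dtype=float
        )
        sch = ReDecodeSchedule()
        llr0 = diff * sch.scale(0)
        single = ReDecodeSchedule(epsilon_end=0.02)  # i = 0 only
        _, ok0, info0 = iterative_redecode(llr0, toy_code, single)
        assert not ok0 and info0["redecode_rounds"] == 1

        clean = toy_code.encode(np.zeros(8, dtype=np.uint8)).astype(float)
        llr = np.column_stack([(1 - 2 * clean) * 10.0, llr0])
        bits, ok, info = iterative_redecode(llr, toy_code, sch)
        assert ok and info["redecode_rounds"] == 2
        assert not toy_code.syndrome(bits).any()

    def test_unrecoverable_column_reported(self, toy_code):
        """A vote pattern BP cannot resolve at any schedule scale (found by
        seeded search) exhausts all four rounds; the clean column is
        decoded once and never re-processed."""
        bad = np.array(
            [1, 1, 1, 2, 2, 0, 0, 1, 3, 1, -1, -1, -2, 1, -2, 1], dtype=float
        )
        sch = ReDecodeSchedule()
        clean = toy_code.encode(np.zeros(8, dtype=np.uint8)).astype(float)
        llr = np.column_stack([(1 - 2 * clean) * 10.0, bad * sch.scale(0)])
        bits, ok, info = iterative_redecode(llr, toy_code, sch)
        assert not ok
        assert info["failed_columns"] == [1]
        assert info["redecode_rounds"] == 4
        assert not bits[:, 0].any()  # clean column decoded correctly


class TestFinalize:
    def test_lossless_round_trip_zero_error_coverage_two(
        self, small_pool, small_cfg, small_code
    ):
        data, records, _ = small_pool
        params = ChannelParams(sub_rate=0, ins_rate=0, del_rate=0)
        reads = sample_reads(
            records, 2 * small_cfg.total_oligos, params, seed=31
        )
        res = decode_reads(reads, small_code, small_cfg)
        assert res.success and res.data == data

    def test_bit_flip_breaks_crc(self, small_pool, small_cfg):
        _, records, _ = small_pool
        from oligocodec.encoder import bases_to_bits

        bits = np.stack(
            [bases_to_bits(r.payload_nt) for r in records]
        )
        bits[0, 0] ^= 1
        with pytest.raises((IntegrityError, ValueError)):
            finalize(bits, small_cfg)

    def test_empty_file_round_trip(self, small_cfg, small_code):
        records, _ = encode_file(b"", small_cfg, code=small_code)
        params = ChannelParams(sub_rate=0, ins_rate=0, del_rate=0)
        reads = sample_reads(
            records, 2 * small_cfg.total_oligos, params, seed=32
        )
        res = decode_reads(reads, small_code, small_cfg)
        assert res.success and res.data == b""


class TestEndToEndNoisy:
    def test_noisy_round_trip_reports(self, small_pool, small_cfg,
                                      small_code):
        data, records, _ = small_pool
        params = ChannelParams(seed=41)
        reads = sample_reads(records, 400, params, seed=41)
        res = decode_reads(reads, small_code, small_cfg,
                           channel_params=params)
        assert res.success and res.data == data
        rep = res.report
        assert rep["used_reads"] <= rep["total_reads"]
        assert rep["crc_ok"] and rep["ldpc_converged"]
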