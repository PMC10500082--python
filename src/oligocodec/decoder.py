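"""Sequence-analysis-aided soft decoder: FASTQ reads back to the stored file.

The decoding pipeline mirrors the encoder in reverse, with the heavy lifting
in how noisy, variable-length reads are turned into per-bit soft information:

1. *Length filter* — keep reads at the frame length L or shortened by one or
   two bases (the exploitable variable-length reads).
2. *Index-based clustering* — RS-decode the first 16 nt of every read (8-nt
   index + 8-nt parity); up to two symbol errors are corrected, failures and
   indices outside the canonical list are discarded.
3. *ED-based clustering* — inside each cluster, any read whose minimum edit
   distance to every other member exceeds d_th (default 10) is evicted as a
   misclustered read.
4. *Condition routing* — clusters whose members all have length L skip
   alignment (condition 1); lone shortened reads (condition 3) contribute only
   their final base, and only when its Phred score exceeds 30; mixed-length
   clusters are co-registered by a center-star MSA (condition 4) and vote
   per aligned position when the alignment spans exactly L (condition 5),
   falling back to the last-base rescue otherwise (condition 6).
5. *Counting and LLRs* — per (oligo, payload-bit) the votes k0/k1/ke feed
   LLR_i = (k0 - k1) * ln[(1 - eps_i)/eps_i] with eps_i = eps0 - i*delta_eps;
   for the last two bits, a read's vote only counts when its last-base Phred
   score exceeds 20.  Unseen oligos give all-zero LLR rows (pure erasures).
6. *Iterative re-decoding* — all bit-position codewords are belief-propagation
   decoded at i = 0; codewords that fail are retried with the LLRs recomputed
   at i+1 (larger magnitudes) until everything converges or eps_i would fall
   below eps_end.
7. *Finalize* — extract the systematic rows, verify CRC-32, de-randomize and
   strip the length header.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from . import algebra
from .channel import ChannelParams, Read, length_filter
from .config import EncodingConfig, FRAME_PREFIX_NT
from .encoder import IntegrityError, unpack_payload, valid_index_codes
from .ldpc import LDPCCode

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitutions, insertions, deletions)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW")["editDistance"]


@dataclass
class Cluster:
    """Reads sharing one RS-decoded index, plus routing state."""

    index_ordinal: int
    members: list[Read] = field(default_factory=list)
    route: str | None = None  # direct | singleton_vl | msa
    post_msa_ok: bool | None = None  # condition 5 (True) vs 6 (False)


@dataclass
class ReDecodeSchedule:
    """Channel-parameter schedule for LDPC re-decoding: eps_i = eps0 - i*d."""

    epsilon0: float = 0.02
    delta_epsilon: float = 0.005
    epsilon_end: float = 0.005

    def epsilon(self, i: int) -> float:
        return self.epsilon0 - i * self.delta_epsilon

    def valid(self, i: int) -> bool:
        eps = self.epsilon(i)
        return eps > 0 and eps >= self.epsilon_end - 1e-12

    def scale(self, i: int) -> float:
        """ln[(1 - eps_i)/eps_i]; strictly increasing in i."""
        if not self.valid(i):
            raise ScheduleExhausted(f"re-decode iteration {i} not allowed")
        eps = self.epsilon(i)
        return float(np.log((1.0 - eps) / eps))


class ScheduleExhausted(RuntimeError):
    pass


def compute_llr(k0: int, k1: int, ke: int, i: int,
                schedule: ReDecodeSchedule) -> float:
    """Soft input for one bit position: (k0 - k1) * ln[(1-eps_i)/eps_i].

    Erasure votes carry no information and do not enter the value.
    """
    return (k0 - k1) * schedule.scale(i)


# ---------------------------------------------------------------------------
# clustering


def _index_ordinal_map(total_oligos: int) -> dict[int, int]:
    codes = valid_index_codes()[:total_oligos]
    keys = (
        (codes[:, 0].astype(np.int64) << 14)
        | (codes[:, 1].astype(np.int64) << 12)
        | (codes[:, 2].astype(np.int64) << 10)
        | (codes[:, 3].astype(np.int64) << 8)
        | (codes[:, 4].astype(np.int64) << 6)
        | (codes[:, 5].astype(np.int64) << 4)
        | (codes[:, 6].astype(np.int64) << 2)
        | codes[:, 7].astype(np.int64)
    )
    return {int(k): i for i, k in enumerate(keys)}


def index_cluster(
    reads: list[Read], config: EncodingConfig
) -> tuple[dict[int, Cluster], dict]:
    """RS-decode each read's index region and group reads by decoded ordinal.

    Returns (clusters, stats); stats counts discards by reason and the number
    of reads whose index needed RS correction.
    """
    stats = {"rs_failed": 0, "unknown_index": 0, "invalid_base": 0,
             "corrected_index": 0}
    clusters: dict[int, Cluster] = {}
    usable: list[Read] = []
    prefixes = []
    for r in reads:
        try:
            codes = r.codes
        except ValueError:
            stats["invalid_base"] += 1
            continue
        if len(codes) < FRAME_PREFIX_NT:
            stats["invalid_base"] += 1
            continue
        usable.append(r)
        prefixes.append(codes[:FRAME_PREFIX_NT])
    if not usable:
        return clusters, stats

    prefix = np.stack(prefixes)
    syms = (prefix[:, 0::2] << 2) | prefix[:, 1::2]  # (N, 8) GF16 symbols
    info, status = algebra.rs_decode_batch(syms)
    keys = (
        (info[:, 0].astype(np.int64) << 12)
        | (info[:, 1].astype(np.int64) << 8)
        | (info[:, 2].astype(np.int64) << 4)
        | info[:, 3].astype(np.int64)
    )
    omap = _index_ordinal_map(config.total_oligos)
    for r, st, key in zip(usable, status, keys):
        if st == 2:
            stats["rs_failed"] += 1
            continue
        ordinal = omap.get(int(key))
        if ordinal is None:
            stats["unknown_index"] += 1
            continue
        if st == 1:
            stats["corrected_index"] += 1
        clusters.setdefault(ordinal, Cluster(ordinal)).members.append(r)
    return clusters, stats


def ed_filter(cluster: Cluster, d_th: int = 10) -> int:
    """Evict members whose minimum edit distance to every other member
    exceeds d_th.  Size-1 clusters pass unchanged.  Eviction is simultaneous:
    in a 2-read cluster at mutual distance > d_th both reads go (neither has
    a close companion).  Returns the number of discarded reads.
    """
    members = cluster.members
    s = len(members)
    if s < 2:
        return 0
    dmin = np.full(s, np.inf)
    for i in range(s):
        for j in range(i + 1, s):
            d = levenshtein(members[i].seq, members[j].seq)
            if d < dmin[i]:
                dmin[i] = d
            if d < dmin[j]:
                dmin[j] = d
    keep = dmin <= d_th
    cluster.members = [m for m, k in zip(members, keep) if k]
    return int((~keep).sum())


def route_cluster(cluster: Cluster, frame_len: int) -> str | None:
    """Conditions 1-4: direct counting, singleton rescue, or MSA."""
    if not cluster.members:
        cluster.route = None
        return None
    if all(len(m) == frame_len for m in cluster.members):
        cluster.route = "direct"  # condition 1
    elif len(cluster.members) == 1:
        cluster.route = "singleton_vl"  # condition 3
    else:
        cluster.route = "msa"  # condition 4
    return cluster.route


# ---------------------------------------------------------------------------
# alignment

GAP = 4  # gap code in aligned rows


def msa_align(
    cluster: Cluster, frame_len: int
) -> tuple[list[np.ndarray], list[np.ndarray], int]:
    """Center-star multiple alignment of a mixed-length cluster.

    The center is the member closest to the frame length (ties: highest mean
    Phred score); every other member is pairwise-aligned to it.  Bases the
    center lacks (insertions) are dropped, missing bases become gap symbols,
    so all rows share the center's length L, returned alongside per-row
    quality arrays (-1 at gaps).
    """
    members = cluster.members
    if len(members) < 2:
        raise ValueError("MSA needs at least two reads")

    def center_key(r: Read):
        return (abs(frame_len - len(r)), -float(np.mean(r.quals)))

    center = min(members, key=center_key)
    L = len(center)
    rows, qrows = [], []
    for m in members:
        if m is center:
            rows.append(center.codes.copy())
            qrows.append(np.asarray(center.quals, dtype=np.int16))
            continue
        res = edlib.align(m.seq, center.seq, mode="NW", task="path")
        row = np.full(L, GAP, dtype=np.uint8)
        qrow = np.full(L, -1, dtype=np.int16)
        qi = 0  # query (member) cursor
        ti = 0  # target (center) cursor
        codes = m.codes
        quals = m.quals
        for num, op in _CIGAR_RE.findall(res["cigar"]):
            num = int(num)
            if op in "=XM":
                row[ti : ti + num] = codes[qi : qi + num]
                qrow[ti : ti + num] = quals[qi : qi + num]
                qi += num
                ti += num
            elif op == "I":  # extra bases in the member: no center position
                qi += num
            elif op == "D":  # gap in the member
                ti += num
        rows.append(row)
        qrows.append(qrow)
    return rows, qrows, L


# ---------------------------------------------------------------------------
# vote counting


@dataclass
class PositionCounts:
    """Per (oligo, payload-bit) vote counts; ke = contributors - k0 - k1."""

    k0: np.ndarray  # (n, B)
    k1: np.ndarray  # (n, B)
    contributors: np.ndarray  # (n,) routed reads contributing to each oligo

    @property
    def ke(self) -> np.ndarray:
        return self.contributors[:, None] - self.k0 - self.k1

    def diff(self) -> np.ndarray:
        return (self.k0 - self.k1).astype(np.float64)


def _payload_bits_from_codes(codes: np.ndarray, B: int) -> np.ndarray:
    """Aligned/full-frame payload codes -> bit votes (-1 = erasure)."""
    votes = np.full(B, -1, dtype=np.int8)
    pay = codes[FRAME_PREFIX_NT:]
    ok = pay != GAP
    idx = np.nonzero(ok)[0]
    votes[2 * idx] = pay[idx] >> 1
    votes[2 * idx + 1] = pay[idx] & 1
    return votes


def singleton_vl_counts(
    read: Read, config: EncodingConfig, use_qscore: bool = True
) -> np.ndarray:
    """Condition 3/6 vote vector: everything is an erasure except the final
    base, kept only when its Phred score exceeds the Q>30 gate (the relative
    position of the last base is trustworthy even after a deletion)."""
    B = config.payload_bits
    votes = np.full(B, -1, dtype=np.int8)
    if len(read) <= FRAME_PREFIX_NT:
        return votes
    if use_qscore and read.last_q <= config.q_last_gate:
        return votes
    last = int(read.codes[-1])
    votes[B - 2] = last >> 1
    votes[B - 1] = last & 1
    return votes


def accumulate_counts(
    clusters: dict[int, Cluster],
    config: EncodingConfig,
    use_qscore: bool = True,
) -> tuple[PositionCounts, dict]:
    """Route every cluster and tally per-position votes.

    The Q>20 gate applies to the last two bit positions of full-frame and
    condition-5 contributions; condition-3/6 reads go through the stricter
    Q>30 last-base rescue.  Reads contributing at least one counted vote are
    reported as "used".
    """
    n, B = config.total_oligos, config.payload_bits
    L = config.oligo_nt
    k0 = np.zeros((n, B), dtype=np.int32)
    k1 = np.zeros((n, B), dtype=np.int32)
    contrib = np.zeros(n, dtype=np.int32)
    used = 0
    cond_counts = {c: 0 for c in (1, 3, 4, 5, 6)}

    def add_votes(ordinal: int, votes: np.ndarray) -> bool:
        nonlocal used
        k0[ordinal] += votes == 0
        k1[ordinal] += votes == 1
        contrib[ordinal] += 1
        if (votes >= 0).any():
            used += 1
            return True
        return False

    def gate_last_two(votes: np.ndarray, read: Read) -> None:
        if use_qscore and read.last_q <= config.q_count_gate:
            votes[B - 2 :] = -1

    for ordinal, cluster in clusters.items():
        route = route_cluster(cluster, L)
        if route is None:
            continue
        if route == "direct":
            cond_counts[1] += len(cluster.members)
            for m in cluster.members:
                votes = _payload_bits_from_codes(m.codes, B)
                gate_last_two(votes, m)
                add_votes(ordinal, votes)
        elif route == "singleton_vl":
            cond_counts[3] += 1
            m = cluster.members[0]
            add_votes(ordinal, singleton_vl_counts(m, config, use_qscore))
        else:  # msa
            cond_counts[4] += len(cluster.members)
            rows, qrows, La = msa_align(cluster, L)
            cluster.post_msa_ok = La == L
            if cluster.post_msa_ok:  # condition 5
                cond_counts[5] += len(cluster.members)
                for m, row in zip(cluster.members, rows):
                    # full-frame members are already positionally registered;
                    # their own bases are authoritative (aligning them to an
                    # imperfect center could only introduce artifacts)
                    src = m.codes if len(m) == L else row
                    votes = _payload_bits_from_codes(src, B)
                    gate_last_two(votes, m)
                    add_votes(ordinal, votes)
            else:  # condition 6: per-read last-base rescue
                cond_counts[6] += len(cluster.members)
                for m in cluster.members:
                    add_votes(
                        ordinal, singleton_vl_counts(m, config, use_qscore)
                    )

    stats = {
        "used_reads": used,
        "erasure_clusters": int((contrib == 0).sum()),
        "condition_counts": cond_counts,
    }
    return PositionCounts(k0, k1, contrib), stats


# ---------------------------------------------------------------------------
# LDPC (re-)decoding


def llr_matrix(
    counts: PositionCounts, schedule: ReDecodeSchedule, i: int = 0
) -> np.ndarray:
    """The (n, B) soft-input matrix at re-decode iteration i."""
    return counts.diff() * schedule.scale(i)


def iterative_redecode(
    llr0: np.ndarray,
    code: LDPCCode,
    schedule: ReDecodeSchedule,
    max_iter: int = 50,
) -> tuple[np.ndarray, bool, dict]:
    """Decode all bit-position codewords; retry failures with boosted LLRs.

    ``llr0`` is the LLR matrix at i = 0.  Because every entry is
    (k0 - k1) * ln[(1-eps_i)/eps_i], recomputing at iteration i amounts to
    rescaling by scale(i)/scale(0); only columns that failed are re-decoded.
    """
    llr0 = np.atleast_2d(np.asarray(llr0, dtype=np.float64))
    if llr0.shape[0] == 1 and code.n != 1:
        llr0 = llr0.T
    if llr0.shape[0] != code.n:
        raise ValueError(f"llr matrix must have {code.n} rows")
    bits = np.zeros(llr0.shape, dtype=np.uint8)
    pending = np.arange(llr0.shape[1])
    rounds = 0
    bp_iters = []
    i = 0
    while len(pending) and schedule.valid(i):
        rounds += 1
        scale = schedule.scale(i) / schedule.scale(0)
        res = code.bp_decode(llr0[:, pending] * scale, max_iter=max_iter)
        bits[:, pending] = res.bits
        bp_iters.append(int(res.iterations_used))
        pending = pending[~res.converged]
        i += 1
    info = {
        "redecode_rounds": rounds,
        "failed_columns": pending.tolist(),
        "bp_iterations": bp_iters,
    }
    return bits, len(pending) == 0, info


def finalize(
    decoded: np.ndarray, config: EncodingConfig
) -> bytes:
    """Systematic extraction + CRC verification + de-randomization."""
    info_rows = decoded[: config.payload_oligos]
    return unpack_payload(info_rows, config)


# ---------------------------------------------------------------------------
# top level


@dataclass
class DecodeResult:
    data: bytes | None
    success: bool
    report: dict


def decode_reads(
    reads: list[Read],
    code: LDPCCode,
    config: EncodingConfig,
    use_vl: bool = True,
    use_qscore: bool = True,
    channel_params: ChannelParams | None = None,
) -> DecodeResult:
    """Run the full decoding pipeline over merged reads.

    ``use_vl=False`` restricts input to full-frame reads and
    ``use_qscore=False`` disables both Phred gates — together they reproduce
    the reference decoder the variable-length/Q-score machinery is measured
    against.
    """
    L = config.oligo_nt
    total = len(reads)
    if use_vl:
        kept, _ = length_filter(reads, L, channel_params)
    else:
        kept = [r for r in reads if len(r) == L]
    clusters, cstats = index_cluster(kept, config)
    ed_discarded = sum(
        ed_filter(c, config.d_th) for c in clusters.values()
    )
    counts, astats = accumulate_counts(clusters, config, use_qscore)
    schedule = ReDecodeSchedule(
        config.epsilon0, config.delta_epsilon, config.epsilon_end
    )
    llr0 = llr_matrix(counts, schedule, 0)
    bits, converged, dinfo = iterative_redecode(
        llr0, code, schedule, config.bp_max_iter
    )
    data: bytes | None = None
    crc_ok = False
    if converged:
        try:
            data = finalize(bits, config)
            crc_ok = True
        except (IntegrityError, ValueError):
            data = None
    report = {
        "total_reads": total,
        "length_filtered_out": total - len(kept),
        "used_reads": astats["used_reads"],
        "used_fraction": astats["used_reads"] / total if total else 0.0,
        "corrected_index": cstats["corrected_index"],
        "rs_failed": cstats["rs_failed"],
        "unknown_index": cstats["unknown_index"],
        "invalid_base": cstats["invalid_base"],
        "ed_discarded": ed_discarded,
        "erasure_clusters": astats["erasure_clusters"],
        "recovered_clusters": config.total_oligos
        - astats["erasure_clusters"],
        "condition_counts": astats["condition_counts"],
        "ldpc_converged": bool(converged),
        "crc_ok": crc_ok,
        **dinfo,
    }
    return DecodeResult(data, data is not None, report)
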