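"""Synthesis/PCR/sequencing channel simulator.

Emulates the post-merge read stream of an Illumina-style run over a designed
oligo pool: reads are drawn i.i.d. uniformly with replacement (so coverage
dropout emerges naturally at low sampling depth), each copy passes through a
left-to-right insertion/deletion/substitution process at ~1% total base error
rate, and per-base Phred scores are drawn conditioned on whether the emitted
base is correct.  The final frame position carries an elevated substitution
rate, reflecting the empirically error-prone last base of merged reads.

Only reads at the frame length L or shortened by one or two bases
(L-1, L-2 — the variable-length reads the decoder can exploit) survive
``length_filter``; shorter or lengthened reads are discarded, standing in for
merge artifacts of real paired-end data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .encoder import OligoRecord, codes_to_seq, seq_to_codes

# Phred distributions conditioned on base correctness.  Correct bases peak at
# Q38 with ~3% mass below Q30; erroneous bases peak at Q15 with a small
# high-quality tail.  Chosen once so a default corpus lands near the observed
# ~96% of bases at Q30+.
Q_CORRECT_VALUES = (24, 28, 32, 34, 36, 38, 40)
Q_CORRECT_PROBS = (0.01, 0.02, 0.03, 0.06, 0.12, 0.36, 0.40)
Q_ERROR_VALUES = (8, 12, 15, 18, 22, 27, 33)
Q_ERROR_PROBS = (0.10, 0.20, 0.30, 0.20, 0.12, 0.05, 0.03)


@dataclass
class ChannelParams:
    """Per-base error model; defaults total ~1% with indels rare enough that
    ~94% of reads keep the full frame length."""

    sub_rate: float = 0.0096
    ins_rate: float = 0.0002
    del_rate: float = 0.0002
    last_base_multiplier: float = 3.0
    q_correct: tuple = (Q_CORRECT_VALUES, Q_CORRECT_PROBS)
    q_error: tuple = (Q_ERROR_VALUES, Q_ERROR_PROBS)
    length_keep_deltas: tuple = (0, 1, 2)  # L, L-1, L-2
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChannelParams":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("q_correct", "q_error"):
            if k in d:
                d[k] = tuple(tuple(x) for x in d[k])
        if "length_keep_deltas" in d:
            d["length_keep_deltas"] = tuple(d["length_keep_deltas"])
        return cls(**d)


@dataclass
class Read:
    """One merged read: bases, per-base Phred scores, and (evaluation-only)
    ground-truth source oligo."""

    seq: str
    quals: np.ndarray
    source_ordinal: int = -1
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.seq) != len(self.quals):
            raise ValueError("bases and quality scores must align")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = seq_to_codes(self.seq)
        return self._codes

    @property
    def last_q(self) -> int:
        return int(self.quals[-1]) if len(self.quals) else -1


def corrupt(oligo: str, params: ChannelParams, rng: np.random.Generator) -> Read:
    """Pass one oligo through the error process (single-read contract)."""
    codes = seq_to_codes(oligo)[None, :]
    reads = _corrupt_batch(codes, np.zeros(1, dtype=np.int64), params, rng)
    return reads[0]


def _draw(dist: tuple, size, rng: np.random.Generator) -> np.ndarray:
    values, probs = dist
    return rng.choice(np.asarray(values, dtype=np.int16), size=size,
                      p=np.asarray(probs, dtype=np.float64))


def _corrupt_batch(
    pool_codes: np.ndarray,
    src: np.ndarray,
    params: ChannelParams,
    rng: np.random.Generator,
) -> list[Read]:
    """Vectorized corruption of many sampled reads.

    Event per original position: none / deletion (skip) / insertion (uniform
    extra base emitted before it) / substitution (uniform different base).
    All random draws are made up front so results are reproducible regardless
    of which path (pure-substitution fast path vs per-read indel path) a read
    takes.
    """
    N, L = len(src), pool_codes.shape[1]
    u = rng.random((N, L))
    sub_vec = np.full(L, params.sub_rate)
    sub_vec[-1] *= params.last_base_multiplier
    t_del = params.del_rate
    t_ins = t_del + params.ins_rate
    t_sub = t_ins + sub_vec
    ev = np.zeros((N, L), dtype=np.uint8)
    ev[u < t_del] = 1
    ev[(u >= t_del) & (u < t_ins)] = 2
    ev[(u >= t_ins) & (u < t_sub)] = 3

    sub_off = rng.integers(1, 4, size=(N, L), dtype=np.int64)
    ins_base = rng.integers(0, 4, size=(N, L), dtype=np.uint8)
    q_corr = _draw(params.q_correct, (N, L), rng)
    q_err = _draw(params.q_error, (N, L), rng)
    q_ins = _draw(params.q_error, (N, L), rng)

    orig = pool_codes[src]
    subbed = ((orig + sub_off) % 4).astype(np.uint8)
    has_indel = ((ev == 1) | (ev == 2)).any(axis=1)

    reads: list[Read] = []
    for r in range(N):
        if not has_indel[r]:
            bases = np.where(ev[r] == 3, subbed[r], orig[r]).astype(np.uint8)
            quals = np.where(ev[r] == 3, q_err[r], q_corr[r])
        else:
            b_parts, q_parts = [], []
            for p in range(L):
                e = ev[r, p]
                if e == 2:
                    b_parts.append(int(ins_base[r, p]))
                    q_parts.append(int(q_ins[r, p]))
                if e == 1:
                    continue
                if e == 3:
                    b_parts.append(int(subbed[r, p]))
                    q_parts.append(int(q_err[r, p]))
                else:
                    b_parts.append(int(orig[r, p]))
                    q_parts.append(int(q_corr[r, p]))
            bases = np.array(b_parts, dtype=np.uint8)
            quals = np.array(q_parts, dtype=np.int16)
        reads.append(
            Read(codes_to_seq(bases), np.asarray(quals, dtype=np.int16),
                 int(src[r]), _codes=bases)
        )
    return reads


def sample_reads(
    pool: list[OligoRecord],
    sampling_number: int,
    params: ChannelParams,
    seed: int | None = None,
) -> list[Read]:
    """Draw ``sampling_number`` reads uniformly with replacement and corrupt
    them; deterministic for a fixed seed."""
    if sampling_number < 0:
        raise ValueError("sampling_number must be >= 0")
    if not pool:
        raise ValueError("oligo pool is empty")
    if sampling_number == 0:
        return []
    rng = np.random.default_rng(params.seed if seed is None else seed)
    pool_codes = np.stack([seq_to_codes(r.sequence) for r in pool])
    src = rng.integers(0, len(pool), size=sampling_number, dtype=np.int64)
    return _corrupt_batch(pool_codes, src, params, rng)


def length_filter(
    reads: list[Read], frame_len: int, params: ChannelParams | None = None
) -> tuple[list[Read], float]:
    """Keep reads of length L, L-1 or L-2 (per params); returns kept fraction."""
    deltas = params.length_keep_deltas if params else (0, 1, 2)
    keep_lens = {frame_len - d for d in deltas}
    kept = [r for r in reads if len(r) in keep_lens]
    frac = len(kept) / len(reads) if reads else 1.0
    return kept, frac


# ---------------------------------------------------------------------------
# FASTQ IO (Phred+33)


def write_fastq(reads: list[Read], path: str | Path) -> None:
    def gen():
        for i, r in enumerate(reads):
            rec = SeqRecord(Seq(r.seq), id=f"read_{i:07d}", description="")
            rec.letter_annotations["phred_quality"] = [int(q) for q in r.quals]
            yield rec

    SeqIO.write(gen(), str(path), "fastq")


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(
                str(rec.seq),
                np.asarray(rec.letter_annotations["phred_quality"],
                           dtype=np.int16),
            )
        )
    return reads


def write_ground_truth(reads: list[Read], path: str | Path) -> None:
    """Evaluation-only TSV (read id -> source ordinal); never decoder input."""
    with Path(path).open("w") as fh:
        fh.write("read_id\tsource_ordinal\n")
        for i, r in enumerate(reads):
            fh.write(f"read_{i:07d}\t{r.source_ordinal}\n")
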