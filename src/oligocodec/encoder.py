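"""File -> oligo pool encoding.

Pipeline: the input bytes get a 64-bit big-endian length header, are XOR-
randomized with a deterministic keystream (to break homopolymer runs and
GC skew), CRC-32 tagged, zero-padded and reshaped into a (payload_oligos x
payload_bits) matrix.  Each bit *column* is then LDPC-encoded across oligos
(the inter-oligo code), bits map to bases two at a time (A=00, C=01, G=10,
T=11), and every row receives its RS-protected 8-nt index.  Optionally the
fixed sequencing primers flank each 152-nt oligo to the synthesized 199 nt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import algebra
from .config import EncodingConfig, FRAME_PREFIX_NT, INDEX_NT
from .ldpc import LDPCCode, construct_code

BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF_BYTE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF_BYTE[_b] = _i

LENGTH_HEADER_BITS = 64
CRC_BITS = 32


class CapacityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# bit/base primitives


def bits_to_bases(bits) -> str:
    """Map an even-length bit array to bases, two bits per base (A=00..T=11)."""
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.size % 2:
        raise ValueError("bit sequence must have even length")
    codes = bits[0::2] * 2 + bits[1::2]
    return _BASE_BYTES[codes].tobytes().decode()


def bases_to_bits(seq: str) -> np.ndarray:
    codes = seq_to_codes(seq)
    bits = np.empty(2 * len(codes), dtype=np.uint8)
    bits[0::2] = codes >> 1
    bits[1::2] = codes & 1
    return bits


def seq_to_codes(seq: str) -> np.ndarray:
    codes = _CODE_OF_BYTE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains a non-ACGT character")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASE_BYTES[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


# ---------------------------------------------------------------------------
# randomization


def _keystream_words(nwords: int, seed: int) -> np.ndarray:
    """xorshift64* keystream; deterministic, involutive use via XOR."""
    state = (seed & 0xFFFFFFFFFFFFFFFF) or 0x9E3779B97F4A7C15
    out = np.empty(nwords, dtype=np.uint64)
    for i in range(nwords):
        state ^= (state >> 12) & 0xFFFFFFFFFFFFFFFF
        state ^= (state << 25) & 0xFFFFFFFFFFFFFFFF
        state ^= (state >> 27) & 0xFFFFFFFFFFFFFFFF
        out[i] = (state * 0x2545F4914F6CDD1D) & 0xFFFFFFFFFFFFFFFF
    return out


def randomize(bits, seed: int) -> np.ndarray:
    """XOR with the seeded pseudo-random keystream (its own inverse)."""
    bits = np.asarray(bits, dtype=np.uint8)
    nwords = (bits.size + 63) // 64
    key = np.unpackbits(
        _keystream_words(nwords, seed).byteswap().view(np.uint8)
    )[: bits.size]
    return bits ^ key


# ---------------------------------------------------------------------------
# payload packing


def pack_payload(file_bytes: bytes, config: EncodingConfig) -> np.ndarray:
    """Header + randomize + CRC + pad -> (payload_oligos, payload_bits) bits."""
    header = len(file_bytes).to_bytes(LENGTH_HEADER_BITS // 8, "big")
    raw = np.unpackbits(np.frombuffer(header + file_bytes, dtype=np.uint8))
    needed = raw.size + CRC_BITS
    if needed > config.capacity_bits:
        max_bytes = (config.capacity_bits - LENGTH_HEADER_BITS - CRC_BITS) // 8
        raise CapacityError(
            f"file of {len(file_bytes)} bytes exceeds pool capacity: "
            f"at most {max_bytes} bytes "
            f"({config.capacity_bits} bits incl. header and CRC)"
        )
    stream = algebra.crc32_append(randomize(raw, config.prbs_seed))
    padded = np.zeros(config.capacity_bits, dtype=np.uint8)
    padded[: stream.size] = stream
    return padded.reshape(config.payload_oligos, config.payload_bits)


def unpack_payload(matrix: np.ndarray, config: EncodingConfig) -> bytes:
    """Inverse of pack_payload; raises on CRC or header inconsistency."""
    stream = np.asarray(matrix, dtype=np.uint8).reshape(-1)
    header = np.packbits(randomize(stream[:LENGTH_HEADER_BITS],
                                   config.prbs_seed)).tobytes()
    nbytes = int.from_bytes(header, "big")
    data_bits = LENGTH_HEADER_BITS + 8 * nbytes
    if data_bits + CRC_BITS > stream.size:
        raise ValueError(f"length header claims {nbytes} bytes, beyond capacity")
    if not algebra.crc32_check(stream[: data_bits + CRC_BITS]):
        raise IntegrityError("CRC-32 verification failed")
    payload = randomize(stream[:data_bits], config.prbs_seed)
    return np.packbits(payload).tobytes()[LENGTH_HEADER_BITS // 8 :]


class IntegrityError(ValueError):
    """Recovered bit stream fails its CRC-32 check."""


# ---------------------------------------------------------------------------
# inter-oligo encoding


def interoligo_encode(payload: np.ndarray, code: LDPCCode) -> np.ndarray:
    """LDPC-encode every bit position (column) across oligos.

    payload: (k, B) data rows; returns (n, B) with parity rows appended.
    """
    payload = np.asarray(payload, dtype=np.uint8)
    if payload.ndim != 2 or payload.shape[0] != code.k:
        raise ValueError(
            f"payload must be ({code.k}, B), got {payload.shape}"
        )
    return code.encode(payload)


# ---------------------------------------------------------------------------
# indices


def _all_8mer_codes() -> np.ndarray:
    return np.indices((4,) * INDEX_NT).reshape(INDEX_NT, -1).T.astype(np.uint8)


def valid_index_codes() -> np.ndarray:
    """All 8-mers with homopolymer run <= 3 and GC count in [2, 6], in
    lexicographic (A<C<G<T) order."""
    codes = _all_8mer_codes()
    same = codes[:, 1:] == codes[:, :-1]
    run4 = same[:, :-2] & same[:, 1:-1] & same[:, 2:]  # any 4-long run
    gc = ((codes == 1) | (codes == 2)).sum(axis=1)
    keep = ~run4.any(axis=1) & (gc >= 2) & (gc <= 6)
    return codes[keep]


def generate_indices(count: int) -> list[str]:
    """The first ``count`` valid 8-nt indices (deterministic policy)."""
    codes = valid_index_codes()
    if count > len(codes):
        raise ValueError(
            f"only {len(codes)} valid index candidates exist, need {count}"
        )
    flat = _BASE_BYTES[codes[:count]].reshape(count, INDEX_NT)
    return [row.tobytes().decode() for row in flat]


def index_with_parity_codes(count: int) -> np.ndarray:
    """(count, 16) base codes: 8-nt index followed by its 8-nt RS parity."""
    codes = valid_index_codes()[:count]
    syms = (codes[:, 0::2] << 2) | codes[:, 1::2]  # (count, 4) GF16 symbols
    cw = algebra.rs_encode_batch(syms)  # (count, 8)
    out = np.empty((count, FRAME_PREFIX_NT), dtype=np.uint8)
    out[:, 0::2] = cw >> 2
    out[:, 1::2] = cw & 3
    return out


# ---------------------------------------------------------------------------
# assembly


@dataclass
class OligoRecord:
    ordinal: int
    sequence: str  # 152-nt frame: index + parity + payload

    @property
    def index_nt(self) -> str:
        return self.sequence[:INDEX_NT]

    @property
    def parity_nt(self) -> str:
        return self.sequence[INDEX_NT:FRAME_PREFIX_NT]

    @property
    def payload_nt(self) -> str:
        return self.sequence[FRAME_PREFIX_NT:]

    def with_primers(self, primer5: str, primer3: str) -> str:
        return primer5 + self.sequence + primer3


def assemble_oligos(
    code_matrix: np.ndarray, config: EncodingConfig
) -> list[OligoRecord]:
    """Attach RS-protected indices to each encoded row."""
    n, B = code_matrix.shape
    if n != config.total_oligos or B != config.payload_bits:
        raise ValueError(
            f"code matrix must be ({config.total_oligos}, "
            f"{config.payload_bits}), got {code_matrix.shape}"
        )
    prefix = index_with_parity_codes(n)
    bits = np.asarray(code_matrix, dtype=np.uint8)
    pay = (bits[:, 0::2] << 1) | bits[:, 1::2]
    frames = np.concatenate([prefix, pay], axis=1)
    chars = _BASE_BYTES[frames]
    return [
        OligoRecord(i, chars[i].tobytes().decode()) for i in range(n)
    ]


def write_fasta(
    records: list[OligoRecord],
    path: str | Path,
    config: EncodingConfig,
    with_primers: bool | None = None,
) -> None:
    if with_primers is None:
        with_primers = config.with_primers
    seqs = (
        SeqRecord(
            Seq(
                r.with_primers(config.primer5, config.primer3)
                if with_primers
                else r.sequence
            ),
            id=f"oligo_{r.ordinal:05d}",
            description="",
        )
        for r in records
    )
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path, config: EncodingConfig) -> list[OligoRecord]:
    """Read a pool written by write_fasta; strips primers if present."""
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq)
        if len(seq) == config.oligo_nt + len(config.primer5) + len(config.primer3):
            seq = seq[len(config.primer5) : -len(config.primer3)]
        if len(seq) != config.oligo_nt:
            raise ValueError(f"record {rec.id}: unexpected length {len(seq)}")
        records.append(OligoRecord(i, seq))
    return records


# ---------------------------------------------------------------------------
# top level


def build_or_load_code(config: EncodingConfig) -> LDPCCode:
    if config.ldpc_code_path and Path(config.ldpc_code_path).exists():
        code = LDPCCode.load(config.ldpc_code_path)
        if (code.n, code.k) != (config.total_oligos, config.payload_oligos):
            raise ValueError("serialized code does not match the configuration")
        return code
    code = construct_code(
        config.total_oligos,
        config.payload_oligos,
        config.column_weight,
        seed=config.ldpc_seed,
    )
    if config.ldpc_code_path:
        code.save(config.ldpc_code_path)
    return code


def encode_file(
    file_bytes: bytes,
    config: EncodingConfig,
    code: LDPCCode | None = None,
) -> tuple[list[OligoRecord], dict]:
    """Full encoding pipeline; returns the oligo records and a metadata
    sidecar (as a dict) that the decoder needs."""
    config.validate()
    if code is None:
        code = build_or_load_code(config)
    payload = pack_payload(file_bytes, config)
    matrix = interoligo_encode(payload, code)
    records = assemble_oligos(matrix, config)
    meta = {
        "total_oligos": config.total_oligos,
        "payload_oligos": config.payload_oligos,
        "payload_nt": config.payload_nt,
        "prbs_seed": config.prbs_seed,
        "ldpc_seed": config.ldpc_seed,
        "column_weight": config.column_weight,
        "ldpc_code_path": config.ldpc_code_path,
        "primer5": config.primer5,
        "primer3": config.primer3,
        "file_bytes": len(file_bytes),
    }
    return records, meta


def write_meta(meta: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(meta, indent=2))


def config_from_meta(meta: dict) -> EncodingConfig:
    cfg = EncodingConfig(
        total_oligos=meta["total_oligos"],
        payload_oligos=meta["payload_oligos"],
        payload_nt=meta["payload_nt"],
        prbs_seed=meta["prbs_seed"],
        ldpc_seed=meta["ldpc_seed"],
        column_weight=meta["column_weight"],
        ldpc_code_path=meta.get("ldpc_code_path"),
        primer5=meta["primer5"],
        primer3=meta["primer3"],
    )
    cfg.validate()
    return cfg
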