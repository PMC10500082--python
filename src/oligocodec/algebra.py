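"""Finite-field arithmetic, the (8,4) Reed-Solomon index code and CRC-32 helpers.

Every oligo carries an 8-nt address index followed by 8 nt of parity; the two
together form one codeword of a systematic (8,4) Reed-Solomon code over
GF(2^4), where each field symbol maps to two bases through the 2-bit/base
alphabet (A=00, C=01, G=10, T=11).  With minimum distance n-k+1 = 5 the code
corrects any two symbol errors, which is what makes index-based clustering of
noisy reads reliable.

Field convention
----------------
GF(16) is built modulo the primitive polynomial x^4 + x + 1 (0b10011) with
primitive element alpha = x (integer 2).  Addition is XOR.  The RS code is the
evaluation code of degree-<=3 message polynomials at the eight points
alpha^0 .. alpha^7, row-reduced once into systematic form.

CRC-32 is the ubiquitous reflected-0x04C11DB7 variant (the one zlib/Ethernet
use); ``crc32_append``/``crc32_check`` operate on bit arrays so they can sit
directly at the end of the randomized payload bit stream.
"""

from __future__ import annotations

import zlib
from typing import Literal

import numpy as np

GF16_PRIMITIVE_POLY = 0b10011  # x^4 + x + 1
GF16_ALPHA = 2

RS_N = 8
RS_K = 4
RS_T = 2  # bounded-distance correction radius (floor((dmin-1)/2))

CRC32_POLY = 0x04C11DB7  # reflected form 0xEDB88320 used internally
_CRC32_POLY_REFLECTED = 0xEDB88320


def _build_field() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    exp = np.zeros(30, dtype=np.uint8)
    log = np.zeros(16, dtype=np.uint8)
    x = 1
    for i in range(15):
        exp[i] = x
        log[x] = i
        x <<= 1
        if x & 0x10:
            x ^= GF16_PRIMITIVE_POLY
    exp[15:30] = exp[0:15]
    mul = np.zeros((16, 16), dtype=np.uint8)
    for a in range(1, 16):
        for b in range(1, 16):
            mul[a, b] = exp[int(log[a]) + int(log[b])]
    inv = np.zeros(16, dtype=np.uint8)
    for a in range(1, 16):
        inv[a] = exp[(15 - int(log[a])) % 15]
    return exp, log, mul, inv


GF16_EXP, GF16_LOG, GF16_MUL, GF16_INV = _build_field()


def gf16_add(a: int, b: int) -> int:
    """Addition in GF(16) (characteristic 2, so identical to subtraction)."""
    return a ^ b


def gf16_mul(a: int, b: int) -> int:
    return int(GF16_MUL[a, b])


def gf16_inv(a: int) -> int:
    if a == 0:
        raise ZeroDivisionError("0 has no inverse in GF(16)")
    return int(GF16_INV[a])


def gf16_pow(a: int, e: int) -> int:
    if a == 0:
        return 0 if e else 1
    return int(GF16_EXP[(int(GF16_LOG[a]) * e) % 15])


def _rref_gf16(mat: np.ndarray) -> np.ndarray:
    """Reduced row-echelon form over GF(16); assumes full row rank on the left."""
    m = mat.copy()
    rows, cols = m.shape
    r = 0
    for c in range(cols):
        if r == rows:
            break
        piv = None
        for i in range(r, rows):
            if m[i, c]:
                piv = i
                break
        if piv is None:
            continue
        m[[r, piv]] = m[[piv, r]]
        inv = GF16_INV[m[r, c]]
        m[r] = GF16_MUL[inv, m[r]]
        for i in range(rows):
            if i != r and m[i, c]:
                m[i] ^= GF16_MUL[m[i, c], m[r]]
        r += 1
    return m


def _build_rs() -> tuple[np.ndarray, np.ndarray]:
    # Evaluation-code generator: G_eval[i, j] = (alpha^j)^i, message degree i<4.
    g_eval = np.zeros((RS_K, RS_N), dtype=np.uint8)
    for i in range(RS_K):
        for j in range(RS_N):
            g_eval[i, j] = gf16_pow(gf16_pow(GF16_ALPHA, j), i)
    g_sys = _rref_gf16(g_eval)  # [I_4 | P]
    assert np.array_equal(g_sys[:, :RS_K], np.eye(RS_K, dtype=np.uint8))
    p = g_sys[:, RS_K:]
    # Systematic parity check: H = [P^T | I_4] (over GF(2^4), -1 == 1).
    h = np.concatenate([p.T, np.eye(RS_N - RS_K, dtype=np.uint8)], axis=1)
    return g_sys, h


RS_G_SYS, RS_H = _build_rs()


def rs_encode(info) -> np.ndarray:
    """Systematically encode 4 GF(16) symbols into an 8-symbol RS codeword."""
    u = np.asarray(info, dtype=np.uint8)
    if u.shape != (RS_K,) or u.max(initial=0) > 15:
        raise ValueError("info must be 4 symbols in [0, 15]")
    return rs_encode_batch(u[None, :])[0]


def rs_encode_batch(info: np.ndarray) -> np.ndarray:
    """Encode a (N, 4) array of messages into (N, 8) codewords."""
    u = np.asarray(info, dtype=np.uint8)
    cw = np.zeros((u.shape[0], RS_N), dtype=np.uint8)
    for i in range(RS_K):
        cw ^= GF16_MUL[RS_G_SYS[i][None, :], u[:, i : i + 1]]
    return cw


def rs_syndrome_batch(received: np.ndarray) -> np.ndarray:
    """Syndromes H r^T for a (N, 8) batch; zero rows are codewords."""
    r = np.asarray(received, dtype=np.uint8)
    syn = np.zeros((r.shape[0], RS_N - RS_K), dtype=np.uint8)
    for j in range(RS_N - RS_K):
        for i in range(RS_N):
            if RS_H[j, i]:
                syn[:, j] ^= GF16_MUL[RS_H[j, i], r[:, i]]
    return syn


def _syndrome_key(syn: np.ndarray) -> np.ndarray:
    s = np.asarray(syn, dtype=np.int64)
    return (s[..., 0] << 12) | (s[..., 1] << 8) | (s[..., 2] << 4) | s[..., 3]


def _build_syndrome_table() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map syndrome key -> correctable error pattern of weight <= 2.

    d_min = 5 guarantees all weight<=2 patterns have distinct syndromes, so
    bounded-distance decoding is a single table lookup.
    """
    pats = [np.zeros(RS_N, dtype=np.uint8)]
    for i in range(RS_N):
        for v in range(1, 16):
            e = np.zeros(RS_N, dtype=np.uint8)
            e[i] = v
            pats.append(e)
    for i in range(RS_N):
        for j in range(i + 1, RS_N):
            for v in range(1, 16):
                for w in range(1, 16):
                    e = np.zeros(RS_N, dtype=np.uint8)
                    e[i] = v
                    e[j] = w
                    pats.append(e)
    pats = np.array(pats, dtype=np.uint8)
    keys = _syndrome_key(rs_syndrome_batch(pats))
    table = np.full(1 << 16, -1, dtype=np.int32)
    table[keys] = np.arange(len(pats))
    weights = (pats != 0).sum(axis=1).astype(np.int8)
    return table, pats, weights


_SYN_TABLE, _SYN_PATTERNS, _SYN_WEIGHTS = _build_syndrome_table()

DecodeStatus = Literal["ok", "corrected", "fail"]


def rs_decode(received) -> tuple[np.ndarray, DecodeStatus]:
    """Bounded-distance decode: correct up to 2 symbol errors or report failure."""
    r = np.asarray(received, dtype=np.uint8)
    if r.shape != (RS_N,) or r.max(initial=0) > 15:
        raise ValueError("received must be 8 symbols in [0, 15]")
    info, status = rs_decode_batch(r[None, :])
    return info[0], ("ok", "corrected", "fail")[int(status[0])]


def rs_decode_batch(received: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized bounded-distance decoding.

    Returns (info, status) with status 0=ok, 1=corrected, 2=fail; info rows for
    failed words are left as the received (uncorrected) prefix and must be
    ignored by the caller.
    """
    r = np.asarray(received, dtype=np.uint8)
    keys = _syndrome_key(rs_syndrome_batch(r))
    idx = _SYN_TABLE[keys]
    status = np.where(idx == 0, 0, np.where(idx > 0, 1, 2)).astype(np.int8)
    corrected = r.copy()
    hit = idx >= 0
    corrected[hit] ^= _SYN_PATTERNS[idx[hit]]
    return corrected[:, :RS_K], status


def rs_min_distance() -> int:
    """Minimum nonzero codeword weight by exhaustive enumeration of 16^4 words."""
    msgs = np.indices((16, 16, 16, 16)).reshape(4, -1).T.astype(np.uint8)
    cw = rs_encode_batch(msgs)
    w = (cw != 0).sum(axis=1)
    return int(w[w > 0].min())


# ---------------------------------------------------------------------------
# CRC-32 over bit streams


def _crc32_bits(bits: np.ndarray) -> int:
    """CRC-32 of a bit array; bits are MSB-first within each byte.

    Byte-aligned prefixes run through zlib; a trailing partial byte is folded
    in bit-by-bit (stream order) through the reflected polynomial.
    """
    bits = np.asarray(bits, dtype=np.uint8)
    nbytes = len(bits) // 8
    crc = 0xFFFFFFFF
    if nbytes:
        data = np.packbits(bits[: nbytes * 8]).tobytes()
        crc = zlib.crc32(data, crc ^ 0xFFFFFFFF) ^ 0xFFFFFFFF
    for b in bits[nbytes * 8 :]:
        crc = (crc >> 1) ^ (_CRC32_POLY_REFLECTED if (crc ^ int(b)) & 1 else 0)
    return crc ^ 0xFFFFFFFF


def crc32_append(bits) -> np.ndarray:
    """Append the 32-bit CRC of ``bits`` (MSB-first) at the suffix."""
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.size == 0:
        raise ValueError("bit sequence must be nonempty")
    crc = _crc32_bits(bits)
    tag = np.unpackbits(np.frombuffer(crc.to_bytes(4, "big"), dtype=np.uint8))
    return np.concatenate([bits, tag])


def crc32_check(bits) -> bool:
    """True iff the last 32 bits equal the CRC-32 of everything before them."""
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.size < 33:
        return False
    stored = int.from_bytes(np.packbits(bits[-32:]).tobytes(), "big")
    return _crc32_bits(bits[:-32]) == stored
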