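"""Binary LDPC code: construction, systematic encoding and sum-product decoding.

The storage scheme protects the oligo pool with a single *inter-oligo* LDPC
code: one codeword per payload bit position, running across all oligos, so a
dropped oligo contributes exactly one erasure to each of the 272 codewords and
a substitution contributes one bit error.  The production code is the
(n=18 432, k=16 572) rate-0.899 code with m = 1 860 parity checks; the same
constructor serves arbitrary (n, k) for scaled experiments and tests.

Construction is a progressive-edge-growth style greedy placement: each column
(variable node) picks ``column_weight`` checks, preferring the currently
least-loaded ones, subject to no two columns sharing more than one check —
that forbids 4-cycles, so the Tanner graph has girth >= 6.  Because an
all-even column profile makes the rows of H linearly dependent (they sum to
zero mod 2), a deterministic rank repair adds one extra entry to each
dependent row until rank(H) = m; a handful of columns therefore end up with
weight ``column_weight + 1``.

Encoding is systematic: columns are permuted once so that an invertible m
by m block sits on the last m positions, and the Gauss-Jordan reduction is
cached as a packed solve matrix, giving O(m·k/64) word operations per
codeword.  Decoding is flooding-schedule log-domain sum-product, vectorized
over many codewords at once (the decoder hands all 272 columns to one call).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

LLR_CLIP = 30.0  # message magnitudes clipped to +-30 to avoid overflow
_TANH_LIM = 1.0 - 1e-15


class ConstructionError(RuntimeError):
    """Raised when no 4-cycle-free placement is found within the retry budget."""


@dataclass
class LDPCCode:
    """A binary LDPC code with cached encoder and decoder structure.

    ``check_cols[i]`` lists the variable (column) indices of check ``i``.
    The code is systematic: information bits occupy positions 0..k-1,
    parity bits positions k..n-1.
    """

    n: int
    k: int
    seed: int
    column_weight: int
    check_cols: list[np.ndarray]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def m(self) -> int:
        return self.n - self.k

    # -- sparse views -------------------------------------------------------

    @property
    def H(self) -> sp.csr_matrix:
        if "H" not in self._cache:
            rows = np.concatenate(
                [np.full(len(c), i) for i, c in enumerate(self.check_cols)]
            )
            cols = np.concatenate(self.check_cols)
            data = np.ones(len(cols), dtype=np.uint8)
            self._cache["H"] = sp.csr_matrix(
                (data, (rows, cols)), shape=(self.m, self.n)
            )
        return self._cache["H"]

    def _packed(self) -> np.ndarray:
        return _pack(self.check_cols, self.n)

    def _solve_matrix(self) -> np.ndarray:
        """Packed (m, k-words) matrix M with parity = M x info over GF(2)."""
        if "solve" not in self._cache:
            self._cache["solve"] = _solve_matrix(self._packed(), self.n, self.k)
        return self._cache["solve"]

    # -- encode / syndrome --------------------------------------------------

    def encode(self, info: np.ndarray) -> np.ndarray:
        """Encode k info bits (or a (k, C) matrix) into n-bit codeword(s)."""
        info = np.asarray(info, dtype=np.uint8)
        single = info.ndim == 1
        if single:
            info = info[:, None]
        if info.shape[0] != self.k:
            raise ValueError(f"info must have {self.k} bits, got {info.shape[0]}")
        M = self._solve_matrix()
        kw = M.shape[1]
        out = np.empty((self.n, info.shape[1]), dtype=np.uint8)
        out[: self.k] = info
        for c in range(info.shape[1]):
            up = np.packbits(info[:, c], bitorder="little")
            up = np.pad(up, (0, kw * 8 - len(up))).view(np.uint64)
            par = np.bitwise_count(M & up[None, :]).sum(axis=1, dtype=np.uint64)
            out[self.k :, c] = (par & 1).astype(np.uint8)
        return out[:, 0] if single else out

    def syndrome(self, word: np.ndarray) -> np.ndarray:
        """H·word over GF(2); accepts an n-vector or an (n, C) matrix."""
        word = np.asarray(word, dtype=np.uint8)
        if word.shape[0] != self.n:
            raise ValueError(f"word must have {self.n} bits, got {word.shape[0]}")
        return np.asarray((self.H @ word) & 1, dtype=np.uint8)

    # -- belief propagation -------------------------------------------------

    def _bp_structure(self):
        if "bp" not in self._cache:
            chk = np.concatenate(
                [np.full(len(c), i) for i, c in enumerate(self.check_cols)]
            )
            var = np.concatenate(self.check_cols)
            row_ptr = np.concatenate(
                [[0], np.cumsum([len(c) for c in self.check_cols])]
            )
            order_v = np.argsort(var, kind="stable")
            var_ptr = np.searchsorted(var[order_v], np.arange(self.n + 1))
            self._cache["bp"] = (chk, var, row_ptr.astype(np.int64), order_v, var_ptr)
        return self._cache["bp"]

    def bp_decode(self, llr: np.ndarray, max_iter: int = 50) -> "BPDecodeResult":
        """Log-domain sum-product decoding with flooding schedule.

        Sign convention: llr = ln P(bit=0)/P(bit=1), positive favours 0.
        ``llr`` may be an n-vector or an (n, C) matrix decoded jointly.
        Stops early once every column has a zero syndrome.
        """
        llr = np.asarray(llr, dtype=np.float64)
        single = llr.ndim == 1
        if single:
            llr = llr[:, None]
        if llr.shape[0] != self.n:
            raise ValueError(f"llr must have {self.n} entries")
        if not np.all(np.isfinite(llr)):
            raise ValueError("llr must be finite")
        llr = np.clip(llr, -LLR_CLIP, LLR_CLIP)
        chk, var, row_ptr, order_v, var_ptr = self._bp_structure()
        C = llr.shape[1]

        bits = (llr < 0).astype(np.uint8)
        done = ~np.any(self.syndrome(bits), axis=0)
        final_bits = bits.copy()
        iterations = 0
        if np.all(done):
            res = BPDecodeResult(final_bits, done, iterations)
            return res.squeeze() if single else res

        m_vc = llr[var]  # (E, C), check-sorted edge order
        m_cv = np.zeros_like(m_vc)
        for it in range(1, max_iter + 1):
            iterations = it
            # check update: exclusive product of tanh(m/2), zeros handled exactly
            t = np.tanh(0.5 * m_vc)
            zero = t == 0.0
            tnz = np.where(zero, 1.0, t)
            prod = np.multiply.reduceat(tnz, row_ptr[:-1], axis=0)
            nzero = np.add.reduceat(zero.astype(np.int64), row_ptr[:-1], axis=0)
            prod_e = prod[chk]
            nzero_e = nzero[chk]
            out = np.where(
                nzero_e == 0,
                prod_e / tnz,
                np.where((nzero_e == 1) & zero, prod_e, 0.0),
            )
            np.clip(out, -_TANH_LIM, _TANH_LIM, out=out)
            m_cv = np.clip(2.0 * np.arctanh(out), -LLR_CLIP, LLR_CLIP)
            # variable update
            total = llr.copy()
            sums = np.add.reduceat(m_cv[order_v], var_ptr[:-1], axis=0)
            total += sums
            m_vc = np.clip(total[var] - m_cv, -LLR_CLIP, LLR_CLIP)

            bits = (total < 0).astype(np.uint8)
            ok = ~np.any(self.syndrome(bits), axis=0)
            newly = ok & ~done  # freeze columns the moment they converge
            final_bits[:, newly] = bits[:, newly]
            done |= ok
            if np.all(done):
                break
        final_bits[:, ~done] = bits[:, ~done]
        res = BPDecodeResult(final_bits, done, iterations)
        return res.squeeze() if single else res

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Plain-text format: JSON header line, then one line of column
        indices per check."""
        path = Path(path)
        with path.open("w") as fh:
            hdr = {
                "n": self.n,
                "k": self.k,
                "m": self.m,
                "seed": self.seed,
                "column_weight": self.column_weight,
            }
            fh.write(json.dumps(hdr) + "\n")
            for cols in self.check_cols:
                fh.write(" ".join(map(str, cols.tolist())) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "LDPCCode":
        path = Path(path)
        with path.open() as fh:
            hdr = json.loads(fh.readline())
            check_cols = [
                np.array(line.split(), dtype=np.int64) for line in fh if line.strip()
            ]
        if len(check_cols) != hdr["m"]:
            raise ValueError("corrupt code file: check count mismatch")
        return cls(
            n=hdr["n"],
            k=hdr["k"],
            seed=hdr["seed"],
            column_weight=hdr["column_weight"],
            check_cols=check_cols,
        )


@dataclass
class BPDecodeResult:
    """Hard decisions plus convergence bookkeeping for one or more codewords."""

    bits: np.ndarray  # (n,) or (n, C)
    converged: np.ndarray  # scalar bool or (C,)
    iterations_used: int

    def squeeze(self) -> "BPDecodeResult":
        return BPDecodeResult(self.bits[:, 0], bool(self.converged[0]),
                              self.iterations_used)


# ---------------------------------------------------------------------------
# packed GF(2) linear algebra


def _pack(check_cols: list[np.ndarray], n: int) -> np.ndarray:
    W = (n + 63) // 64
    H = np.zeros((len(check_cols), W), dtype=np.uint64)
    for i, cols in enumerate(check_cols):
        w, b = np.divmod(np.asarray(cols, dtype=np.int64), 64)
        np.bitwise_or.at(H[i], w, np.uint64(1) << b.astype(np.uint64))
    return H


def _eliminate(Hb: np.ndarray, n: int):
    """Right-to-left Gauss-Jordan; returns (reduced rows, pivot columns, rank)."""
    H = Hb.copy()
    m = H.shape[0]
    pivots = []
    r = 0
    for c in range(n - 1, -1, -1):
        if r == m:
            break
        w, b = divmod(c, 64)
        col = (H[r:, w] >> np.uint64(b)) & np.uint64(1)
        nz = np.nonzero(col)[0]
        if len(nz) == 0:
            continue
        piv = r + int(nz[0])
        if piv != r:
            H[[r, piv]] = H[[piv, r]]
        mask = ((H[:, w] >> np.uint64(b)) & np.uint64(1)).astype(bool)
        mask[r] = False
        H[mask] ^= H[r]
        pivots.append(c)
        r += 1
    return H, pivots, r


def _solve_matrix(Hb: np.ndarray, n: int, k: int) -> np.ndarray:
    """Packed parity-solve matrix assuming the last m columns are invertible."""
    m = Hb.shape[0]
    H, pivots, rank = _eliminate(Hb, n)
    if rank < m:
        raise ConstructionError("parity-check matrix is rank deficient")
    if sorted(pivots) != list(range(k, n)):
        raise ConstructionError("last m columns are not invertible; "
                                "code was not systematized")
    kw = (k + 63) // 64
    M = np.zeros((m, kw), dtype=np.uint64)
    # pivot column k+j corresponds to parity bit j; extract info-column bits
    for row_idx, c in enumerate(pivots):
        j = c - k
        M[j] = H[row_idx, :kw]
        extra = kw * 64 - k  # mask tail bits beyond column k-1
        if extra:
            M[j, -1] &= np.uint64((1 << (64 - extra)) - 1)
    return M


# ---------------------------------------------------------------------------
# construction


def construct_code(
    n: int,
    k: int,
    column_weight: int = 4,
    seed: int = 0,
    max_retries: int = 50,
) -> LDPCCode:
    """Build a girth->=6, near-regular (n, k) LDPC code, deterministically.

    Greedy degree-balanced placement with 4-cycle avoidance, followed by rank
    repair and a one-off column permutation that moves an invertible block to
    the last m positions (so encoding is systematic with info bits first).
    """
    if not (n > k > 0):
        raise ValueError("need n > k > 0")
    m = n - k
    if column_weight < 2 or column_weight > m:
        raise ValueError("column weight must be in [2, m]")
    # girth >= 6 forces all n * C(wc, 2) check pairs to be distinct
    need = n * column_weight * (column_weight - 1) // 2
    avail = m * (m - 1) // 2
    if need > avail:
        raise ConstructionError(
            f"girth >= 6 infeasible: {need} check pairs required but only "
            f"{avail} exist; lower the column weight or the rate"
        )
    rng = np.random.default_rng(seed)
    col_checks = _place_columns(n, m, column_weight, rng, max_retries)

    # rows-of-column view for 4-cycle-safe repair
    rows_of_col = [set() for _ in range(n)]
    check_sets: list[set] = [set() for _ in range(m)]
    for c, checks in enumerate(col_checks):
        for r in checks:
            check_sets[r].add(c)
            rows_of_col[c].add(r)

    check_cols = [np.array(sorted(s), dtype=np.int64) for s in check_sets]
    check_cols = _rank_repair(check_cols, rows_of_col, n, m)

    # systematize: permute columns so pivots occupy the last m positions
    Hb = _pack(check_cols, n)
    _, pivots, rank = _eliminate(Hb, n)
    if rank < m:
        raise ConstructionError("rank repair failed")
    piv_set = set(pivots)
    new_order = [c for c in range(n) if c not in piv_set] + sorted(piv_set)
    remap = np.empty(n, dtype=np.int64)
    remap[np.array(new_order)] = np.arange(n)
    check_cols = [np.sort(remap[cols]) for cols in check_cols]

    code = LDPCCode(n=n, k=k, seed=seed, column_weight=column_weight,
                    check_cols=check_cols)
    code._solve_matrix()  # fail fast if anything went wrong
    return code


def _place_columns(n, m, wc, rng, max_retries):
    used_pairs: set[int] = set()
    degrees = np.zeros(m, dtype=np.int64)
    col_checks: list[list[int]] = []
    for _ in range(n):
        placed = None
        for _attempt in range(max_retries):
            if _attempt < max_retries // 2:
                # degree-balanced with a little noise: keeps rows near-regular
                order = np.argsort(
                    degrees + rng.uniform(0.0, 0.9, size=m), kind="stable"
                )
            else:
                # saturation regime: pure random order escapes greedy dead ends
                order = rng.permutation(m)
            chosen: list[int] = []
            for cand in order:
                cand = int(cand)
                if all((min(s, cand) * m + max(s, cand)) not in used_pairs
                       for s in chosen):
                    chosen.append(cand)
                    if len(chosen) == wc:
                        break
            if len(chosen) == wc:
                placed = chosen
                break
        if placed is None:
            raise ConstructionError(
                f"no 4-cycle-free placement for column {len(col_checks)} "
                f"within {max_retries} retries"
            )
        for a_i, a in enumerate(placed):
            for b in placed[a_i + 1 :]:
                used_pairs.add(min(a, b) * m + max(a, b))
        degrees[placed] += 1
        col_checks.append(placed)
    return col_checks


def _rank_repair(check_cols, rows_of_col, n, m, max_rounds: int = 20):
    """Add single entries to dependent rows until rank(H) = m, keeping girth >= 6."""
    col_weight = np.array([len(rows_of_col[c]) for c in range(n)], dtype=np.int64)
    for _ in range(max_rounds):
        Hb = _pack(check_cols, n)
        _, _, rank = _eliminate(Hb, n)
        deficit = m - rank
        if deficit == 0:
            return check_cols
        # deterministically pick `deficit` distinct rows, lightest columns first
        target_rows = list(range(m - 1, m - 1 - deficit, -1))
        for row in target_rows:
            present = set(check_cols[row].tolist())
            for c in np.argsort(col_weight, kind="stable"):
                c = int(c)
                if c in present:
                    continue
                # adding (row, c) must not create a 4-cycle with row's columns
                if any(rows_of_col[c] & rows_of_col[c2] for c2 in present):
                    continue
                check_cols[row] = np.sort(np.append(check_cols[row], c))
                rows_of_col[c].add(row)
                col_weight[c] += 1
                break
            else:
                raise ConstructionError("rank repair: no girth-safe entry found")
    raise ConstructionError("rank repair did not converge")
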