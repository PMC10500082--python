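# Methods

This note records the models, parameter choices and numerical conventions
behind `oligocodec`, and what the synthetic experiments do and do not show.

## Code structure

**Inter-oligo LDPC code.** The pool is protected by a single binary LDPC
code applied across oligos: one codeword per payload bit position. The
production code is (n = 18 432, k = 16 572, m = 1 860), rate 0.899. The
constructor is a progressive-edge-growth-style greedy placement: each
variable node (column) selects `column_weight` checks, preferring the
currently least-loaded ones, under the constraint that no two columns share
more than one check — equivalently, the Tanner graph has girth ≥ 6. This
constraint is satisfiable only when `n·C(w,2) ≤ C(m,2)`; the constructor
refuses infeasible regimes. The full-scale code uses column weight 4; the
reduced codes used in tests (1024/920, 256/200) use weight 3 because weight
4 is infeasible at their check counts.

An all-even column-weight profile forces the rows of H to sum to zero mod 2,
so H is always initially rank-deficient. A deterministic *rank repair* adds
one extra entry (girth-checked, lightest column first) to dependent rows
until rank(H) = m; a handful of columns end up with weight w+1. Finally the
columns are permuted once so that an invertible m×m block occupies the last
m positions: information bits are oligo ordinals 0..k−1, parity ordinals
k..n−1, and the cached Gauss–Jordan reduction gives O(m·k/64) encoding per
codeword. Construction is deterministic in the seed and the code serializes
to a plain-text file (JSON header + one line of column indices per check).

**Belief propagation.** Flooding-schedule log-domain sum-product, vectorized
over all 272 codewords at once. Message magnitudes are clipped to ±30;
exact zeros (erasures) are propagated exactly through the check update by
counting zero factors rather than dividing. Default 50 iterations; a
codeword's output is frozen the moment its syndrome reaches zero. Sign
convention throughout: LLR = ln P(bit=0)/P(bit=1), positive favours 0.

**RS index code.** GF(16) is built modulo x⁴+x+1 with α = x; the (8,4) code
is the evaluation code of degree-≤3 polynomials at α⁰..α⁷, row-reduced to
systematic form. Minimum distance 5 (MDS), bounded-distance decoding radius
2, implemented as a precomputed syndrome table over all 6 420 correctable
patterns. Decoded indices must additionally match the canonical index list;
RS-valid but unused indices are discarded.

**Index policy.** Of the 65 536 8-mers, those with homopolymer runs > 3 are
eliminated (61 452 survive) and, as a robustness refinement, those with GC
count outside [2, 6]; the first 18 432 in lexicographic order are used.
Any deterministic policy satisfying the run-length constraint would do; this
one is reproducible and leaves margin (57 928 candidates).

**Bit stream framing.** A 64-bit big-endian length header precedes the file
bits; the header+file stream is randomized (xorshift64* keystream, seeded in
the config), the CRC-32 (reflected 0x04C11DB7, the zlib variant) of the
*randomized* stream is appended, and zero padding fills the last row. The
CRC therefore certifies exactly the bits the channel carried, and decoding
is self-contained: de-randomize the first 64 bits, locate the CRC from the
recovered length, verify, de-randomize, strip.

## Channel model

`ChannelParams` defaults: substitution 0.96%, insertion 0.02%, deletion
0.02% per base (1.0% total), with the substitution rate tripled at the final
frame position (the last base of merged reads is empirically the most
error-prone). Reads are sampled i.i.d. uniformly with replacement, so
coverage dropout at low sampling depth follows the occupancy distribution.
Phred scores are drawn conditioned on correctness: correct bases peak at Q38
with ~3% mass below Q30, erroneous bases peak at Q15 with a small
high-quality tail. These choices place a default corpus at ~96% of bases at
Q30+ and ~94% of reads at full frame length, matching the aggregate
statistics of the Illumina-class runs the codec targets. The indel split is
deliberately much smaller than substitutions: at 0.1%+0.1% per base barely
74% of 152-nt reads would keep their length, contradicting the ~93%
full-length fraction observed in practice.

Paired-end merging is not simulated; the simulator emits already-merged,
primer-free reads in the 152-nt frame. Reads shorter than L−2 or longer
than L are discarded by the length filter, standing in for merge artifacts.
Not modelled: PCR amplification bias, strand chimeras, nanopore error
profiles, position-dependent quality decay within a read.

## Decoder conventions

- **ED filter:** a read is evicted iff its *minimum* edit distance to every
  other member exceeds d_th = 10 (configurable). Eviction is simultaneous:
  a 2-read cluster at mutual distance > d_th loses both members — with only
  two mutually distant reads there is no evidence which one is right.
- **MSA backend:** center-star alignment via pairwise Needleman–Wunsch
  (edlib). The center is the member closest to the frame length (ties:
  highest mean Phred). Members align to the center; bases the center lacks
  are dropped, missing bases become gaps, so the alignment length equals the
  center's length. "Aligned output has the correct length" therefore means
  the center is full-length.
- **Condition-5 voting:** full-frame members of an aligned cluster vote from
  their own positional bases; only shortened members vote through their
  alignment rows. Full-length reads are already registered to the frame, and
  aligning them to an imperfect center can convert two substitutions into a
  gap-plus-shift, creating correlated majority errors — observed in testing
  as the single failure mode of the coverage-5 round trip before this rule.
- **Q-score gates:** both gates are strict (`> 30` for the last-base rescue
  in conditions 3/6, `> 20` for counting the last two bits), and both can be
  disabled (`use_qscore=False`); together with `use_vl=False` this
  reproduces a full-length-only, quality-blind reference decoder for
  ablation.
- **Re-decode schedule:** ε₀ = 0.02, Δε = 0.005, floor ε_end = 0.005, with
  ε_i = ε_end the last value used — i ∈ {0, 1, 2, 3} at the defaults. Only
  failed codewords are re-decoded; since every LLR entry is (k₀−k₁)·ln[(1−ε_i)/ε_i],
  recomputation is a rescaling of the i = 0 matrix.
- **Degenerate inputs:** clusters of size 0 are all-zero LLR rows; empty
  files and byte streams shorter than a row round-trip through the padding
  rules; ties in the BP hard decision (total LLR exactly 0) resolve to 0.

## Study conditions for the synthetic experiments

- Full-scale encoding (structure checks): the production (18 432, 16 572)
  layout with a capacity-filling 563 436-byte random payload.
- Round-trip reliability: 50 KB payload, (1024, 920) weight-3 code, 239-nt
  frames, default channel, coverage 5, 100 seeded trials.
- Success-vs-depth sweep: 4 KB payload, (256, 200) code, 100-nt frames,
  coverages 2.0–5.0 in five steps, 30 trials each.
- Ablation corpus: deletion rate lowered to 5.6·10⁻⁵/base so ~1.3% of reads
  are shortened by 1–2 nt, isolating the contribution of variable-length
  reads and Phred gating.

Problem sizes were chosen as the smallest that still exercise every decoder
path (dropout erasures, index correction, all six routing conditions,
re-decoding); conclusions from them are about the codec's mechanisms, not
about wet-lab performance. Passing tests show the pipeline is lossless under
the stated channel model; they cannot certify behaviour under error profiles
the simulator does not model (see above).

## Known limitations

- The inter-oligo design assumes the index survives often enough for
  clustering; at index-region error rates far above ~1%/base the RS(8,4)
  failure rate would dominate before the LDPC code saturates.
- The internal center-star MSA is not a full progressive aligner; clusters
  whose members disagree by large structural variants fall back to the
  last-base rescue path rather than being reconstructed.
- `bp_decode` is a flooding sum-product decoder without min-sum or layered
  optimizations; full-scale decoding of all 272 codewords is therefore
  memory- and time-heavier than a production implementation would be.
- Reading cost is reported as sampled reads × nominal read length /
  information bits; other conventions (e.g. counting only used reads)
  yield slightly different numbers and the choice is stated in the report
  header.
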