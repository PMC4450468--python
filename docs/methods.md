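# Methods

## Probability–phred curve

The informativeness probability is piecewise:

- `p_b(q, t) = 1 − 2^(−q/t)` for `q ≤ q0 = max(20, t)`;
- a cubic Bézier segment for `q0 < q < 45`, with control values
  `p1 = p_b(q0, t)`, `p2` on the tangent to `p_b` at `q0` evaluated one third
  of the way from `q0` to 45, and `p3 = p4 = 1`;
- exactly 1 for `q ≥ 45` (modern phred scores can exceed 45; the curve is
  clamped there).

The Bézier parameter is scaled as `u = (q − q0)/(45 − q0)`, so the spline
starts exactly at the branch point (`B(0) = p1 = p_b(q0, t)`, continuity) and
ends at `B(1) = 1` at phred 45. An alternative scaling `u = (q − t)/(45 − t)`
is kept behind the internal switch `_literal_scaling` for comparison; it is
discontinuous at the branch point whenever `t < 20` and is not used.

Placing `p2` one third of the way along the tangent follows the standard
cubic-Bézier construction (the first control point lies at one third of the
parameter interval along the departure tangent), which makes the curve C¹ at
the branch point. For small thresholds (`t ≲ 8`) the tangent at `q0 = 20` is
steep enough that this construction puts `p2` slightly above 1, which would
let the spline overshoot 1 and lose monotonicity by ~1e−3. `p2` is therefore
capped at 1: the control points are then non-decreasing
(`p1 ≤ p2 ≤ p3 = p4 = 1`), which guarantees a monotone spline bounded by 1
for every threshold. The property suite checks boundedness, monotonicity and
branch-point continuity on a dense grid over `t ∈ [1, 45]`. At `t = 45`
exactly, the spline region is empty and the hard `p(45) = 1` constraint meets
the raw branch (`p_b(45, 45) = 0.5`) at the same point; the curve is defined
as 1 there, and the practical threshold range is `1 ≤ t < 45`.

`build_curve(t)` materialises the curve as a lookup over integer
`q ∈ [0, 93]` (the printable-ASCII-encodable range at offset 33); the table
agrees bit-for-bit with direct evaluation. Non-integer `t` is allowed
(`t = 3.0103` reproduces the classical phred curve to < 1e−4).

## Segmentation likelihood

For a candidate tail cut `k` the log-likelihood is

    Σ_{i≤k} [log f0(n_i) − log k]  +  Σ_{i>k} [log f1(n_i) − log(m−k)]

with the second sum empty at `k = m`. The per-position normaliser of the
unreliable segment is `1/(m−k)` — one factor per occupied position, with the
empty-segment product defined as 1. `Pr(N)` in `f0` is the empirical
frequency of `N` over `[1, k]`; since this is the closed-form
maximum-likelihood estimate for each candidate `k`, the cut and the
frequencies are jointly optimised by a single scan (profile likelihood — the
complete-data view of EM with no iteration needed).

Every probability factor is floored at 1e−30 before the logarithm so the
arithmetic stays finite when `p(0, t) = 0`. The floor can only affect
candidates whose likelihood is zero in exact arithmetic, so it never changes
an argmax between non-degenerate candidates.

Tie-breaking: equal likelihoods go to the largest `k1` and the smallest `k2`,
i.e. the cut retaining the most nucleotides — trimming should never remove
more than the evidence demands. The head cut is computed by reversing the
subsequence `[1, k1]` and re-running the tail search (`k2 = k1 − k1' + 1`),
which maps the largest-`k'` rule onto smallest-`k2`; a property test checks
this against the direct (un-mirrored) head likelihood.

The production scan is vectorised with numpy: cumulative nucleotide counts
give every segment profile at once, and per-position `f1` terms are suffix
sums. The search ranges are `k1 ∈ [1, m]` and `k2 ∈ [1, k1]`, so the minimum
retained segment is one nucleotide; whole-read rejection is delegated to the
`min_read_size` filter. Ambiguity codes (full IUB/IUPAC alphabet) participate
in `Pr(N)` as their own symbols, while `f1`'s uniform factor stays 1/4.

The poly-N variant replaces `f1` by `p(q_i, t)` when `n_i` equals the chosen
letter and `(1 − p(q_i, t))/4` otherwise: a confidently called occurrence of
the letter supports the homopolymer segment, and a miscalled base could have
been the letter. When both poly-N and quality trimming are requested the pass
order is a CLI choice; the default runs the poly-N pass first so that the
quality pass sees the read without its homopolymer run. The model itself does
not prescribe an order.

## Behaviour worth knowing

On short reads whose informative segment has `p(q, t) < 1` (e.g. q = 40 at
t = 20, where p ≈ 0.96), the segment-frequency term `Pr(N)` can make it
marginally advantageous to shave a base or two off an otherwise clean
boundary: moving a position out of the informative segment changes both the
profile and the `1/k` normaliser. This is a property of the likelihood, not a
bug; the exhaustive search oracle exhibits it identically. Planted-boundary
tests that need an unambiguous optimum therefore use phred 45 (p = 1) for the
informative segment.

## Synthetic data

The generator emulates the canonical quality shape of short-read data — low
base quality at both extremities, high in the middle — as a step profile:
per-segment mean phred scores (defaults 2 / 40 / 2, i.e. raw-error rates of
~63% at the ends and 0.01% in the core for the classical phred reading) with
optional per-position Gaussian jitter, rounded and clipped to [0, 93], over a
uniform A/C/G/T sequence, plus an optional homopolymer block for poly-N
scenarios. It deliberately does not emulate substitution/indel sequencing
errors, instrument-specific quality distributions, or quality binning, so
passing recovery tests demonstrate correctness of the segmentation under the
model's own assumptions, not performance on any particular instrument's data.

Recovery experiments use 500 reads of length 100 with the informative segment
planted at [11, 90] and a 2→40→2 phred step at `t = 20`; ≥ 95% of cut-points
are recovered within ±2, and mean retained length is non-increasing in `t`
over {5, 10, 20, 30}. Oracle-equivalence checks use 1,000 random reads of
length ≤ 30 per mode — small enough for the pure-Python exhaustive reference,
large enough to hit ties and degenerate reads. All generators are seeded;
seeds are part of the fixture identity.

## I/O and execution contracts

Only the 4-line FASTQ dialect is accepted (wrapped records are rejected with
a clear error). gzip is detected from the two magic bytes, not the file name.
The `+` separator line is written bare, the dominant dialect. Phred offset is
33 by default, 64 selectable; a quality character below the offset aborts
with a hint toward the other offset. Paired files are paired by position
(never by identifier parsing) and a dropped mate drops the whole pair, so
outputs stay synchronized for downstream mappers. Parallel execution
partitions reads into batches processed by worker processes; an ordered map
restores input order before writing, so output bytes are identical for any
worker count.

## Limitations

- No adapter-sequence matching, k-mer error correction, or multi-segment
  (more than two cut-points) segmentation.
- Interleaved FASTQ, FASTA and SAM/BAM are out of scope.
- The minimum-length filter is the only whole-read rejection mechanism; the
  segmentation itself always retains at least one nucleotide.
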