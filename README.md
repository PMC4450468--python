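# mltrim

Unsupervised quality and homopolymer trimming of FASTQ reads by maximum
likelihood, for anyone preprocessing short-read sequencing data (DNA- or
RNA-seq) ahead of mapping or assembly.

Most trimmers slide a window over the quality string and cut where a running
statistic crosses a threshold, which entangles several tuning knobs. `mltrim`
instead treats each read as three contiguous segments — an unreliable head, an
informative core, and an unreliable tail — and finds the two cut-points
`(k2, k1)` that maximise a segment likelihood. The only user parameter is `t`,
the minimal phred score considered informative.

## Model

The classical phred relation gives the probability that a base call is
correct, `p_a(q) = 1 − 10^(−q/10)`. For trimming, the relevant notion is
*informativeness* relative to the threshold `t`:

    p_b(q, t) = 1 − 2^(−q/t)

so that `p_b(t, t) = 0.5`: a base exactly at the threshold is as likely to be
informative as not (and `t = 10·log10 2 ≈ 3.0103` recovers `p_a` exactly).
Because `p_b` stays well below 1 even for high phred scores when `t ≤ 20`,
the curve is extended above `max(20, t)` by a cubic Bézier spline that rises
smoothly to exactly 1 at phred 45, giving the full curve `p(q, t)`.

For a read `(n_1, …, n_m)` with qualities `(q_1, …, q_m)`, the tail cut-point
is

    k1 = argmax_k  ∏_{i≤k} (1/k) f0(n_i)  ·  ∏_{i>k} (1/(m−k)) f1(n_i)

where the informative model is `f0(n_i) = p(q_i, t) · Pr(n_i)` with `Pr(N)`
the empirical nucleotide frequencies of the candidate segment (their
maximum-likelihood estimate, so no iteration is needed), and the unreliable
model is `f1(n_i) = (1 − p(q_i, t)) / 4`. The head cut-point `k2` is then
found by the same search restricted to `[1, k1]`. This double binary
segmentation yields the best two cut-points per read; the retained segment is
`[k2, k1]` (1-based, inclusive).

Replacing `f1` by a letter-aware variant — `p(q_i, t)` when `n_i` equals a
chosen letter, `(1 − p(q_i, t))/4` otherwise — turns the same machinery into
an unsupervised homopolymer (poly-A/poly-N) trimmer.

## Worked example

Generate 50 synthetic 100-nt reads whose informative segment spans positions
11–90 (mean phred 40, jitter SD 3) framed by unreliable ends (mean phred 2),
then trim at `t = 20`:

```sh
mltrim simulate --n 50 --m 100 --k2 11 --k1 90 --sd 3 --seed 4 \
    --out sim.fastq --truth truth.tsv
mltrim trim --in sim.fastq --out out.fastq.gz --t 20 --gz --threads 2 \
    --json-report report.json
```

which prints

```
kept 50/50 reads, 3988/5000 nucleotides
```

All 50 reads survive (their informative cores are far longer than the default
minimum of 1 nt) and 1012 of the 5000 input nucleotides are removed — the 20
low-quality positions planted per read, give or take the positions whose
jittered scores cross the threshold. `report.json` holds the same counts
machine-readably. Paired-end files are trimmed with `--inpair/--outpair`; a
pair is dropped whenever either mate falls below `--min_read_size`, so the
two output files stay synchronized. `--N A` additionally trims poly-A runs.

Inspect the probability curve itself with:

```sh
mltrim curve --t 20      # TSV of (q, p(q, 20)) for q = 0..93
```

e.g. rows `20 → 0.5` and `45 → 1.0`.

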