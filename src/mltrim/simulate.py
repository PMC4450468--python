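"""Synthetic read generator with planted cut-points for recovery experiments.

Real short-read data tends to have low base-calling quality at both read
extremities — dropping sharply over the first few cycles and degrading slowly
toward the end of the read.  The generator emulates that shape with the
simplest structure sufficient for cut-point recovery testing: a step quality
profile (low head / high core / low tail mean phred, per-position Gaussian
jitter) over a uniformly random A/C/G/T sequence, with an optional
homopolymer block for poly-N scenarios.  It does not emulate
substitution/indel sequencing errors or instrument-specific quality
distributions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Union

import numpy as np

from .fastq_io import FastqRecord, PhredEncoding, write_fastq
from .segmentation import POLY_LETTERS, CutPoints, Read

PathLike = Union[str, Path]

#: default per-segment mean phred scores: unreliable ends vs informative core
DEFAULT_Q_LOW = 2
DEFAULT_Q_HIGH = 40


@dataclass(frozen=True)
class SimProfile:
    """Blueprint for one synthetic read.

    Positions [1, k2_true-1] and [k1_true+1, m] get the low mean phreds;
    the planted informative segment [k2_true, k1_true] gets the high one.
    ``q_sd`` is the standard deviation of the per-position jitter (rounded,
    clipped to the encodable range).  When ``polyN_letter`` is set, the last
    ``polyN_len`` positions are a homopolymer of that letter.
    """

    m: int
    k2_true: int
    k1_true: int
    q_low_head: float = DEFAULT_Q_LOW
    q_high: float = DEFAULT_Q_HIGH
    q_low_tail: float = DEFAULT_Q_LOW
    q_sd: float = 0.0
    polyN_letter: Optional[str] = None
    polyN_len: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.k2_true <= self.k1_true <= self.m:
            raise ValueError(
                f"need 1 <= k2_true <= k1_true <= m, got "
                f"({self.k2_true}, {self.k1_true}, m={self.m})"
            )
        for q in (self.q_low_head, self.q_high, self.q_low_tail):
            if not 0 <= q <= 93:
                raise ValueError(f"mean phred {q} outside [0, 93]")
        if self.polyN_letter is not None and self.polyN_letter not in POLY_LETTERS:
            raise ValueError(
                f"polyN_letter must be one of {sorted(POLY_LETTERS)}"
            )


def simulate_read(
    profile: SimProfile, rng: np.random.Generator, read_id: str = "sim"
) -> tuple[Read, CutPoints]:
    """Draw one read from the profile; returns it with the planted cut-points."""
    m = profile.m
    bases = rng.choice(list("ACGT"), size=m)
    if profile.polyN_letter is not None and profile.polyN_len > 0:
        bases[m - profile.polyN_len :] = profile.polyN_letter
    means = np.empty(m, dtype=np.float64)
    means[: profile.k2_true - 1] = profile.q_low_head
    means[profile.k2_true - 1 : profile.k1_true] = profile.q_high
    means[profile.k1_true :] = profile.q_low_tail
    jitter = rng.normal(0.0, profile.q_sd, size=m) if profile.q_sd > 0 else 0.0
    qualities = np.clip(np.rint(means + jitter), 0, 93).astype(np.int64)
    read = Read(id=read_id, sequence="".join(bases), qualities=qualities)
    return read, CutPoints(k2=profile.k2_true, k1=profile.k1_true)


def simulate_reads(
    profile: SimProfile, n_reads: int, seed: int
) -> Iterator[tuple[Read, CutPoints]]:
    """Yield ``n_reads`` independent reads from one seeded generator."""
    rng = np.random.default_rng(seed)
    for i in range(n_reads):
        yield simulate_read(profile, rng, read_id=f"sim_{i}")


def simulate_dataset(
    profile: SimProfile,
    n_reads: int,
    seed: int,
    fastq_path: PathLike,
    truth_path: Optional[PathLike] = None,
    gzip_output: bool = False,
    encoding: PhredEncoding = PhredEncoding(33),
) -> int:
    """Write a synthetic FASTQ file plus a TSV of planted cut-points.

    The truth table has columns (id, k2_true, k1_true) for scoring recovery.
    Returns the number of reads written; identical seeds give byte-identical
    files.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    truths: list[tuple[str, int, int]] = []

    def records() -> Iterator[FastqRecord]:
        for read, cut in simulate_reads(profile, n_reads, seed):
            truths.append((read.id, cut.k2, cut.k1))
            yield FastqRecord(
                id=read.id,
                sequence=read.sequence,
                plus="",
                quality_string=encoding.encode(read.qualities),
            )

    n = write_fastq(records(), fastq_path, gzip_output=gzip_output)
    if truth_path is not None:
        with open(truth_path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["id", "k2_true", "k1_true"])
            writer.writerows(truths)
    return n
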