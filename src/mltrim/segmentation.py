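"""Maximum-likelihood segmentation of a read into unreliable/informative parts.

A read of length m is modelled as (at most) three contiguous segments: an
unreliable head, an informative core, and an unreliable tail.  The trimmer
finds the two cut-points by double binary segmentation: first the tail
cut-point k1 on the whole read (where the most positions support the choice),
then the head cut-point k2 on the subsequence [1, k1].  Each single cut is the
argmax of a complete-data likelihood in which bases before the cut follow the
informative model f0 (informativeness probability times the segment's own
empirical nucleotide frequencies) and bases after it follow the unreliable
model f1 (complementary probability, uniform over four nucleotides).

The nucleotide frequencies Pr(N) of a candidate informative segment have a
closed-form maximum-likelihood estimate (the empirical frequencies), so the
cut and the frequencies are jointly optimised by a single scan over k — no
EM iterations are required.

A poly-N variant swaps f1 for a letter-aware model so that homopolymer runs
(e.g. poly-A tails in RNA-seq) at either extremity are trimmed even when
their phred scores are moderate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .quality_model import PROB_FLOOR, ProbabilityCurve

#: IUB/IUPAC nucleotide alphabet, including ambiguity codes
ALPHABET = "ACGTURYSWKMBDHVN"
_CHAR_TO_INDEX = {c: i for i, c in enumerate(ALPHABET)}

#: letters accepted for homopolymer (poly-N) trimming
POLY_LETTERS = frozenset("ACGTU")

_LOG_FLOOR = float(np.log(PROB_FLOOR))


@dataclass
class Read:
    """A sequencing read: identifier, nucleotides, per-base phred scores."""

    id: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"read {self.id!r}: characters {sorted(bad)} outside the "
                f"IUB/IUPAC alphabet"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CutPoints:
    """1-based inclusive bounds [k2, k1] of the retained informative segment."""

    k2: int
    k1: int

    def __post_init__(self) -> None:
        if not 1 <= self.k2 <= self.k1:
            raise ValueError(f"invalid cut-points k2={self.k2}, k1={self.k1}")

    @property
    def length(self) -> int:
        return self.k1 - self.k2 + 1


@dataclass(frozen=True)
class TrimResult:
    """Outcome of trimming one read."""

    cut: Optional[CutPoints]
    kept_sequence: str
    kept_qualities: np.ndarray
    kept: bool


def nucleotide_profile(sequence: str) -> dict[str, float]:
    """Empirical frequencies Pr(N) over the IUPAC alphabet for a segment."""
    if not sequence:
        raise ValueError("cannot profile an empty segment")
    n = len(sequence)
    profile = dict.fromkeys(ALPHABET, 0.0)
    for c in sequence.upper():
        profile[c] += 1.0 / n
    return profile


def f0(n: str, q: int, profile: dict[str, float], curve: ProbabilityCurve) -> float:
    """Informative-segment probability: p(q, t) * Pr(n), floored."""
    if n not in _CHAR_TO_INDEX:
        raise ValueError(f"nucleotide {n!r} outside the IUB/IUPAC alphabet")
    return max(curve[q] * profile[n], PROB_FLOOR)


def f1_quality(n: str, q: int, curve: ProbabilityCurve) -> float:
    """Unreliable-segment probability: (1 - p(q, t)) / 4, floored."""
    return max((1.0 - curve[q]) / 4.0, PROB_FLOOR)


def f1_polyN(n: str, q: int, letter: str, curve: ProbabilityCurve) -> float:
    """Homopolymer-segment probability.

    p(q, t) if the base equals the homopolymer letter (a confidently-called
    occurrence of the letter), otherwise (1 - p(q, t)) / 4 (the base could
    have been the letter but was miscalled).
    """
    if letter not in POLY_LETTERS:
        raise ValueError(f"poly-N letter must be one of {sorted(POLY_LETTERS)}")
    p = curve[q]
    return max(p if n == letter else (1.0 - p) / 4.0, PROB_FLOOR)


def _encode(sequence: str) -> np.ndarray:
    return np.fromiter(
        (_CHAR_TO_INDEX[c] for c in sequence), dtype=np.int64, count=len(sequence)
    )


def _p_values(qualities: np.ndarray, curve: ProbabilityCurve) -> np.ndarray:
    return curve.values[qualities]


def _log_f1_vector(
    sequence: str,
    p: np.ndarray,
    poly_letter: Optional[str],
) -> np.ndarray:
    """Per-position log f1, independent of the cut position."""
    miscall = np.maximum((1.0 - p) / 4.0, PROB_FLOOR)
    if poly_letter is None:
        return np.log(miscall)
    if poly_letter not in POLY_LETTERS:
        raise ValueError(f"poly-N letter must be one of {sorted(POLY_LETTERS)}")
    is_letter = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8) == ord(
        poly_letter
    )
    return np.log(np.where(is_letter, np.maximum(p, PROB_FLOOR), miscall))


def _loglik_all_cuts(
    seq_idx: np.ndarray, p: np.ndarray, log_f1: np.ndarray
) -> np.ndarray:
    """Log-likelihood of every tail cut k in [1, m], vectorised.

    Entry k-1 holds sum_{i<=k} [log f0(n_i) - log k] +
    sum_{i>k} [log f1(n_i) - log(m-k)], with the second sum empty at k = m.
    """
    m = len(seq_idx)
    k = np.arange(1, m + 1, dtype=np.float64)

    # counts[c, a]: occurrences of letter a among positions 0..c
    onehot = np.zeros((m, len(ALPHABET)))
    onehot[np.arange(m), seq_idx] = 1.0
    counts = np.cumsum(onehot, axis=0)

    # f0 for position i under cut c >= i: p_i * counts[c, n_i] / (c+1)
    count_of_own = counts[:, seq_idx]  # (cut c, position i)
    f0_mat = np.maximum(p[None, :] * count_of_own / k[:, None], PROB_FLOOR)
    lower = np.tril(np.ones((m, m), dtype=bool))
    log_f0 = np.where(lower, np.log(f0_mat), 0.0)
    informative = log_f0.sum(axis=1) - k * np.log(k)

    tail_sums = np.concatenate([np.cumsum(log_f1[::-1])[::-1][1:], [0.0]])
    m_minus_k = m - k
    with np.errstate(divide="ignore", invalid="ignore"):
        tail_norm = np.where(m_minus_k > 0, m_minus_k * np.log(m_minus_k), 0.0)
    return informative + tail_sums - tail_norm


def loglik_at_cut(
    read: Read,
    k: int,
    curve: ProbabilityCurve,
    poly_letter: Optional[str] = None,
) -> float:
    """Log-likelihood of a single tail cut at position k (1-based).

    Pr(N) is estimated from positions [1, k]; the tail model is the quality
    model by default, or the poly-N model when ``poly_letter`` is given.
    """
    m = len(read)
    if not 1 <= k <= m:
        raise ValueError(f"cut k={k} outside [1, {m}]")
    seq_idx = _encode(read.sequence)
    p = _p_values(read.qualities, curve)
    log_f1 = _log_f1_vector(read.sequence, p, poly_letter)
    return float(_loglik_all_cuts(seq_idx, p, log_f1)[k - 1])


def estimate_tail_cut(
    read: Read,
    curve: ProbabilityCurve,
    poly_letter: Optional[str] = None,
) -> int:
    """Best tail cut-point k1 in [1, m]; ties broken toward the largest k."""
    m = len(read)
    if m == 0:
        raise ValueError("cannot segment an empty read")
    seq_idx = _encode(read.sequence)
    p = _p_values(read.qualities, curve)
    log_f1 = _log_f1_vector(read.sequence, p, poly_letter)
    loglik = _loglik_all_cuts(seq_idx, p, log_f1)
    # argmax on the reversed array selects the largest k among exact ties
    return m - int(np.argmax(loglik[::-1]))


def estimate_head_cut(
    read: Read,
    k1: int,
    curve: ProbabilityCurve,
    poly_letter: Optional[str] = None,
) -> int:
    """Best head cut-point k2 in [1, k1]; ties broken toward the smallest k2.

    Implemented by reversing the subsequence [1, k1] and reusing the tail
    scan; the mirrored result maps back as k2 = k1 - k1' + 1, so the
    largest-k' tie rule becomes smallest-k2.
    """
    m = len(read)
    if not 1 <= k1 <= m:
        raise ValueError(f"k1={k1} outside [1, {m}]")
    mirrored = Read(
        id=read.id,
        sequence=read.sequence[:k1][::-1],
        qualities=read.qualities[:k1][::-1],
    )
    k1_prime = estimate_tail_cut(mirrored, curve, poly_letter)
    return k1 - k1_prime + 1


def _trim(
    read: Read,
    curve: ProbabilityCurve,
    min_len: int,
    poly_letter: Optional[str],
) -> TrimResult:
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    if len(read) == 0:
        return TrimResult(
            cut=None, kept_sequence="", kept_qualities=np.array([], dtype=np.int64),
            kept=False,
        )
    k1 = estimate_tail_cut(read, curve, poly_letter)
    k2 = estimate_head_cut(read, k1, curve, poly_letter)
    cut = CutPoints(k2=k2, k1=k1)
    kept = cut.length >= min_len
    return TrimResult(
        cut=cut,
        kept_sequence=read.sequence[k2 - 1 : k1],
        kept_qualities=read.qualities[k2 - 1 : k1],
        kept=kept,
    )


def trim_read(read: Read, curve: ProbabilityCurve, min_len: int = 1) -> TrimResult:
    """Quality-trim a read: k1 on the full read, then k2 on [1, k1].

    The retained segment [k2, k1] is kept only if it has at least
    ``min_len`` nucleotides.
    """
    return _trim(read, curve, min_len, poly_letter=None)


def trim_polyN(
    read: Read, letter: str, curve: ProbabilityCurve, min_len: int = 1
) -> TrimResult:
    """Trim homopolymer runs of ``letter`` from the read extremities."""
    if letter not in POLY_LETTERS:
        raise ValueError(f"poly-N letter must be one of {sorted(POLY_LETTERS)}")
    return _trim(read, curve, min_len, poly_letter=letter)
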