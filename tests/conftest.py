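"""Shared fixtures and the naive segmentation oracle.

The oracle recomputes, for every candidate cut, the nucleotide profile and
both likelihood products from scratch in pure Python.  It shares no code
with the vectorised production scan and serves as the independent reference
for argmax equivalence tests.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from mltrim.quality_model import PROB_FLOOR, ProbabilityCurve, build_curve

ALPHABET = "ACGTURYSWKMBDHVN"


@pytest.fixture(scope="session")
def curve20() -> ProbabilityCurve:
    return build_curve(20.0)


def naive_loglik(
    sequence: str,
    qualities,
    k: int,
    curve: ProbabilityCurve,
    letter: str | None = None,
) -> float:
    """Log-likelihood of tail cut k, recomputed from scratch (1-based k)."""
    m = len(sequence)
    assert 1 <= k <= m
    prefix = sequence[:k]
    ll = 0.0
    for i in range(k):
        pr = prefix.count(sequence[i]) / k
        f0 = max(curve[int(qualities[i])] * pr, PROB_FLOOR)
        ll += math.log(f0) - math.log(k)
    for i in range(k, m):
        p = curve[int(qualities[i])]
        if letter is not None and sequence[i] == letter:
            f1 = p
        else:
            f1 = (1.0 - p) / 4.0
        ll += math.log(max(f1, PROB_FLOOR)) - math.log(m - k)
    return ll


def naive_tail_cut(sequence, qualities, curve, letter=None) -> int:
    """Exhaustive argmax over k1 in [1, m]; ties toward the largest k."""
    m = len(sequence)
    return max(
        range(1, m + 1),
        key=lambda k: (naive_loglik(sequence, qualities, k, curve, letter), k),
    )


def naive_head_loglik(sequence, qualities, k2, k1, curve, letter=None) -> float:
    """Direct (un-mirrored) head-cut likelihood: f1 on [1,k2-1], f0 on [k2,k1]."""
    assert 1 <= k2 <= k1 <= len(sequence)
    segment = sequence[k2 - 1 : k1]
    seg_len = k1 - k2 + 1
    ll = 0.0
    for i in range(k2 - 1):
        p = curve[int(qualities[i])]
        if letter is not None and sequence[i] == letter:
            f1 = p
        else:
            f1 = (1.0 - p) / 4.0
        ll += math.log(max(f1, PROB_FLOOR)) - math.log(k2 - 1)
    for i in range(k2 - 1, k1):
        pr = segment.count(sequence[i]) / seg_len
        f0 = max(curve[int(qualities[i])] * pr, PROB_FLOOR)
        ll += math.log(f0) - math.log(seg_len)
    return ll


def naive_head_cut(sequence, qualities, k1, curve, letter=None) -> int:
    """Exhaustive argmax over k2 in [1, k1]; ties toward the smallest k2."""
    return max(
        range(1, k1 + 1),
        key=lambda k2: (
            naive_head_loglik(sequence, qualities, k2, k1, curve, letter),
            -k2,
        ),
    )


def assert_same_cut(k_prod: int, k_naive: int, loglik_of) -> None:
    """Production and oracle argmax agree, allowing float-level ties.

    Likelihood ties that are exact in real arithmetic can round differently
    in the two implementations; in that case both cuts must score equally
    (to 1e-9) under the oracle's own likelihood.
    """
    if k_prod == k_naive:
        return
    a, b = loglik_of(k_prod), loglik_of(k_naive)
    assert math.isclose(a, b, rel_tol=1e-9, abs_tol=1e-9), (
        f"cuts {k_prod} vs {k_naive} differ beyond a tie: {a} vs {b}"
    )


def random_read(rng: np.random.Generator, max_len: int = 30, q_max: int = 45):
    """Random sequence/qualities; occasional ambiguity codes in the sequence."""
    m = int(rng.integers(1, max_len + 1))
    letters = list("ACGT") * 6 + ["N", "R", "Y"]
    sequence = "".join(rng.choice(letters, size=m))
    qualities = rng.integers(0, q_max + 1, size=m)
    return sequence, qualities
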