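"""Probability model mapping phred scores to informativeness probabilities.

The classical phred relation gives the probability that a base call is
*correct*: ``p_a(q) = 1 - 10**(-q/10)``.  Quality trimming, however, asks a
different question — is a base *informative*, i.e. does its quality exceed a
user-chosen threshold ``t``?  We therefore use a shifted function
``p_b(q, t) = 1 - 2**(-q/t)`` which equals 0.5 exactly at ``q = t``: bases at
the threshold are as likely to be informative as not.

``p_b`` has a drawback for t <= 20: even high phred scores map to middling
probabilities (``p_b(40, 20) = 0.75``), so unreliable bases would dominate the
segment likelihoods.  Above ``max(20, t)`` the function is therefore replaced
by a cubic Bezier spline that rises smoothly to reach exactly 1 at phred 45,
giving the full piecewise curve ``p(q, t)``.

Setting ``t = 10*log10(2) ~ 3.0103`` recovers the classical phred function:
``p_b(q, 3.0103) = p_a(q)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

#: phred score at which p(q, t) is constrained to reach probability 1
Q_MAX_INFORMATIVE = 45

#: largest phred score representable in printable-ASCII FASTQ (offset 33)
Q_ENCODABLE_MAX = 93

#: floor applied to probability factors inside log-likelihoods downstream
PROB_FLOOR = 1e-30

#: threshold value at which p_b coincides with the classical phred function
T_PHRED_EQUIVALENT = 10 * math.log10(2)


def prob_correct(q: float) -> float:
    """Probability that a base call with phred score ``q`` is correct.

    ``p_a(q) = 1 - 10**(-q/10)``; e.g. ``prob_correct(20) == 0.99``.
    """
    if q < 0:
        raise ValueError(f"negative phred score {q}: check the quality offset")
    return 1.0 - 10.0 ** (-q / 10.0)


def prob_informative_raw(q: float, t: float) -> float:
    """Shifted informativeness probability ``p_b(q, t) = 1 - 2**(-q/t)``.

    Equals 0.5 at ``q = t`` and 0 at ``q = 0``, for any threshold ``t > 0``.
    """
    if t <= 0:
        raise ValueError(f"threshold t must be positive, got {t}")
    if q < 0:
        raise ValueError(f"negative phred score {q}: check the quality offset")
    return 1.0 - 2.0 ** (-q / t)


def tangent_line(q0: float, t: float) -> Callable[[float], float]:
    """Tangent to ``q -> 1 - 2**(-q/t)`` at ``q0``, as an affine map of q.

    The slope is ``(ln 2 / t) * 2**(-q0/t)``; the tangent touches the curve
    at ``q0`` by construction.
    """
    if t <= 0:
        raise ValueError(f"threshold t must be positive, got {t}")
    f0 = 1.0 - 2.0 ** (-q0 / t)
    slope = (math.log(2.0) / t) * 2.0 ** (-q0 / t)
    return lambda q: f0 + slope * (q - q0)


def bezier_cubic(u: float, p1: float, p2: float, p3: float, p4: float) -> float:
    """Cubic Bezier curve in Bernstein form, evaluated at ``u`` in [0, 1].

    Starts at ``p1`` heading toward ``p2`` and arrives at ``p4`` from the
    direction of ``p3``.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"Bezier parameter u={u} outside [0, 1]: scaling bug")
    v = 1.0 - u
    return v * v * v * p1 + 3.0 * v * v * u * p2 + 3.0 * v * u * u * p3 + u * u * u * p4


def _bezier_controls(t: float) -> tuple[float, float, float]:
    """Switch point q0 = max(20, t) and control values (p1, p2) of the spline.

    p1 is the raw curve value at q0; p2 lies on the tangent at q0, one third
    of the way to 45.  p2 is capped at 1 so the control points stay
    non-decreasing (p1 <= p2 <= 1 = p3 = p4), which keeps the Bezier segment
    monotone and bounded by 1 for every threshold.
    """
    q0 = max(20.0, t)
    p1 = prob_informative_raw(q0, t)
    g = tangent_line(q0, t)
    p2 = min(g(q0 + (Q_MAX_INFORMATIVE - q0) / 3.0), 1.0)
    return q0, p1, p2


def prob_informative(q: float, t: float, *, _literal_scaling: bool = False) -> float:
    """Full informativeness probability ``p(q, t)`` of the piecewise spline.

    Returns ``p_b(q, t)`` for ``q <= max(20, t)``, exactly 1 for
    ``q >= 45``, and the cubic Bezier extension in between.  Continuous and
    non-decreasing in q.

    ``_literal_scaling`` selects the alternative Bezier parameterisation
    ``u = (q - t)/(45 - t)``; it is discontinuous at the branch switch for
    ``t < 20`` and exists only for comparison.
    """
    if q >= Q_MAX_INFORMATIVE:
        return 1.0
    q0, p1, p2 = _bezier_controls(t)
    if q <= q0:
        return prob_informative_raw(q, t)
    if _literal_scaling:
        u = (q - t) / (Q_MAX_INFORMATIVE - t)
    else:
        u = (q - q0) / (Q_MAX_INFORMATIVE - q0)
    u = min(max(u, 0.0), 1.0)
    return bezier_cubic(u, p1, p2, 1.0, 1.0)


@dataclass(frozen=True)
class ProbabilityCurve:
    """Lookup table of ``p(q, t)`` over the integer phred range [0, 93].

    ``curve[q]`` equals ``prob_informative(q, t)`` bit-for-bit.  Instances
    are immutable and safe to share across worker processes.
    """

    t: float
    values: np.ndarray = field(repr=False)

    def __getitem__(self, q: int) -> float:
        return float(self.values[q])

    def __call__(self, q: int) -> float:
        return float(self.values[q])

    def __len__(self) -> int:
        return len(self.values)


def build_curve(t: float) -> ProbabilityCurve:
    """Materialise ``p(q, t)`` as a :class:`ProbabilityCurve` for integer q."""
    if t <= 0:
        raise ValueError(f"threshold t must be positive, got {t}")
    values = np.array(
        [prob_informative(q, t) for q in range(Q_ENCODABLE_MAX + 1)], dtype=np.float64
    )
    values.setflags(write=False)
    return ProbabilityCurve(t=t, values=values)
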