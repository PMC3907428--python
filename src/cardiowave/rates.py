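"""Voltage-dependent gate rate functions in canonical form.

Every opening/closing rate of the Hodgkin-Huxley gates is an instance of

    rate(V) = (c1*exp(c2*(V+c3)) + c4*(V+c5)) / (exp(c6*(V+c3)) + c7)  [1/ms]

Some specs (e.g. the sodium-activation alpha rate) have a removable 0/0
singularity at a voltage where numerator and denominator vanish together;
such specs carry the singular point and its analytic (L'Hopital) limit, and
evaluation within a configured half-width of the point returns the limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateRatesError, InvalidInputError
from .kernels import rate_eval

#: default half-width of the window around a singular point inside which the
#: stored analytic limit replaces the 0/0 expression
SINGULAR_HALFWIDTH = 1e-6


@dataclass(frozen=True)
class RateSpec:
    """Coefficients of one canonical-form rate function."""

    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    c4: float = 0.0
    c5: float = 0.0
    c6: float = 0.0
    c7: float = 0.0
    singular_v: float | None = None
    singular_limit: float | None = None

    def packed(self) -> np.ndarray:
        """9-vector [c1..c7, singular_v (nan if none), singular_limit]."""
        sv = math.nan if self.singular_v is None else self.singular_v
        sl = 0.0 if self.singular_limit is None else self.singular_limit
        return np.array([self.c1, self.c2, self.c3, self.c4, self.c5,
                         self.c6, self.c7, sv, sl], dtype=np.float64)

    def scaled(self, factor: float) -> "RateSpec":
        """Rate multiplied by ``factor`` (scales numerator and limit)."""
        return RateSpec(
            c1=self.c1 * factor, c2=self.c2, c3=self.c3,
            c4=self.c4 * factor, c5=self.c5, c6=self.c6, c7=self.c7,
            singular_v=self.singular_v,
            singular_limit=None if self.singular_limit is None
            else self.singular_limit * factor)


def evaluate_rate(v: float, spec: RateSpec,
                  halfwidth: float = SINGULAR_HALFWIDTH) -> float:
    """Evaluate a canonical-form rate at membrane potential ``v`` (mV)."""
    v = float(v)
    if not math.isfinite(v):
        raise InvalidInputError(f"non-finite membrane potential: {v!r}")
    if spec.singular_v is not None and spec.singular_limit is None:
        raise InvalidInputError("singular_v set without singular_limit")
    return float(rate_eval(v, spec.packed(), halfwidth))


def gate_steady_state(alpha: float, beta: float) -> tuple[float, float]:
    """Steady-state open fraction and time constant of a two-state gate.

    Returns ``(g_inf, tau)`` with g_inf = alpha/(alpha+beta) and
    tau = 1/(alpha+beta) ms.
    """
    if alpha < 0.0 or beta < 0.0:
        raise InvalidInputError("rates must be non-negative")
    s = alpha + beta
    if s == 0.0:
        raise DegenerateRatesError("alpha + beta == 0: steady state undefined")
    return alpha / s, 1.0 / s
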