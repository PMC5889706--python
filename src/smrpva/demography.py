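"""Maximum intrinsic growth rate from a two-survival Euler-Lotka identity.

The classic Euler-Lotka equation links the intrinsic rate of increase ``r``
to age at first reproduction ``a``, per-female fecundity ``m`` (female
offspring per female per year) and survivorship.  The variant solved here
separates adult survival ``S = e^{-M}`` (with ``M`` the instantaneous
natural mortality rate) from survivorship to first parturition ``l_a``:

    f(r) = e^{r a} - S * e^{r (a - 1)} - m * l_a = 0.

For ``a = 2`` this is a quadratic in ``x = e^r`` with positive root
``x = (S + sqrt(S^2 + 4 m l_a)) / 2``; for general integer ``a`` the root
is found by bisection, which is unconditionally robust on a bracket with a
sign change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import optimize

__all__ = ["DemogParams", "solve_r"]


@dataclass(frozen=True)
class DemogParams:
    """Inputs to the Euler-Lotka solver.

    Attributes
    ----------
    a
        Age at first parturition (whole years, >= 1).
    m
        Female offspring per female per year.
    l_a
        Survivorship from birth to age ``a`` (probability).
    survival
        Annual adult survival ``e^{-M}`` (probability).
    """

    a: int = 2
    m: float = 1.5
    l_a: float = 0.35
    survival: float = 0.8

    def __post_init__(self) -> None:
        if int(self.a) != self.a or self.a < 1:
            raise ValueError("age at first parturition must be an integer >= 1")
        if self.m < 0:
            raise ValueError("fecundity m must be >= 0")
        if not 0.0 <= self.l_a <= 1.0:
            raise ValueError("survivorship l_a must lie in [0, 1]")
        if not 0.0 <= self.survival <= 1.0:
            raise ValueError("annual survival must lie in [0, 1]")


def _euler_lotka(r: float, p: DemogParams) -> float:
    return math.exp(r * p.a) - p.survival * math.exp(r * (p.a - 1)) - p.m * p.l_a


def solve_r(
    params: DemogParams,
    tol: float = 1e-10,
    bracket: tuple[float, float] = (-2.0, 2.0),
    method: str = "auto",
) -> float:
    """Solve the Euler-Lotka equation for the maximum intrinsic growth rate.

    Parameters
    ----------
    params
        Demographic inputs.
    tol
        Absolute tolerance on ``r``.
    bracket
        Search interval for the bisection solver.
    method
        ``"auto"`` uses the closed form when ``a == 2`` and bisection
        otherwise; ``"closed_form"`` and ``"bisect"`` force one route (the
        two are cross-checked in the test suite).

    Returns
    -------
    float
        The growth rate ``r`` (per year).
    """
    p = params
    if method not in ("auto", "closed_form", "bisect"):
        raise ValueError(f"unknown method {method!r}")
    if method == "closed_form" or (method == "auto" and p.a == 2):
        if p.a != 2:
            raise ValueError("closed form only applies to a = 2")
        x = (p.survival + math.sqrt(p.survival**2 + 4.0 * p.m * p.l_a)) / 2.0
        if x <= 0:
            raise ValueError("no positive root for e^r")
        return math.log(x)
    lo, hi = bracket
    flo, fhi = _euler_lotka(lo, p), _euler_lotka(hi, p)
    if flo * fhi > 0:
        raise ValueError(f"no sign change on bracket [{lo}, {hi}]")
    return float(optimize.bisect(_euler_lotka, lo, hi, args=(p,), xtol=tol))
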