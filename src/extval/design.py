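"""Validation design: minimum sample size and clinical risk bands.

The sample-size rule is the C-statistic precision criterion for external
validation of a binary-outcome model: choose the smallest n whose
anticipated 95% confidence interval for the C-statistic is no wider than a
stated full width ``w``, using the Newcombe-style variance approximation

    var(C) = C(1-C) * [1 + (n/2 - 1)(1-C)/(2-C) + (n/2 - 1) C/(1+C)]
             / (n^2 * phi * (1-phi))

with anticipated C-statistic ``C`` and outcome prevalence ``phi``. For
C = 0.82, phi = 0.11 and w = 0.1 this gives n = 700 with 77 expected events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SampleSizeInput",
    "SampleSizeResult",
    "c_statistic_variance",
    "min_validation_n",
    "classify_risk",
    "RISK_BAND_BOUNDS",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class SampleSizeInput:
    """Anticipated C-statistic, outcome prevalence, and target 95% CI width."""

    c_statistic: float
    prevalence: float
    ci_width: float

    def __post_init__(self) -> None:
        if not 0.5 < self.c_statistic < 1.0:
            raise ValueError("anticipated C-statistic must lie in (0.5, 1)")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0.0 < self.ci_width < 1.0:
            raise ValueError("CI width must lie in (0, 1)")


@dataclass(frozen=True)
class SampleSizeResult:
    n: int
    events: int
    achieved_width: float


def c_statistic_variance(c: float, phi: float, n: int) -> float:
    """Newcombe-style approximation to var(C-hat) at sample size n."""
    half = n / 2 - 1
    num = c * (1 - c) * (1 + half * (1 - c) / (2 - c) + half * c / (1 + c))
    return num / (n**2 * phi * (1 - phi))


def _width(c: float, phi: float, n: int) -> float:
    return 2 * _Z95 * math.sqrt(c_statistic_variance(c, phi, n))


def min_validation_n(inp: SampleSizeInput, n_cap: int = 10_000_000) -> SampleSizeResult:
    """Smallest integer n whose anticipated 95% CI full width is <= the target.

    Ascending search from n = 2; the returned n brackets the target
    (width(n) <= w < width(n-1)). Expected events are rounded up. Raises if
    no n up to ``n_cap`` satisfies the width.
    """
    c, phi, w = inp.c_statistic, inp.prevalence, inp.ci_width
    n = 2
    # geometric jump then linear backtrack keeps this O(log n) in practice
    while n <= n_cap and _width(c, phi, n) > w:
        n *= 2
    if n > n_cap:
        raise ValueError(f"required n exceeds cap {n_cap} for width {w}")
    lo = n // 2
    for cand in range(max(2, lo), n + 1):
        if _width(c, phi, cand) <= w:
            n = cand
            break
    return SampleSizeResult(
        n=n, events=math.ceil(phi * n), achieved_width=_width(c, phi, n)
    )


#: Risk-band boundaries used by the bedside calculator interpretation:
#: low < 5%, intermediate 5-15% (inclusive at both ends), high > 15%.
RISK_BAND_BOUNDS = (0.05, 0.15)


def classify_risk(p: float, bounds: tuple[float, float] = RISK_BAND_BOUNDS) -> str:
    """Map a predicted probability to a clinical risk band.

    Boundary convention: both boundary values belong to the intermediate
    band. Probabilities must lie strictly inside (0, 1).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("probability must lie strictly inside (0, 1)")
    lo, hi = bounds
    if p < lo:
        return "low"
    if p <= hi:
        return "intermediate"
    return "high"
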