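"""Phenotype-level summary statistics.

Small, exact operations on group summaries (mean, SD, n): percent reduction
of a treated group relative to control, the two-sample Student's t-test
computed from summary data (pooled-variance by default, Welch optional), and
affected-embryo proportions with an optional Wilson confidence interval.
These are the statistics used to quantify effects such as reduced
proliferating-cell density or the fraction of virus-infected embryos with
visibly reduced wings.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class GroupSummary:
    """Summary of one experimental group: label, mean, SD and unit count."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @classmethod
    def from_data(cls, label: str, values) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        return cls(label, float(values.mean()), float(values.std(ddof=1)), len(values))


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_reduction(
    control: GroupSummary, treated: GroupSummary, decimals: int = 0
) -> float:
    """100 * (1 - treated.mean / control.mean), round-half-up to ``decimals``.

    A relative measure: it is not antisymmetric under swapping the groups.
    """
    if control.mean <= 0:
        raise ValueError("control mean must be positive")
    pct = 100.0 * (1.0 - treated.mean / control.mean)
    return _round_half_up(pct, decimals)


def two_sample_t_summary(
    a: GroupSummary, b: GroupSummary, variant: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test from group summaries.

    ``pooled`` is the classic Student test with a pooled variance estimate
    and df = n_a + n_b - 2; ``welch`` uses Satterthwaite degrees of freedom.
    Returns ``(t, df, p)``. Zero pooled variance gives t = 0, p = 1 for
    equal means, else an infinite t with p = 0.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    diff = a.mean - b.mean
    if variant == "pooled":
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = np.sqrt(va + vb)
        if va + vb > 0:
            df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        else:
            df = float(a.n + b.n - 2)
    if se == 0:
        if diff == 0:
            return 0.0, df, 1.0
        import warnings

        warnings.warn("zero variance with unequal means: p = 0", UserWarning, stacklevel=2)
        return float(np.sign(diff) * np.inf), df, 0.0
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def two_sample_t_data(x, y, variant: str = "pooled") -> tuple[float, float, float]:
    """Raw-data convenience wrapper around :func:`two_sample_t_summary`."""
    return two_sample_t_summary(
        GroupSummary.from_data("x", x), GroupSummary.from_data("y", y), variant=variant
    )


def affected_proportion(
    k: int, n: int, decimals: int = 1, ci: bool = False
) -> float | tuple[float, tuple[float, float]]:
    """Percentage of affected cases 100*k/n, round-half-up to ``decimals``.

    With ``ci=True`` also returns the Wilson 95% interval (as percentages,
    unrounded).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    # high-precision decimal arithmetic before rounding (no float detour)
    q = Decimal(1).scaleb(-decimals)
    pct = float((Decimal(100) * Decimal(k) / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP))
    if not ci:
        return pct
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return pct, (100.0 * lo, 100.0 * hi)
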