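"""Fourfold tables and implication indices for dichotomous variables.

Statistical implication treats the directed statement "A implies B" as a
probabilistic claim: subjects with A=1 almost always have B=1, so the
counterexample cell (A=1, B=0) is rare relative to what independence would
predict. Two indices are provided:

* :func:`iota` — a full-information, Iota-style index on the log-odds scale
  that combines direct evidence (odds of B given A against the marginal
  odds of B) with contrapositive evidence (odds of not-A given not-B against
  the marginal odds of not-A). It ranges over (-inf, +inf); positive values
  favour the implication, 0 is the independence point, negative values count
  against it. Jeffreys-style smoothing keeps it finite on every table.
* :func:`gras_intensity` — the classical implication intensity based on the
  rarity of counterexamples only: the upper tail probability of the
  counterexample count under a Poisson independence model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FourfoldTable",
    "SmoothedProbs",
    "crosstab",
    "smooth",
    "iota",
    "gras_intensity",
]


@dataclass(frozen=True)
class FourfoldTable:
    """2x2 cross-tabulation of an ordered pair of binary variables.

    ``a`` counts (A=1, B=1), ``b`` counts (A=1, B=0) — the counterexamples
    of A=>B — ``c`` counts (A=0, B=1) — the counterexamples of B=>A — and
    ``d`` counts (A=0, B=0).
    """

    a: int
    b: int
    c: int
    d: int
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "FourfoldTable":
        """The table for the reversed pair (B, A): cells (a, c, b, d)."""
        return FourfoldTable(self.a, self.c, self.b, self.d,
                             self.label_b, self.label_a)

    def contrapositive(self) -> "FourfoldTable":
        """The table for (not-B, not-A): cells (d, b, c, a)."""
        return FourfoldTable(self.d, self.b, self.c, self.a,
                             f"not {self.label_b}", f"not {self.label_a}")

    @property
    def degenerate_margin(self) -> bool:
        """True when either variable is constant in the sample."""
        return min(self.a + self.b, self.c + self.d,
                   self.a + self.c, self.b + self.d) == 0

    def __str__(self) -> str:  # printable 2x2 with margins, for logs
        w = max(5, len(str(self.n)))
        rows = [
            f"{self.label_a} \\ {self.label_b:>{w}}  {'B=1':>{w}} {'B=0':>{w}} {'sum':>{w}}",
            f"{'A=1':>{w + 2}}  {self.a:>{w}} {self.b:>{w}} {self.a + self.b:>{w}}",
            f"{'A=0':>{w + 2}}  {self.c:>{w}} {self.d:>{w}} {self.c + self.d:>{w}}",
            f"{'sum':>{w + 2}}  {self.a + self.c:>{w}} {self.b + self.d:>{w}} {self.n:>{w}}",
        ]
        return "\n".join(rows)


@dataclass(frozen=True)
class SmoothedProbs:
    """Smoothed cell probabilities of a fourfold table and their margins."""

    p11: float
    p10: float
    p01: float
    p00: float
    alpha: float

    @property
    def p1_(self) -> float:  # margin P(A=1)
        return self.p11 + self.p10

    @property
    def p0_(self) -> float:
        return self.p01 + self.p00

    @property
    def p_1(self) -> float:  # margin P(B=1)
        return self.p11 + self.p01

    @property
    def p_0(self) -> float:
        return self.p10 + self.p00


def crosstab(m, label_a: str, label_b: str) -> FourfoldTable:
    """Fourfold table of an ordered outcome pair from an outcome matrix.

    Rows with a missing value in either column are excluded (a no-op after
    complete-case filtering).
    """
    if label_a == label_b:
        raise ValueError(f"cannot cross-tabulate {label_a!r} with itself")
    x = m.column(label_a)
    y = m.column(label_b)
    keep = ~(np.isnan(x) | np.isnan(y))
    x = x[keep].astype(bool)
    y = y[keep].astype(bool)
    return FourfoldTable(
        a=int((x & y).sum()),
        b=int((x & ~y).sum()),
        c=int((~x & y).sum()),
        d=int((~x & ~y).sum()),
        label_a=label_a,
        label_b=label_b,
    )


def smooth(t: FourfoldTable, alpha: float = 0.5) -> SmoothedProbs:
    """Add a pseudo-count ``alpha`` to every cell and renormalize.

    With ``alpha > 0`` every smoothed cell and margin is strictly positive,
    so log-odds contrasts stay finite even for tables with empty cells.
    ``alpha = 0.5`` (Jeffreys-style) is the default throughout the package.
    """
    if not alpha > 0:
        raise ValueError(f"smoothing pseudo-count must be positive, got {alpha}")
    denom = t.n + 4.0 * alpha
    return SmoothedProbs(
        p11=(t.a + alpha) / denom,
        p10=(t.b + alpha) / denom,
        p01=(t.c + alpha) / denom,
        p00=(t.d + alpha) / denom,
        alpha=alpha,
    )


def _iota_from_counts(a, b, c, d, alpha: float = 0.5):
    """Vectorized iota from raw cell counts (arrays or scalars).

    The common smoothing denominator cancels from both log-ratios, so the
    index can be computed from smoothed counts directly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    direct = (a + alpha) * (b + d + 2 * alpha) / ((b + alpha) * (a + c + 2 * alpha))
    contra = (d + alpha) * (a + b + 2 * alpha) / ((b + alpha) * (c + d + 2 * alpha))
    return 0.5 * (np.log(direct) + np.log(contra))


def iota(t: FourfoldTable, alpha: float = 0.5) -> float:
    """Full-information implication index for the directed pair A => B.

    With smoothed probabilities ``p``:

        iota = 1/2 * [ ln( p11 * p+0 / (p10 * p+1) )
                     + ln( p00 * p1+ / (p10 * p0+) ) ]

    The first term compares the odds of B among subjects with A to the
    marginal odds of B (direct evidence); the second compares the odds of
    not-A among subjects without B to the marginal odds of not-A
    (contrapositive evidence). Both are penalized by the counterexample
    cell p10, so the index is exactly invariant under the contrapositive
    relabeling (not-B => not-A). It is 0 exactly when the smoothed table
    factors into its margins.
    """
    if not alpha > 0:
        raise ValueError(f"smoothing pseudo-count must be positive, got {alpha}")
    return float(_iota_from_counts(t.a, t.b, t.c, t.d, alpha))


def gras_intensity(t: FourfoldTable) -> float:
    """Counterexample-rarity implication intensity for A => B, in [0, 1].

    Models the counterexample count as Poisson with mean
    ``lambda = (a+b)(b+d)/n`` (its expectation under independence) and
    returns ``P(N >= b)``: values near 1 mean counterexamples are rarer
    than independence predicts. Defined only when both the A=1 margin and
    the B=0 margin are non-empty.
    """
    n_a = t.a + t.b
    n_notb = t.b + t.d
    if n_a == 0 or n_notb == 0:
        raise ValueError(
            f"implication undefined for empty margin "
            f"({t.label_a}=1 margin {n_a}, {t.label_b}=0 margin {n_notb})"
        )
    lam = n_a * n_notb / t.n
    # P(N >= b) = survival function at b-1
    return float(stats.poisson.sf(t.b - 1, lam))
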