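"""Exact binomial tests and the 2x2 Pearson chi-square.

Tail conventions follow the reporting style of small-N forced-choice
studies: one-tailed values are exact binomial tail sums; the default
two-sided value doubles the smaller tail and caps at 1 (``tail doubling``).
The minimum-likelihood two-sided definition is available as
``two_sided_minlike`` but is not the default, because tail doubling is what
reproduces the published two-tailed values this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from scipy import stats

from .trial_model import ValidationError

Tail = Literal["upper", "lower", "smaller", "two_sided_double", "two_sided_minlike"]

#: Printed-convention chance level for 3-alternative trials. Deliberately
#: 0.33, not 1/3: the analyses this package reproduces round the chance
#: parameter before testing (1/3 is available by passing p0 explicitly).
CHANCE_3ALT = 0.33
CHANCE_2ALT = 0.5


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test, with everything needed to recompute it."""

    test: Literal["binomial", "chisq2x2", "monte_carlo"]
    p_value: float
    tail: Tail | None = None
    k: int | None = None
    n: int | None = None
    chance_level: float | None = None
    table: tuple[tuple[int, int], tuple[int, int]] | None = None
    statistic: float | None = None
    df: int | None = None
    label: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p_value outside [0, 1]")
        if self.statistic is not None and self.statistic < -1e-12:
            raise ValidationError("chi-square statistic must be nonnegative")

    def as_dict(self) -> dict:
        out = {"test": self.test, "label": self.label, "p_value": self.p_value}
        if self.test == "chisq2x2":
            out.update(table=self.table, statistic=self.statistic, df=self.df)
        else:
            out.update(k=self.k, n=self.n, chance_level=self.chance_level, tail=self.tail)
        if self.note:
            out["note"] = self.note
        return out


def binom_pvalue(
    k: int, n: int, p0: float, tail: Tail = "smaller", label: str = "", note: str = ""
) -> TestResult:
    """Exact binomial test of k successes in n trials against chance p0.

    Tails: ``upper`` = P(X >= k); ``lower`` = P(X <= k); ``smaller`` = the
    smaller of the two (the tail containing k); ``two_sided_double`` =
    min(1, 2 * smaller); ``two_sided_minlike`` sums all outcomes no more
    likely than k.
    """
    if not (0 <= k <= n) or n <= 0:
        raise ValidationError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"chance level must be in (0, 1), got {p0}")
    upper = float(stats.binom.sf(k - 1, n, p0))
    lower = float(stats.binom.cdf(k, n, p0))
    if tail == "upper":
        p = upper
    elif tail == "lower":
        p = lower
    elif tail == "smaller":
        p = min(upper, lower)
    elif tail == "two_sided_double":
        p = min(1.0, 2.0 * min(upper, lower))
    elif tail == "two_sided_minlike":
        p = float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return TestResult(
        test="binomial",
        p_value=min(1.0, p),
        tail=tail,
        k=k,
        n=n,
        chance_level=p0,
        label=label,
        note=note,
    )


def chisq2x2(
    a: int, b: int, c: int, d: int, label: str = "", note: str = ""
) -> TestResult:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]].

    No continuity correction; df = 1. Raises when a margin is zero (the
    statistic is undefined).
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("counts must be nonnegative")
    if 0 in (a + b, c + d, a + c, b + d):
        raise ValidationError("2x2 table has a zero margin")
    stat, p, df, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return TestResult(
        test="chisq2x2",
        p_value=float(p),
        table=((a, b), (c, d)),
        statistic=float(stat),
        df=int(df),
        label=label,
        note=note,
    )
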