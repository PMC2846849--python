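"""Per-gene case-control burden statistics.

Carrier collapse (a subject counts once per gene if it carries at least
one qualifying variant), two-sided Fisher exact test by full
hypergeometric enumeration, uncorrected Pearson chi-square, and cohort
relative risk with the Katz log-method confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "TwoByTwo",
    "BurdenResult",
    "carrier_table",
    "fisher_exact_two_sided",
    "pearson_chi2",
    "cohort_rr",
    "burden_table",
    "CASE_COHORT",
    "CONTROL_COHORT",
    "EXPOSURE_RATIO",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding, half away from zero (``0.005`` -> ``0.01``).

    Internal math never rounds; this is for rendering only.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))

CASE_COHORT = "case-cohort"
CONTROL_COHORT = "control-cohort"
EXPOSURE_RATIO = "exposure-ratio"

#: z for the 95% interval (fixed, not recomputed per call)
Z_95 = 1.959964

#: relative tolerance absorbing floating-point ties in the two-sided rule
_TIE_REL_TOL = 1e-7


@dataclass(frozen=True)
class TwoByTwo:
    """Carrier counts: a/b = case/control carriers, c/d = non-carriers."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    @property
    def n_controls(self) -> int:
        return self.b + self.d

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "TwoByTwo":
        """Cohort labels exchanged."""
        return TwoByTwo(self.b, self.a, self.d, self.c)


def _log_hypergeom_pmf(k: int, r1: int, c1: int, n: int) -> float:
    """log P(a = k) for fixed margins (row1=r1, col1=c1, total=n)."""
    lg = math.lgamma
    return (
        lg(r1 + 1) - lg(k + 1) - lg(r1 - k + 1)
        + lg(n - r1 + 1) - lg(c1 - k + 1) - lg(n - r1 - c1 + k + 1)
        - (lg(n + 1) - lg(c1 + 1) - lg(n - c1 + 1))
    )


def fisher_exact_two_sided(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums the probabilities of every table with the observed margins
    whose point probability does not exceed that of the observed table
    (up to a small relative tolerance absorbing floating-point ties).
    """
    r1 = t.a + t.b  # carriers
    c1 = t.a + t.c  # cases
    n = t.n
    if n == 0:
        raise ValueError("empty table")
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0

    lo = max(0, c1 + r1 - n)
    hi = min(r1, c1)
    log_pmf = [_log_hypergeom_pmf(k, r1, c1, n) for k in range(lo, hi + 1)]
    observed = log_pmf[t.a - lo]
    cutoff = observed + math.log1p(_TIE_REL_TOL)
    p = sum(math.exp(lp) for lp in log_pmf if lp <= cutoff)
    return min(p, 1.0)


def pearson_chi2(t: TwoByTwo) -> tuple[float, float]:
    """Uncorrected Pearson chi-square statistic and p (1 df)."""
    a, b, c, d = t.a, t.b, t.c, t.d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValueError("chi-square requires all margins positive")
    n = t.n
    stat = n * (a * d - b * c) ** 2 / math.prod(margins)
    return stat, float(_chi2_dist.sf(stat, 1))


def cohort_rr(
    t: TwoByTwo, orientation: str = CASE_COHORT, z: float = Z_95
) -> tuple[float, float, float]:
    """Relative risk with the Katz log-method confidence interval.

    Case-cohort orientation: risk of being a case among carriers,
    ``[a/(a+b)] / [c/(c+d)]``.  Control-cohort swaps the outcome;
    exposure-ratio compares carriage between cohorts,
    ``[a/(a+c)] / [b/(b+d)]``.  No continuity correction is applied; a
    zero cell in the numerator risks is an error.
    """
    if orientation == CONTROL_COHORT:
        a, b, c, d = t.b, t.a, t.d, t.c
    elif orientation == CASE_COHORT:
        a, b, c, d = t.a, t.b, t.c, t.d
    elif orientation == EXPOSURE_RATIO:
        a, b, c, d = t.a, t.c, t.b, t.d
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if a == 0 or c == 0:
        raise ValueError(
            "relative risk undefined with a zero numerator cell; "
            "no continuity correction is applied — report the row descriptively"
        )
    if a + b == 0 or c + d == 0:
        raise ValueError("empty exposure group")
    rr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return rr, rr * math.exp(-z * se), rr * math.exp(z * se)


def carrier_table(
    gene: str,
    case_cohort: Sequence[set[str]] | Mapping[object, set[str]],
    control_cohort: Sequence[set[str]] | Mapping[object, set[str]],
    *,
    rna_pool: Iterable[str] | None = None,
) -> TwoByTwo:
    """Per-gene 2x2 from per-subject sets of qualifying-variant genes.

    Each cohort is a collection of per-subject gene sets (a subject's
    genes holding at least one qualifying variant).  ``rna_pool`` pools
    several gene symbols into one row (the RNA-gene "Others" row).
    """
    genes = set(rna_pool) if rna_pool is not None else {gene}

    def count(cohort) -> tuple[int, int]:
        subjects = list(cohort.values()) if isinstance(cohort, Mapping) else list(cohort)
        if not subjects:
            raise ValueError("empty cohort")
        carriers = sum(1 for s in subjects if s & genes)
        return carriers, len(subjects) - carriers

    a, c = count(case_cohort)
    b, d = count(control_cohort)
    return TwoByTwo(a, b, c, d)


@dataclass
class BurdenResult:
    gene: str
    table: TwoByTwo
    p_value: float
    test_used: str  # "fisher" | "chi2"
    rr: float | None
    rr_ci_low: float | None
    rr_ci_high: float | None
    orientation: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.rr is not None and not (self.rr_ci_low <= self.rr <= self.rr_ci_high):
            raise ValueError("CI does not bracket the point estimate")


def _run_test(t: TwoByTwo, policy: str) -> tuple[float, str]:
    if policy == "fisher":
        return fisher_exact_two_sided(t), "fisher"
    if policy == "chi2":
        return pearson_chi2(t)[1], "chi2"
    if policy == "auto":
        if t.n == 0:
            raise ValueError("empty table")
        expected_min = min(
            (t.a + t.b) * (t.a + t.c), (t.a + t.b) * (t.b + t.d),
            (t.c + t.d) * (t.a + t.c), (t.c + t.d) * (t.b + t.d),
        ) / t.n
        if expected_min < 5:
            return fisher_exact_two_sided(t), "fisher"
        return pearson_chi2(t)[1], "chi2"
    raise ValueError(f"unknown test policy {policy!r}")


def burden_table(
    tables: Mapping[str, TwoByTwo],
    policy: str | Mapping[str, str] = "fisher",
    orientation: str = CASE_COHORT,
) -> list[BurdenResult]:
    """One BurdenResult per gene row from prebuilt 2x2 tables.

    ``policy`` is a single test name (``fisher`` / ``chi2`` / ``auto``)
    or a per-gene mapping.  Rows whose relative risk is undefined (zero
    numerator cell) carry ``rr=None`` rather than an error.
    """
    results = []
    for gene, t in tables.items():
        pol = policy.get(gene, "fisher") if isinstance(policy, Mapping) else policy
        if t.a == 0 and t.b == 0:
            p, used = 1.0, "fisher" if pol != "chi2" else "chi2"
        else:
            p, used = _run_test(t, pol)
        try:
            rr, lo, hi = cohort_rr(t, orientation)
        except ValueError:
            rr = lo = hi = None
        results.append(BurdenResult(gene, t, p, used, rr, lo, hi, orientation))
    return results
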