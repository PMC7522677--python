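"""Cohort sperm-retrieval statistics: rates, chi-square tests, synthesis.

Compares sperm retrieval rates (SRR) between two surgical cohorts —
the historical bivalve-and-search method versus the systematic
longitudinal-incision/transverse-slicing method — overall and within
etiology and histopathology subgroups, using the uncorrected Pearson
chi-square test on 2x2 tables (no Yates continuity correction, no
exact-test fallback; see docs/methods.md for the small-expected-count
caveat).  Also generates synthetic Bernoulli cohorts for end-to-end
testing and Monte-Carlo calibration of the test.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import chi2_contingency

__all__ = [
    "COHORTS",
    "ETIOLOGIES",
    "HISTOPATHOLOGIES",
    "Cohort2x2",
    "PatientRecord",
    "SubgroupSummary",
    "SubgroupArm",
    "Chi2Result",
    "PowerResult",
    "DegenerateTableError",
    "UndefinedRateError",
    "VocabularyError",
    "srr",
    "pearson_chi2",
    "compare_cohorts",
    "synth_cohort",
    "power_sim",
]

COHORTS = ("previous", "new")
ETIOLOGIES = (
    "klinefelter",
    "azfc_deletion",
    "47xyy",
    "post_chemotherapy",
    "cryptorchidism_history",
    "other",
)
HISTOPATHOLOGIES = (
    "hypospermatogenesis",
    "uniform_maturation_arrest",
    "sertoli_cell_only",
    "unknown",
)


class DegenerateTableError(ValueError):
    """2x2 table with an empty row or column margin."""


class UndefinedRateError(ZeroDivisionError):
    """Retrieval rate requested for an empty group."""


class VocabularyError(ValueError):
    """Label outside the closed cohort/etiology/histopathology vocabularies."""


@dataclass(frozen=True)
class Cohort2x2:
    """Success/failure counts for two cohorts."""

    successes_g1: int
    failures_g1: int
    successes_g2: int
    failures_g2: int

    def __post_init__(self) -> None:
        counts = (self.successes_g1, self.failures_g1, self.successes_g2, self.failures_g2)
        if any(x < 0 or x != int(x) for x in counts):
            raise ValueError(f"counts must be non-negative integers, got {counts}")
        if self.n_g1 == 0 or self.n_g2 == 0 or self.total < 2:
            raise ValueError("each group must be non-empty and grand total >= 2")

    @property
    def n_g1(self) -> int:
        return self.successes_g1 + self.failures_g1

    @property
    def n_g2(self) -> int:
        return self.successes_g2 + self.failures_g2

    @property
    def total(self) -> int:
        return self.n_g1 + self.n_g2

    @property
    def degenerate(self) -> bool:
        """True if a row or column margin is zero (test undefined)."""
        return (
            self.successes_g1 + self.successes_g2 == 0
            or self.failures_g1 + self.failures_g2 == 0
        )

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.successes_g1, self.failures_g1], [self.successes_g2, self.failures_g2]]
        )


@dataclass(frozen=True)
class PatientRecord:
    """One patient: cohort, etiology subgroup, histopathology, outcome.

    ``outcome`` is True for successful sperm retrieval.  Continuous
    baseline covariates (age, hormones) are optional and unused by the
    analyses here; they exist for forward-compatibility of the CSV
    schema only.
    """

    id: str
    cohort: str
    subgroup: str
    histopathology: str
    outcome: bool
    age: float | None = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise VocabularyError(f"unknown cohort {self.cohort!r}; expected one of {COHORTS}")
        if self.subgroup not in ETIOLOGIES:
            raise VocabularyError(
                f"unknown etiology subgroup {self.subgroup!r}; expected one of {ETIOLOGIES}"
            )
        if self.histopathology not in HISTOPATHOLOGIES:
            raise VocabularyError(
                f"unknown histopathology {self.histopathology!r}; "
                f"expected one of {HISTOPATHOLOGIES}"
            )


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class SubgroupSummary:
    """One row of the cohort-comparison table."""

    label: str
    kind: str  # "overall" | "etiology" | "histopathology"
    successes_g1: int
    n_g1: int
    successes_g2: int
    n_g2: int
    srr_g1: float | None  # % rounded per policy; None if the arm is empty
    srr_g2: float | None
    statistic: float | None  # None when the test is not computable
    p: float | None
    significant: bool | None  # p < alpha; None when not computable

    def fraction(self, group: int) -> str:
        s, n = (self.successes_g1, self.n_g1) if group == 1 else (self.successes_g2, self.n_g2)
        r = self.srr_g1 if group == 1 else self.srr_g2
        if n == 0:
            return f"{s}/{n}"
        return f"{s}/{n} ({r:g}%)"


def srr(successes: int, n: int, decimals: int = 0) -> float:
    """Sperm retrieval rate 100*successes/n, rounded half-up to ``decimals``."""
    if n <= 0:
        raise UndefinedRateError(f"rate undefined for empty group (n={n})")
    if not (0 <= successes <= n):
        raise ValueError(f"successes must be in [0, n], got {successes}/{n}")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(successes) / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP)
    )


def pearson_chi2(table: Cohort2x2) -> Chi2Result:
    """Uncorrected Pearson chi-square test on a 2x2 table, df = 1.

    Deliberately no Yates continuity correction and no exact-test
    fallback for small expected counts: this is the variant the
    clinical comparison uses throughout, including subgroup rows with
    expected counts below 5 (caveat documented in docs/methods.md).
    """
    if table.degenerate:
        raise DegenerateTableError(
            "chi-square undefined: a row or column margin of the 2x2 table is zero"
        )
    stat, p, df, _ = chi2_contingency(table.as_array(), correction=False)
    return Chi2Result(statistic=float(stat), df=int(df), p=float(p))


def _summarize_row(
    label: str,
    kind: str,
    group1: list[PatientRecord],
    group2: list[PatientRecord],
    alpha: float,
    decimals: int,
) -> SubgroupSummary:
    s1, n1 = sum(r.outcome for r in group1), len(group1)
    s2, n2 = sum(r.outcome for r in group2), len(group2)
    rate1 = srr(s1, n1, decimals) if n1 else None
    rate2 = srr(s2, n2, decimals) if n2 else None
    stat = p = sig = None
    if n1 and n2:
        table = Cohort2x2(s1, n1 - s1, s2, n2 - s2)
        if not table.degenerate:
            res = pearson_chi2(table)
            stat, p, sig = res.statistic, res.p, res.p < alpha
    return SubgroupSummary(label, kind, s1, n1, s2, n2, rate1, rate2, stat, p, sig)


def compare_cohorts(
    records: list[PatientRecord], alpha: float = 0.05
) -> list[SubgroupSummary]:
    """Cohort comparison table: overall, per-etiology, per-histopathology rows.

    SRRs are rounded half-up to the reporting precision: 0 decimals for
    the overall row, 1 decimal for subgroup rows.  A row whose test is
    not computable (one cohort empty in that subgroup, or a degenerate
    table such as zero successes on both sides) carries ``p = None``.
    Subgroups with no patients in either cohort are omitted.
    """
    by_cohort: dict[str, list[PatientRecord]] = {c: [] for c in COHORTS}
    for r in records:
        by_cohort[r.cohort].append(r)
    g1, g2 = by_cohort["previous"], by_cohort["new"]
    if not g1 or not g2:
        raise ValueError("both cohorts must be present in the records")

    rows = [_summarize_row("overall", "overall", g1, g2, alpha, decimals=0)]
    for etiology in ETIOLOGIES:
        sub1 = [r for r in g1 if r.subgroup == etiology]
        sub2 = [r for r in g2 if r.subgroup == etiology]
        if sub1 or sub2:
            rows.append(_summarize_row(etiology, "etiology", sub1, sub2, alpha, decimals=1))
    for histo in HISTOPATHOLOGIES:
        sub1 = [r for r in g1 if r.histopathology == histo]
        sub2 = [r for r in g2 if r.histopathology == histo]
        if sub1 or sub2:
            rows.append(_summarize_row(histo, "histopathology", sub1, sub2, alpha, decimals=1))
    return rows


@dataclass(frozen=True)
class SubgroupArm:
    """One synthesis arm: a subgroup of one cohort with a true SRR."""

    cohort: str
    subgroup: str
    n: int
    rate: float
    histopathology: str = "unknown"

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError(f"rate must be in [0, 1], got {self.rate}")
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n}")


def synth_cohort(arms: list[SubgroupArm], seed: int) -> list[PatientRecord]:
    """Generate a synthetic cohort of independent Bernoulli outcomes.

    Each arm contributes exactly ``n`` patients whose success outcomes
    are i.i.d. Bernoulli(rate); deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    i = 0
    for arm in arms:
        outcomes = rng.random(arm.n) < arm.rate
        for outcome in outcomes:
            i += 1
            records.append(
                PatientRecord(
                    id=f"P{i:04d}",
                    cohort=arm.cohort,
                    subgroup=arm.subgroup,
                    histopathology=arm.histopathology,
                    outcome=bool(outcome),
                )
            )
    return records


@dataclass(frozen=True)
class PowerResult:
    rejection_fraction: float
    n_degenerate: int
    reps: int


def power_sim(
    n1: int,
    n2: int,
    p1: float,
    p2: float,
    alpha: float = 0.05,
    reps: int = 10_000,
    seed: int = 0,
) -> PowerResult:
    """Monte-Carlo rejection rate of the uncorrected chi-square test.

    Simulates ``reps`` pairs of Binomial(n1, p1) / Binomial(n2, p2)
    success counts, tests each 2x2 table, and returns the fraction with
    p < alpha.  Replicates whose table is degenerate (all successes or
    all failures) are skipped — counted as non-rejections and reported
    in ``n_degenerate``.  With p1 = p2 this measures the type-I error
    of the test at the given group sizes.
    """
    if reps < 100:
        raise ValueError(f"reps must be >= 100, got {reps}")
    rng = np.random.default_rng(seed)
    s1 = rng.binomial(n1, p1, size=reps)
    s2 = rng.binomial(n2, p2, size=reps)
    rejections = 0
    degenerate = 0
    for k1, k2 in zip(s1, s2):
        table = Cohort2x2(int(k1), n1 - int(k1), int(k2), n2 - int(k2))
        if table.degenerate:
            degenerate += 1
            continue
        if pearson_chi2(table).p < alpha:
            rejections += 1
    return PowerResult(
        rejection_fraction=rejections / reps, n_degenerate=degenerate, reps=reps
    )
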