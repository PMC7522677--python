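"""Incision-strategy enumeration, searchable-area totals, and ranking.

A microTESE procedure in this model is a tunical incision (which
bivalves the testis and fixes the exposure plane) followed by serial
parenchymal slicing in one anatomical plane.  A slicing plane parallel
to the bivalve exposure plane is infeasible: the slices would be
detached from the tunica albuginea and fall apart.  That leaves four
feasible methods, conventionally numbered

    1. longitudinal tunical incision, transverse slices
    2. longitudinal tunical incision, sagittal slices
    3. transverse tunical incision, sagittal slices
    4. transverse tunical incision, coronal slices

For a strictly oblate-ordered testis (a > b > c) the total searchable
area is strictly decreasing in the method number, so method 1 —
longitudinal tunical incision with transverse slicing — is optimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .geometry import (
    AreaBreakdown,
    PlaneOrientation,
    TestisEllipsoid,
    slice_face_sum_closed,
    slice_face_sum_direct,
)

__all__ = [
    "TunicalIncision",
    "IncisionStrategy",
    "StrategyComparison",
    "Recommendation",
    "InfeasibleStrategyError",
    "enumerate_strategies",
    "feasible_strategies",
    "strategy_by_label",
    "bivalve_face_area",
    "total_search_area",
    "pairwise_difference",
    "adjacent_difference_closed",
    "rank_strategies",
    "recommend",
]


class InfeasibleStrategyError(ValueError):
    """Strategy whose slices would detach from the tunica albuginea."""


class TunicalIncision(Enum):
    """Initial incision through the tunica albuginea."""

    LONGITUDINAL = "longitudinal"
    TRANSVERSE = "transverse"

    @property
    def exposure_plane(self) -> PlaneOrientation:
        """Plane of the two cut faces the bivalved testis exposes.

        A longitudinal incision runs along the X axis and opens the
        testis in the X-Y (coronal) plane; a transverse incision opens
        it in the Y-Z (transverse) plane.
        """
        if self is TunicalIncision.LONGITUDINAL:
            return PlaneOrientation.CORONAL
        return PlaneOrientation.TRANSVERSE


# Feasible (tunical, slicing) pairs in conventional method order 1-4.
_METHOD_ORDER: tuple[tuple[TunicalIncision, PlaneOrientation], ...] = (
    (TunicalIncision.LONGITUDINAL, PlaneOrientation.TRANSVERSE),
    (TunicalIncision.LONGITUDINAL, PlaneOrientation.SAGITTAL),
    (TunicalIncision.TRANSVERSE, PlaneOrientation.SAGITTAL),
    (TunicalIncision.TRANSVERSE, PlaneOrientation.CORONAL),
)


@dataclass(frozen=True)
class IncisionStrategy:
    tunical: TunicalIncision
    slicing: PlaneOrientation
    feasible: bool
    method_label: int | None  # 1-4 for feasible strategies, else None

    def describe(self) -> str:
        tag = f"method {self.method_label}" if self.feasible else "infeasible"
        return f"{self.tunical.value} tunical incision, {self.slicing.value} slices ({tag})"


def _is_feasible(tunical: TunicalIncision, slicing: PlaneOrientation) -> bool:
    # Slices parallel to the exposure plane detach from the tunica.
    return slicing is not tunical.exposure_plane


def enumerate_strategies() -> list[IncisionStrategy]:
    """All 6 tunical x slicing combinations; exactly 4 are feasible."""
    out = []
    for tunical in TunicalIncision:
        for slicing in PlaneOrientation:
            feasible = _is_feasible(tunical, slicing)
            label = _METHOD_ORDER.index((tunical, slicing)) + 1 if feasible else None
            out.append(IncisionStrategy(tunical, slicing, feasible, label))
    return out


def feasible_strategies() -> list[IncisionStrategy]:
    """The four feasible strategies ordered by method label."""
    return sorted(
        (s for s in enumerate_strategies() if s.feasible),
        key=lambda s: s.method_label,  # type: ignore[arg-type,return-value]
    )


def strategy_by_label(label: int) -> IncisionStrategy:
    for s in feasible_strategies():
        if s.method_label == label:
            return s
    raise ValueError(f"method label must be 1-4, got {label}")


def bivalve_face_area(testis: TestisEllipsoid, tunical: TunicalIncision) -> float:
    """Area of the two cut faces of the bivalved testis, mm^2.

    Each face is the central section in the exposure plane, so the
    bivalve contributes twice that ellipse area: 2*pi*a*b*l**2 for a
    longitudinal incision, 2*pi*b*c*l**2 for a transverse one.
    """
    p, q = testis.in_plane_ratios(tunical.exposure_plane)
    return 2 * math.pi * p * q * testis.l**2


def total_search_area(
    testis: TestisEllipsoid, strategy: IncisionStrategy
) -> AreaBreakdown:
    """Total searchable area = bivalve faces + serial slice faces."""
    if not strategy.feasible:
        raise InfeasibleStrategyError(
            f"{strategy.describe()}: slices parallel to the bivalve exposure "
            f"plane would be detached from the tunica albuginea and fall apart"
        )
    bivalve = bivalve_face_area(testis, strategy.tunical)
    if testis.strict:
        slices = slice_face_sum_closed(testis, strategy.slicing)
    else:
        slices = slice_face_sum_direct(testis, strategy.slicing)
    return AreaBreakdown(bivalve_face_area=bivalve, slice_face_sum=slices)


def pairwise_difference(
    testis: TestisEllipsoid, s_i: IncisionStrategy, s_j: IncisionStrategy
) -> float:
    """Signed difference total(s_i) - total(s_j), mm^2."""
    return total_search_area(testis, s_i).total - total_search_area(testis, s_j).total


def adjacent_difference_closed(testis: TestisEllipsoid, first_label: int) -> float:
    """Closed-form total-area difference between adjacent methods.

    method 1 - method 2 = 2*c*l**2*(a**2 - b**2) / (3ab) * pi
    method 2 - method 3 = 2*b*l**2*(a - c) * pi
    method 3 - method 4 = 2*a*l**2*(b**2 - c**2) / (3bc) * pi

    All are strictly positive when a > b > c, which is the ranking
    theorem in algebraic form.
    """
    a, b, c = testis.ratios
    l2 = testis.l**2
    if first_label == 1:
        return 2 * c * l2 * (a**2 - b**2) / (3 * a * b) * math.pi
    if first_label == 2:
        return 2 * b * l2 * (a - c) * math.pi
    if first_label == 3:
        return 2 * a * l2 * (b**2 - c**2) / (3 * b * c) * math.pi
    raise ValueError(f"first_label must be 1, 2 or 3, got {first_label}")


@dataclass(frozen=True)
class StrategyComparison:
    """All four feasible strategies evaluated on one testis."""

    testis: TestisEllipsoid
    breakdowns: dict[int, AreaBreakdown]  # method label -> areas
    differences: dict[tuple[int, int], float]  # (i, j) -> total_i - total_j
    order: tuple[int, ...]  # labels by descending total, ties label-ascending
    ties: tuple[frozenset[int], ...]  # groups of labels with equal totals

    @property
    def best_label(self) -> int:
        return self.order[0]


def rank_strategies(testis: TestisEllipsoid, rel_tol: float = 1e-12) -> StrategyComparison:
    """Evaluate and rank the four feasible strategies.

    Ranking is by descending total searchable area; exact ties (which
    arise when a = b or b = c) are broken by ascending method label and
    reported in ``ties``.
    """
    strategies = feasible_strategies()
    breakdowns = {s.method_label: total_search_area(testis, s) for s in strategies}
    labels = sorted(breakdowns)
    differences = {
        (i, j): breakdowns[i].total - breakdowns[j].total
        for i in labels
        for j in labels
        if i != j
    }
    order = tuple(sorted(labels, key=lambda k: (-breakdowns[k].total, k)))

    ties: list[frozenset[int]] = []
    group = [order[0]]
    for k in order[1:]:
        if math.isclose(breakdowns[k].total, breakdowns[group[0]].total, rel_tol=rel_tol):
            group.append(k)
        else:
            if len(group) > 1:
                ties.append(frozenset(group))
            group = [k]
    if len(group) > 1:
        ties.append(frozenset(group))

    return StrategyComparison(
        testis=testis,
        breakdowns=breakdowns,
        differences=differences,
        order=order,
        ties=tuple(ties),
    )


@dataclass(frozen=True)
class Recommendation:
    """Clinical front-end result for physical semi-axis measurements."""

    semi_axes_mm: tuple[float, float, float]  # sorted descending
    slice_width_mm: float
    testis: TestisEllipsoid
    rounding_residuals_mm: tuple[float, float, float]  # axis - ratio*l
    comparison: StrategyComparison
    best: IncisionStrategy
    gain_over_second_pct: float


def recommend(axes_mm: tuple[float, float, float], l_mm: float) -> Recommendation:
    """Rank strategies for a testis measured in mm.

    ``axes_mm`` are the three semi-axis lengths (any order); they are
    sorted descending, divided by the slice width and rounded to the
    nearest integer ratios so the closed forms apply, with the rounding
    residual reported.  The percentage gain of the best method over the
    second best is relative to the second best's total.
    """
    if l_mm <= 0:
        raise ValueError(f"slice width must be positive, got {l_mm}")
    if len(axes_mm) != 3 or any(ax <= 0 for ax in axes_mm):
        raise ValueError(f"need three positive semi-axis lengths, got {axes_mm!r}")
    axes = tuple(sorted((float(ax) for ax in axes_mm), reverse=True))
    if axes[2] <= l_mm:
        raise ValueError(
            f"slice width {l_mm} mm is not smaller than the shortest "
            f"semi-axis {axes[2]} mm; no interior slice is possible"
        )
    ratios = tuple(max(1, round(ax / l_mm)) for ax in axes)
    residuals = tuple(ax - r * l_mm for ax, r in zip(axes, ratios))
    testis = TestisEllipsoid(*ratios, l=l_mm)
    comparison = rank_strategies(testis)
    best = strategy_by_label(comparison.best_label)
    totals = [comparison.breakdowns[k].total for k in comparison.order]
    gain = 100.0 * (totals[0] - totals[1]) / totals[1]
    return Recommendation(
        semi_axes_mm=axes,
        slice_width_mm=l_mm,
        testis=testis,
        rounding_residuals_mm=residuals,
        comparison=comparison,
        best=best,
        gain_over_second_pct=gain,
    )
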