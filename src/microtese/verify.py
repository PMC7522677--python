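"""Self-verification suite: closed forms vs oracles, ranking positivity.

Runs the package's structural invariants on exhaustive integer grids:

* closed-form slice sums vs direct summation (relative 1e-9);
* closed forms vs the implicit-equation quadrature oracle (relative
  1e-4, sampled sections);
* strict total-area ordering method 1 > 2 > 3 > 4 for all a > b > c,
  with the adjacent differences matching their algebraic closed forms;
* the continuum limit: slice-face sum x l -> 2 x ellipsoid volume
  under slice-width refinement, with monotonically shrinking error.

``perturbation`` is a test hook that corrupts the closed-form sums
before comparison, to prove the harness can fail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .geometry import (
    PlaneOrientation,
    TestisEllipsoid,
    ellipsoid_volume,
    half_cross_section_area,
    plane_section_area_quadrature,
    slice_face_sum_closed,
    slice_face_sum_direct,
)
from .strategies import adjacent_difference_closed, rank_strategies

CLOSED_VS_DIRECT_RTOL = 1e-9
QUADRATURE_RTOL = 1e-4


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    detail: str


def _strict_triples(depth: int):
    for a in range(1, depth + 1):
        for b in range(1, a):
            for c in range(1, b):
                yield a, b, c


def _all_triples(depth: int):
    for a in range(1, depth + 1):
        for b in range(1, a + 1):
            for c in range(1, b + 1):
                yield a, b, c


def check_closed_vs_direct(depth: int, perturbation: float = 0.0) -> CheckResult:
    worst = 0.0
    worst_at = ""
    for a, b, c in _all_triples(depth):
        t = TestisEllipsoid(a, b, c, l=1.0)
        for orient in PlaneOrientation:
            closed = slice_face_sum_closed(t, orient) * (1.0 + perturbation)
            direct = slice_face_sum_direct(t, orient)
            rel = abs(closed - direct) / direct
            if rel > worst:
                worst, worst_at = rel, f"({a},{b},{c}) {orient.value}"
    ok = worst <= CLOSED_VS_DIRECT_RTOL
    return CheckResult(
        "closed_vs_direct",
        ok,
        f"max rel err {worst:.3e} at {worst_at} (tol {CLOSED_VS_DIRECT_RTOL:g})",
    )


def check_quadrature(depth: int, resolution: int = 256, perturbation: float = 0.0) -> CheckResult:
    """Sampled sections: quadrature vs 2x the closed-form half-area."""
    worst = 0.0
    worst_at = ""
    for a, b, c in _strict_triples(depth):
        t = TestisEllipsoid(a, b, c, l=1.0)
        for orient in PlaneOrientation:
            r = int(t.ratio_along(orient))
            for idx in {0, r // 2, r - 1}:
                closed = 2 * half_cross_section_area(t, orient, idx) * (1.0 + perturbation)
                quad = plane_section_area_quadrature(t, orient, idx, resolution)
                rel = abs(closed - quad) / closed
                if rel > worst:
                    worst, worst_at = rel, f"({a},{b},{c}) {orient.value} idx={idx}"
    ok = worst <= QUADRATURE_RTOL
    return CheckResult(
        "quadrature_oracle",
        ok,
        f"max rel err {worst:.3e} at {worst_at} (tol {QUADRATURE_RTOL:g})",
    )


def check_ranking(depth: int, perturbation: float = 0.0) -> CheckResult:
    for a, b, c in _strict_triples(depth):
        for l in (1.0, 2.5):
            t = TestisEllipsoid(a, b, c, l=l)
            comp = rank_strategies(t)
            if comp.order != (1, 2, 3, 4) or comp.ties:
                return CheckResult(
                    "ranking_positivity", False, f"order {comp.order} at ({a},{b},{c}), l={l}"
                )
            for first in (1, 2, 3):
                measured = comp.differences[(first, first + 1)]
                closed = adjacent_difference_closed(t, first) * (1.0 + perturbation)
                if closed <= 0 or abs(measured - closed) / closed > CLOSED_VS_DIRECT_RTOL:
                    return CheckResult(
                        "ranking_positivity",
                        False,
                        f"difference {first}-{first+1} mismatch at ({a},{b},{c}), l={l}: "
                        f"measured {measured}, closed {closed}",
                    )
    return CheckResult(
        "ranking_positivity", True, f"order (1,2,3,4) on all strict triples up to a={depth}"
    )


def check_continuum_limit(refinements=(10, 20, 40, 80)) -> CheckResult:
    """Fixed physical testis (A,B,C)=(1, 0.8, 0.6) mm; l = A/a -> 0."""
    A, B, C = 1.0, 0.8, 0.6
    errors = []
    for a in refinements:
        l = A / a
        t = TestisEllipsoid(a, round(B / l), round(C / l), l=l, strict=False)
        target = 2 * ellipsoid_volume(t)
        got = slice_face_sum_direct(t, PlaneOrientation.TRANSVERSE) * l
        errors.append(abs(got - target) / target)
    monotone = all(e2 < e1 for e1, e2 in zip(errors, errors[1:]))
    return CheckResult(
        "continuum_limit",
        monotone and errors[-1] < errors[0],
        "rel errors " + ", ".join(f"{e:.2e}" for e in errors),
    )


def run_all(depth: int = 10, perturbation: float = 0.0) -> list[CheckResult]:
    if depth < 2:
        raise ValueError(f"depth must be >= 2, got {depth}")
    return [
        check_closed_vs_direct(depth, perturbation),
        check_quadrature(min(depth, 5), perturbation=perturbation),
        check_ranking(depth, perturbation),
        check_continuum_limit(),
    ]
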