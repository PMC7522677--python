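"""Reconstructed clinical count tables and a matching synthetic cohort.

The published comparison reports, for each surgical cohort, success
counts by etiology subgroup and (separately) by histopathology — the
joint etiology-by-histopathology assignment of individual patients was
never published.  :func:`reference_cohort` therefore builds a SYNTHETIC
158-patient record list whose etiology and histopathology margins both
match the printed counts exactly (a northwest-corner transport,
applied separately to successes and failures).  Every marginal summary
computed from it — which is all the comparison table uses — equals the
printed table; the individual etiology-histopathology pairings are an
arbitrary feasible choice.
"""

from __future__ import annotations

from .cohort import PatientRecord, SubgroupArm

__all__ = [
    "ETIOLOGY_COUNTS",
    "HISTOPATHOLOGY_COUNTS",
    "reference_cohort",
    "reference_synth_arms",
]

# (successes, n) per etiology subgroup, per cohort.
ETIOLOGY_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "previous": {
        "klinefelter": (1, 8),
        "azfc_deletion": (0, 0),
        "47xyy": (0, 0),
        "post_chemotherapy": (0, 4),
        "cryptorchidism_history": (3, 3),
        "other": (12, 41),
    },
    "new": {
        "klinefelter": (5, 11),
        "azfc_deletion": (1, 2),
        "47xyy": (2, 2),
        "post_chemotherapy": (0, 3),
        "cryptorchidism_history": (6, 7),
        "other": (32, 77),
    },
}

# (successes, n) per histopathology category, per cohort.
HISTOPATHOLOGY_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "previous": {
        "hypospermatogenesis": (13, 24),
        "uniform_maturation_arrest": (0, 2),
        "sertoli_cell_only": (3, 30),
    },
    "new": {
        "hypospermatogenesis": (32, 44),
        "uniform_maturation_arrest": (8, 9),
        "sertoli_cell_only": (6, 49),
    },
}


def _northwest_corner(rows: list[tuple[str, int]], cols: list[tuple[str, int]]):
    """Feasible joint counts matching both margins (greedy transport)."""
    cells: list[tuple[str, str, int]] = []
    i = j = 0
    rows = [list(r) for r in rows]  # type: ignore[assignment]
    cols = [list(c) for c in cols]  # type: ignore[assignment]
    while i < len(rows) and j < len(cols):
        take = min(rows[i][1], cols[j][1])
        if take > 0:
            cells.append((rows[i][0], cols[j][0], take))
        rows[i][1] -= take
        cols[j][1] -= take
        if rows[i][1] == 0:
            i += 1
        if j < len(cols) and cols[j][1] == 0:
            j += 1
    return cells


def reference_cohort() -> list[PatientRecord]:
    """Synthetic 158-patient cohort matching the published count margins."""
    records: list[PatientRecord] = []
    i = 0
    for cohort in ("previous", "new"):
        for outcome in (True, False):
            etio_margin = [
                (label, (s if outcome else n - s))
                for label, (s, n) in ETIOLOGY_COUNTS[cohort].items()
            ]
            histo_margin = [
                (label, (s if outcome else n - s))
                for label, (s, n) in HISTOPATHOLOGY_COUNTS[cohort].items()
            ]
            for etiology, histology, count in _northwest_corner(etio_margin, histo_margin):
                for _ in range(count):
                    i += 1
                    records.append(
                        PatientRecord(
                            id=f"R{i:04d}",
                            cohort=cohort,
                            subgroup=etiology,
                            histopathology=histology,
                            outcome=outcome,
                        )
                    )
    return records


def reference_synth_arms() -> list[SubgroupArm]:
    """Synthesis arms mirroring the published subgroup mix and observed SRRs."""
    arms = []
    for cohort, counts in ETIOLOGY_COUNTS.items():
        for subgroup, (s, n) in counts.items():
            if n > 0:
                arms.append(SubgroupArm(cohort=cohort, subgroup=subgroup, n=n, rate=s / n))
    return arms
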