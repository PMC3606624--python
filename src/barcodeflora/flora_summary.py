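"""Flora-level summaries of likely-source-region calls.

Two denominators matter and are kept explicit throughout:

* ``pct_of_included`` - category shares among all species that passed
  eligibility (the "n included" view);
* ``pct_of_assigned`` - shares among only those with a determinate call
  (atlantic/pacific/both), the extrapolated composition of the flora.

Percentages round half-up, to the nearest integer by default or to one
decimal for checklist-style summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .lsr_inference import (
    ATLANTIC,
    BOTH,
    EXCLUDED,
    LSRCall,
    PACIFIC,
    POSITIVE,
    UNCERTAIN,
)

NEAREST_INTEGER = "nearest_integer"
ONE_DECIMAL = "one_decimal"


class EmptySummaryError(ValueError):
    """No included (or no assigned) species to summarize."""


def round_half_up(x: float, rounding: str = NEAREST_INTEGER) -> float:
    """Round half-way cases away from zero at the configured precision."""
    if rounding == NEAREST_INTEGER:
        return float(int(x + 0.5)) if x >= 0 else -float(int(-x + 0.5))
    if rounding == ONE_DECIMAL:
        return round_half_up(x * 10) / 10
    raise ValueError(f"unknown rounding mode {rounding!r}")


@dataclass
class SummaryTable:
    """Category counts and percentages over a set of LSR calls."""

    basis: str
    counts: dict[str, int]
    n_included: int
    n_excluded: int
    rounding: str = NEAREST_INTEGER
    pct_of_included: dict[str, float] = field(default_factory=dict)
    pct_assigned: float = 0.0
    pct_of_assigned: dict[str, float] = field(default_factory=dict)

    @property
    def n_assigned(self) -> int:
        return sum(self.counts[c] for c in POSITIVE)


def summarize_lsr(
    calls: Sequence[LSRCall],
    basis: str,
    rounding: str = NEAREST_INTEGER,
    n_excluded: int = 0,
) -> SummaryTable:
    """Tabulate calls of one basis into a :class:`SummaryTable`.

    Excluded species never enter a denominator; "both" counts as assigned.
    """
    selected = [c for c in calls if c.basis == basis and c.call != EXCLUDED]
    seen = set()
    for c in selected:
        if c.species in seen:
            raise ValueError(f"duplicate call for species {c.species!r}")
        seen.add(c.species)
    if not selected:
        raise EmptySummaryError("no included species to summarize")
    counts = {cat: 0 for cat in (ATLANTIC, PACIFIC, BOTH, UNCERTAIN)}
    for c in selected:
        counts[c.call] += 1
    n_inc = len(selected)
    n_assigned = sum(counts[c] for c in POSITIVE)
    table = SummaryTable(
        basis=basis,
        counts=counts,
        n_included=n_inc,
        n_excluded=n_excluded,
        rounding=rounding,
    )
    table.pct_of_included = {
        cat: round_half_up(100.0 * counts[cat] / n_inc, rounding) for cat in counts
    }
    table.pct_assigned = round_half_up(100.0 * n_assigned / n_inc, rounding)
    if n_assigned:
        table.pct_of_assigned = {
            cat: round_half_up(100.0 * counts[cat] / n_assigned, rounding)
            for cat in POSITIVE
        }
    return table


def extrapolate_assigned(table: SummaryTable) -> tuple[float, float, float]:
    """Percentages of atlantic/pacific/both among assigned species only
    (the flora-composition extrapolation that drops the uncertain class)."""
    if table.n_assigned == 0:
        raise EmptySummaryError("no assigned species; extrapolation undefined")
    return (
        table.pct_of_assigned[ATLANTIC],
        table.pct_of_assigned[PACIFIC],
        table.pct_of_assigned[BOTH],
    )


@dataclass(frozen=True)
class ChecklistCounts:
    """Distributional classes of a morphology-based regional checklist."""

    atlantic_only: int
    atlantic_and_pacific: int
    pacific_only: int
    arctic_endemic: int

    def __post_init__(self) -> None:
        for f in (
            self.atlantic_only,
            self.atlantic_and_pacific,
            self.pacific_only,
            self.arctic_endemic,
        ):
            if f < 0:
                raise ValueError("checklist counts must be >= 0")


# The classic morphology-based compilation for the Canadian Arctic flora
# (~175 taxa): 80 shared only with the Atlantic, 80 with both oceans, 3 only
# with the Pacific, 12 treated as Arctic endemics.
HISTORICAL_ARCTIC_CHECKLIST = ChecklistCounts(
    atlantic_only=80, atlantic_and_pacific=80, pacific_only=3, arctic_endemic=12
)


def checklist_summary(
    cc: ChecklistCounts,
    exclude_arctic: bool = False,
    rounding: str = ONE_DECIMAL,
) -> dict[str, float]:
    """Percentage composition of a checklist, optionally dropping the Arctic
    endemics from the denominator (source-region rather than distributional
    perspective)."""
    total = cc.atlantic_only + cc.atlantic_and_pacific + cc.pacific_only
    if not exclude_arctic:
        total += cc.arctic_endemic
    if total == 0:
        raise EmptySummaryError("all-zero checklist")
    out = {
        "atlantic_only": round_half_up(100.0 * cc.atlantic_only / total, rounding),
        "shared": round_half_up(100.0 * cc.atlantic_and_pacific / total, rounding),
        "pacific_only": round_half_up(100.0 * cc.pacific_only / total, rounding),
    }
    if not exclude_arctic:
        out["arctic"] = round_half_up(100.0 * cc.arctic_endemic / total, rounding)
    return out


ASSIGNED_ELSEWHERE = "other"


def scenario_analysis(
    table: SummaryTable,
    add_as: Iterable[tuple[str, str]] = (),
    reassign: Iterable[tuple[str, str]] = (),
    rounding: Optional[str] = None,
    region: str = PACIFIC,
    current_calls: Optional[Sequence[LSRCall]] = None,
) -> float:
    """What-if percentage of ``region`` among assigned species.

    ``add_as`` lists species not in the table's denominators (excluded or
    never barcoded) added with a hypothesized region; ``reassign`` moves
    currently uncertain species to a region. A region value of ``"other"``
    places the species in the assigned denominator without crediting the
    queried region (used for "half of these species" scenarios). With empty
    lists this returns the baseline assigned-only share exactly.
    """
    rounding = rounding or table.rounding
    add_as, reassign = list(add_as), list(reassign)
    counts = dict(table.counts)
    uncertain_left = counts[UNCERTAIN]
    known = None
    if current_calls is not None:
        known = {c.species: c.call for c in current_calls}
    for species, target in reassign:
        if known is not None:
            if known.get(species) in POSITIVE:
                raise ValueError(
                    f"{species!r} already has an assigned region; cannot reassign"
                )
        if uncertain_left <= 0:
            raise ValueError("no uncertain species left to reassign")
        uncertain_left -= 1
    counts[UNCERTAIN] = uncertain_left
    n_target = counts.get(region, 0)
    n_assigned = sum(counts[c] for c in POSITIVE)
    n_assigned += len(reassign)
    n_target += sum(1 for _, t in reassign if t == region)
    seen_added = set()
    for species, target in add_as:
        if species in seen_added:
            raise ValueError(f"{species!r} added twice")
        seen_added.add(species)
        n_assigned += 1
        if target == region:
            n_target += 1
    if n_assigned == 0:
        raise EmptySummaryError("no assigned species in scenario")
    return round_half_up(100.0 * n_target / n_assigned, rounding)


def render_summary(table: SummaryTable) -> str:
    """Human-readable report block for one summary table."""
    lines = [
        f"LSR summary ({table.basis} basis)",
        f"  included species : {table.n_included}"
        + (f"  (excluded: {table.n_excluded})" if table.n_excluded else ""),
    ]
    for cat in (ATLANTIC, PACIFIC, BOTH, UNCERTAIN):
        lines.append(
            f"  {cat:<9}: {table.counts[cat]:>3}  ({table.pct_of_included[cat]:g}% of included)"
        )
    lines.append(f"  assigned : {table.n_assigned}  ({table.pct_assigned:g}% of included)")
    if table.pct_of_assigned:
        a, p, b = (
            table.pct_of_assigned[ATLANTIC],
            table.pct_of_assigned[PACIFIC],
            table.pct_of_assigned[BOTH],
        )
        lines.append(f"  among assigned only: atlantic {a:g}% / pacific {p:g}% / both {b:g}%")
    return "\n".join(lines)
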