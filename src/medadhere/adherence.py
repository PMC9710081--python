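"""Dispensing-based adherence metrics: MPR, stockpile-aware PDC, switching.

Two standard measures are computed from pharmacy dispensing records over a
period of days:

* **MPR** (medication possession ratio) sums days' supply dispensed in the
  period indiscriminately, so overlapping refills can push it above 100%.
* **PDC** (proportion of days covered) counts the days the patient can
  reliably hold medication.  Overlapping supply is *shifted* forward — an
  early refill starts covering only when the previous supply runs out — so
  surplus ("stockpile") closes later gaps but never back-fills a gap that
  has already elapsed, and PDC is bounded by 100%.

Medication *switching* within a therapeutic class (e.g. simvastatin to
atorvastatin) is handled by computing PDC per drug independently and, per
quarter, summing across the class's drugs with an upper bound of 100%.

All intervals are half-open ``[start, end)`` in integer days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence


@dataclass(frozen=True)
class Period:
    """Half-open day interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty period [{self.start}, {self.end})")

    @property
    def days(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CoverageInterval:
    """Maximal run of covered days after stockpile shifting."""

    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("empty coverage interval")


@dataclass(frozen=True)
class MPRResult:
    period: Period
    supply_days: int

    @property
    def mpr(self) -> float:
        return 100.0 * self.supply_days / self.period.days


@dataclass(frozen=True)
class PDCResult:
    period: Period
    covered_days: int

    @property
    def pdc(self) -> float:
        return 100.0 * self.covered_days / self.period.days


@dataclass(frozen=True)
class QuarterlyClassPDC:
    """Per-quarter class-level PDC: per-drug values and the capped sum."""

    quarter_index: int
    per_drug: Mapping[str, float]

    @property
    def combined(self) -> float:
        return min(100.0, sum(self.per_drug.values()))


def build_coverage(
    events: Sequence, carry_in_days: int = 0
) -> list[CoverageInterval]:
    """Build shifted coverage intervals for one patient and one drug.

    Events are processed in date order maintaining a supply frontier: each
    dispense starts covering at ``max(dispense_date, frontier)`` and runs
    for its days' supply, then the frontier advances to that end.  Days
    before a dispense on which the patient held no supply stay uncovered.

    Parameters
    ----------
    events : sequence of DispenseEvent-like
        Objects with ``dispense_date`` and ``days_supply``, sorted
        ascending by date.  ``(date, supply)`` tuples are also accepted.
    carry_in_days : int
        Stockpile (days of supply) already on hand at the first event,
        e.g. surplus carried in from dispenses before an analysis window.
    """
    if carry_in_days < 0:
        raise ValueError("carry_in_days must be non-negative")
    pairs = [_as_pair(e) for e in events]
    for (d, s) in pairs:
        if s <= 0:
            raise ValueError(f"non-positive days_supply {s}")
    for a, b in zip(pairs, pairs[1:]):
        if b[0] < a[0]:
            raise ValueError("events must be sorted ascending by dispense_date")
    if not pairs:
        return []
    if carry_in_days > 0:
        # carried-in stockpile behaves like a virtual dispense at the first date
        pairs.insert(0, (pairs[0][0], carry_in_days))

    intervals: list[CoverageInterval] = []
    frontier: Optional[int] = None
    for date, supply in pairs:
        start = date if frontier is None else max(date, frontier)
        end = start + supply
        if intervals and start == intervals[-1].end:
            intervals[-1] = CoverageInterval(intervals[-1].start, end)
        else:
            intervals.append(CoverageInterval(start, end))
        frontier = end
    return intervals


def _as_pair(event) -> tuple[int, int]:
    if isinstance(event, tuple):
        return int(event[0]), int(event[1])
    return int(event.dispense_date), int(event.days_supply)


def mpr(events: Iterable, period: Period) -> MPRResult:
    """Medication possession ratio over ``period``.

    Sums the days' supply of every dispense whose date falls inside the
    period, with no regard for overlaps or gaps and no cap, so the value
    may exceed 100%.
    """
    supply = sum(
        s for (d, s) in (_as_pair(e) for e in events) if period.start <= d < period.end
    )
    return MPRResult(period=period, supply_days=supply)


def pdc(coverage: Sequence[CoverageInterval], period: Period) -> PDCResult:
    """Proportion of days covered: overlap of shifted coverage with ``period``."""
    covered = 0
    for iv in coverage:
        covered += max(0, min(iv.end, period.end) - max(iv.start, period.start))
    return PDCResult(period=period, covered_days=covered)


def quarterly_class_pdc(
    events: Iterable,
    quarters: Sequence[Period],
    carry_in_days: Optional[Mapping[str, int]] = None,
) -> list[QuarterlyClassPDC]:
    """Quarterly class-level PDC for one patient across switching drugs.

    Coverage is built independently per ``drug_code`` (stockpile shifting
    never crosses drugs), each drug's PDC is computed per quarter, and the
    per-quarter values are summed with an upper bound of 100%.

    ``events`` must carry ``drug_code``; they may span any date range — each
    drug's full history participates in shifting, and quarterly values come
    from intersecting the resulting coverage with each quarter.
    """
    carry_in_days = carry_in_days or {}
    by_drug: dict[str, list] = {}
    for e in events:
        by_drug.setdefault(e.drug_code, []).append(e)
    coverage = {
        drug: build_coverage(
            sorted(evs, key=lambda e: e.dispense_date),
            carry_in_days.get(drug, 0),
        )
        for drug, evs in by_drug.items()
    }
    out = []
    for qi, q in enumerate(quarters):
        per_drug = {drug: pdc(cov, q).pdc for drug, cov in coverage.items()}
        out.append(QuarterlyClassPDC(quarter_index=qi, per_drug=per_drug))
    return out


def adherence_label(ll_pdc: Sequence[float]) -> int:
    """Binary adherence label from prediction-window quarterly class PDC.

    Label 1 (adherent) iff the mean quarterly value is >= 80%, else 0.
    """
    values = list(ll_pdc)
    if not values:
        raise ValueError("adherence_label requires at least one quarter")
    return int(sum(values) / len(values) >= 80.0)
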