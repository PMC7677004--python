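"""Coverage statistics: per-primer counts, pair percentages, per-genus
matrices, and the closed-form PCR amplification-bias factor.

Percentages are reported to one decimal with half-up rounding, as in the
published coverage tables; raw counts are always retained so that exact
conservation checks (genus cells vs. pair totals) remain possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import pandas as pd

from .pcr import Mode, extract_amplicon
from .primers import PrimerPool, find_sites
from .reference import ReferenceDatabase

UNASSIGNED_GENUS = "(unassigned)"


class CoverageError(ValueError):
    pass


def round_percent(matched: int, total: int) -> float:
    """matched/total as a percentage, half-up to 1 decimal."""
    if total <= 0:
        raise CoverageError("total must be positive")
    pct = Decimal(matched) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CoverageReport:
    subject: str
    approach: str  # plain | pessimistic | optimistic | single-primer
    matched_count: int
    database_size: int

    def __post_init__(self) -> None:
        if not (0 <= self.matched_count <= self.database_size):
            raise CoverageError(
                f"{self.subject}: matched_count {self.matched_count} outside "
                f"[0, {self.database_size}]"
            )

    @property
    def percent(self) -> float:
        return round_percent(self.matched_count, self.database_size)


def primer_coverage(db: ReferenceDatabase, pool: PrimerPool) -> CoverageReport:
    """Fraction of database records with at least one exact site for a pool."""
    if len(db) == 0:
        raise CoverageError("empty database")
    matched = sum(1 for rec in db if find_sites(rec, pool))
    return CoverageReport(pool.name, "single-primer", matched, len(db))


def pair_coverage(
    db: ReferenceDatabase,
    fwd: PrimerPool,
    rev: PrimerPool,
    approach: Mode = "plain",
    truncation_slack: int = 100,
) -> CoverageReport:
    """Fraction of records amplified by a primer pair under one accounting
    mode (``assumed_amplified`` counts under ``optimistic``)."""
    if len(db) == 0:
        raise CoverageError("empty database")
    matched = sum(
        1
        for rec in db
        if extract_amplicon(rec, fwd, rev, approach, truncation_slack).counted
    )
    return CoverageReport(f"{fwd.name}-{rev.name}", approach, matched, len(db))


@dataclass
class GenusCoverageMatrix:
    """Per-genus coverage for a set of primer pairs.

    ``counts`` holds (amplified, total) integer pairs; ``percent`` derives
    the familiar heatmap cells.  Records without a genus annotation are
    aggregated under ``(unassigned)`` rather than dropped, so column
    totals are conserved.
    """

    counts: pd.DataFrame  # MultiIndex columns (pair, {"amplified","total"})

    @property
    def genera(self) -> list[str]:
        return list(self.counts.index)

    @property
    def pairs(self) -> list[str]:
        return list(self.counts.columns.levels[0])

    def percent(self) -> pd.DataFrame:
        amp = self.counts.xs("amplified", axis=1, level=1)
        tot = self.counts.xs("total", axis=1, level=1)
        out = amp.astype(float).copy()
        for pair in amp.columns:
            out[pair] = [
                round_percent(int(a), int(t)) for a, t in zip(amp[pair], tot[pair])
            ]
        return out

    def column_matched_count(self, pair: str) -> int:
        return int(self.counts[(pair, "amplified")].sum())


def genus_coverage_matrix(
    db: ReferenceDatabase,
    pairs: list[tuple[PrimerPool, PrimerPool, Mode]],
    truncation_slack: int = 100,
) -> GenusCoverageMatrix:
    """Per-genus, per-pair coverage matrix (heatmap-shaped)."""
    if len(db) == 0:
        raise CoverageError("empty database")
    if not pairs:
        raise CoverageError("pair list is empty")

    genera: list[str] = []
    for rec in db:
        g = rec.lineage.genus or UNASSIGNED_GENUS
        if g not in genera:
            genera.append(g)

    columns: dict[tuple[str, str], list[int]] = {}
    for fwd, rev, mode in pairs:
        label = f"{fwd.name}-{rev.name}"
        amplified = {g: 0 for g in genera}
        total = {g: 0 for g in genera}
        for rec in db:
            g = rec.lineage.genus or UNASSIGNED_GENUS
            total[g] += 1
            if extract_amplicon(rec, fwd, rev, mode, truncation_slack).counted:
                amplified[g] += 1
        columns[(label, "amplified")] = [amplified[g] for g in genera]
        columns[(label, "total")] = [total[g] for g in genera]

    frame = pd.DataFrame(columns, index=pd.Index(genera, name="genus"))
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["pair", "count"])
    return GenusCoverageMatrix(frame)


def amplification_bias(efficiency: float, cycles: int) -> float:
    """Fold-underrepresentation of a template amplified at sub-perfect
    per-cycle efficiency, relative to one amplified perfectly.

    After ``cycles`` rounds of PCR, a template copied ``efficiency``-fold
    per cycle ends up (2/efficiency)^cycles less abundant than a template
    doubling every cycle.  At efficiency 1.9 and 30 cycles this is ~4.66,
    i.e. the template appears about 5 times less abundant.
    """
    if not (1 < efficiency <= 2):
        raise CoverageError(f"efficiency must be in (1, 2], got {efficiency}")
    if cycles < 0 or int(cycles) != cycles:
        raise CoverageError(f"cycles must be a nonnegative integer, got {cycles}")
    return (2.0 / efficiency) ** cycles


def coverage_table(reports: list[CoverageReport]) -> pd.DataFrame:
    """Tabulate reports in the published layout (counts + percent)."""
    return pd.DataFrame(
        {
            "subject": [r.subject for r in reports],
            "approach": [r.approach for r in reports],
            "matched_count": [r.matched_count for r in reports],
            "database_size": [r.database_size for r in reports],
            "percent": [r.percent for r in reports],
        }
    )
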