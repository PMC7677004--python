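"""Degenerate primers, primer pools, and exact binding-site search.

Primers are stored 5'->3' as IUPAC strings.  A *pool* is one or more
primers of the same orientation used as a single reagent (e.g. the
six-variant 27f pool).  Site search is exact and full-length: a reference
sequence matches a primer only where every template base is compatible
with the corresponding primer code, with no mismatches and no partial
overlap at the sequence ends.  Reverse-orientation primers are searched as
their reverse complement on the forward-oriented template, and all
coordinates are 0-based half-open on that forward strand.

A template ambiguity code is considered compatible with a primer code only
when the template code's nucleotide set is a subset of the primer code's
set (so a template ``N`` matches only a primer ``N``); this keeps
low-quality reference bases from inflating coverage.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from importlib import resources
from math import prod
from pathlib import Path
from typing import Optional

from Bio.Seq import Seq

from .reference import ReferenceRecord

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


class PrimerError(ValueError):
    """Raised for invalid primer definitions or sequences."""


def _validate_iupac(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in IUPAC_SETS:
            raise PrimerError(f"invalid IUPAC character {ch!r} at position {i} in {what}")
    return seq


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (an involution)."""
    if not isinstance(seq, str):
        raise PrimerError("sequence must be a string")
    _validate_iupac(seq)
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class DegeneratePrimer:
    """A single (possibly degenerate) primer, 5'->3'.

    ``expected_position`` is the approximate E. coli 16S coordinate of the
    binding locus (the number in names like "27f" or "534r"); it is used
    only by the 5'-truncation heuristic.
    """

    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"
    expected_position: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PrimerError(f"primer {self.name!r}: empty sequence")
        object.__setattr__(self, "sequence", _validate_iupac(self.sequence, f"primer {self.name!r}"))
        if self.orientation not in ("forward", "reverse"):
            raise PrimerError(
                f"primer {self.name!r}: orientation must be forward/reverse, "
                f"got {self.orientation!r}"
            )

    @property
    def degeneracy(self) -> int:
        """Number of concrete sequences the primer represents."""
        return prod(len(IUPAC_SETS[ch]) for ch in self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def expand_degenerate(primer: DegeneratePrimer | str) -> set[str]:
    """Enumerate every concrete A/C/G/T sequence consistent with the primer."""
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else _validate_iupac(primer)
    choices = [sorted(IUPAC_SETS[ch]) for ch in seq]
    return {"".join(combo) for combo in itertools.product(*choices)}


@dataclass(frozen=True)
class PrimerPool:
    """One or more primers of identical orientation used as one reagent."""

    name: str
    members: tuple[DegeneratePrimer, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise PrimerError(f"pool {self.name!r}: no members")
        orientations = {m.orientation for m in self.members}
        if len(orientations) != 1:
            raise PrimerError(f"pool {self.name!r}: mixed orientations {orientations}")

    @property
    def orientation(self) -> str:
        return self.members[0].orientation

    @property
    def expected_position(self) -> Optional[int]:
        for m in self.members:
            if m.expected_position is not None:
                return m.expected_position
        return None

    @classmethod
    def single(
        cls,
        name: str,
        sequence: str,
        orientation: str,
        expected_position: Optional[int] = None,
    ) -> "PrimerPool":
        return cls(name, (DegeneratePrimer(name, sequence, orientation, expected_position),))


@dataclass(frozen=True)
class BindingSite:
    """An exact full-length primer match on the forward-oriented template."""

    record_id: str
    start: int
    end: int
    matched_variant: str
    primer_name: str
    orientation: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise PrimerError(f"bad site coordinates [{self.start}, {self.end})")


def _template_class(primer_code: str) -> str:
    """Regex character class of template codes compatible with one primer code."""
    allowed = IUPAC_SETS[primer_code]
    chars = [t for t, tset in IUPAC_SETS.items() if tset <= allowed]
    return "[" + "".join(sorted(chars)) + "]"


def _search_pattern(search_seq: str) -> re.Pattern[str]:
    # lookahead so overlapping occurrences (distinct starts) are all found
    body = "".join(_template_class(ch) for ch in search_seq)
    return re.compile(f"(?=({body}))")


def find_sites(record: ReferenceRecord, pool: PrimerPool) -> list[BindingSite]:
    """All exact full-length occurrences of any pool member on a record.

    Reverse pools are searched as the reverse complement of each member.
    One site is reported per distinct start position, sorted by start, so
    the result does not depend on pool member order.
    """
    template = record.sequence
    by_start: dict[int, BindingSite] = {}
    for member in pool.members:
        search_seq = (
            member.sequence
            if member.orientation == "forward"
            else reverse_complement(member.sequence)
        )
        for m in _search_pattern(search_seq).finditer(template):
            start = m.start()
            if start not in by_start:
                by_start[start] = BindingSite(
                    record_id=record.id,
                    start=start,
                    end=start + len(search_seq),
                    matched_variant=m.group(1),
                    primer_name=pool.name,
                    orientation=member.orientation,
                )
    return [by_start[s] for s in sorted(by_start)]


def find_sites_by_expansion(record: ReferenceRecord, pool: PrimerPool) -> list[BindingSite]:
    """Alternation-over-expanded-variants search; agrees with
    :func:`find_sites` on unambiguous (A/C/G/T-only) templates and is kept
    as an internal cross-check of the character-class scan."""
    template = record.sequence
    by_start: dict[int, BindingSite] = {}
    for member in pool.members:
        search_seq = (
            member.sequence
            if member.orientation == "forward"
            else reverse_complement(member.sequence)
        )
        for variant in sorted(expand_degenerate(search_seq)):
            start = template.find(variant)
            while start != -1:
                if start not in by_start:
                    by_start[start] = BindingSite(
                        record_id=record.id,
                        start=start,
                        end=start + len(variant),
                        matched_variant=variant,
                        primer_name=pool.name,
                        orientation=member.orientation,
                    )
                start = template.find(variant, start + 1)
    return [by_start[s] for s in sorted(by_start)]


def load_primer_config(path: str | Path) -> dict[str, PrimerPool]:
    """Read a primer config TSV into pools keyed by name.

    Columns: name, orientation, sequence, expected_position (blank allowed).
    Pools are expressed as repeated rows sharing a name.
    """
    rows: dict[str, list[DegeneratePrimer]] = {}
    with open(path) as fh:
        header: Optional[list[str]] = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if header is None and parts[0].lower() == "name":
                header = parts
                continue
            name, orientation, sequence = parts[0], parts[1].lower(), parts[2]
            pos = int(parts[3]) if len(parts) > 3 and parts[3] else None
            rows.setdefault(name, []).append(
                DegeneratePrimer(name, sequence, orientation, pos)
            )
    return {name: PrimerPool(name, tuple(members)) for name, members in rows.items()}


def builtin_pools() -> dict[str, PrimerPool]:
    """The shipped primer config: the commonly used vaginal-microbiome
    primer pairs (27f simple and pool, 319f, 341f, 357f, 515f, 967f;
    338r, 515r, 534r, 805r, 806r, 907r, 926r, 1061r) plus the
    extended-degeneracy 515r/534r variants that add Chlamydia coverage."""
    with resources.as_file(resources.files("ampliscan") / "data" / "primers.tsv") as p:
        return load_primer_config(p)
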