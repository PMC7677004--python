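"""Taxonomically annotated 16S reference databases.

A reference database pairs a FASTA file of 16S rRNA gene sequences with a
tab-separated taxonomy table mapping each record id to a ranked lineage
(SILVA-style seven ranks: domain, phylum, class, order, family, genus,
species).  Because public 16S collections are frequently incomplete at the
5' end of the gene — which matters when judging whether a 27f-position
primer could bind — each record additionally carries a tri-state
5'-completeness flag (``complete`` / ``truncated`` / ``unknown``) read from
an optional third taxonomy column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus", "species")
N_RANKS = len(RANK_NAMES)

# Full IUPAC nucleotide alphabet; sequences are normalised to upper case
# and U -> T on read, so this is the post-normalisation alphabet.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

FivePrime = str  # "complete" | "truncated" | "unknown"
_FIVE_PRIME_STATES = ("complete", "truncated", "unknown")


class ReferenceDBError(ValueError):
    """Raised for malformed reference databases or taxonomy tables."""


@dataclass(frozen=True)
class Lineage:
    """Ranked seven-level lineage; a suffix of ranks may be unannotated.

    The genus label is a single token and the species label holds the
    epithet only (a leading repeat of the genus token is stripped on
    construction, so ``Lactobacillus;Lactobacillus crispatus`` and
    ``Lactobacillus;crispatus`` are the same lineage).
    """

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != N_RANKS:
            raise ReferenceDBError(
                f"lineage must have exactly {N_RANKS} ranks, got {len(self.ranks)}"
            )
        seen_empty = False
        for label in self.ranks:
            if label == "":
                seen_empty = True
            elif seen_empty:
                raise ReferenceDBError(
                    f"lineage has a filled rank after an empty one: {self.ranks!r}"
                )
        genus, species = self.ranks[5], self.ranks[6]
        if genus and len(genus.split()) != 1:
            raise ReferenceDBError(f"genus label must be a single token: {genus!r}")
        if genus and species.startswith(genus + " "):
            object.__setattr__(
                self, "ranks", self.ranks[:6] + (species[len(genus) + 1 :],)
            )

    @property
    def domain(self) -> str:
        return self.ranks[0]

    @property
    def family(self) -> str:
        return self.ranks[4]

    @property
    def genus(self) -> str:
        return self.ranks[5]

    @property
    def species(self) -> str:
        return self.ranks[6]

    @property
    def depth(self) -> int:
        """Number of filled ranks (0-7)."""
        return sum(1 for r in self.ranks if r)

    def truncated_to(self, depth: int) -> "Lineage":
        """Copy keeping only the first *depth* ranks."""
        return Lineage(self.ranks[:depth] + ("",) * (N_RANKS - depth))

    def __str__(self) -> str:
        return ";".join(self.ranks).rstrip(";")


EMPTY_LINEAGE = Lineage(("",) * N_RANKS)


def parse_lineage(text: str, delimiter: str = ";") -> Lineage:
    """Parse a delimited lineage string into exactly seven ranks.

    Missing trailing ranks are padded with empties; surrounding whitespace
    is stripped from each label.  More than seven fields is a hard error.
    """
    fields = [f.strip() for f in text.split(delimiter)] if text.strip() else []
    if len(fields) > N_RANKS:
        raise ReferenceDBError(
            f"lineage string has {len(fields)} fields, at most {N_RANKS} allowed: {text!r}"
        )
    fields += [""] * (N_RANKS - len(fields))
    return Lineage(tuple(fields))


@dataclass(frozen=True)
class ReferenceRecord:
    """One 16S sequence with its ranked lineage and 5'-completeness flag."""

    id: str
    sequence: str
    lineage: Lineage
    five_prime_complete: FivePrime = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ReferenceDBError("record id must be nonempty")
        if not self.sequence:
            raise ReferenceDBError(f"record {self.id!r}: sequence must be nonempty")
        bad = set(self.sequence) - IUPAC_ALPHABET
        if bad:
            raise ReferenceDBError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        if self.five_prime_complete not in _FIVE_PRIME_STATES:
            raise ReferenceDBError(
                f"record {self.id!r}: five_prime_complete must be one of "
                f"{_FIVE_PRIME_STATES}, got {self.five_prime_complete!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceDatabase:
    """Ordered collection of reference records with unique ids."""

    records: list[ReferenceRecord]
    source_label: str = ""
    _by_id: dict[str, ReferenceRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for rec in self.records:
            if rec.id in self._by_id:
                raise ReferenceDBError(f"duplicate record id {rec.id!r}")
            self._by_id[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def __getitem__(self, record_id: str) -> ReferenceRecord:
        return self._by_id[record_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceDatabase):
            return NotImplemented
        return self.records == other.records

    def genera(self) -> list[str]:
        """Distinct genus labels in first-seen order (empty label excluded)."""
        seen: dict[str, None] = {}
        for rec in self.records:
            if rec.lineage.genus:
                seen.setdefault(rec.lineage.genus, None)
        return list(seen)


@dataclass(frozen=True)
class TaxonEntry:
    name: str
    rank: Optional[str] = None  # one of RANK_NAMES, or None for any rank
    note: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ReferenceDBError("taxon name must be nonempty")
        if self.rank is not None and self.rank not in RANK_NAMES:
            raise ReferenceDBError(f"unknown rank {self.rank!r}")


@dataclass
class TaxonList:
    """Curated list of taxa (e.g. the vaginotropic species list)."""

    entries: list[TaxonEntry]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            key = e.name.casefold()
            if key in seen:
                raise ReferenceDBError(f"duplicate taxon name {e.name!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)


def _normalise_sequence(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_reference_db(
    fasta_path: str | Path,
    taxonomy_path: str | Path,
    source_label: str = "",
) -> ReferenceDatabase:
    """Read a FASTA + TSV-taxonomy pair into a :class:`ReferenceDatabase`.

    The taxonomy file is tab-separated with two mandatory columns
    (record id, lineage string) and an optional third column holding the
    5'-completeness flag (``complete``/``truncated``).  Every FASTA id must
    appear in the taxonomy table; duplicates on either side are hard errors.
    """
    fasta_path, taxonomy_path = Path(fasta_path), Path(taxonomy_path)
    taxonomy: dict[str, tuple[Lineage, FivePrime]] = {}
    with open(taxonomy_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ReferenceDBError(
                    f"{taxonomy_path}:{lineno}: expected at least 2 tab-separated columns"
                )
            rec_id = parts[0].strip()
            if rec_id in taxonomy:
                raise ReferenceDBError(f"duplicate id {rec_id!r} in taxonomy table")
            flag: FivePrime = "unknown"
            if len(parts) >= 3 and parts[2].strip():
                flag = parts[2].strip().lower()
                if flag not in ("complete", "truncated"):
                    raise ReferenceDBError(
                        f"{taxonomy_path}:{lineno}: bad five_prime_complete value {parts[2]!r}"
                    )
            taxonomy[rec_id] = (parse_lineage(parts[1]), flag)
    if not taxonomy:
        raise ReferenceDBError(f"taxonomy file {taxonomy_path} is empty")

    records: list[ReferenceRecord] = []
    seen_ids: set[str] = set()
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        if seq_rec.id in seen_ids:
            raise ReferenceDBError(f"duplicate id {seq_rec.id!r} in FASTA")
        seen_ids.add(seq_rec.id)
        if seq_rec.id not in taxonomy:
            raise ReferenceDBError(
                f"FASTA id {seq_rec.id!r} missing from taxonomy table"
            )
        lineage, flag = taxonomy[seq_rec.id]
        records.append(
            ReferenceRecord(
                id=seq_rec.id,
                sequence=_normalise_sequence(str(seq_rec.seq)),
                lineage=lineage,
                five_prime_complete=flag,
            )
        )
    if not records:
        raise ReferenceDBError(f"FASTA file {fasta_path} contains no records")
    return ReferenceDatabase(records, source_label=source_label or fasta_path.name)


def write_reference_db(
    db: ReferenceDatabase, fasta_path: str | Path, taxonomy_path: str | Path
) -> None:
    """Write FASTA + taxonomy TSV such that re-reading round-trips exactly."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in db
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    with open(taxonomy_path, "w") as fh:
        for rec in db:
            flag = "" if rec.five_prime_complete == "unknown" else rec.five_prime_complete
            fh.write(f"{rec.id}\t{';'.join(rec.lineage.ranks)}\t{flag}\n")


def read_taxon_list(path: str | Path) -> TaxonList:
    """Read a taxon list TSV: name, optional rank, optional provenance note."""
    entries: list[TaxonEntry] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            name = parts[0].strip()
            rank = parts[1].strip().lower() or None if len(parts) > 1 else None
            note = parts[2].strip() if len(parts) > 2 else ""
            entries.append(TaxonEntry(name=name, rank=rank, note=note))
    return TaxonList(entries)


def _entry_matches(entry: TaxonEntry, lineage: Lineage) -> bool:
    target = entry.name.casefold()
    if entry.rank is not None:
        idx = RANK_NAMES.index(entry.rank)
        labels = [lineage.ranks[idx]]
        if entry.rank == "species" and lineage.genus:
            labels.append(f"{lineage.genus} {lineage.species}")
    else:
        labels = list(lineage.ranks)
        if lineage.genus and lineage.species:
            labels.append(f"{lineage.genus} {lineage.species}")
    return any(label.casefold() == target for label in labels if label)


def subset_by_taxa(db: ReferenceDatabase, taxa: TaxonList) -> ReferenceDatabase:
    """Keep records whose lineage contains any listed taxon at its stated rank.

    Binomial names ("Gardnerella vaginalis") match at species level even
    though species labels store the epithet alone.  Input order is
    preserved; an empty result is a warning, not an error.
    """
    if not taxa.entries:
        raise ReferenceDBError("taxon list is empty")
    kept = [
        rec
        for rec in db
        if any(_entry_matches(e, rec.lineage) for e in taxa.entries)
    ]
    if not kept:
        warnings.warn("subset_by_taxa: no records matched the taxon list")
    return ReferenceDatabase(kept, source_label=db.source_label)
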