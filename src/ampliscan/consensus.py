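"""Paired-read consensus taxonomy and accuracy scoring.

When forward and reverse reads of an unmergeable amplicon are annotated
independently, the two annotations must be reconciled.  Three rules apply:

(i)   if any rank where both annotations are filled disagrees, the result
      is truncated to the lowest common ancestor (the deepest rank above
      the first disagreement);
(ii)  if one annotation is a prefix-compatible extension of the other, the
      more detailed one is kept (an empty rank conflicts with nothing);
(iii) at species level, annotations may carry a *set* of candidate
      epithets ("Lactobacillus crispatus/gasseri/jensenii"); when both
      reads carry candidate sets under an agreeing genus, the intersection
      is kept.  An empty intersection is treated as a species-level
      disagreement and falls back to the genus-level annotation.

The consensus is commutative and idempotent.  Scoring against a known
truth lineage produces per-rank verdicts (correct / incorrect /
unannotated, plus an "ambiguous" verdict for a non-singleton candidate set
containing the true epithet) and aggregates into per-rank accuracy
summaries of the kind shown in primer-comparison bar plots.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .reference import Lineage, N_RANKS, RANK_NAMES

GENUS_IDX = 5
SPECIES_IDX = 6

Verdict = str  # "correct" | "incorrect" | "unannotated" | "ambiguous"


class ConsensusError(ValueError):
    pass


@dataclass(frozen=True)
class RankedAnnotation:
    """A ranked lineage, optionally with a set of candidate species epithets.

    A singleton candidate set is normalised to a filled species rank, so
    two representations of the same annotation compare equal.  A candidate
    set requires a filled genus and an empty species rank.
    """

    lineage: Lineage
    species_candidates: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        cands = self.species_candidates
        if cands is not None:
            if not isinstance(cands, frozenset):
                cands = frozenset(cands)
                object.__setattr__(self, "species_candidates", cands)
            if not cands:
                raise ConsensusError("species_candidates must be nonempty when present")
            if not self.lineage.genus:
                raise ConsensusError("species_candidates require a filled genus rank")
            if self.lineage.species:
                raise ConsensusError(
                    "species_candidates and a filled species rank are mutually exclusive"
                )
            if len(cands) == 1:
                (epithet,) = cands
                object.__setattr__(
                    self,
                    "lineage",
                    Lineage(self.lineage.ranks[:SPECIES_IDX] + (epithet,)),
                )
                object.__setattr__(self, "species_candidates", None)

    @property
    def depth(self) -> int:
        """Filled-rank depth in [0, 7]; a (non-singleton) candidate set
        counts as genus depth, 6."""
        return self.lineage.depth

    def _species_set(self) -> Optional[frozenset[str]]:
        if self.species_candidates is not None:
            return self.species_candidates
        if self.lineage.species:
            return frozenset({self.lineage.species})
        return None

    def __str__(self) -> str:
        if self.species_candidates is None:
            return str(self.lineage)
        base = str(self.lineage)
        return f"{base};{'/'.join(sorted(self.species_candidates))}"


def parse_annotation(text: str, delimiter: str = ";") -> RankedAnnotation:
    """Parse a lineage string whose species field may be a candidate set.

    The species field accepts both "epi1/epi2" and the field notation
    "Genus epi1/epi2"; a leading repeat of the genus token is stripped.
    """
    fields = [f.strip() for f in text.split(delimiter)] if text.strip() else []
    if len(fields) > N_RANKS:
        raise ConsensusError(f"annotation has more than {N_RANKS} fields: {text!r}")
    fields += [""] * (N_RANKS - len(fields))
    species_field = fields[SPECIES_IDX]
    genus = fields[GENUS_IDX]
    if genus and species_field.startswith(genus + " "):
        species_field = species_field[len(genus) + 1 :]
    if "/" in species_field:
        cands = frozenset(e for e in species_field.split("/") if e)
        return RankedAnnotation(
            Lineage(tuple(fields[:SPECIES_IDX]) + ("",)), species_candidates=cands
        )
    return RankedAnnotation(Lineage(tuple(fields[:SPECIES_IDX]) + (species_field,)))


def annotation_depth(a: RankedAnnotation) -> int:
    """Number of filled ranks; genus + multi-species candidates -> 6,
    a singleton candidate set -> 7 (it *is* a species annotation)."""
    return a.depth


def consensus_annotation(a: RankedAnnotation, b: RankedAnnotation) -> RankedAnnotation:
    """Reconcile two read annotations by the three-rule scheme above."""
    ranks: list[str] = []
    for idx in range(GENUS_IDX + 1):  # domain .. genus
        x, y = a.lineage.ranks[idx], b.lineage.ranks[idx]
        if x and y:
            if x != y:  # rule (i): truncate to LCA
                return RankedAnnotation(
                    Lineage(tuple(ranks) + ("",) * (N_RANKS - idx))
                )
            ranks.append(x)
        else:  # rule (ii): empty conflicts with nothing
            ranks.append(x or y)

    sa, sb = a._species_set(), b._species_set()
    base = tuple(ranks)
    if sa is None and sb is None:
        return RankedAnnotation(Lineage(base + ("",)))
    if sa is None or sb is None:
        chosen = sa if sb is None else sb
        return RankedAnnotation(Lineage(base + ("",)), species_candidates=chosen)
    inter = sa & sb  # rule (iii)
    if not inter:  # null intersection: species-level disagreement -> genus
        return RankedAnnotation(Lineage(base + ("",)))
    return RankedAnnotation(Lineage(base + ("",)), species_candidates=inter)


def score_against_truth(pred: RankedAnnotation, truth: Lineage) -> tuple[Verdict, ...]:
    """Per-rank verdicts of an annotation against a fully specified truth.

    Species with a candidate set: "correct" only when the set is a
    singleton containing the true epithet (normalised at construction to a
    filled rank); a larger set containing the truth scores "ambiguous";
    a set excluding the truth scores "incorrect".
    """
    if truth.depth != N_RANKS:
        raise ConsensusError("truth lineage must be fully specified to species")
    verdicts: list[Verdict] = []
    for idx in range(GENUS_IDX + 1):
        label = pred.lineage.ranks[idx]
        if not label:
            verdicts.append("unannotated")
        elif label == truth.ranks[idx]:
            verdicts.append("correct")
        else:
            verdicts.append("incorrect")
    cands = pred.species_candidates
    if cands is not None:
        verdicts.append("ambiguous" if truth.species in cands else "incorrect")
    elif not pred.lineage.species:
        verdicts.append("unannotated")
    elif pred.lineage.species == truth.species:
        verdicts.append("correct")
    else:
        verdicts.append("incorrect")
    return tuple(verdicts)


@dataclass
class AccuracySummary:
    """Per-rank verdict counts plus a deepest-correct-rank histogram.

    ``per_rank[rank][verdict]`` counts scored items; ``deepest_correct``
    maps depth d (0-7) to the number of items whose annotation is correct
    down to exactly d ranks (0 = not even the domain is correct).
    """

    per_rank: dict[str, Counter]
    deepest_correct: Counter
    n_items: int

    @classmethod
    def from_scores(cls, scores: Iterable[Sequence[Verdict]]) -> "AccuracySummary":
        per_rank: dict[str, Counter] = {r: Counter() for r in RANK_NAMES}
        deepest = Counter()
        n = 0
        for verdicts in scores:
            n += 1
            for rank_name, v in zip(RANK_NAMES, verdicts):
                per_rank[rank_name][v] += 1
            d = 0
            for v in verdicts:
                if v != "correct":
                    break
                d += 1
            deepest[d] += 1
        return cls(per_rank=per_rank, deepest_correct=deepest, n_items=n)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[RankedAnnotation, Lineage]]
    ) -> "AccuracySummary":
        return cls.from_scores(score_against_truth(p, t) for p, t in pairs)


def read_annotations(path, delimiter: str = ";") -> dict[str, RankedAnnotation]:
    """Read a TSV of ``read_id<TAB>lineage string`` into annotations."""
    out: dict[str, RankedAnnotation] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            read_id, text = line.split("\t", 1)
            out[read_id] = parse_annotation(text.split("\t")[0], delimiter)
    return out


def write_annotations(annotations: dict[str, RankedAnnotation], path) -> None:
    with open(path, "w") as fh:
        for read_id, ann in annotations.items():
            fh.write(f"{read_id}\t{ann}\n")
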