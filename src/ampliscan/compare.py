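"""Quantitative comparison of three-taxon profiles against qPCR truth.

qPCR quantifies a handful of key taxa absolutely (here by default
L. crispatus, L. iners, and G. vaginalis).  To compare any sequencing-based
method against that ground truth, the abundances of exactly those taxa are
renormalised to sum to 1 ("triaxial" profiles on the 2-simplex) and the
Manhattan (L1) distance between method and qPCR profiles is computed per
sample.  For two points on the simplex this distance lies in [0, 2]; 0
means identical profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

DEFAULT_TAXA = ("Lactobacillus crispatus", "Lactobacillus iners", "Gardnerella vaginalis")


class CompareError(ValueError):
    pass


@dataclass(frozen=True)
class TriaxialProfile:
    """Relative abundances of three taxa summing to 1."""

    taxa: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.values):
            raise CompareError("taxa and values must have equal length")
        if any(v < 0 for v in self.values):
            raise CompareError(f"negative abundance in {self.values}")
        if abs(sum(self.values) - 1.0) > 1e-9:
            raise CompareError(f"values must sum to 1, got {sum(self.values)}")


@dataclass(frozen=True)
class DistanceReport:
    sample_id: str
    method: str
    manhattan: float


def normalize_three_taxa(
    raw: Sequence[float],
    taxa: Sequence[str] = DEFAULT_TAXA,
    sample_id: str = "",
) -> TriaxialProfile:
    """Normalise raw (nonnegative) abundances of the key taxa to sum to 1.

    A sample in which none of the taxa was detected cannot be placed on
    the simplex and is a hard error.
    """
    total = sum(raw)
    if any(v < 0 for v in raw):
        raise CompareError(f"negative abundance in sample {sample_id!r}")
    if total <= 0:
        raise CompareError(
            f"sample {sample_id!r}: all three taxa are zero; cannot normalise"
        )
    return TriaxialProfile(tuple(taxa), tuple(v / total for v in raw))


def manhattan_distance(p: TriaxialProfile, q: TriaxialProfile) -> float:
    """L1 distance between two profiles over the same ordered taxa."""
    if p.taxa != q.taxa:
        raise CompareError(f"taxa mismatch: {p.taxa} vs {q.taxa}")
    return sum(abs(a - b) for a, b in zip(p.values, q.values))


def batch_compare(
    profiles: pd.DataFrame, reference: pd.DataFrame
) -> list[DistanceReport]:
    """Distance of every (sample, method) profile from its qPCR reference.

    Both tables are long-format with columns ``sample_id``, ``taxon``,
    ``abundance``; ``profiles`` additionally carries ``method``.  Both
    sides are normalised before the distance is taken.  Output is sorted
    by sample then method.
    """
    for col in ("sample_id", "method", "taxon", "abundance"):
        if col not in profiles.columns:
            raise CompareError(f"profiles table missing column {col!r}")
    for col in ("sample_id", "taxon", "abundance"):
        if col not in reference.columns:
            raise CompareError(f"reference table missing column {col!r}")

    taxa = tuple(dict.fromkeys(reference["taxon"]))
    ref_profiles: dict[str, TriaxialProfile] = {}
    for sample_id, grp in reference.groupby("sample_id", sort=False):
        vals = grp.set_index("taxon")["abundance"]
        ref_profiles[str(sample_id)] = normalize_three_taxa(
            [float(vals.get(t, 0.0)) for t in taxa], taxa, str(sample_id)
        )

    reports: list[DistanceReport] = []
    for (sample_id, method), grp in profiles.groupby(["sample_id", "method"], sort=False):
        sample_id, method = str(sample_id), str(method)
        if sample_id not in ref_profiles:
            raise CompareError(f"no qPCR reference for sample {sample_id!r}")
        vals = grp.set_index("taxon")["abundance"]
        prof = normalize_three_taxa(
            [float(vals.get(t, 0.0)) for t in taxa], taxa, sample_id
        )
        reports.append(
            DistanceReport(sample_id, method, manhattan_distance(prof, ref_profiles[sample_id]))
        )
    return sorted(reports, key=lambda r: (r.sample_id, r.method))


def distance_table(reports: list[DistanceReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in reports],
            "method": [r.method for r in reports],
            "manhattan": [r.manhattan for r in reports],
        }
    )
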