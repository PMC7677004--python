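"""Deterministic synthetic test-data generation.

Every analysis operation in this toolkit is validated against *planted*
ground truth: reference databases whose primer-site composition (both
sites / forward only / reverse only / neither), 5'-truncation flags, and
genus structure are chosen up front and recorded in a truth table, and
FASTQ pairs engineered so that their pass/fail outcome under the default
QC parameters is known by construction.

Background sequence is rejection-sampled so that no spurious primer
variant occurs anywhere outside the planted loci — ground truth is exact,
not probabilistic.  A single integer seed governs all randomness and
identical seeds give byte-identical outputs.

These generators emulate the *structure* real analyses depend on (site
presence, coordinates, lineages, quality profiles), not the biology of
real 16S sequences: background composition is uniform-random, lineage
labels are synthetic, and no sequencing-error model is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .primers import PrimerPool, expand_degenerate, find_sites, reverse_complement
from .qc import QCParams, QualityRead
from .reference import Lineage, ReferenceDatabase, ReferenceRecord, parse_lineage

ALPHABET = np.array(list("ACGT"))


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Plan for a planted reference database.

    Fractions partition the records into site categories (the remainder
    gets neither site).  ``truncated_fraction`` controls how many records
    carry the 5'-truncated flag; truncated flags are assigned to
    reverse-only records first (these are the records the optimistic
    accounting rescues), then to no-site records.  When ``genus_plan`` is
    given — a list of (genus, record count, amplified fraction) — it
    overrides the global ``frac_both`` per genus, with each genus's
    non-amplified remainder assigned no sites.
    """

    seed: int
    n_records: int
    frac_both: float = 0.7
    frac_forward_only: float = 0.0
    frac_reverse_only: float = 0.0
    truncated_fraction: Optional[float] = None  # default: frac_reverse_only
    genus_plan: Optional[tuple[tuple[str, int, float], ...]] = None
    length_range: tuple[int, int] = (700, 900)
    inner_length_range: tuple[int, int] = (150, 400)

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise FixtureError("n_records must be positive")
        fracs = (self.frac_both, self.frac_forward_only, self.frac_reverse_only)
        if any(not (0 <= f <= 1) for f in fracs):
            raise FixtureError("fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-9:
            raise FixtureError("site-category fractions exceed 1")
        if self.truncated_fraction is not None and not (
            0 <= self.truncated_fraction <= 1
        ):
            raise FixtureError("truncated_fraction must lie in [0, 1]")
        if self.genus_plan is not None:
            total = sum(count for _, count, _ in self.genus_plan)
            if total != self.n_records:
                raise FixtureError(
                    f"genus_plan counts sum to {total}, expected {self.n_records}"
                )


def _round_count(frac: float, n: int) -> int:
    return int(round(frac * n))


def _random_background(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[rng.integers(0, 4, size=length)])


def _has_any_site(sequence: str, pools: Sequence[PrimerPool]) -> bool:
    probe = ReferenceRecord("probe", sequence, parse_lineage("Bacteria"))
    return any(find_sites(probe, pool) for pool in pools)


def _clean_background(
    rng: np.random.Generator, length: int, pools: Sequence[PrimerPool], max_tries: int = 200
) -> str:
    """Rejection-sample a background with no occurrence of any pool variant."""
    for _ in range(max_tries):
        seq = _random_background(rng, length)
        if not _has_any_site(seq, pools):
            return seq
    raise FixtureError(
        f"could not sample a clean background of length {length} "
        f"in {max_tries} tries"
    )


def _pick_variant(rng: np.random.Generator, pool: PrimerPool) -> str:
    """A concrete template-strand variant of a random pool member."""
    member = pool.members[rng.integers(0, len(pool.members))]
    variants = sorted(expand_degenerate(member.sequence))
    variant = variants[rng.integers(0, len(variants))]
    return variant if member.orientation == "forward" else reverse_complement(variant)


def _lineage_for(genus: str, index: int) -> Lineage:
    stem = genus.lower()
    return parse_lineage(
        f"Bacteria;Synthophyta;Synthia;Synthales;{genus}aceae;{genus};{stem}ii{index}"
    )


@dataclass
class _RecordPlan:
    genus: str
    category: str  # both | forward_only | reverse_only | neither
    truncated: bool = False


def make_reference_db(
    spec: FixtureSpec, fwd: PrimerPool, rev: PrimerPool
) -> tuple[ReferenceDatabase, pd.DataFrame]:
    """Build a planted reference database plus its exact truth table.

    The truth table has one row per record: id, genus, site category,
    5'-completeness flag, planted forward/reverse site coordinates (-1
    when absent), and the inner amplicon length (-1 when not amplified).
    """
    rng = np.random.default_rng(spec.seed)
    pools = (fwd, rev)
    fwd_len = len(fwd.members[0].sequence)
    rev_len = len(rev.members[0].sequence)
    min_len = spec.length_range[0]
    needed = 30 + fwd_len + spec.inner_length_range[1] + rev_len
    if needed > min_len:
        raise FixtureError(
            f"planted amplicon can need up to {needed} bases but minimum record "
            f"length is {min_len}"
        )

    plans: list[_RecordPlan] = []
    if spec.genus_plan is not None:
        for genus, count, cov in spec.genus_plan:
            k_both = _round_count(cov, count)
            plans.extend(_RecordPlan(genus, "both") for _ in range(k_both))
            plans.extend(_RecordPlan(genus, "neither") for _ in range(count - k_both))
    else:
        n = spec.n_records
        n_both = _round_count(spec.frac_both, n)
        n_fwd = _round_count(spec.frac_forward_only, n)
        n_rev = _round_count(spec.frac_reverse_only, n)
        if n_both + n_fwd + n_rev > n:
            raise FixtureError("rounded category counts exceed n_records")
        plans.extend(_RecordPlan("Synthegenus", "both") for _ in range(n_both))
        plans.extend(_RecordPlan("Synthegenus", "forward_only") for _ in range(n_fwd))
        plans.extend(_RecordPlan("Synthegenus", "reverse_only") for _ in range(n_rev))
        plans.extend(
            _RecordPlan("Synthegenus", "neither")
            for _ in range(n - n_both - n_fwd - n_rev)
        )

    trunc_frac = (
        spec.truncated_fraction
        if spec.truncated_fraction is not None
        else sum(1 for p in plans if p.category == "reverse_only") / len(plans)
    )
    n_trunc = _round_count(trunc_frac, len(plans))
    eligible = [p for p in plans if p.category == "reverse_only"] + [
        p for p in plans if p.category == "neither"
    ]
    if n_trunc > len(eligible):
        raise FixtureError(
            f"truncated_fraction asks for {n_trunc} truncated records but only "
            f"{len(eligible)} records lack a forward site"
        )
    for p in plans:
        p.truncated = False
    for p in eligible[:n_trunc]:
        p.truncated = True

    records: list[ReferenceRecord] = []
    truth_rows: list[dict] = []
    for i, plan in enumerate(plans):
        rec_id = f"SYN{i:05d}"
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        fwd_variant = _pick_variant(rng, fwd)
        rev_variant = _pick_variant(rng, rev)
        inner_len = int(
            rng.integers(spec.inner_length_range[0], spec.inner_length_range[1] + 1)
        )

        f_start = r_start = -1
        f_end = r_end = -1
        for _ in range(50):
            seq = _clean_background(rng, length, pools)
            if plan.category in ("both", "forward_only"):
                f_start = int(rng.integers(5, 30))
                f_end = f_start + len(fwd_variant)
                seq = seq[:f_start] + fwd_variant + seq[f_end:]
            if plan.category in ("both", "reverse_only"):
                if plan.category == "both":
                    r_start = f_end + inner_len
                else:
                    r_start = int(rng.integers(50, length - rev_len - 5))
                r_end = r_start + len(rev_variant)
                seq = seq[:r_start] + rev_variant + seq[r_end:]
            probe = ReferenceRecord(rec_id, seq, _lineage_for(plan.genus, i))
            f_sites = find_sites(probe, fwd)
            r_sites = find_sites(probe, rev)
            want_f = [f_start] if plan.category in ("both", "forward_only") else []
            want_r = [r_start] if plan.category in ("both", "reverse_only") else []
            if [s.start for s in f_sites] == want_f and [s.start for s in r_sites] == want_r:
                break
        else:
            raise FixtureError(f"could not plant record {rec_id} without spurious sites")

        flag = "truncated" if plan.truncated else "complete"
        records.append(
            ReferenceRecord(rec_id, seq, _lineage_for(plan.genus, i), flag)
        )
        truth_rows.append(
            {
                "record_id": rec_id,
                "genus": plan.genus,
                "category": plan.category,
                "five_prime_complete": flag,
                "fwd_start": f_start if plan.category in ("both", "forward_only") else -1,
                "fwd_end": f_end if plan.category in ("both", "forward_only") else -1,
                "rev_start": r_start if plan.category in ("both", "reverse_only") else -1,
                "rev_end": r_end if plan.category in ("both", "reverse_only") else -1,
                "inner_length": inner_len if plan.category == "both" else -1,
                "lineage": str(_lineage_for(plan.genus, i)),
            }
        )

    db = ReferenceDatabase(records, source_label=f"synthetic(seed={spec.seed})")
    return db, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class FastqSpec:
    """Plan for paired FASTQ whose QC outcome is known by construction.

    ``frac_fail_short`` pairs are engineered so one read falls below the
    fixed trim length after 3'-quality truncation (either born short, or
    given a low-quality 3' tail that truncation removes);
    ``frac_fail_ee`` pairs are full-length but uniformly low quality
    (Phred 15-17: untouched by the Phred-15 truncation yet far above the
    expected-error ceiling).  The remainder pass: full-length with Phred
    25-40, whose worst-case expected error is well under the ceiling.
    """

    seed: int
    n_pairs: int
    frac_fail_short: float = 0.0
    frac_fail_ee: float = 0.0
    read_len_range: tuple[int, int] = (270, 300)
    good_q_range: tuple[int, int] = (25, 40)
    qc: QCParams = field(default_factory=QCParams)

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise FixtureError("n_pairs must be positive")
        if not (0 <= self.frac_fail_short <= 1 and 0 <= self.frac_fail_ee <= 1):
            raise FixtureError("fractions must lie in [0, 1]")
        if self.frac_fail_short + self.frac_fail_ee > 1 + 1e-9:
            raise FixtureError("failure fractions exceed 1")
        if self.read_len_range[0] < self.qc.trim_len:
            raise FixtureError("read_len_range must start at or above trim_len")
        if self.good_q_range[0] <= self.qc.q_cutoff:
            raise FixtureError("good_q_range must sit above q_cutoff")
        # worst case for a "pass" pair must clear the EE ceiling
        worst = 2 * self.read_len_range[1] * 10 ** (-self.good_q_range[0] / 10)
        if worst > self.qc.max_ee:
            raise FixtureError(
                f"good_q_range too low: worst-case EE {worst:.2f} exceeds "
                f"max_ee {self.qc.max_ee}"
            )


def _good_read(
    rng: np.random.Generator, spec: FastqSpec, read_id: str
) -> QualityRead:
    length = int(rng.integers(spec.read_len_range[0], spec.read_len_range[1] + 1))
    seq = _random_background(rng, length)
    quals = tuple(
        int(q) for q in rng.integers(spec.good_q_range[0], spec.good_q_range[1] + 1, length)
    )
    return QualityRead(read_id, seq, quals)


def _short_read(rng: np.random.Generator, spec: FastqSpec, read_id: str) -> QualityRead:
    """A read that ends up below trim_len after quality truncation."""
    trim_len = spec.qc.trim_len
    if rng.integers(0, 2) == 0:  # born short
        length = int(rng.integers(max(1, trim_len - 80), trim_len))
        seq = _random_background(rng, length)
        quals = tuple(
            int(q)
            for q in rng.integers(spec.good_q_range[0], spec.good_q_range[1] + 1, length)
        )
        return QualityRead(read_id, seq, quals)
    # full length with a Phred-2 3' tail the truncation removes
    good_len = int(rng.integers(trim_len - 40, trim_len))
    tail_len = int(rng.integers(5, 20))
    seq = _random_background(rng, good_len + tail_len)
    quals = tuple(
        int(q)
        for q in rng.integers(spec.good_q_range[0], spec.good_q_range[1] + 1, good_len)
    ) + (2,) * tail_len
    return QualityRead(read_id, seq, quals)


def _low_q_read(rng: np.random.Generator, spec: FastqSpec, read_id: str) -> QualityRead:
    length = int(rng.integers(spec.read_len_range[0], spec.read_len_range[1] + 1))
    seq = _random_background(rng, length)
    quals = tuple(int(q) for q in rng.integers(spec.qc.q_cutoff, spec.qc.q_cutoff + 3, length))
    return QualityRead(read_id, seq, quals)


def make_fastq_pairs(
    spec: FastqSpec,
) -> tuple[list[QualityRead], list[QualityRead], pd.DataFrame]:
    """Generate (forward reads, reverse reads, truth table).

    The truth table records each pair's engineered QC outcome
    (``kept`` / ``rejected_short`` / ``rejected_ee``).
    """
    rng = np.random.default_rng(spec.seed)
    n_short = _round_count(spec.frac_fail_short, spec.n_pairs)
    n_ee = _round_count(spec.frac_fail_ee, spec.n_pairs)
    if n_short + n_ee > spec.n_pairs:
        raise FixtureError("rounded failure counts exceed n_pairs")
    categories = (
        ["rejected_short"] * n_short
        + ["rejected_ee"] * n_ee
        + ["kept"] * (spec.n_pairs - n_short - n_ee)
    )

    fwd_reads: list[QualityRead] = []
    rev_reads: list[QualityRead] = []
    rows: list[dict] = []
    for i, category in enumerate(categories):
        pair_id = f"pair{i:05d}"
        if category == "rejected_short":
            if rng.integers(0, 2) == 0:
                f = _short_read(rng, spec, pair_id)
                r = _good_read(rng, spec, pair_id)
            else:
                f = _good_read(rng, spec, pair_id)
                r = _short_read(rng, spec, pair_id)
        elif category == "rejected_ee":
            f = _low_q_read(rng, spec, pair_id)
            r = _low_q_read(rng, spec, pair_id)
        else:
            f = _good_read(rng, spec, pair_id)
            r = _good_read(rng, spec, pair_id)
        fwd_reads.append(f)
        rev_reads.append(r)
        rows.append({"pair_id": pair_id, "expected_status": category})

    return fwd_reads, rev_reads, pd.DataFrame(rows)
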