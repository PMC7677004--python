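# Methods

This note documents the models and procedures `ampliscan` implements, the
parameter defaults and why they hold, the design decisions taken where the
problem was genuinely open, and what the synthetic fixtures do and do not
establish about real data.

## Reference databases

A reference database is a FASTA file of 16S rRNA gene sequences plus a
tab-separated taxonomy table (id, lineage string, optional
5′-completeness flag).  Lineages are SILVA-style seven-rank paths
(domain…species); a lineage may be annotated only to some depth, in which
case all deeper ranks are empty — a filled rank below an empty one is
rejected.  Species labels store the epithet alone; a leading repeat of
the genus token is stripped on parse so binomial and epithet notations
compare equal.  Sequences are upper-cased and U→T-normalised on read,
since rRNA gene collections mix DNA and RNA conventions, and taxon
matching is case-insensitive.

The 5′-completeness flag exists because public 16S collections are often
incomplete at the gene's 5′ end, which makes coverage of 27f-position
primers unassessable record by record.  The flag is tri-state
(`complete` / `truncated` / `unknown`) so that curated knowledge can
override the length heuristic described below.

## Primer matching

Primers are IUPAC strings, 5′→3′; a pool is a set of same-orientation
primers used as one reagent.  Matching is exact and full-length: no
mismatches, no indels, no partial overlap at sequence ends.  Reverse
primers are searched as their reverse complement on the stored (forward)
strand, and all coordinates are 0-based half-open on that strand.

Two open choices were fixed here:

- **Template ambiguity codes.**  A template position matches a primer
  position iff the template code's nucleotide set is a subset of the
  primer code's set; a template `N` therefore matches only a primer `N`.
  The alternative (any intersection) would let low-quality reference
  bases inflate coverage.
- **Implementation.**  The scanner compiles each (possibly expanded)
  member into a per-position character class; an independent
  alternation-over-expanded-variants search is kept in the code base and
  the two are cross-checked in tests on unambiguous templates.

## Amplicon extraction and the optimistic/pessimistic accounting

For a primer pair, extraction uses the outermost compatible site pair:
the 5′-most forward site and the 3′-most reverse site that leave a
positive-length inner (primer-trimmed) span.  This mirrors PCR, which
yields the longest product, and is unambiguous under exact coordinates.
A zero- or negative-length inner span is reported as `no_product`.

Pair coverage is reported under two accountings.  *Pessimistic* requires
both sites.  *Optimistic* additionally counts a record as
`assumed_amplified` when it has a reverse site, no forward site, and is
classified 5′-truncated — the assumption being that the forward locus is
simply missing from the record, not absent from the organism.  The truth
for any real pair lies between the two numbers.

Truncation classification uses the metadata flag when present.  When the
flag is `unknown`, a length heuristic applies: the expected number of
bases upstream of the reverse-primer locus is the difference of the two
primers' approximate E. coli 16S coordinates (the numbers in names like
27f and 534r, shipped in the primer config); a record with fewer upstream
bases than that expectation minus a slack is called truncated.  The slack
defaults to 100 bp to absorb 16S length heterogeneity and is
configurable.  This heuristic is a reconstruction — there is no single
published operational rule for "lacks the 5′ end" — so optimistic
coverage of real databases carries a corresponding margin, and the
synthetic fixtures always set explicit flags when exactness matters.

The per-cycle amplification-bias factor is the closed form
(2/e)^c for efficiency e ∈ (1, 2] and cycle count c: the fold by which a
sub-perfectly amplified template is underrepresented relative to perfect
doubling.  No GC- or length-dependent modelling is attempted beyond this
single factor.

## Read simulation

Simulation is deliberately error-free: its purpose is to compare primers
and processing strategies under ideal conditions, not to model a
sequencer.  Reads are 250 bp — a realistic usable length after primer and
quality trimming on current 2×300 chemistry.  The merge rule compares the
*inner* (primer-trimmed) amplicon length L to a 500-bp threshold
(2 × 250): L below the threshold yields one merged sequence (the full
inner sequence), L above yields an independent pair (the first 250 bases,
and the reverse complement of the last 250), and L within ±10 bp of the
threshold yields both representations, because mergeability that close to
2×read-length depends on the sequencer's error profile.  The with-primer
interpretation of the threshold was considered and rejected: the 250-bp
reads are already primer-trimmed, so 2×250 = 500 is only consistent with
the inner length.

## Consensus taxonomy

Forward- and reverse-read annotations of an unmerged pair are reconciled
by three rules, applied so that the operation is commutative and
idempotent:

1. If any rank where *both* annotations are filled disagrees, the result
   is truncated to the deepest rank above the disagreement (the lowest
   common ancestor); deeper ranks and any candidate sets are cleared.
2. An empty rank conflicts with nothing: when one annotation is a
   prefix-compatible extension of the other, the more detailed one is
   kept.  (Rule 1 concerns diverging annotations; rule 2 detail
   asymmetry — an empty-vs-filled rank is governed by rule 2, not
   rule 1.)
3. At species level an annotation may carry a set of candidate epithets
   ("crispatus/gasseri/jensenii").  When both annotations carry species
   information under an agreeing genus, the intersection is kept; a
   singleton intersection becomes a definite species call.  An *empty*
   intersection is not defined by the published scheme; it is treated
   here as a species-level disagreement and the result falls back to the
   genus-level annotation, by analogy with rule 1.

A singleton candidate set is normalised to a filled species rank at
construction, so the two notations compare equal.  Candidate sets
serialise with epithets sorted lexicographically.

Accuracy scoring assigns one verdict per rank: `correct`, `incorrect`, or
`unannotated`, and at species level `ambiguous` for a non-singleton
candidate set containing the true epithet (tracked separately from
`correct`, which requires a definite call).  Summaries report per-rank
verdict counts — which partition the scored items at every rank — and a
deepest-correct-rank histogram.

## Concatenation quality control

For amplicons too long to merge, the pipeline is: 3′ quality truncation
of both reads at Phred 15; rejection of the pair if either truncated read
is shorter than 270 bp (a read of exactly 270 bp passes — "did not reach
270 bp" is read as strictly below); trimming to exactly 270 bp;
rejection if the expected error over the concatenated 540 bases exceeds
4.0; concatenation, with the reverse read in as-sequenced orientation
(the two halves are annotated independently downstream, so no reverse
complement is taken).

"Remove bases with Phred < 15" is implemented as 3′-end partial-sums
truncation — scanning from the 3′ end, accumulate (15 − Q) and cut where
the running sum is maximal and positive, ties favouring the shortest cut
— rather than per-base masking, which would corrupt positional structure.
This is the algorithm of standard read-trimming tools.  Expected error is
EE = Σ 10^(−Q/10); it is additive over concatenation and monotone
nonincreasing under any per-base quality improvement, both property-tested.

Defaults: Phred cutoff 15, trim length 270 bp (so the concatenated
product is 540 bp), EE ceiling 4.0, matching the V1-V3 concatenation
protocol the toolkit evaluates.

## Profile comparison

The three key taxa quantified by qPCR (*L. crispatus*, *L. iners*,
*G. vaginalis*) are extracted from each method's output and renormalised
to sum to 1; a sample in which all three are zero cannot be placed on the
simplex and is a hard error rather than silently uniform.  Profiles are
compared by Manhattan (L1) distance, 0 for identical profiles.  For two
nonnegative vectors each summing to 1 the attainable maximum is 2 (a
brute-force sweep of a simplex grid is part of the test suite); a looser
bound of 3 is sometimes quoted for this construction, but 2 is the sharp
bound and the implementation asserts it.  Distances are kept at full
precision; rounding is left to presentation.

## Synthetic fixtures

The fixture generator is the toolkit's primary oracle: it plants ground
truth and the analysis operations must recover it exactly.

*Reference fixtures.*  Records are partitioned into site categories
(both / forward-only / reverse-only / neither) by specified fractions, or
per genus by a (genus, count, coverage) plan.  Background sequence is
rejection-sampled so that no variant of either pool occurs anywhere, then
concrete variants are spliced at recorded coordinates and the record is
re-verified, so coverage truth is exact rather than probabilistic.
Truncation flags are assigned to reverse-only records first — these are
precisely the records the optimistic accounting rescues — then to
no-site records.  Planted inner lengths default to 150-400 bp on 700-900
bp records.

*FASTQ fixtures.*  Pairs are engineered so their QC outcome is known by
construction: passing pairs are full-length at Phred 25-40 (worst-case EE
over 540 bp ≈ 1.7, safely under the 4.0 ceiling — a floor of 16 would
not guarantee this, and the generator rejects such specs); short-failing
pairs are either born under 270 bp or given a Phred-2 3′ tail that
truncation removes; EE-failing pairs are full-length at Phred 15-17,
which the Phred-15 truncation leaves untouched while EE ≥ 540×10^-1.7 ≈
10.8 stays far above the ceiling.

A single integer seed drives one PRNG for everything; identical seeds
give byte-identical FASTA/FASTQ output.

What passing these oracles shows — and does not.  The fixtures exercise
the combinatorial and arithmetic structure the analyses depend on: site
presence and coordinates, truncation accounting, category fractions,
quality arithmetic.  They are uniform-random background with synthetic
lineages: they say nothing about real 16S conservation structure,
real primer-taxon mismatch patterns, chimeras, or abundance
distributions, and no sequencing-error model is applied anywhere.
Conclusions about a particular primer pair on real taxa require running
the toolkit on a real annotated database.

## Problem sizes and tolerances

The planted-coverage oracle runs on databases of 10-1,000 records over
five seeds; consensus algebra (commutativity, idempotence, depth bounds)
is swept over 10,000 random annotation pairs plus derandomised
property-based suites; the QC oracle uses batches of 40-60 engineered
pairs over several seeds against an independent brute-force filter; the
distance bound is verified on a full simplex grid.  Floating-point
comparisons use relative tolerances ~1e-6 except where closed forms are
exact; percentage reporting rounds half-up to one decimal, with raw
counts retained for exact conservation checks (the count-weighted genus
rows of a coverage matrix sum exactly to the pair's matched count).

## Known limitations

- Exact matching only: no mismatch-tolerant or thermodynamic binding
  model, so coverage is a lower bound on amplifiability for primers that
  tolerate internal mismatches.
- The 5′-truncation heuristic is coordinate-based and approximate;
  optimistic coverage of databases without explicit flags inherits that
  approximation.
- Primer removal, read merging/overlap assembly, denoising, clustering
  and chimera removal are out of scope; the toolkit consumes or emulates
  their inputs and outputs.
- The consensus scheme assumes both annotations come from the same
  classifier/database family; it does not attempt synonym resolution
  across taxonomies.
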