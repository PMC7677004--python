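"""Amplicon extraction, truncation classification, and read simulation."""

import pytest

from ampliscan.pcr import (
    InSilicoPCRError,
    SimulationParams,
    classify_truncation,
    extract_amplicon,
    simulate_reads,
)
from ampliscan.primers import PrimerPool, find_sites, reverse_complement

# short synthetic primers keep the fixtures readable
FWD = PrimerPool.single("fwdP", "ACGTACGTAC", "forward", expected_position=8)
REV = PrimerPool.single("revP", "GGATCCGGAT", "reverse", expected_position=534)
REV_SITE = reverse_complement("GGATCCGGAT")  # as it appears on the template
BG = "T" * 10


def template(inner_len=50, lead=10):
    # AG-alternating inner cannot spawn spurious primer matches
    inner = ("AG" * inner_len)[:inner_len]
    return "T" * lead + "ACGTACGTAC" + inner + REV_SITE + BG


class TestExtractAmplicon:
    def test_both_sites_amplified_with_planted_coordinates(self, record_factory):
        rec = record_factory(template(inner_len=50, lead=10))
        ext = extract_amplicon(rec, FWD, REV, "plain")
        assert ext.status == "amplified"
        assert ext.outer_span == (10, 10 + 10 + 50 + 10)
        assert ext.inner_span == (20, 70)
        assert ext.inner_length == 50

    def test_no_reverse_site_in_any_mode(self, record_factory):
        rec = record_factory(BG + "ACGTACGTAC" + BG * 5)
        for mode in ("plain", "pessimistic", "optimistic"):
            assert extract_amplicon(rec, FWD, REV, mode).status == "no_reverse"

    def test_truncated_record_assumed_amplified_only_in_optimistic(self, record_factory):
        rec = record_factory(BG + REV_SITE + BG, five_prime="truncated")
        assert extract_amplicon(rec, FWD, REV, "optimistic").status == "assumed_amplified"
        assert extract_amplicon(rec, FWD, REV, "pessimistic").status == "no_forward"
        assert extract_amplicon(rec, FWD, REV, "plain").status == "no_forward"

    def test_complete_record_without_forward_site_is_no_forward(self, record_factory):
        rec = record_factory(BG + REV_SITE + BG, five_prime="complete")
        assert extract_amplicon(rec, FWD, REV, "optimistic").status == "no_forward"

    def test_pessimistic_identical_to_plain_when_both_sites_present(self, record_factory):
        rec = record_factory(template())
        plain = extract_amplicon(rec, FWD, REV, "plain")
        pess = extract_amplicon(rec, FWD, REV, "pessimistic")
        opt = extract_amplicon(rec, FWD, REV, "optimistic")
        assert plain.inner_span == pess.inner_span == opt.inner_span
        assert plain.status == pess.status == opt.status == "amplified"

    def test_outermost_compatible_pair_chosen(self, record_factory):
        # two forward sites and two reverse sites; expect 5'-most fwd, 3'-most rev
        seq = (BG + "ACGTACGTAC" + BG + "ACGTACGTAC" + BG * 3
               + REV_SITE + BG + REV_SITE + BG)
        rec = record_factory(seq)
        ext = extract_amplicon(rec, FWD, REV)
        f_sites = find_sites(rec, FWD)
        r_sites = find_sites(rec, REV)
        assert ext.forward_site == f_sites[0]
        assert ext.reverse_site == r_sites[-1]

    def test_adjacent_sites_give_no_product(self, record_factory):
        # reverse site starts exactly at the forward site's end: inner length 0
        rec = record_factory(BG + "ACGTACGTAC" + REV_SITE + BG)
        assert extract_amplicon(rec, FWD, REV).status == "no_product"

    def test_wrong_pool_orientations_rejected(self, record_factory):
        rec = record_factory(template())
        with pytest.raises(InSilicoPCRError, match="not reverse-oriented"):
            extract_amplicon(rec, FWD, FWD)


class TestClassifyTruncation:
    def _rev_site(self, rec):
        sites = find_sites(rec, REV)
        assert sites
        return sites[-1]

    def test_metadata_flag_wins(self, record_factory):
        rec = record_factory("T" * 600 + REV_SITE + BG, five_prime="truncated")
        assert classify_truncation(rec, FWD, REV, self._rev_site(rec)) == "truncated"

    def test_heuristic_truncated_when_upstream_too_short(self, record_factory):
        # expected upstream = 534 - 8 = 526; site at offset 80 < 526 - 100
        rec = record_factory("T" * 80 + REV_SITE + BG)
        assert classify_truncation(rec, FWD, REV, self._rev_site(rec)) == "truncated"

    def test_heuristic_complete_when_upstream_sufficient(self, record_factory):
        rec = record_factory("T" * 526 + REV_SITE + BG)
        assert classify_truncation(rec, FWD, REV, self._rev_site(rec)) == "complete"

    def test_heuristic_without_expected_positions_errors(self, record_factory):
        fwd = PrimerPool.single("f", "ACGTACGTAC", "forward")
        rec = record_factory("T" * 80 + REV_SITE + BG)
        with pytest.raises(InSilicoPCRError, match="expected_position"):
            classify_truncation(rec, fwd, REV, self._rev_site(rec))


class TestSimulateReads:
    def _amplified(self, record_factory, inner_len):
        rec = record_factory(template(inner_len=inner_len))
        return rec, extract_amplicon(rec, FWD, REV)

    @pytest.mark.parametrize(
        "inner_len,expected", [(400, "merged"), (600, "paired"), (495, "both"),
                               (489, "merged"), (511, "paired"), (490, "both"),
                               (510, "both")]
    )
    def test_representation_rule(self, record_factory, inner_len, expected):
        rec, ext = self._amplified(record_factory, inner_len)
        sim = simulate_reads(rec, ext, SimulationParams())
        assert sim.representation == expected

    def test_merged_is_full_inner_sequence(self, record_factory):
        rec, ext = self._amplified(record_factory, 400)
        sim = simulate_reads(rec, ext)
        lo, hi = ext.inner_span
        assert sim.merged_seq == rec.sequence[lo:hi]
        assert len(sim.merged_seq) == 400

    def test_paired_reads_reconstruct_inner(self, record_factory):
        rec, ext = self._amplified(record_factory, 480)
        lo, hi = ext.inner_span
        inner = rec.sequence[lo:hi]
        # L=480 <= 2*read_len: shrink the threshold to force a pair, then
        # overlaying the un-reverse-complemented tail reconstructs the inner
        sim = simulate_reads(rec, ext, SimulationParams(250, 400, 0))
        assert sim.representation == "paired"
        assert sim.fwd_read == inner[:250]
        assert reverse_complement(sim.rev_read) == inner[-250:]
        # overlay reconstructs the inner sequence exactly (L <= 2*read_len)
        overlap = 2 * 250 - 480
        assert sim.fwd_read[-overlap:] == reverse_complement(sim.rev_read)[:overlap]
        assert sim.fwd_read + reverse_complement(sim.rev_read)[overlap:] == inner

    def test_rev_read_is_reverse_complement_of_tail(self, record_factory):
        rec, ext = self._amplified(record_factory, 600)
        sim = simulate_reads(rec, ext)
        lo, hi = ext.inner_span
        inner = rec.sequence[lo:hi]
        assert sim.rev_read == reverse_complement(inner[350:600])

    def test_simulating_unamplified_extraction_errors(self, record_factory):
        rec = record_factory(BG + REV_SITE + BG)
        ext = extract_amplicon(rec, FWD, REV)
        with pytest.raises(InSilicoPCRError, match="no_forward"):
            simulate_reads(rec, ext)

    def test_true_lineage_carried(self, record_factory, full_lineage):
        rec = record_factory(template(400), lineage=full_lineage)
        sim = simulate_reads(rec, extract_amplicon(rec, FWD, REV))
        assert sim.true_lineage == full_lineage


class TestSimulationParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(InSilicoPCRError):
            SimulationParams(read_len=0)
        with pytest.raises(InSilicoPCRError):
            SimulationParams(read_len=250, merge_threshold=200)
        with pytest.raises(InSilicoPCRError):
            SimulationParams(near_window=-1)
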