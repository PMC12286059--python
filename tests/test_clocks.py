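"""UCSC chain parsing, point liftover, clock harmonization and overlap."""

import numpy as np
import pytest

from nanoage import clocks, io
from nanoage.clocks import Chain, ChainBlock, liftover_point, read_chain
from nanoage.io import ClockCpG, CpGSite, ParseError


class TestReadChain:
    def test_identity_chain_parses(self, fixtures):
        (chain,) = read_chain(fixtures["chain_identity"])
        assert chain.t_name == chain.q_name == "chr1"
        assert chain.blocks == (ChainBlock(100000, 0, 0),)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.chain"
        p.write_text("")
        assert read_chain(p) == []

    def test_truncated_block_line_errors_with_line_number(self, tmp_path):
        p = tmp_path / "t.chain"
        p.write_text("chain 1 chr1 100 + 0 10 chr1 100 + 0 10 1\n5\t2\n")
        with pytest.raises(ParseError, match=":2"):
            read_chain(p)

    def test_block_sums_checked_against_header(self, tmp_path):
        p = tmp_path / "b.chain"
        p.write_text("chain 1 chr1 100 + 0 10 chr1 100 + 0 10 7\n5\n\n")
        with pytest.raises(ParseError, match="chain 7"):
            read_chain(p)

    def test_minus_target_strand_rejected(self, tmp_path):
        p = tmp_path / "m.chain"
        p.write_text("chain 1 chr1 100 - 0 10 chr1 100 + 0 10 1\n10\n\n")
        with pytest.raises(ParseError, match="target strand"):
            read_chain(p)


class TestLiftoverPoint:
    def test_identity_maps_everything_to_itself(self, fixtures):
        chains = read_chain(fixtures["chain_identity"])
        for pos in (0, 1, 99_999, 12345):
            res = liftover_point(chains, "chr1", pos)
            assert (res.mapped, res.chrom, res.pos0, res.same_strand) == (
                True, "chr1", pos, True,
            )

    def test_constant_offset_block(self, tmp_path):
        p = tmp_path / "o.chain"
        p.write_text("chain 10 chrT 1000 + 100 200 chrQ 2000 + 1100 1200 1\n100\n\n")
        res = liftover_point(read_chain(p), "chrT", 150)
        assert (res.chrom, res.pos0) == ("chrQ", 1150)
        assert not liftover_point(read_chain(p), "chrT", 50).mapped  # before chain

    def test_gapped_chain_hand_walked(self, fixtures):
        # target chr2 [1000,2100) -> query [5000,6000), blocks 500 / dt 100 / 500
        chains = read_chain(fixtures["chain_gapped"])
        cases = {
            1000: 5000,       # first base of block 1
            1499: 5499,       # last base of block 1
            1600: 5500,       # first base of block 2 (after 100 bp target gap)
            2099: 5999,       # last base of block 2
        }
        for t, q in cases.items():
            res = liftover_point(chains, "chr2", t)
            assert (res.mapped, res.pos0) == (True, q)
        for deleted in (1500, 1550, 1599):
            res = liftover_point(chains, "chr2", deleted)
            assert (res.mapped, res.reason) == (False, "deleted")

    def test_minus_strand_chain_hand_walked(self, fixtures):
        # target [10000,11000) -> query minus-strand window; forward-strand
        # result runs backwards: 10000+k -> 10999-k
        chains = read_chain(fixtures["chain_minus"])
        for k in (0, 1, 500, 999):
            res = liftover_point(chains, "chr1", 10000 + k)
            assert (res.mapped, res.pos0, res.same_strand) == (True, 10999 - k, False)

    def test_minus_chain_round_trips_through_itself(self, fixtures):
        # this fixture's target and flipped-query windows coincide, so the
        # chain is its own inverse on the forward strand
        chains = read_chain(fixtures["chain_minus"])
        for pos in (10000, 10100, 10998):
            once = liftover_point(chains, "chr1", pos)
            back = liftover_point(chains, "chr1", once.pos0)
            assert back.pos0 == pos

    def test_offset_chains_compose(self, tmp_path):
        a = tmp_path / "a.chain"
        a.write_text("chain 1 chrT 1000 + 0 500 chrU 1000 + 100 600 1\n500\n\n")
        b = tmp_path / "b.chain"
        b.write_text("chain 1 chrU 1000 + 0 800 chrV 1000 + 7 807 1\n800\n\n")
        mid = liftover_point(read_chain(a), "chrT", 250)
        end = liftover_point(read_chain(b), "chrU", mid.pos0)
        assert end.pos0 == 250 + 100 + 7

    def test_highest_scoring_chain_wins(self, tmp_path):
        p = tmp_path / "two.chain"
        p.write_text(
            "chain 100 chrT 1000 + 0 500 chrQ 1000 + 0 500 1\n500\n\n"
            "chain 900 chrT 1000 + 0 500 chrQ 1000 + 300 800 2\n500\n\n"
        )
        res = liftover_point(read_chain(p), "chrT", 10)
        assert res.pos0 == 310


class TestHarmonize:
    def test_hg38_manifest_passes_through(self):
        cpgs = [ClockCpG("cg1", "c", "hg38", "chr1", 500)]
        lifted, unmapped = clocks.harmonize_clock(cpgs, {})
        assert lifted == cpgs and unmapped == []

    def test_deleted_cpg_reported_unmapped(self, fixtures):
        chains = {"hg19": read_chain(fixtures["chain_gapped"])}
        cpgs = [ClockCpG("cg1", "c", "hg19", "chr2", 1551)]  # pos0 1550: in the gap
        lifted, unmapped = clocks.harmonize_clock(cpgs, chains)
        assert lifted == [] and unmapped[0][1] == "deleted"

    def test_missing_chain_set_is_error(self):
        with pytest.raises(ValueError, match="hg18"):
            clocks.harmonize_clock([ClockCpG("cg1", "c", "hg18", "chr1", 5)], {})

    def test_ten_cpg_fixture_hand_computed(self, fixtures):
        chains = {
            "hg19": read_chain(fixtures["chain_offset"]),
            "hg18": read_chain(fixtures["chain_minus"]),
        }
        cpgs = [ClockCpG(f"cg{i}", "c", "hg19", "chr1", 1000 + i) for i in range(5)]
        cpgs += [ClockCpG(f"cg{i+5}", "c", "hg18", "chr1", 10001 + i) for i in range(5)]
        lifted, unmapped = clocks.harmonize_clock(cpgs, chains)
        assert unmapped == []
        got = {c.ilmn_id: c.pos1 for c in lifted}
        # offset chain: pos0 -> pos0+50; minus chain: pos0 -> 10999-offset
        assert got == {
            **{f"cg{i}": 1000 + i + 50 for i in range(5)},
            **{f"cg{i+5}": (10999 - i) + 1 for i in range(5)},
        }
        assert all(c.build == "hg38" for c in lifted)

    def test_chrom_name_styles_normalized(self, fixtures):
        chains = {"hg19": read_chain(fixtures["chain_offset"])}
        cpgs = [ClockCpG("cg1", "c", "hg19", "1", 1000)]  # bare "1" spelling
        lifted, _ = clocks.harmonize_clock(cpgs, chains)
        assert lifted[0].chrom == "chr1" and lifted[0].pos1 == 1050


class TestOverlap:
    def test_exact_match_zero_tolerance(self):
        reports = clocks.overlap(
            [CpGSite("chr1", 100)], [ClockCpG("cg1", "c", "hg38", "chr1", 101)],
            tolerance=0,
        )
        assert reports[0].n_overlap == 1

    def test_off_by_one_needs_tolerance(self):
        sites = [CpGSite("chr1", 100)]
        cpgs = [ClockCpG("cg1", "c", "hg38", "chr1", 102)]  # pos0 101
        assert clocks.overlap(sites, cpgs, tolerance=1)[0].n_overlap == 1
        assert clocks.overlap(sites, cpgs, tolerance=0)[0].n_overlap == 0

    def test_tie_breaks_to_lower_position(self):
        sites = [CpGSite("chr1", 99), CpGSite("chr1", 101)]
        cpgs = [ClockCpG("cg1", "c", "hg38", "chr1", 101)]  # pos0 100, equidistant
        (rep,) = clocks.overlap(sites, cpgs, tolerance=1)
        assert rep.pairs[0][1].pos0 == 99

    def test_invariant_chain_and_random_oracle(self, rng):
        sites = sorted(
            {int(p) for p in rng.integers(0, 3000, 1000)}
        )
        ont = [CpGSite("chr1", p) for p in sites]
        cpgs = [
            ClockCpG(f"cg{i:03d}", f"clock{i % 3}", "hg38", "chr1", int(p) + 1)
            for i, p in enumerate(rng.integers(0, 3000, 100))
        ]
        reports = clocks.overlap(ont, cpgs, tolerance=1)
        site_arr = np.array(sites)
        for rep in reports:
            assert rep.n_overlap <= rep.n_lifted <= rep.clock_size
            expected = 0
            for cpg in cpgs:
                if cpg.clock_name != rep.clock_name:
                    continue
                if np.min(np.abs(site_arr - (cpg.pos1 - 1))) <= 1:
                    expected += 1
            assert rep.n_overlap == expected

    def test_shared_probe_counts_once_per_clock(self):
        sites = [CpGSite("chr1", 100)]
        cpgs = [
            ClockCpG("cg1", "clockA", "hg38", "chr1", 101),
            ClockCpG("cg1", "clockB", "hg38", "chr1", 101),
        ]
        reports = clocks.overlap(sites, cpgs)
        assert {r.clock_name: r.n_overlap for r in reports} == {"clockA": 1, "clockB": 1}
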