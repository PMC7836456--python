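"""sgRNA design: PAM enumeration, uniqueness, selection, controls, oligos."""

import re

import numpy as np
import pytest

from isoscreen import design
from isoscreen.promoters import PromoterRecord
from tests.conftest import random_seq


def oracle_enumerate(seq: str, tss: int, strand: str, window: int) -> set[tuple[str, int]]:
    """Independent regex-based candidate scan returning (spacer, offset) pairs."""
    sign = 1 if strand == "+" else -1
    out = set()
    for m in re.finditer(r"(?=[ACGT]GG)", seq):
        i = m.start()  # position of PAM N on the forward strand
        if i >= 20:
            spacer = seq[i - 20 : i]
            offset = sign * ((i - 1) - tss)
            if abs(offset) <= window and not set(spacer) - set("ACGT") and "TTTT" not in spacer:
                out.add((spacer, offset))
    for m in re.finditer(r"(?=CC[ACGT])", seq):
        i = m.start()
        if i + 23 <= len(seq):
            spacer = design.revcomp(seq[i + 3 : i + 23])
            offset = sign * ((i + 3) - tss)
            if abs(offset) <= window and not set(spacer) - set("ACGT") and "TTTT" not in spacer:
                out.add((spacer, offset))
    return out


class TestEnumerateCandidates:
    def test_single_planted_pam(self):
        # AT-alternating background has no GG/CC dinucleotides anywhere;
        # plant one forward protospacer+PAM so the only candidate is known.
        spacer = "ATATATATATATATATATGC"
        background = "AT" * 200
        pos = 180  # protospacer start
        seq = background[:pos] + spacer + "AGG" + background[pos + 23 :]
        genome = {"chr1": seq}
        p = PromoterRecord("p1", "g1", "chr1", 190, "+")
        cands = design.enumerate_candidates(genome, p, window=150)
        assert [c.spacer for c in cands] == [spacer]
        # anchor = PAM-proximal base at pos+19 = 199 -> offset +9
        assert cands[0].offset == 9
        assert cands[0].pam_site == pos + 20

    def test_no_pam_no_candidates(self):
        genome = {"chr1": "AT" * 300}
        p = PromoterRecord("p1", "g1", "chr1", 300, "+")
        assert design.enumerate_candidates(genome, p, window=150) == []

    @pytest.mark.parametrize("offset, included", [(150, True), (151, False), (-150, True), (-151, False)])
    def test_window_boundary_inclusive(self, offset, included):
        spacer = "ATATATATATATATATATGC"
        background = "AT" * 400
        tss = 400
        anchor = tss + offset  # PAM-proximal protospacer base
        pos = anchor - 19
        seq = background[:pos] + spacer + "AGG" + background[pos + 23 :]
        p = PromoterRecord("p1", "g1", "chr1", tss, "+")
        cands = design.enumerate_candidates({"chr1": seq}, p, window=150)
        assert (len(cands) == 1) is included

    def test_agrees_with_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(7)
        for strand in "+-":
            for _ in range(50):
                seq = random_seq(rng, 1000)
                p = PromoterRecord("p", "g", "chr", 500, strand)
                got = {(c.spacer, c.offset) for c in design.enumerate_candidates({"chr": seq}, p)}
                assert got == oracle_enumerate(seq, 500, strand, 150)

    def test_missing_chromosome(self, small_genome):
        genome, _ = small_genome
        p = PromoterRecord("p", "g", "chrX", 100, "+")
        with pytest.raises(KeyError):
            design.enumerate_candidates(genome, p)


class TestGenomeMatching:
    def test_planted_multi_locus_counts(self, rng):
        spacer = random_seq(rng, 20)
        filler = lambda: random_seq(rng, 300)
        seq = filler() + spacer + filler() + design.revcomp(spacer) + filler() + spacer + filler()
        genome = {"chr1": seq}
        assert design.count_genome_matches(spacer, genome) == 3
        assert design.count_genome_matches(design.revcomp(spacer), genome) == 3

    def test_bulk_matches_single_scan(self, small_genome, rng):
        genome, promoter = small_genome
        cands = design.enumerate_candidates(genome, promoter)
        spacers = sorted({c.spacer for c in cands})[:30] + [random_seq(rng, 20) for _ in range(10)]
        bulk = design.count_matches_bulk(spacers, genome)
        singles = [design.count_genome_matches(s, genome) for s in spacers]
        assert bulk.tolist() == singles

    def test_palindromic_site_counted_once(self):
        pal = "ACGTACGTACGTACGTACGT"
        assert design.revcomp(pal) == pal
        genome = {"c": "AT" * 50 + pal + "AT" * 50}
        assert design.count_genome_matches(pal, genome) == 1
        assert design.count_matches_bulk([pal], genome).tolist() == [1]

    def test_invalid_spacer_rejected(self):
        with pytest.raises(ValueError):
            design.count_genome_matches("ACGTN" * 4, {"c": "ACGT"})


class TestSelection:
    def _mk(self, offset, spacer=None):
        return design.GuideRecord(
            guide_id=f"g{offset}", spacer=spacer or ("A" * 19 + "C"), chrom="c",
            pam_site=0, strand="+", offset=offset, target_promoter_id="p",
            gene_id="g", category=design.CATEGORY_TARGETING, genome_hits=1,
        )

    def test_closest_to_tss_first(self):
        cands = [self._mk(o) for o in (-40, 10, 100, -5, 60, 20, -90, 35, -22, 3)]
        chosen = design.select_guides(cands, n=6)
        assert [g.offset for g in chosen] == [3, -5, 10, 20, -22, 35]

    def test_shortfall_warns_and_returns_all(self):
        cands = [self._mk(o) for o in (1, 2, 3)]
        with pytest.warns(design.DesignShortfallWarning):
            chosen = design.select_guides(cands, n=6)
        assert len(chosen) == 3

    def test_tie_break_positive_offset_first(self):
        cands = [self._mk(-5), self._mk(5)]
        chosen = design.select_guides(cands, n=1)
        assert chosen[0].offset == 5


class TestOligo:
    def test_template_bit_exact(self):
        assert design.emit_oligo("A" * 20) == (
            "AGGCACTTGCTCGTACGACGCGTCTCACACCG"
            + "AAAAAAAAAAAAAAAAAAAA"
            + "GTTTCGAGACGTTAAGGTGCCGGGCCCACAT"
        )

    def test_length_is_83(self):
        assert len(design.emit_oligo("ACGT" * 5)) == 32 + 20 + 31

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            design.emit_oligo("A" * 19)


@pytest.fixture(scope="module")
def toy_genome():
    from isoscreen import simulate

    cfg = simulate.SimConfig(
        seed=5, n_genes=3, two_promoter_fraction=1.0, gain_fraction=0.5,
        bidirectional_decoys=0, n_essential_genes=1, n_negative=10,
    )
    genome, promoters, truth, _ = simulate.make_genome_and_promoters(cfg)
    return genome, promoters, truth


class TestLibrary:

    def test_composition_arithmetic(self, toy_genome):
        genome, promoters, truth = toy_genome
        by_id = {p.promoter_id: p for p in promoters}
        targets = [by_id[p] for p in truth.index[truth["role"] == "target"]][:2]
        essential = [by_id[p] for p in truth.index[truth["role"] == "positive_control"]]
        lib = design.build_library(genome, targets, essential_promoters=essential, n_negative=10)
        counts = lib.category_counts()
        assert counts[design.CATEGORY_TARGETING] <= 12
        assert counts[design.CATEGORY_POSITIVE] <= 6
        assert counts[design.CATEGORY_NEGATIVE] == 10
        assert len(lib.guides) <= 28

    def test_zero_negative_controls(self, toy_genome):
        genome, promoters, truth = toy_genome
        by_id = {p.promoter_id: p for p in promoters}
        targets = [by_id[truth.index[truth["role"] == "target"][0]]]
        lib = design.build_library(genome, targets, n_negative=0)
        assert design.CATEGORY_NEGATIVE not in lib.category_counts()

    def test_unaltered_controls_designed_for_partner(self, toy_genome):
        genome, promoters, truth = toy_genome
        by_id = {p.promoter_id: p for p in promoters}
        targets = [by_id[p] for p in truth.index[(truth["role"] == "target")][:2]]
        partners = [
            by_id[p]
            for p in truth.index[truth["role"] == "unaltered"]
            if by_id[p].gene_id in {t.gene_id for t in targets}
        ]
        lib = design.build_library(genome, targets, unaltered_promoters=partners, n_negative=0)
        counts = lib.category_counts()
        assert counts.get(design.CATEGORY_UNALTERED, 0) >= len(partners)  # 6 per partner barring shortfall

    def test_duplicate_promoter_across_categories_rejected(self, toy_genome):
        genome, promoters, truth = toy_genome
        by_id = {p.promoter_id: p for p in promoters}
        t = by_id[truth.index[truth["role"] == "target"][0]]
        with pytest.raises(ValueError, match="duplicate"):
            design.build_library(genome, [t], essential_promoters=[t], n_negative=0)

    def test_deterministic_given_seed(self, toy_genome):
        genome, promoters, truth = toy_genome
        by_id = {p.promoter_id: p for p in promoters}
        targets = [by_id[p] for p in truth.index[truth["role"] == "target"]]
        a = design.build_library(genome, targets, n_negative=25, seed=11).to_frame()
        b = design.build_library(genome, targets, n_negative=25, seed=11).to_frame()
        assert a.to_csv() == b.to_csv()

    def test_negative_controls_nontargeting_gc_bounded(self, toy_genome):
        genome, *_ = toy_genome
        rng = np.random.default_rng(3)
        controls = design.make_negative_controls(15, genome, rng)
        assert len(set(controls)) == 15
        for s in controls:
            assert design.count_genome_matches(s, genome) == 0
            gc = (s.count("G") + s.count("C")) / 20
            assert 0.4 <= gc <= 0.6
            assert "TTTT" not in s

    def test_targeting_guides_verified_unique_and_in_window(self, toy_genome):
        genome, promoters, truth = toy_genome
        by_id = {p.promoter_id: p for p in promoters}
        targets = [by_id[p] for p in truth.index[truth["role"] == "target"]]
        lib = design.build_library(genome, targets, n_negative=0)
        for g in lib.guides:
            assert abs(g.offset) <= 150
            assert g.genome_hits == 1
            assert design.count_genome_matches(g.spacer, genome) == 1
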