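"""Junction arithmetic, in-silico PCR, and band-pattern genotyping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kindredscope.junction import (
    AssayConfig,
    BandPattern,
    Breakpoints,
    PrimerPair,
    characterize_junction,
    deletion_length,
    genotype_from_bands,
    in_silico_pcr,
    screen_cohort,
)
from kindredscope.simulate import DEFAULT_PRIMERS, simulate_sequences


class TestDeletionLength:
    def test_published_breakpoint_pair(self):
        bp = Breakpoints("19", 11_198_406, 11_201_384, build="hg19")
        assert deletion_length(bp) == 2_977

    def test_single_base_deletion(self):
        assert deletion_length(Breakpoints("1", 100, 102)) == 1

    def test_against_base_counting_oracle(self, rng):
        for _ in range(1_000):
            left = int(rng.integers(1, 10_000))
            right = left + int(rng.integers(2, 5_000))
            bp = Breakpoints("1", left, right)
            # oracle: count positions strictly between the retained bases
            deleted = [p for p in range(left + 1, right)]
            assert deletion_length(bp) == len(deleted)

    @given(shift=st.integers(min_value=0, max_value=10**7))
    @settings(max_examples=50, derandomize=True)
    def test_translation_invariant(self, shift):
        a = deletion_length(Breakpoints("1", 100, 400))
        b = deletion_length(Breakpoints("1", 100 + shift, 400 + shift))
        assert a == b

    def test_non_deletion_coordinates_rejected(self):
        with pytest.raises(ValueError):
            Breakpoints("1", 100, 101)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestCharacterizeJunction:
    def test_recovers_four_base_insert(self, rng):
        left, right = _random_seq(rng, 80), _random_seq(rng, 80)
        read = left[-30:] + "TTCG" + right[:30]
        insert, mh = characterize_junction(left, right, read)
        assert insert == "TTCG" and mh == 0

    def test_blunt_junction(self, rng):
        left = _random_seq(rng, 80) + "AC"
        right = "GT" + _random_seq(rng, 80)  # no terminal overlap by construction
        read = left[-25:] + right[:25]
        insert, mh = characterize_junction(left, right, read)
        assert insert == "" and mh == 0

    @pytest.mark.parametrize("overlap", [1, 2, 3, 5])
    def test_terminal_microhomology_detected(self, rng, overlap):
        # homopolymer cores make any overlap longer than the constructed one
        # impossible, whatever the shared sequence is
        shared = _random_seq(rng, overlap)
        left = "A" * 60 + shared
        right = shared + "C" * 60
        read = left[-25:] + right[:25]
        insert, mh = characterize_junction(left, right, read)
        assert insert == ""
        assert mh == overlap

    def test_unanchored_read_is_error(self, rng):
        with pytest.raises(ValueError, match="no anchor"):
            characterize_junction(
                _random_seq(rng, 60), _random_seq(rng, 60), _random_seq(rng, 50)
            )


class TestInSilicoPcr:
    def test_wild_type_yields_only_internal_product(self, allele_pair):
        products = in_silico_pcr(allele_pair.wild_type, DEFAULT_PRIMERS)
        assert products == [("internal", allele_pair.internal_product_bp)]

    def test_deleted_allele_yields_only_breakpoint_product(self, allele_pair):
        products = in_silico_pcr(allele_pair.deleted, DEFAULT_PRIMERS)
        assert products == [("flanking", allele_pair.flanking_product_bp)]

    def test_no_primer_sites_no_products(self, rng):
        assert in_silico_pcr(_random_seq(rng, 500), DEFAULT_PRIMERS) == []

    def test_product_size_by_position_arithmetic(self):
        from Bio.Seq import Seq

        fwd = "ACGTACGTACGTACGTA"
        rev = "TTGCATTGCATTGCATT"
        spacer = "C" * 50
        template = "G" * 20 + fwd + spacer + str(Seq(rev).reverse_complement()) + "G" * 20
        (name, size), = in_silico_pcr(template, [PrimerPair("p", fwd, rev)])
        assert size == len(fwd) + 50 + len(rev)

    def test_reverse_strand_searched(self):
        from Bio.Seq import Seq

        fwd = "ACGTACGTACGTACGTA"
        rev = "TTGCATTGCATTGCATT"
        template = "G" * 20 + fwd + "C" * 50 + str(Seq(rev).reverse_complement()) + "G" * 20
        flipped = str(Seq(template).reverse_complement())
        assert in_silico_pcr(template, [PrimerPair("p", fwd, rev)]) == in_silico_pcr(
            flipped, [PrimerPair("p", fwd, rev)]
        )

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError, match="ambiguity|unsupported"):
            PrimerPair("bad", "ACGTNACGTACGTACGT", "ACGTACGTACGTACGT")

    def test_internal_sites_strictly_inside_deletion_never_amplify_deleted(
        self, allele_pair
    ):
        names = {name for name, _ in in_silico_pcr(allele_pair.deleted, DEFAULT_PRIMERS)}
        assert "internal" not in names


class TestBandGenotyping:
    @pytest.mark.parametrize(
        "bands,call",
        [
            ({481, 254}, "wt/del"),
            ({481}, "wt/wt"),
            ({254}, "del/del"),
            (set(), "fail"),
            ({478, 260}, "wt/del"),  # within the +/-10 bp gel tolerance
            ({300}, "fail"),
        ],
    )
    def test_band_logic(self, bands, call):
        g = genotype_from_bands(BandPattern("s", bands), AssayConfig())
        assert g.call == call

    def test_pcr_then_genotype_recovers_constructed_genotypes(self, allele_pair):
        assay = AssayConfig()
        pairs = {
            "wt/wt": (allele_pair.wild_type, allele_pair.wild_type),
            "wt/del": (allele_pair.wild_type, allele_pair.deleted),
            "del/del": (allele_pair.deleted, allele_pair.deleted),
        }
        for expected, alleles in pairs.items():
            sizes = set()
            for seq in alleles:
                sizes |= {s for _, s in in_silico_pcr(seq, DEFAULT_PRIMERS)}
            assert genotype_from_bands(BandPattern("x", sizes), assay).call == expected


class TestCohortScreen:
    def test_family_screen_counts_carriers(self, kindred1, allele_pair):
        _, _, table = kindred1
        patterns = []
        for sid in table.subjects():
            dose = table.dose(sid, "LDLR:exon1del")
            alleles = [allele_pair.wild_type] * (2 - dose) + [allele_pair.deleted] * dose
            sizes = set()
            for seq in alleles:
                sizes |= {s for _, s in in_silico_pcr(seq, DEFAULT_PRIMERS)}
            patterns.append(BandPattern(sid, sizes))
        screen = screen_cohort(patterns, AssayConfig())
        assert len(screen.carriers) == 5
        assert sum(screen.counts.values()) == 12

    def test_all_wild_type_cohort_no_carriers(self):
        patterns = [BandPattern(f"s{i}", {481}) for i in range(641)]
        screen = screen_cohort(patterns, AssayConfig())
        assert screen.carriers == []
        assert screen.counts["wt/wt"] == 641

    def test_counts_match_brute_force_tally(self, rng):
        calls = {0: {481}, 1: {481, 254}, 2: {254}}
        doses = rng.integers(0, 3, size=200)
        patterns = [BandPattern(f"s{i}", set(calls[int(d)])) for i, d in enumerate(doses)]
        screen = screen_cohort(patterns, AssayConfig())
        assert screen.counts["wt/wt"] == int((doses == 0).sum())
        assert screen.counts["wt/del"] == int((doses == 1).sum())
        assert screen.counts["del/del"] == int((doses == 2).sum())
        assert len(screen.carriers) == int((doses > 0).sum())

    def test_duplicate_sample_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            screen_cohort(
                [BandPattern("a", {481}), BandPattern("a", {481})], AssayConfig()
            )
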