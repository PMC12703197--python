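import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from convar import (
    AmbiguityError,
    MultipleAlignment,
    ScanLevel,
    SiteProfilePair,
    SpeciesPartition,
    classify_site_type,
    classify_synonymy,
    label_con_div,
    scan_alignment,
    site_profiles,
    trace_nucleotide_source,
    translate_codon_alignment,
)
from convar.seqio import GENETIC_CODE, IdentityError

from _oracles import brute_force_scan


def aa_alignment(columns_by_species):
    """Build an amino-acid alignment from {species: row-string}."""
    ids = sorted(columns_by_species)
    return MultipleAlignment(ids, [columns_by_species[s] for s in ids], "amino_acid")


class TestSiteProfiles:
    def test_exclusive_profiles(self):
        aln = aa_alignment({"a1": "N", "a2": "N", "b1": "H", "b2": "H"})
        part = SpeciesPartition({"a1", "a2"}, {"b1", "b2"})
        p = site_profiles(aln, part, 1)
        assert p.set_a == {"N"} and p.set_b == {"H"} and p.scannable

    def test_ambiguity_marks_unscannable(self):
        aln = aa_alignment({"a1": "N", "b1": "X", "b2": "H"})
        part = SpeciesPartition({"a1"}, {"b1", "b2"})
        assert not site_profiles(aln, part, 1).scannable

    def test_excluded_species_ignored(self):
        aln = aa_alignment({"a1": "N", "b1": "H", "x1": "W"})
        part = SpeciesPartition({"a1"}, {"b1"}, {"x1"})
        p = site_profiles(aln, part, 1)
        assert "W" not in p.set_a | p.set_b

    def test_gap_is_a_state(self):
        aln = aa_alignment({"a1": "V", "b1": "I", "b2": "-"})
        part = SpeciesPartition({"a1"}, {"b1", "b2"})
        p = site_profiles(aln, part, 1)
        assert p.set_b == {"I", "-"} and p.scannable

    def test_missing_group_member(self):
        aln = aa_alignment({"a1": "N", "b1": "H"})
        part = SpeciesPartition({"a1"}, {"b1", "ghost"})
        with pytest.raises(IdentityError):
            site_profiles(aln, part, 1)


class TestTypeClassification:
    @pytest.mark.parametrize(
        "set_a,set_b,expected",
        [
            ({"N"}, {"H"}, 1),
            ({"V"}, {"I", "-"}, 2),
            ({"Q", "L"}, {"A"}, 3),
            ({"Q", "V", "L"}, {"A", "I"}, 4),
            ({"N"}, {"N", "H"}, None),
        ],
    )
    def test_examples(self, set_a, set_b, expected):
        p = SiteProfilePair(frozenset(set_a), frozenset(set_b), ScanLevel.AMINO_ACID)
        assert classify_site_type(p) == expected

    def test_empty_set_rejected(self):
        p = SiteProfilePair(frozenset(), frozenset("H"), ScanLevel.AMINO_ACID)
        with pytest.raises(ValueError):
            classify_site_type(p)

    @given(
        set_a=st.sets(st.sampled_from("ACDEFGHIKL-"), min_size=1, max_size=4),
        set_b=st.sets(st.sampled_from("ACDEFGHIKL-"), min_size=1, max_size=4),
    )
    @settings(derandomize=True, max_examples=200)
    def test_types_partition_disjoint_profiles(self, set_a, set_b):
        """Every disjoint non-empty profile gets exactly one type in 1..4."""
        p = SiteProfilePair(frozenset(set_a), frozenset(set_b), ScanLevel.AMINO_ACID)
        t = classify_site_type(p)
        if set_a & set_b:
            assert t is None
        else:
            assert t in (1, 2, 3, 4)
            assert label_con_div(t) == ("convergent" if t in (1, 2) else "divergent")

    def test_con_div_mapping_total(self):
        assert [label_con_div(t) for t in (1, 2, 3, 4)] == [
            "convergent", "convergent", "divergent", "divergent",
        ]
        with pytest.raises(ValueError):
            label_con_div(5)


class TestSynonymyAndSource:
    def test_nonsynonymous_snv(self):
        p = SiteProfilePair(
            frozenset({"AAT"}), frozenset({"CAT", "CAC"}), ScanLevel.CODON
        )
        assert classify_synonymy(p) == "nonsynonymous"
        trace = trace_nucleotide_source(p)
        assert trace.source == "ConSNV" and trace.position == 1

    def test_synonymous_same_residue(self):
        p = SiteProfilePair(frozenset({"CTT"}), frozenset({"CTC"}), ScanLevel.CODON)
        assert classify_synonymy(p) == "synonymous"
        assert trace_nucleotide_source(p).source == "ConSNV"

    def test_cnenv_derived_by_per_position_oracle(self):
        set_a, set_b = {"TCA", "AGT"}, {"ACT"}
        # oracle: translate every codon with the standard code
        aa_a = {GENETIC_CODE[c] for c in set_a}
        aa_b = {GENETIC_CODE[c] for c in set_b}
        assert aa_a == {"S"} and aa_b == {"T"} and not aa_a & aa_b
        # oracle: no single codon position is mutually exclusive
        for pos in range(3):
            assert {c[pos] for c in set_a} & {c[pos] for c in set_b}
        p = SiteProfilePair(frozenset(set_a), frozenset(set_b), ScanLevel.CODON)
        assert classify_synonymy(p) == "nonsynonymous"
        assert trace_nucleotide_source(p).source == "CNENV"

    def test_third_position_snv(self):
        p = SiteProfilePair(frozenset({"AAA"}), frozenset({"AAG"}), ScanLevel.CODON)
        assert trace_nucleotide_source(p).position == 3

    def test_untranslatable_codon_rejected(self):
        p = SiteProfilePair(frozenset({"ANT"}), frozenset({"CAT"}), ScanLevel.CODON)
        with pytest.raises(AmbiguityError):
            classify_synonymy(p)

    def test_source_partition_exhaustive(self, rng):
        """Every random mutually exclusive codon profile gets exactly one source."""
        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
        seen = set()
        for _ in range(300):
            a = frozenset(rng.choice(codons, size=int(rng.integers(1, 4)), replace=False))
            b = frozenset(rng.choice(codons, size=int(rng.integers(1, 4)), replace=False))
            if a & b:
                continue
            src = trace_nucleotide_source(SiteProfilePair(a, b, ScanLevel.CODON)).source
            assert src in ("ConSNV", "DivSNV", "CNENV")
            seen.add(src)
        assert seen == {"ConSNV", "DivSNV", "CNENV"}


class TestScanAlignment:
    def test_single_planted_column(self):
        rows = {
            "a1": "AAAANAAAAA", "a2": "AAAANAAAAA",
            "b1": "AAAAHAAAAA", "b2": "AAAAHAAAAA",
        }
        part = SpeciesPartition({"a1", "a2"}, {"b1", "b2"})
        rep = scan_alignment(aa_alignment(rows), part)
        assert [(v.site_index, v.variant_type) for v in rep.variants] == [(5, 1)]
        assert rep.total_sites == 10 and rep.continuous_sites == 0

    def test_adjacent_columns_filtered_as_continuous(self):
        rows = {
            "a1": "AAAANWAAAA", "a2": "AAAANWAAAA",
            "b1": "AAAAHGAAAA", "b2": "AAAAHGAAAA",
        }
        part = SpeciesPartition({"a1", "a2"}, {"b1", "b2"})
        rep = scan_alignment(aa_alignment(rows), part)
        # brute-force site-by-site confirms both sites are variants pre-filter
        assert brute_force_scan(rows, {"a1", "a2"}, {"b1", "b2"}, None) == {5: 1, 6: 1}
        assert rep.variants == [] and rep.continuous_sites == 2

    def test_run_threshold_configurable(self):
        rows = {
            "a1": "AAAANWAAAA", "a2": "AAAANWAAAA",
            "b1": "AAAAHGAAAA", "b2": "AAAAHGAAAA",
        }
        part = SpeciesPartition({"a1", "a2"}, {"b1", "b2"})
        rep = scan_alignment(aa_alignment(rows), part, run_threshold=3)
        assert len(rep.variants) == 2

    def test_scanner_equals_brute_force_oracle(self, rng):
        """Scanner agrees with a naive set-intersection scan on 200 fixtures."""
        for _ in range(200):
            n_sp = int(rng.integers(4, 13))
            n_sites = int(rng.integers(5, 301))
            ids = [f"s{i}" for i in range(n_sp)]
            alphabet = list("ACDEF-X")
            rows = {
                s: "".join(rng.choice(alphabet, size=n_sites)) for s in ids
            }
            n_a = int(rng.integers(1, n_sp))
            group_a, group_b = set(ids[:n_a]), set(ids[n_a:])
            expected = brute_force_scan(rows, group_a, group_b)
            rep = scan_alignment(
                aa_alignment(rows), SpeciesPartition(group_a, group_b)
            )
            got = {v.site_index: v.variant_type for v in rep.variants}
            assert got == expected

    def test_cross_level_consistency(self, rng):
        """Amino-acid variant sites equal nonsynonymous codon variant sites.

        The identity that lets codon-level exclusivity fully explain
        amino-acid exclusivity on the same genes.
        """
        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
        codons.append("---")
        for _ in range(30):
            n_sp = int(rng.integers(4, 9))
            n_cod = int(rng.integers(10, 60))
            ids = [f"s{i}" for i in range(n_sp)]
            # draw from a narrow codon pool so exclusive columns are common
            pool = list(rng.choice(codons, size=4, replace=False))
            rows = {
                s: "".join(rng.choice(pool, size=n_cod)) for s in ids
            }
            n_a = int(rng.integers(1, n_sp))
            part = SpeciesPartition(set(ids[:n_a]), set(ids[n_a:]))
            aln = MultipleAlignment(ids, [rows[s] for s in ids], "nucleotide")
            codon_rep = scan_alignment(aln, part, ScanLevel.CODON, run_threshold=None)
            aa_rep = scan_alignment(
                translate_codon_alignment(aln), part, run_threshold=None
            )
            nonsyn = {
                v.site_index for v in codon_rep.variants
                if v.synonymy == "nonsynonymous"
            }
            aa_sites = {v.site_index for v in aa_rep.variants}
            assert aa_sites == nonsyn

    def test_empty_alignment_rejected(self):
        aln = MultipleAlignment(["a", "b"], ["", ""], "amino_acid")
        with pytest.raises(Exception):
            scan_alignment(aln, SpeciesPartition({"a"}, {"b"}))
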