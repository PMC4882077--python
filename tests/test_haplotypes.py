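"""Haplotype typing, clone classification, and trace-superposition modelling."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itsloci.haplotypes import (
    CloneRecord,
    CoordinateMismatchError,
    ITSHaplotype,
    SpecificityUndefinedError,
    TruncatedCloneError,
    assign_haplotype_group,
    classify_clone,
    equal_ratio_chisq,
    find_polymorphic_sites,
    parsimony_informative_sites,
    superpose_traces,
    type_specific_sites,
)

TABLE3_COLUMNS = [39, 114, 122, 130, 145, 146, 200, 269, 334, 466, 475, 559, 649]


class TestPolymorphicSites:
    def test_builtin_three_types_have_13_polymorphic_columns(self, haplotypes):
        sites = find_polymorphic_sites(haplotypes)
        assert [s.column for s in sites] == TABLE3_COLUMNS

    def test_region_annotation_splits_8_1_4(self, haplotypes):
        regions = [s.region for s in find_polymorphic_sites(haplotypes)]
        assert regions.count("ITS1") == 8
        assert regions.count("5.8S") == 1
        assert regions.count("ITS2") == 4

    def test_a_vs_b_alone_differ_at_ten_columns(self, haplotypes):
        pair = [h for h in haplotypes if h.name in "AB"]
        cols = [s.column for s in find_polymorphic_sites(pair)]
        assert cols == [c for c in TABLE3_COLUMNS if c not in (269, 466, 475)]
        assert len(cols) == 10

    def test_identical_haplotypes_yield_no_sites(self):
        a = ITSHaplotype("x", {1: "A", 5: "G"})
        b = ITSHaplotype("y", {1: "A", 5: "G"})
        assert find_polymorphic_sites([a, b]) == []

    def test_unequal_alignment_lengths_rejected(self):
        a = ITSHaplotype("x", {1: "A"}, "ACGT")
        b = ITSHaplotype("y", {1: "A"}, "ACGTT")
        with pytest.raises(CoordinateMismatchError):
            find_polymorphic_sites([a, b])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.text(alphabet="ACGT-", min_size=6, max_size=6), min_size=2, max_size=5))
    def test_matches_pairwise_union_oracle(self, seqs):
        haps = [ITSHaplotype(f"h{i}", {}, s) for i, s in enumerate(seqs)]
        got = {s.column for s in find_polymorphic_sites(haps)}
        oracle = set()
        for h1, h2 in itertools.combinations(haps, 2):
            for col in range(1, 7):
                if h1.state(col) != h2.state(col):
                    oracle.add(col)
        assert got == oracle


class TestTypeSpecificSites:
    @pytest.mark.parametrize("focal,expected", [
        ("A", [39, 122, 130, 145, 146, 200]),
        ("B", [114, 334, 559, 649]),
        ("C", [269, 466, 475]),
    ])
    def test_diagnostic_sites_per_type(self, haplotypes, focal, expected):
        assert type_specific_sites(haplotypes, focal) == expected

    def test_undefined_below_three_haplotypes(self, haplotypes):
        with pytest.raises(SpecificityUndefinedError):
            type_specific_sites(haplotypes[:2], "A")


class TestCloneClassification:
    def test_exact_type_c_clone(self, haplotypes):
        seq = next(h.sequence for h in haplotypes if h.name == "C")
        rec = classify_clone(CloneRecord("c1", seq), haplotypes)
        assert (rec.assignment, rec.assigned_type) == ("type-exact", "C")
        assert rec.variant_positions == ()

    def test_single_substitution_makes_a_variant(self, haplotypes):
        seq = next(h.sequence for h in haplotypes if h.name == "A")
        mutated = seq[:59] + ("C" if seq[59] != "C" else "G") + seq[60:]  # column 60
        rec = classify_clone(CloneRecord("v1", mutated), haplotypes)
        assert (rec.assignment, rec.assigned_type) == ("type-variant", "A")
        assert rec.variant_positions == (60,)

    def test_constructed_chimera_a_c_with_breakpoint(self, haplotypes):
        by = {h.name: h for h in haplotypes}
        # A states up to column 200, C states from column 269 on
        seq = by["A"].sequence[:200] + by["C"].sequence[200:]
        rec = classify_clone(CloneRecord("x1", seq), haplotypes)
        assert rec.assignment == "chimera"
        assert rec.assigned_type == "A/C"
        assert rec.breakpoint == (200, 269)

    def test_scrambled_diagnostics_are_unassigned(self, haplotypes):
        by = {h.name: h for h in haplotypes}
        # alternate A/C states across diagnostic columns: no contiguous blocks
        chars = list(by["A"].sequence)
        for col in (122, 146):
            chars[col - 1] = by["C"].state(col)
        for col in (269, 466):
            chars[col - 1] = by["C"].state(col)
        chars[130 - 1] = by["A"].state(130)
        chars[475 - 1] = by["A"].state(475)
        rec = classify_clone(CloneRecord("u1", "".join(chars)), haplotypes)
        assert rec.assignment == "unassigned"

    def test_truncated_clone_is_an_error(self, haplotypes):
        with pytest.raises(TruncatedCloneError):
            classify_clone(CloneRecord("t1", "ACGT" * 40), haplotypes)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_total_and_deterministic_on_random_clones(self, haplotypes, seed):
        import random
        rng = random.Random(seed)
        by = {h.name: h for h in haplotypes}
        chars = list(by[rng.choice("ABC")].sequence)
        for _ in range(rng.randrange(5)):
            i = rng.randrange(len(chars))
            if chars[i] != "-":
                chars[i] = rng.choice("ACGT")
        clone = CloneRecord("r", "".join(chars))
        first = classify_clone(clone, haplotypes)
        second = classify_clone(clone, haplotypes)
        assert first.assignment in {"type-exact", "type-variant", "chimera", "unassigned"}
        assert first == second


class TestEqualRatioChisq:
    def test_published_clone_counts(self):
        res = equal_ratio_chisq([59, 47, 58])
        assert round(res.statistic, 2) == 1.62
        assert res.df == 2
        assert round(res.pvalue, 2) == 0.44

    def test_perfect_fit(self):
        res = equal_ratio_chisq([10, 10, 10])
        assert res.statistic == 0
        assert res.pvalue == 1

    def test_two_class_closed_form(self):
        res = equal_ratio_chisq([38, 31])
        assert res.statistic == pytest.approx(2 * 3.5 ** 2 / 34.5, abs=1e-12)
        assert round(res.statistic, 3) == 0.710

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            equal_ratio_chisq([0, 0])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.integers(0, 500), min_size=2, max_size=5).filter(lambda c: sum(c) > 0))
    def test_matches_hand_computation_and_p_monotone(self, counts):
        res = equal_ratio_chisq(counts)
        e = sum(counts) / len(counts)
        assert res.statistic == pytest.approx(sum((c - e) ** 2 / e for c in counts), abs=1e-9)
        bigger = equal_ratio_chisq([c * 3 + i for i, c in enumerate(counts)])
        if bigger.statistic > res.statistic:
            assert bigger.pvalue <= res.pvalue + 1e-12


class TestParsimonyInformativeSites:
    def test_nineteen_specimen_matrix_all_nine_informative(self):
        # 9-column state vectors of the three ITS haplotype groups, with the
        # published per-group specimen counts (4 A, 4 B, 14 single-type C)
        a = "TAAGATGAT"
        b = "-GGATCGAT"
        c = "-GGATCAC-"
        seqs = [a] * 4 + [b] * 4 + [c] * 14
        assert parsimony_informative_sites(seqs) == list(range(1, 10))

    def test_identical_sequences_give_none(self):
        assert parsimony_informative_sites(["ACGT"] * 4) == []

    def test_minimal_example(self):
        assert parsimony_informative_sites(["AAT", "AAT", "ACT", "ACT"]) == [2]

    def test_fewer_than_four_sequences_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert parsimony_informative_sites(["AAT", "ACT", "AGT"]) == []

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.text(alphabet="AC-", min_size=4, max_size=4), min_size=4, max_size=8))
    def test_brute_force_oracle(self, seqs):
        got = parsimony_informative_sites(seqs)
        oracle = []
        for col in range(4):
            states = [s[col] for s in seqs]
            shared = {x for x in set(states) if states.count(x) >= 2}
            if len(shared) >= 2:
                oracle.append(col + 1)
        assert got == oracle


class TestHaplotypeGroupAssignment:
    NINE = [39, 122, 130, 145, 146, 200, 269, 466, 475]

    def test_pure_groups(self, haplotypes):
        for name, states in [("A", "TAAGATGAT"), ("B", "-GGATCGAT"), ("C", "-GGATCAC-")]:
            obs = dict(zip(self.NINE, states))
            assert assign_haplotype_group(obs, haplotypes) == (name, (name,))

    def test_superposed_a_b_specimen(self, haplotypes):
        obs = dict(zip(self.NINE, ["T/-", "A/G", "A/G", "G/A", "A/T", "T/C", "G", "A", "T"]))
        group, parts = assign_haplotype_group(obs, haplotypes)
        assert group == "mixed" and parts == ("A", "B")

    def test_triple_superposition(self, haplotypes):
        obs = dict(zip(self.NINE, ["T/-", "A/G", "A/G", "G/A", "A/T", "T/C",
                                   "G/A", "A/C", "T/-"]))
        assert assign_haplotype_group(obs, haplotypes) == ("mixed", ("A", "B", "C"))

    def test_unassignable_states_raise(self, haplotypes):
        obs = dict(zip(self.NINE, ["T", "G", "G", "A", "T", "C", "G", "A", "T"]))
        with pytest.raises(ValueError):
            assign_haplotype_group(obs, haplotypes)


class TestTraceSuperposition:
    def test_b_specific_g_at_334_is_masked_by_frame_shift(self, haplotypes):
        profile = superpose_traces(haplotypes)
        assert profile.masked_columns == (334,)
        assert profile.detectable[334] is False
        # the other twelve polymorphisms remain visible as extra peaks
        assert sum(profile.detectable.values()) == 12

    def test_single_haplotype_single_peaks(self, haplotypes):
        profile = superpose_traces(haplotypes[:1])
        assert all(len(set(col)) == 1 for col in profile.columns)
        assert profile.masked_columns == ()

    def test_deletion_shifts_downstream_contributions(self):
        base = "ACGTACGTACGTACGTACGT"
        with_del = base[:9] + "-" + base[10:]
        h1 = ITSHaplotype("full", {}, base)
        h2 = ITSHaplotype("del", {}, with_del)
        profile = superpose_traces([h1, h2])
        # downstream of the deletion the shorter sequence reads one base ahead
        assert profile.shifts["del"][-1] == -1
        assert len(profile.columns[-1]) == 1  # only the full sequence reaches the end
        assert all(len(col) == 2 for col in profile.columns[:-1])

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.text(alphabet="ACGT", min_size=8, max_size=8), min_size=2, max_size=4))
    def test_no_masking_without_indels(self, seqs):
        haps = [ITSHaplotype(f"h{i}", {}, s) for i, s in enumerate(seqs)]
        profile = superpose_traces(haps)
        assert profile.masked_columns == ()
        # gap-free superposition is the column-wise state multiset
        for t, col in enumerate(profile.columns):
            assert col == tuple(sorted(s[t] for s in seqs))
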