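"""Primer-evaluation module: IUPAC semantics, scanning, patterns."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thaumflow.errors import (
    InconsistentPatternError,
    InputSizeError,
    InvalidAlphabetError,
    PatternParseError,
)
from thaumflow.primers import (
    CREN529F,
    CREN981R,
    IUPAC_SETS,
    MATCH,
    DegeneratePrimer,
    MismatchPattern,
    TemplateRecord,
    align_primer,
    expand_iupac,
    parse_pattern,
    position_matches,
    reconstruct_site,
    render_pattern,
    reverse_complement,
    summarize_groups,
)

from conftest import brute_force_align, random_iupac_primer, random_template


class TestIupac:
    @pytest.mark.parametrize(
        "code,expected",
        [("W", {"A", "T"}), ("N", {"A", "C", "G", "T"}), ("A", {"A"}),
         ("y", {"C", "T"}), ("B", {"C", "G", "T"})],
    )
    def test_expansion(self, code, expected):
        assert expand_iupac(code) == frozenset(expected)

    def test_unknown_character_names_offender(self):
        with pytest.raises(InvalidAlphabetError, match="'X'.*position 7"):
            expand_iupac("X", position=7)

    @pytest.mark.parametrize(
        "p,t,expected",
        [("W", "T", True), ("Y", "A", False), ("K", "K", True),
         ("A", "A", True), ("N", "W", True), ("W", "N", False)],
    )
    def test_subset_match_rule(self, p, t, expected):
        assert position_matches(p, t) is expected

    def test_subset_rule_equals_brute_force_expansion(self):
        for p in IUPAC_SETS:
            for t in IUPAC_SETS:
                brute = all(b in IUPAC_SETS[p] for b in IUPAC_SETS[t])
                assert position_matches(p, t) is brute

    def test_reverse_complement_is_involution_and_base_correct(self):
        assert reverse_complement("GCWATG") == "CATWGC"
        for s in ("ACGT", "RYSWKM", "BDHVN"):
            assert reverse_complement(reverse_complement(s)) == s


class TestPrimerFixtures:
    def test_primer_lengths(self):
        assert len(CREN529F) == 24
        assert len(CREN981R) == 21

    def test_empty_primer_rejected(self):
        with pytest.raises(InputSizeError):
            DegeneratePrimer("bad", "", "forward")


class TestAlign:
    def test_self_match_is_perfect(self):
        site_seq = "".join(min(IUPAC_SETS[c]) for c in CREN529F.sequence)
        site = align_primer(CREN529F, TemplateRecord("t", site_seq))
        assert site.pattern.count == 0
        assert site.start == 0
        assert len(site.pattern) == 24

    def test_published_three_mismatch_site(self, panel):
        """The Sargasso metagenome contig with G/A/C at primer positions 3/18/21."""
        row = next(r for r in panel.rows if "2097946" in r.name)
        site = align_primer(CREN529F, row.template)
        assert site.pattern.count == 3
        assert site.pattern.mismatch_positions() == (3, 18, 21)
        assert [site.pattern.tokens[i - 1] for i in (3, 18, 21)] == ["G", "A", "C"]

    def test_template_shorter_than_primer_raises(self):
        with pytest.raises(InputSizeError):
            align_primer(CREN529F, TemplateRecord("short", "ACGT"))

    def test_reverse_primer_reported_in_primer_coordinates(self):
        """A planted single mismatch at primer position 16 of the reverse
        primer must surface at token 16, not at the plus-strand position."""
        tokens = [MATCH] * 21
        tokens[15] = "A"  # primer pos 16 is T; A is incompatible
        pattern = MismatchPattern(CREN981R.name, tuple(tokens))
        site_seq = reconstruct_site(CREN981R, pattern)
        template = TemplateRecord("t", "CCCCCCCC" + reverse_complement(site_seq) + "CCCCCCCC")
        found = align_primer(CREN981R, template)
        assert found.strand == "-"
        assert found.pattern.tokens == pattern.tokens

    def test_agrees_with_brute_force_on_random_pairs(self, rng):
        """Oracle equivalence on 200 random primer/template pairs."""
        for k in range(200):
            primer = random_iupac_primer(rng, f"p{k}")
            template = random_template(rng, f"t{k}")
            expected_count, expected_start = brute_force_align(primer, template)
            site = align_primer(primer, template)
            assert site.pattern.count == expected_count
            assert site.start == expected_start

    def test_incompatible_substitution_never_lowers_count(self, rng):
        """Monotonicity on decoy-free templates: corrupting one matched base
        of the unique binding site raises the minimum mismatch count by one."""
        from thaumflow.simulate import SimConfig, simulate_templates

        for primer in (CREN529F, CREN981R):
            cfg = SimConfig(seed=int(rng.integers(2**31)))
            records, truth = simulate_templates(cfg, primer, {"g": [0, 1, 2, 3]})
            for rec in records:
                before = align_primer(primer, rec)
                assert before.pattern.count == truth[rec.id]
                L = len(primer)
                matched = [i for i, t in enumerate(before.pattern.tokens) if t == MATCH]
                i = matched[int(rng.integers(len(matched)))]
                pos = before.start + (i if primer.orientation.value == "forward" else L - 1 - i)
                pc = primer.sequence[i]
                bad = sorted(set("ACGT") - set(expand_iupac(pc)))
                if not bad:
                    continue
                sub = bad[0] if primer.orientation.value == "forward" else reverse_complement(bad[0])
                seq = rec.sequence[:pos] + sub + rec.sequence[pos + 1:]
                after = align_primer(primer, TemplateRecord(rec.id, seq))
                assert after.pattern.count == before.pattern.count + 1


class TestPatterns:
    def test_render_no_mismatch_dialect(self):
        assert render_pattern(MismatchPattern("x", (MATCH,) * 21)) == "No mismatch"

    def test_render_single_mismatch(self):
        tokens = [MATCH] * 24
        tokens[20] = "T"
        expected = "= = = = = = = = = = = = = = = = = = = = T = = ="
        assert render_pattern(MismatchPattern("x", tuple(tokens))) == expected

    def test_parse_no_mismatch(self):
        pat = parse_pattern("No mismatch", CREN529F)
        assert pat.count == 0 and len(pat) == 24

    def test_parse_counts_tokens(self):
        pat = parse_pattern("= = G = = = = = = = = = = = = = = A = = C = = =", CREN529F)
        assert pat.count == 3

    def test_parse_token_count_mismatch(self):
        with pytest.raises(PatternParseError, match="expected 21.*got 20"):
            parse_pattern(" ".join(["="] * 20), CREN981R)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from([MATCH, "A", "C", "G", "T"]), min_size=24, max_size=24))
    def test_parse_render_round_trip(self, tokens):
        pat = MismatchPattern(CREN529F.name, tuple(tokens))
        assert parse_pattern(render_pattern(pat), CREN529F).tokens == pat.tokens


class TestReconstruct:
    def test_all_match_reconstruction_is_first_lexicographic(self):
        site = reconstruct_site(CREN529F, MismatchPattern("f", (MATCH,) * 24))
        assert site == "GCAATGACAGACTTTGTCATAATG"

    def test_compatible_token_rejected(self):
        tokens = [MATCH] * 24
        tokens[2] = "T"  # primer pos 3 is W = {A,T}; T is not a mismatch
        with pytest.raises(InconsistentPatternError):
            reconstruct_site(CREN529F, MismatchPattern("f", tuple(tokens)))

    def test_round_trip_reproduces_every_published_pattern(self, panel):
        """parse -> reconstruct -> embed -> align reproduces the printed
        mismatch count for every panel row and both primers (46 patterns)."""
        checked = 0
        for row in panel.rows:
            for pname, pattern in row.patterns.items():
                site = align_primer(panel.primers[pname], row.template)
                assert site.pattern.count == pattern.count, (row.name, pname)
                checked += 1
        assert checked == 46

    def test_reverse_primer_reconstruction_count(self, panel):
        """Soil-lineage reference: five incompatible bases for the reverse
        primer, independently counted from the printed tokens."""
        row = next(r for r in panel.rows if "gargensis" in r.name)
        pat = row.patterns[CREN981R.name]
        independent = sum(1 for t in pat.tokens if t != MATCH)
        assert independent == 5
        site_seq = reconstruct_site(CREN981R, pat)
        template = TemplateRecord("t", "CCCCC" + reverse_complement(site_seq) + "CCCCC")
        assert align_primer(CREN981R, template).pattern.count == 5


class TestGroupSummary:
    def test_shallow_cluster_statistics(self, panel):
        results = [
            ("Shallow cluster", "Cren529F", c)
            for c in panel.counts("Shallow cluster", "Cren529F")
        ]
        (s,) = summarize_groups(results)
        assert s.n == 6
        assert s.mean == pytest.approx(1.0)
        assert s.sd == pytest.approx(1.095, abs=0.001)
        assert s.se == pytest.approx(0.447, abs=0.001)
        assert s.perfect_fraction == pytest.approx(2 / 6)

    def test_all_perfect_group(self):
        (s,) = summarize_groups([("deep", "f", 0)] * 4)
        assert (s.mean, s.sd, s.se, s.perfect_fraction) == (0.0, 0.0, 0.0, 1.0)

    def test_singleton_group_sd_convention(self):
        (s,) = summarize_groups([("solo", "f", 3)])
        assert (s.n, s.mean, s.sd, s.se) == (1, 3.0, 0.0, 0.0)

    def test_empty_input_gives_empty_summary(self):
        assert summarize_groups([]) == []

    def test_se_never_exceeds_sd(self, rng):
        counts = [("g", "p", int(c)) for c in rng.integers(0, 5, size=12)]
        (s,) = summarize_groups(counts)
        assert s.se <= s.sd
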