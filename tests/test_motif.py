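"""Unit and property tests for patterns, tolerance scoring and the classifier."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from brctscan.motif import (
    AMINO_ACIDS,
    Category,
    HYDROPHOBIC,
    MINUS4_POLAR_EXCLUDED,
    PatternParseError,
    PhosphoWindow,
    classify_compatibility,
    count_matching_kmers,
    default_tolerance_table,
    load_pattern_config,
    match_window,
    parse_prosite_pattern,
    subsite_score,
)

from conftest import make_window

AA = sorted(AMINO_ACIDS)
residue = st.sampled_from(AA)


@st.composite
def windows(draw, context_mode="short"):
    res = {off: draw(residue) for off in range(-6, 3)}
    res[0] = draw(st.sampled_from("ST"))
    return PhosphoWindow(res, context_mode=context_mode)


# --- parsing ---------------------------------------------------------------


class TestParsePrositePattern:
    def test_brct2_pattern_structure(self):
        p = parse_prosite_pattern("[FILMV]-x-x-[ST]-P")
        assert len(p) == 5
        kinds = [e.kind for e in p.elements]
        assert kinds == ["residue-class", "any", "any", "residue-class", "literal"]
        assert p.elements[0].allowed == frozenset("FILMV")
        assert p.phospho_index == 3
        assert p.elements[4].allowed == frozenset("P")

    def test_brct1_pattern_structure(self):
        p = parse_prosite_pattern("[FILMV]-[FILMV]-[FILMV]-x-x-[ST]-P")
        assert len(p) == 7
        assert p.phospho_index == 5

    def test_round_trip_is_canonical(self):
        text = "[FILMV]-x-x-[ST]-P"
        p = parse_prosite_pattern(text)
        assert p.to_prosite() == text
        assert parse_prosite_pattern(p.to_prosite()).to_prosite() == text

    @pytest.mark.parametrize(
        "bad",
        [
            "[FILMV-x",          # unbalanced bracket
            "[FILMV]-x-FILMV]",  # unbalanced the other way
            "[FILMV]-x-[SZ]-P",  # non-standard code
            "[FILMV]-x-x-P",     # no phospho element
            "[ST]-x-[ST]-P",     # two phospho elements
            "[FILMV]--x-[ST]",   # empty token
        ],
    )
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises(PatternParseError):
            parse_prosite_pattern(bad)

    def test_config_file_loading(self, tmp_path):
        cfg = tmp_path / "patterns.cfg"
        cfg.write_text(
            "# custom patterns\nmini = [ST]-P\nbrct2like = [FILMV]-x-x-[ST]-P\n"
        )
        with open(cfg) as handle:
            patterns = load_pattern_config(handle)
        assert set(patterns) == {"mini", "brct2like"}
        assert len(patterns["mini"]) == 2


# --- matching --------------------------------------------------------------


class TestMatchWindow:
    def test_rhno1_window_matches_brct1(self, patterns):
        # ...PVLVKD-pT-P, the RHNO1-Thr202 context
        w = make_window(minus6="P", minus5="V", minus4="L", minus3="V",
                        minus2="K", minus1="D", phospho="T", plus1="P", plus2="E")
        assert match_window(w, patterns["BRCT1"])
        assert match_window(w, patterns["BRCT2"])

    def test_rad9_window_fails_strict(self, patterns):
        # VLAED-pS-E: -3 is Ala (not in [FILMV]) and +1 is not Pro
        w = make_window()
        assert not match_window(w, patterns["BRCT1"])
        assert not match_window(w, patterns["BRCT2"])

    @given(windows())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bare_phospho_element_matches_everything(self, w):
        assert match_window(w, parse_prosite_pattern("[ST]-x"))

    def test_padding_never_matches(self, patterns):
        w = PhosphoWindow(
            {-6: "-", -5: "-", -4: "-", -3: "-", -2: "-", -1: "A",
             0: "T", 1: "P", 2: "-"}
        )
        assert not match_window(w, patterns["BRCT2"])

    def test_too_long_pattern_is_an_error(self):
        p = parse_prosite_pattern("x-x-x-x-x-x-x-[ST]-x")  # needs offset -7
        with pytest.raises(ValueError):
            match_window(make_window(), p)


class TestCountMatchingKmers:
    def test_analytic_counts(self, patterns):
        assert count_matching_kmers(patterns["BRCT2"]) == 4_000
        assert count_matching_kmers(patterns["BRCT1"]) == 100_000

    def test_matches_explicit_enumeration_on_short_pattern(self):
        # Small enough to enumerate naively: [DE]-[ST]-P over 20^3 words
        p = parse_prosite_pattern("[DE]-[ST]-P")
        brute = sum(
            1
            for word in itertools.product(AA, repeat=3)
            if word[0] in "DE" and word[1] in "ST" and word[2] == "P"
        )
        assert count_matching_kmers(p) == brute == 4


# --- tolerance table -------------------------------------------------------


class TestSubsiteScore:
    def test_native_rad9_window_is_tight_everywhere(self):
        score = subsite_score(make_window())
        assert all(c is Category.TIGHT for c in score.categories.values())
        assert score.total == 8

    @pytest.mark.parametrize(
        "offset,residue,category",
        [
            (-3, "V", Category.TIGHT),
            (-3, "F", Category.REDUCED),
            (-1, "K", Category.ABOLISHED),
            (-1, "L", Category.ABOLISHED),
            (-1, "S", Category.TIGHT),
            (-4, "F", Category.REDUCED),
            (-4, "I", Category.REDUCED),
            (-5, "D", Category.REDUCED),
            (-5, "Q", Category.TIGHT),
        ],
    )
    def test_panel_categories(self, offset, residue, category):
        kwargs = {f"minus{-offset}": residue}
        score = subsite_score(make_window(**kwargs))
        assert score.categories[offset] is category

    def test_untested_residue_is_unknown_scored_as_reduced(self):
        score = subsite_score(make_window(minus5="W"))
        assert score.categories[-5] is Category.UNKNOWN
        assert score.categories[-5].score == Category.REDUCED.score

    def test_table_rejects_unscored_offsets(self):
        from brctscan.motif import ToleranceTable

        with pytest.raises(ValueError):
            ToleranceTable(entries={(-2, "A"): Category.TIGHT},
                           native={-5: "V", -4: "L", -3: "A", -1: "D"})


# --- classifier ------------------------------------------------------------


class TestClassifyCompatibility:
    @pytest.mark.parametrize(
        "kwargs,context,expected",
        [
            # RAD9 pS387: -3 Ala restricts to BRCT1
            (dict(), "short", {"BRCT1"}),
            # Sld3 pT650: -4 Glu excludes BRCT1
            (dict(minus5="T", minus4="E", minus3="L", minus2="P", minus1="D",
                  phospho="T", plus1="P"), "short", {"BRCT2"}),
            # Mdb1 pT113: -4 Thr (small polar) excludes BRCT1 in short context
            (dict(minus5="M", minus4="T", minus3="V", minus2="P", minus1="N",
                  phospho="T", plus1="P"), "short", {"BRCT2"}),
            # Treslin pS1001: hydrophobic -4/-3, compatible with both
            (dict(minus5="G", minus4="V", minus3="V", minus2="E", minus1="E",
                  phospho="S", plus1="P"), "short", {"BRCT1", "BRCT2"}),
            # Treslin pT969: small-polar -4 tolerated only in long context
            (dict(minus5="K", minus4="S", minus3="V", minus2="A", minus1="E",
                  phospho="T", plus1="P"), "short", {"BRCT2"}),
            (dict(minus5="K", minus4="S", minus3="V", minus2="A", minus1="E",
                  phospho="T", plus1="P"), "long", {"BRCT1", "BRCT2"}),
            # Mdb1 SDT site: no hydrophobic -3, neither domain
            (dict(minus5="E", minus4="G", minus3="D", minus2="H", minus1="S",
                  phospho="S", plus1="D"), "short", set()),
            # Crb2-pT235-like synthetic window: -4 Arg restricts to BRCT2
            (dict(minus5="A", minus4="R", minus3="L", minus2="N", minus1="D",
                  phospho="T", plus1="P"), "short", {"BRCT2"}),
        ],
    )
    def test_reported_binding_outcomes(self, kwargs, context, expected):
        compat = classify_compatibility(make_window(**kwargs), context_mode=context)
        assert compat.compatible == frozenset(expected)

    def test_excluded_domain_always_has_a_trace(self):
        compat = classify_compatibility(make_window(minus4="R"))
        assert compat.compatible == frozenset()
        excluding = [r for r in compat.trace if "excluded" in r.effect]
        assert excluding

    def test_extrapolated_minus4_exclusions_are_flagged(self):
        compat = classify_compatibility(make_window(minus4="K"))
        assert any("extrapolated" in r.effect for r in compat.trace)
        observed = classify_compatibility(make_window(minus4="E"))
        assert not any("extrapolated" in r.effect for r in observed.trace)

    def test_truncated_context_is_flagged_but_classified(self):
        w = PhosphoWindow(
            {-6: "-", -5: "-", -4: "-", -3: "-", -2: "A", -1: "T",
             0: "T", 1: "P", 2: "-"}
        )
        compat = classify_compatibility(w)
        assert "truncated context" in compat.flags
        assert compat.compatible == frozenset()

    def test_preferred_requires_membership(self):
        w = make_window()  # {BRCT1}
        compat = classify_compatibility(w, preferred_evidence="BRCT1")
        assert compat.preferred == "BRCT1"
        compat = classify_compatibility(w, preferred_evidence="BRCT2")
        assert compat.preferred == "none"

    def test_phosphotyrosine_rejected(self):
        with pytest.raises(ValueError):
            make_window(phospho="Y")

    @given(windows())
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_compatible_is_subset_of_both_domains(self, w):
        compat = classify_compatibility(w)
        assert compat.compatible <= {"BRCT1", "BRCT2"}

    @given(windows(), st.sampled_from(sorted(MINUS4_POLAR_EXCLUDED)))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_large_polar_minus4_always_excludes_brct1(self, w, polar):
        res = dict(w.residues)
        res[-4] = polar
        compat = classify_compatibility(PhosphoWindow(res, w.context_mode))
        assert "BRCT1" not in compat.compatible

    @given(windows(), st.sampled_from([-5, -4, -3, -1]), residue, residue)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_brct1_monotone_in_tolerance_category(self, w, offset, r_low, r_high):
        """A strictly better-tolerated residue never costs BRCT1 membership.

        The tolerance panel probed BRCT1-mediated binding, so monotonicity is
        a BRCT1 statement; BRCT2 can legitimately drop when moving to the
        BRCT1-specific -3 alanine.
        """
        table = default_tolerance_table()
        if not table.category(offset, r_low).score < table.category(offset, r_high).score:
            return
        low = dict(w.residues)
        high = dict(w.residues)
        low[offset], high[offset] = r_low, r_high
        compat_low = classify_compatibility(PhosphoWindow(low, w.context_mode))
        compat_high = classify_compatibility(PhosphoWindow(high, w.context_mode))
        if "BRCT1" in compat_low.compatible:
            assert "BRCT1" in compat_high.compatible

    @given(windows())
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_strict_brct1_implies_strict_brct2(self, w):
        from brctscan.motif import builtin_patterns

        pats = builtin_patterns()
        if match_window(w, pats["BRCT1"]):
            assert match_window(w, pats["BRCT2"])
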