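"""Fatty-acid nomenclature, PLFA quantification and biomarker logic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spongeflux.fixtures import bacteria_food_chromatogram
from spongeflux.plfa import (
    ExtractionRecord,
    FattyAcid,
    FattyAcidParseError,
    PLFAPeak,
    classify,
    correct_fame_delta,
    detect_de_novo,
    parse_fatty_acid,
    plfa_backgrounds,
    plfa_concentration,
    profile_summary,
    uncorrect_fame_delta,
)


def _ext(sample_id="s1", gs=1.0, f=1.0, a19=1.0, c19=1.0, d_meth=-40.0):
    return ExtractionRecord(sample_id, gs, f, a19, c19, d_meth)


class TestParser:
    @pytest.mark.parametrize(
        "name, chain, db, omega, prefix",
        [
            ("C20:5ω3", 20, 5, 3, ""),
            ("Cy-C17:0", 17, 0, None, "Cy"),
            ("i-C25:1ω7", 25, 1, 7, "i"),
            ("aiC15:0", 15, 0, None, "ai"),
            ("me-c18:0", 18, 0, None, "Me"),
            ("Cy-C19", 19, 0, None, "Cy"),  # missing :Y read as saturated
            ("C16:1w7", 16, 1, 7, ""),  # ascii omega
        ],
    )
    def test_grammar(self, name, chain, db, omega, prefix):
        fa = parse_fatty_acid(name)
        assert (fa.chain_length, fa.double_bonds, fa.omega_position, fa.prefix) == (
            chain, db, omega, prefix,
        )

    def test_canonical_round_trip_idempotent(self):
        for name in ["C20:5ω3", "cy-c17:0", "i-C25:1ω7", "ME-C16:0"]:
            fa = parse_fatty_acid(name)
            assert parse_fatty_acid(fa.name) == fa

    @pytest.mark.parametrize("bad", ["", "X20:5", "C9:0", "C20:9", "zz-C16:0"])
    def test_rejects_bad_tokens(self, bad):
        with pytest.raises(FattyAcidParseError) as err:
            parse_fatty_acid(bad)
        assert err.value.token == bad


class TestConcentration:
    def test_reference_value(self):
        # equal areas, unit masses: only the 19/20 methyl factor remains
        peak = PLFAPeak("s1", FattyAcid(19), 1.0, -30.0)
        assert plfa_concentration(peak, _ext()) == pytest.approx(0.95)

    def test_zero_area(self):
        peak = PLFAPeak("s1", FattyAcid(16), 0.0, -30.0)
        assert plfa_concentration(peak, _ext()) == 0.0

    def test_halving_recovery_doubles_concentration(self):
        peak = PLFAPeak("s1", FattyAcid(16), 2.0, -30.0)
        full = plfa_concentration(peak, _ext(f=1.0))
        half = plfa_concentration(peak, _ext(f=0.5))
        assert half == pytest.approx(2 * full)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(min_value=1e-3, max_value=1e6),
        st.floats(min_value=1e-2, max_value=1e3),
        st.floats(min_value=0.05, max_value=1.0),
        st.floats(min_value=2.0, max_value=10.0),
    )
    def test_homogeneity(self, area, gs, f, k):
        """Degree 1 in area, degree -1 in sample mass and recovery."""
        peak = PLFAPeak("s1", FattyAcid(16), area, -30.0)
        base = plfa_concentration(peak, _ext(gs=gs, f=f))
        scaled_area = plfa_concentration(
            PLFAPeak("s1", FattyAcid(16), area * k, -30.0), _ext(gs=gs, f=f)
        )
        assert scaled_area == pytest.approx(k * base, rel=1e-9)
        scaled_gs = plfa_concentration(peak, _ext(gs=gs * k, f=f))
        assert scaled_gs == pytest.approx(base / k, rel=1e-9)


class TestFameCorrection:
    def test_fixed_point(self):
        peak = PLFAPeak("s1", FattyAcid(16), 1.0, -40.0)
        assert correct_fame_delta(peak, _ext(d_meth=-40.0)) == pytest.approx(-40.0)

    def test_reference_value(self):
        peak = PLFAPeak("s1", FattyAcid(15), 1.0, 0.0)
        assert correct_fame_delta(peak, _ext(d_meth=-40.0)) == pytest.approx(
            8.0 / 3.0, abs=1e-3
        )

    def test_correction_shrinks_with_chain_length(self):
        mags = []
        for n in (12, 16, 20, 28):
            peak = PLFAPeak("s1", FattyAcid(n), 1.0, -30.0)
            mags.append(abs(correct_fame_delta(peak, _ext(d_meth=-40.0)) - (-30.0)))
        assert mags == sorted(mags, reverse=True)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(min_value=-50.0, max_value=5000.0),
        st.integers(min_value=10, max_value=34),
        st.floats(min_value=-60.0, max_value=-20.0),
    )
    def test_inverse_mixing_round_trip(self, d_plfa, n, d_meth):
        fame = uncorrect_fame_delta(d_plfa, n, d_meth)
        peak = PLFAPeak("s1", FattyAcid(n), 1.0, fame)
        assert correct_fame_delta(peak, _ext(d_meth=d_meth)) == pytest.approx(
            d_plfa, abs=1e-10
        )


class TestClassification:
    @pytest.mark.parametrize(
        "name, expected",
        [
            # bacterial biomarkers named in deep-sea sponge work
            ("i-C15:0", "bacteria_specific"),
            ("ai-C15:0", "bacteria_specific"),
            ("i-C17:0", "bacteria_specific"),
            ("Cy-C17", "bacteria_specific"),
            ("Cy-C19", "bacteria_specific"),
            ("Me-C16:0", "bacteria_specific"),
            ("Me-C18:0", "bacteria_specific"),
            # long-chain demospongic and hexactinellid acids
            ("C26:2", "sponge_specific"),
            ("C28:2", "sponge_specific"),
            ("C26:3", "sponge_specific"),
            ("C28:3", "sponge_specific"),
            ("C30:3ω7", "sponge_specific"),
            ("C22:1ω7", "sponge_specific"),
            ("C24:1ω9", "sponge_specific"),
            ("i-C25:1ω7", "sponge_specific"),
            # shared acids
            ("C16:1", "unspecific"),
            ("C16:0", "unspecific"),
            ("C18:1", "unspecific"),
        ],
    )
    def test_rule_based_assignments(self, name, expected):
        assert classify(name) == expected

    def test_explicit_table_wins(self):
        assert classify("C16:1", {"C16:1": "bacteria_specific"}) == "bacteria_specific"
        assert classify("C16:1", {"C18:0": "sponge_specific"}) == "unspecific"


class TestDeNovo:
    def test_source_absent_acid_detected(self):
        source = {"C16:0", "C18:0", "C18:1"}
        labelled = {"C18:1", "Cy-C17:0"}
        out = {fa.name for fa in detect_de_novo(labelled, source)}
        assert out == {"Cy-C17:0"}

    def test_subset_of_source_is_empty(self):
        assert detect_de_novo({"C16:0"}, {"C16:0", "C18:1"}) == set()
        assert detect_de_novo(set(), {"C16:0"}) == set()

    @settings(max_examples=30, deadline=None)
    @given(st.sets(st.sampled_from(
        ["C16:0", "C18:0", "C18:1", "Cy-C17:0", "i-C15:0", "C26:2"]), max_size=6),
        st.sets(st.sampled_from(
            ["C16:0", "C18:0", "C18:1", "C14:0"]), max_size=4))
    def test_disjoint_from_source(self, labelled, source):
        out = {fa.name for fa in detect_de_novo(labelled, source)}
        canon_source = {parse_fatty_acid(s).name for s in source}
        assert not (out & canon_source)


class TestProfileSummary:
    def test_single_peak_is_100(self):
        peaks = [PLFAPeak("s1", FattyAcid(16), 5.0, -30.0)]
        df, summary = profile_summary(peaks, _ext())
        assert df.pct_of_total_plfa.iloc[0] == pytest.approx(100.0)

    def test_bacterial_food_fixture_composition(self):
        """The packaged bacterial food-source chromatogram reproduces the
        published three-component composition."""
        peaks, ext = bacteria_food_chromatogram()
        df, summary = profile_summary(peaks, ext)
        by_name = df.set_index("fatty_acid").pct_of_total_plfa
        assert by_name["C16:0"] == pytest.approx(22.4, abs=1e-6)
        assert by_name["C18:1"] == pytest.approx(59.9, abs=1e-6)
        assert by_name["C18:0"] == pytest.approx(17.7, abs=1e-6)

    def test_order_invariance_and_class_totals_sum(self):
        peaks = [
            PLFAPeak("s1", parse_fatty_acid(n), a, -30.0)
            for n, a in [("C16:0", 3.0), ("i-C15:0", 2.0), ("C26:2", 1.5),
                         ("Cy-C17:0", 0.5)]
        ]
        df1, s1 = profile_summary(peaks, _ext())
        df2, s2 = profile_summary(peaks[::-1], _ext())
        m1 = df1.set_index("fatty_acid").pct_of_total_plfa
        m2 = df2.set_index("fatty_acid").pct_of_total_plfa
        assert np.allclose(m1.sort_index(), m2.sort_index())
        total = s1["bacteria_specific"] + s1["sponge_specific"] + s1["unspecific"]
        assert total == pytest.approx(100.0, abs=1e-9)


def test_background_pooling_weights_by_concentration():
    ext = _ext()
    p_small = PLFAPeak("s1", FattyAcid(16), 1.0, uncorrect_fame_delta(-30.0, 16, -40.0))
    p_big = PLFAPeak("s1", FattyAcid(16), 3.0, uncorrect_fame_delta(-26.0, 16, -40.0))
    bg = plfa_backgrounds([([p_small], ext), ([p_big], ext)])
    assert bg["C16:0"] == pytest.approx((1 * -30.0 + 3 * -26.0) / 4, abs=1e-9)
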