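"""Product-profile analysis: background, classification, percent composition."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from tpskit.errors import InputError
from tpskit.profiles import (
    Peak,
    PeakTable,
    ProductProfile,
    classify_peaks,
    match_spectrum,
    percent_composition,
    substrate_activity_matrix,
    subtract_background,
)
from tpskit.reference import PANEL_PRODUCT_PROFILES
from tpskit.synthetic import gen_boiled_control, gen_peak_table


def table_of(peaks, sample_id="s", substrate="GPP"):
    return PeakTable(sample_id, substrate, tuple(peaks))


class TestBackgroundSubtraction:
    def test_empty_control_leaves_sample_unchanged(self):
        sample = table_of([Peak(15.0, 1000.0, "limonene")])
        out = subtract_background(sample, table_of([]))
        assert out == sample

    def test_identical_control_removes_everything(self):
        peaks = [Peak(15.0, 1000.0, "limonene"), Peak(13.4, 50.0, "β-myrcene")]
        sample = table_of(peaks)
        out = subtract_background(sample, table_of(peaks))
        assert len(out.peaks) == 0

    def test_large_peak_retained_with_control_subtracted(self):
        sample = table_of([Peak(15.0, 1000.0, "limonene")])
        control = table_of([Peak(15.02, 100.0, "limonene")])
        out = subtract_background(sample, control)
        assert len(out.peaks) == 1
        assert out.peaks[0].area == pytest.approx(900.0)

    def test_small_peak_dropped_as_background(self):
        sample = table_of([Peak(15.0, 150.0, "limonene")])
        control = table_of([Peak(15.0, 100.0, "limonene")])
        out = subtract_background(sample, control)
        assert len(out.peaks) == 0

    def test_rt_outside_tolerance_not_matched(self):
        sample = table_of([Peak(15.0, 150.0, "limonene")])
        control = table_of([Peak(15.5, 100.0, "limonene")])
        out = subtract_background(sample, control, rt_tol_min=0.1)
        assert out.peaks[0].area == 150.0

    @settings(max_examples=50, derandomize=True)
    @given(ctrl_area=st.floats(min_value=0.0, max_value=2000.0))
    def test_background_monotonicity(self, ctrl_area):
        """A larger control peak never increases the retained terpene area."""
        sample = table_of([Peak(15.0, 1000.0, "limonene")])
        small = subtract_background(sample, table_of([Peak(15.0, ctrl_area, "x")]))
        big = subtract_background(
            sample, table_of([Peak(15.0, ctrl_area + 100.0, "x")])
        )
        area_small = sum(p.area for p in small.peaks)
        area_big = sum(p.area for p in big.peaks)
        assert area_big <= area_small


class TestClassification:
    @pytest.mark.parametrize(
        "compound,klass",
        [
            ("β-myrcene", "monoterpene"),
            ("beta-myrcene", "monoterpene"),
            ("germacrene B", "sesquiterpene"),
            ("geranyl methyl ether", "non_terpene"),
            ("pinene hydrate", "non_terpene"),
            ("isobutylbenzene", "internal_standard"),
            ("mystery compound", "unknown"),
        ],
    )
    def test_lexicon_classes(self, compound, klass):
        out = classify_peaks(table_of([Peak(12.0, 100.0, compound)]))
        assert out.peaks[0].klass == klass


class TestPercentComposition:
    def test_single_terpene_is_exactly_100(self):
        table, _ = gen_peak_table({"β-myrcene": 100.00})
        profile = percent_composition(table)
        assert profile.active
        assert profile.composition == {"β-myrcene": 100.00}

    def test_three_to_one_with_internal_standard(self):
        table = table_of(
            [
                Peak(15.0, 750.0, "limonene", klass="monoterpene"),
                Peak(13.0, 250.0, "β-pinene", klass="monoterpene"),
                Peak(10.2, 500.0, "isobutylbenzene", klass="internal_standard"),
            ]
        )
        profile = percent_composition(table)
        assert profile.composition == {"limonene": 75.00, "β-pinene": 25.00}
        assert ("isobutylbenzene", "internal standard") in profile.excluded

    def test_non_terpene_excluded_from_denominator(self):
        table = table_of(
            [
                Peak(15.0, 500.0, "limonene", klass="monoterpene"),
                Peak(21.9, 500.0, "geranyl methyl ether", klass="non_terpene"),
            ]
        )
        profile = percent_composition(table)
        assert profile.composition == {"limonene": 100.00}

    def test_no_terpene_area_is_inactive(self):
        table = table_of([Peak(10.2, 500.0, "isobutylbenzene", klass="internal_standard")])
        profile = percent_composition(table)
        assert not profile.active and profile.composition == {}

    def test_alias_parent_reporting(self):
        table = classify_peaks(table_of([Peak(32.84, 100.0, "elemol")]))
        assert percent_composition(table).composition == {"elemol": 100.00}
        parent = percent_composition(table, alias_parent=True)
        assert parent.composition == {"hedycaryol": 100.00}

    @settings(max_examples=50, derandomize=True)
    @given(
        areas=st.lists(
            st.floats(min_value=1.0, max_value=1e6), min_size=1, max_size=8
        ),
        extra=st.floats(min_value=0.0, max_value=1e7),
    )
    def test_normalisation_and_exclusion_idempotence(self, areas, extra):
        """Active profiles sum to 100 ± 0.1, and adding internal-standard or
        non-terpene peaks of any size never changes the terpene percentages."""
        terpenes = ["limonene", "β-pinene", "β-myrcene", "terpinolene",
                    "linalool", "geraniol", "α-pinene", "camphene"]
        base_peaks = [
            Peak(10.0 + i, a, terpenes[i], klass="monoterpene")
            for i, a in enumerate(areas)
        ]
        profile = percent_composition(table_of(base_peaks))
        assert sum(profile.composition.values()) == pytest.approx(100.0, abs=0.1)

        with_extras = base_peaks + [
            Peak(9.0, extra, "isobutylbenzene", klass="internal_standard"),
            Peak(21.9, extra, "geranyl methyl ether", klass="non_terpene"),
        ]
        again = percent_composition(table_of(with_extras))
        assert again.composition == profile.composition

    @pytest.mark.parametrize(
        "key", [k for k, v in PANEL_PRODUCT_PROFILES.items() if abs(sum(v.values()) - 100) <= 0.05]
    )
    def test_generator_roundtrip_published_profiles(self, key):
        """percent_composition inverts gen_peak_table for every published
        panel profile (to the 2-decimal reporting precision)."""
        profile = PANEL_PRODUCT_PROFILES[key]
        table, _ = gen_peak_table(profile, sample_id=key[0], substrate=key[1])
        out = percent_composition(table)
        # the reported composition renormalises over the terpene total, so
        # compare against the renormalised input (printed sums can be 100.01)
        total = sum(profile.values())
        expected = {k: 100.0 * v / total for k, v in profile.items()}
        assert out.composition == pytest.approx(expected, abs=0.01)


class TestActivityMatrix:
    def _profile(self, enzyme, substrate, active):
        comp = {"limonene": 100.0} if active else {}
        return ProductProfile(enzyme, substrate, comp, (), active)

    def test_substrate_specificity_labels(self):
        profiles = [
            self._profile("monoTPS", "GPP", True),
            self._profile("monoTPS", "FPP", False),
            self._profile("dualTPS", "GPP", True),
            self._profile("dualTPS", "FPP", True),
            self._profile("deadTPS", "GPP", False),
            self._profile("deadTPS", "GGPP", False),
        ]
        out = substrate_activity_matrix(profiles).set_index("enzyme_id")
        assert out.loc["monoTPS", "classification"] == "Mono"
        assert out.loc["dualTPS", "classification"] == "Mono/Sesqui"
        assert out.loc["deadTPS", "classification"] == "inactive"
        assert bool(out.loc["deadTPS", "ggpp_tested"])
        assert not bool(out.loc["deadTPS", "ggpp_active"])


class TestSpectrumMatch:
    def test_identical_spectra_score_1000(self):
        assert match_spectrum([1, 5, 3, 0], [1, 5, 3, 0]) == pytest.approx(1000.0)

    def test_orthogonal_spectra_score_0(self):
        assert match_spectrum([1, 0, 0], [0, 1, 0]) == pytest.approx(0.0)

    def test_scale_invariance_and_symmetry(self):
        a, b = [1, 5, 3, 0], [2, 10, 6, 0]
        assert match_spectrum(a, b) == pytest.approx(1000.0)
        assert match_spectrum(a, [4, 1, 0, 9]) == pytest.approx(
            match_spectrum([4, 1, 0, 9], a)
        )

    def test_all_zero_scores_0(self):
        assert match_spectrum([0, 0], [1, 2]) == 0.0

    def test_mismatched_binning_rejected(self):
        with pytest.raises(InputError):
            match_spectrum([1, 2], [1, 2, 3])


class TestBackgroundThroughGenerator:
    def test_boiled_control_subtraction_preserves_profile(self):
        profile = {"limonene": 74.72, "β-pinene": 25.28}
        table, _ = gen_peak_table(profile, seed=5)
        control = gen_boiled_control({"pinene hydrate": 400.0}, seed=6)
        cleaned = subtract_background(table, control)
        out = percent_composition(classify_peaks(cleaned))
        assert out.composition == pytest.approx(profile, abs=0.01)
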