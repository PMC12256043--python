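"""Condition parsing, corpus statistics, and screen generation."""

from __future__ import annotations

import pytest

from tpskit.errors import GenerationError, InputError, SelectionError
from tpskit.reference import BEST_CRYSTAL_CONDITION, MINED_CONDITION_FREQUENCIES
from tpskit.screen import (
    Selection,
    export_screen,
    filter_published,
    frequency_stats,
    generate_screen,
    parse_condition,
    read_corpus,
    read_screen,
    reference_selection,
    select_components,
    write_corpus,
)
from tpskit.synthetic import gen_condition_corpus


class TestParseCondition:
    def test_best_crystal_condition_parses_to_four_components(self):
        rec = parse_condition(BEST_CRYSTAL_CONDITION)
        assert rec.published
        assert len(rec.components) == 4
        buffer = rec.first("buffer")
        assert buffer.chemical == "Bis-Tris"
        assert buffer.concentration == 0.1 and buffer.unit == "M"
        assert buffer.pH == 7.0
        prec = rec.first("precipitant")
        assert prec.chemical == "PEG-3350"
        assert prec.concentration == 25.0 and prec.unit == "%w/v"
        salts = {c.chemical for c in rec.all("salt")}
        assert salts == {"NaCl", "MgCl2"}

    def test_empty_string_is_unpublished(self):
        rec = parse_condition("")
        assert not rec.published and rec.components == ()

    def test_reparsing_is_stable(self):
        rec1 = parse_condition(BEST_CRYSTAL_CONDITION, entry_id="x")
        rec2 = parse_condition(rec1.raw_text, entry_id="x")
        assert rec1 == rec2

    def test_synonyms_and_case_insensitivity(self):
        rec = parse_condition("25% polyethylene glycol 3350, 0.2 m nacl")
        assert rec.first("precipitant").chemical == "PEG-3350"
        assert rec.first("salt").chemical == "NaCl"

    def test_ammonium_sulfate_role_depends_on_concentration(self):
        low = parse_condition("0.2 M ammonium sulfate").first("salt")
        assert low is not None and low.chemical == "ammonium sulfate"
        high = parse_condition("1.5 M ammonium sulphate").first("precipitant")
        assert high is not None and high.chemical == "ammonium sulfate"

    def test_unknown_fragment_kept_as_other(self):
        rec = parse_condition("0.1 M Tris pH 8.0, 5 mM wunderchemical")
        assert [c.role for c in rec.components] == ["buffer", "other"]

    def test_nothing_parseable_raises(self):
        with pytest.raises(InputError):
            parse_condition("complete gibberish !!!")

    def test_parser_totality_over_generator_output(self):
        """Every generated condition string parses without role=other."""
        records, _ = gen_condition_corpus(200, 0, seed=21)
        for rec in records:
            parsed = parse_condition(rec.raw_text, entry_id=rec.entry_id)
            assert all(c.role != "other" for c in parsed.components), rec.raw_text
            assert parsed.first("buffer") is not None


class TestFilterPublished:
    def test_120_minus_16_retains_104(self):
        records, _ = gen_condition_corpus(120, 16, seed=0)
        result = filter_published(records)
        assert (result.n_before, result.n_after) == (120, 104)

    def test_all_published_unchanged(self):
        records, _ = gen_condition_corpus(15, 0, seed=1)
        result = filter_published(records)
        assert result.n_after == 15

    def test_empty_corpus(self):
        result = filter_published([])
        assert (result.n_before, result.n_after) == (0, 0)


class TestFrequencyStats:
    def _parsed(self, n, n_missing=0, seed=0):
        records, _ = gen_condition_corpus(n, n_missing, seed=seed)
        kept = filter_published(records).records
        return [parse_condition(r.raw_text, entry_id=r.entry_id) for r in kept]

    def test_simple_fraction(self):
        texts = ["0.1 M Bis-Tris pH 6.5"] * 2 + ["0.1 M Tris pH 8.0"] * 6
        parsed = [parse_condition(t, entry_id=str(i)) for i, t in enumerate(texts)]
        report = frequency_stats(parsed)
        assert report.buffer_pct["Bis-Tris"] == pytest.approx(25.0)

    def test_category_conservation(self):
        report = frequency_stats(self._parsed(300, seed=3))
        for pct in (report.buffer_pct, report.ph_bin_pct, report.salt_pct,
                    report.precipitant_pct, report.peg_subtype_pct):
            assert sum(pct.values()) == pytest.approx(100.0, abs=0.5)

    def test_salt_only_record_counts_toward_salt_denominator_only(self):
        parsed = [
            parse_condition("0.1 M Tris pH 8.0, 0.2 M NaCl", entry_id="a"),
            parse_condition("0.1 M Tris pH 7.5, 25% PEG-3350", entry_id="b"),
        ]
        report = frequency_stats(parsed)
        assert report.denominators["salt"] == 1
        assert report.denominators["precipitant"] == 1
        assert report.salt_pct["NaCl"] == pytest.approx(100.0)

    def test_corpus_scale_frequencies_near_target(self):
        """At the mined corpus size (~104 records) the observed major-category
        frequencies sit within multinomial noise (10 points) of the spec."""
        report = frequency_stats(self._parsed(120, 16, seed=7))
        assert report.buffer_pct["Bis-Tris"] == pytest.approx(
            MINED_CONDITION_FREQUENCIES["buffer_pct"]["Bis-Tris"], abs=10.0
        )
        assert report.ph_bin_pct["6.0–6.9"] == pytest.approx(
            MINED_CONDITION_FREQUENCIES["ph_bin_pct"]["6.0–6.9"], abs=10.0
        )

    def test_empty_corpus_rejected(self):
        with pytest.raises(InputError):
            frequency_stats([])


class TestSelectComponents:
    def _large_corpus_report(self):
        records, _ = gen_condition_corpus(4000, 0, seed=5)
        parsed = [parse_condition(r.raw_text) for r in records]
        return frequency_stats(parsed)

    def test_reference_outcome_recovered_from_large_corpus(self):
        selection = select_components(self._large_corpus_report())
        ref = reference_selection()
        assert selection.buffer_ph == ref.buffer_ph
        assert selection.precipitants == ref.precipitants
        assert set(selection.salts) == set(ref.salts)

    def test_six_buffer_ph_combos(self):
        selection = select_components(self._large_corpus_report())
        assert len(selection.buffer_ph) == 6

    def test_single_buffer_report_fails_selection(self):
        parsed = [
            parse_condition("0.1 M Tris pH 8.0, 25% PEG-3350, 0.2 M NaCl",
                            entry_id=str(i))
            for i in range(4)
        ]
        with pytest.raises(SelectionError):
            select_components(frequency_stats(parsed))


class TestGenerateScreen:
    def test_reference_selection_yields_48(self):
        spec = generate_screen(reference_selection())
        assert len(spec) == 48

    def test_minimal_selection_single_condition(self):
        selection = Selection(
            buffer_ph=(("Tris", 8.0),),
            precipitants=("PEG-3350",),
            precipitant_pcts=(25.0,),
            salts=("MgCl2", "NaCl"),
        )
        spec = generate_screen(selection)
        assert len(spec) == 1
        cond = spec.conditions[0]
        assert cond.salts == (("MgCl2", 200.0), ("NaCl", 200.0))
        assert cond.buffer_mM == 100.0

    def test_best_crystal_composition_is_unique(self):
        spec = generate_screen(reference_selection())
        hits = [
            c for c in spec.conditions
            if (c.buffer, c.pH, c.precipitant, c.precipitant_pct_wv)
            == ("Bis-Tris", 7.0, "PEG-3350", 25.0)
        ]
        assert len(hits) == 1
        assert {s for s, _ in hits[0].salts} == {"MgCl2", "NaCl"}
        assert all(mM == 200.0 for _, mM in hits[0].salts)

    @pytest.mark.parametrize("n_buf,n_prec,n_conc", [(6, 2, 4), (2, 1, 3), (1, 1, 1)])
    def test_cross_product_cardinality(self, n_buf, n_prec, n_conc):
        selection = Selection(
            buffer_ph=tuple((f"buf{i}", 6.0 + 0.5 * i) for i in range(n_buf)),
            precipitants=tuple(f"P{i}" for i in range(n_prec)),
            precipitant_pcts=tuple(5.0 * (i + 1) for i in range(n_conc)),
            salts=("MgCl2", "NaCl"),
        )
        assert len(generate_screen(selection)) == n_buf * n_prec * n_conc

    def test_empty_category_rejected(self):
        selection = Selection(
            buffer_ph=(), precipitants=("PEG-3350",),
            precipitant_pcts=(5.0,), salts=("MgCl2", "NaCl"),
        )
        with pytest.raises(GenerationError):
            generate_screen(selection)


class TestExportAndDeterminism:
    def test_export_roundtrip(self, tmp_path):
        spec = generate_screen(reference_selection())
        csv_path, sheet_path = export_screen(spec, tmp_path / "screen.csv")
        assert sheet_path.exists()
        again = read_screen(csv_path)
        assert again == spec

    def test_refuses_empty_screen(self, tmp_path):
        from tpskit.screen import ScreenSpec

        with pytest.raises(GenerationError):
            export_screen(ScreenSpec(()), tmp_path / "empty.csv")

    def test_corpus_roundtrip_jsonl(self, tmp_path):
        records, _ = gen_condition_corpus(30, 5, seed=9)
        pairs = [(r.entry_id, r.raw_text) for r in records]
        path = write_corpus(pairs, tmp_path / "corpus.jsonl")
        assert read_corpus(path) == pairs

    def test_corpus_to_screen_byte_determinism(self, tmp_path):
        """Identical corpus → identical report → identical screen bytes."""
        outputs = []
        for run in range(2):
            records, _ = gen_condition_corpus(150, 10, seed=33)
            kept = filter_published(records)
            parsed = [parse_condition(r.raw_text, entry_id=r.entry_id)
                      for r in kept.records]
            report = frequency_stats(parsed)
            spec = generate_screen(select_components(report))
            path, _ = export_screen(spec, tmp_path / f"screen{run}.csv")
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]
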