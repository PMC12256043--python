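"""Thermal-stability analysis: Tm estimation, ΔTm, ranking, screen design."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tpskit.errors import ConfigError, InputError
from tpskit.reference import REFERENCE_TM_C, PANEL_STABILITY
from tpskit.synthetic import gen_buffer_screen_dataset, gen_melt_curve
from tpskit.thermal import (
    MeltCurve,
    analyse_buffer_screen,
    best_condition_per_protein,
    compute_delta_tm,
    delta_tm_entry,
    estimate_tm,
    make_buffer_screen,
    rank_buffers,
)


class TestEstimateTm:
    def test_boltzmann_recovers_noiseless_midpoint(self):
        curve, _ = gen_melt_curve(83.18, noise_sd=0.0)
        res = estimate_tm(curve, "boltzmann")
        assert res.transition_detected
        assert res.tm_C == pytest.approx(83.18, abs=0.05)

    def test_derivative_hits_on_grid_midpoint_of_symmetric_sigmoid(self):
        curve, _ = gen_melt_curve(60.0, slope_pre=0.0, slope_post=0.0)
        res = estimate_tm(curve, "derivative")
        assert res.tm_C == pytest.approx(60.0, abs=1e-6)

    def test_flat_curve_reports_no_transition(self):
        T = np.arange(20.0, 96.0)
        curve = MeltCurve("flat", "p", T, np.full_like(T, 500.0))
        res = estimate_tm(curve)
        assert not res.transition_detected
        assert res.tm_C is None

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            MeltCurve("x", "p", np.arange(5.0), np.arange(5.0))

    def test_unknown_method_rejected(self):
        curve, _ = gen_melt_curve(70.0)
        with pytest.raises(InputError):
            estimate_tm(curve, "sigmoid")

    @pytest.mark.parametrize("method", ["boltzmann", "derivative"])
    def test_monotone_invariance_offset_and_scale(self, method):
        curve, _ = gen_melt_curve(72.4, noise_sd=0.0)
        base = estimate_tm(curve, method).tm_C
        shifted = MeltCurve(
            "s", "p", curve.temperatures_C, 3.0 * curve.fluorescence_AU + 250.0
        )
        assert estimate_tm(shifted, method).tm_C == pytest.approx(base, abs=1e-3)

    @pytest.mark.parametrize(
        "tm,steepness",
        [(55.0, 1.0), (55.0, 2.0), (55.0, 3.0), (70.5, 1.0), (70.5, 2.0),
         (70.5, 3.0), (83.18, 1.0), (83.18, 2.0)],
    )
    def test_derivative_boltzmann_agreement_noiseless(self, tm, steepness):
        """Both estimators agree on noiseless curves whose transition
        completes inside the scanned window (the derivative peak acquires a
        structural bias once the post-transition decay overlaps still-broader
        or scan-truncated transitions; the Boltzmann fit is the primary
        method there)."""
        curve, _ = gen_melt_curve(tm, steepness=steepness, noise_sd=0.0)
        boltz = estimate_tm(curve, "boltzmann").tm_C
        deriv = estimate_tm(curve, "derivative").tm_C
        assert abs(boltz - deriv) <= 0.5

    def test_noisy_recovery_rate(self):
        """With per-point noise at 2% of amplitude, the Boltzmann estimate
        lands within 0.3 °C of the generative midpoint in >= 95/100 curves."""
        hits = 0
        for seed in range(100):
            curve, truth = gen_melt_curve(74.0, amplitude=1000.0, noise_sd=20.0,
                                          seed=seed)
            res = estimate_tm(curve, "boltzmann")
            if res.tm_C is not None and abs(res.tm_C - truth.params["tm_C"]) <= 0.3:
                hits += 1
        assert hits >= 95


class TestDeltaTm:
    def test_published_best_condition_shifts(self):
        assert compute_delta_tm(83.18, REFERENCE_TM_C) == pytest.approx(6.72)
        assert compute_delta_tm(81.13, REFERENCE_TM_C) == pytest.approx(4.67)

    def test_identity_is_zero(self):
        assert compute_delta_tm(70.0, 70.0) == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(
        a=st.floats(min_value=20.0, max_value=95.0),
        b=st.floats(min_value=20.0, max_value=95.0),
    )
    def test_antisymmetry(self, a, b):
        assert compute_delta_tm(a, b) == -compute_delta_tm(b, a)

    def test_absent_tm_propagates(self):
        entry = delta_tm_entry("c1", None, 76.46)
        assert entry.no_transition and entry.delta_tm_C is None and not entry.stabilising


class TestRankBuffers:
    def test_median_of_four_panel_shifts(self):
        frame = pd.DataFrame(
            {
                "protein_id": ["p1", "p2", "p3", "p4"],
                "condition_id": ["c1"] * 4,
                "delta_tm_C": [4.67, 4.79, 4.11, 4.57],
            }
        )
        out = rank_buffers(frame)
        assert out.loc[0, "median_delta_tm_C"] == pytest.approx(4.62)
        assert bool(out.loc[0, "stabilising"])

    def test_threshold_is_strict(self):
        frame = pd.DataFrame(
            {"protein_id": ["p1"], "condition_id": ["c1"], "delta_tm_C": [4.0]}
        )
        out = rank_buffers(frame)
        assert not bool(out.loc[0, "stabilising"])

    def test_no_transitions_excluded_and_counted(self):
        frame = pd.DataFrame(
            {
                "protein_id": ["p1", "p2", "p3"],
                "condition_id": ["c1"] * 3,
                "delta_tm_C": [5.0, np.nan, 7.0],
            }
        )
        out = rank_buffers(frame)
        assert out.loc[0, "median_delta_tm_C"] == pytest.approx(6.0)
        assert out.loc[0, "n_no_transition"] == 1

    def test_sorted_descending_with_id_tiebreak(self):
        frame = pd.DataFrame(
            {
                "protein_id": ["p1"] * 3,
                "condition_id": ["c3", "c1", "c2"],
                "delta_tm_C": [2.0, 5.0, 5.0],
            }
        )
        out = rank_buffers(frame)
        assert list(out["condition_id"]) == ["c1", "c2", "c3"]

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            rank_buffers(pd.DataFrame())


class TestBestConditionPerProtein:
    def test_panel_recovery_from_published_parameters(self):
        """Full round trip: per-protein datasets generated at the published
        best-condition shifts are analysed back to the published ΔTm."""
        design = make_buffer_screen()
        cid = design.ids()[0]
        curves_by_protein = {}
        for i, (enzyme, (_, _tm, dtm)) in enumerate(PANEL_STABILITY.items()):
            curves, _ = gen_buffer_screen_dataset(
                {cid: dtm}, REFERENCE_TM_C, noise_sd=0.0, seed=i, protein_id=enzyme
            )
            curves_by_protein[enzyme] = curves
        table = analyse_buffer_screen(curves_by_protein)
        best = best_condition_per_protein(table).set_index("protein_id")
        assert best.loc["CsTPS9FN", "delta_tm_C"] == pytest.approx(6.72, abs=0.1)
        assert best.loc["CsTPS9FN", "tm_C"] == pytest.approx(83.18, abs=0.1)

    def test_single_condition_is_best(self):
        frame = pd.DataFrame(
            {"protein_id": ["p"], "condition_id": ["c9"], "tm_C": [80.0],
             "delta_tm_C": [3.0]}
        )
        assert best_condition_per_protein(frame).loc[0, "condition_id"] == "c9"

    def test_tie_breaks_to_lower_condition_id(self):
        frame = pd.DataFrame(
            {
                "protein_id": ["p", "p"],
                "condition_id": ["c2", "c1"],
                "tm_C": [80.0, 80.0],
                "delta_tm_C": [5.0, 5.0],
            }
        )
        assert best_condition_per_protein(frame).loc[0, "condition_id"] == "c1"

    def test_protein_without_transitions_flagged(self):
        frame = pd.DataFrame(
            {"protein_id": ["p"], "condition_id": ["c1"], "tm_C": [np.nan],
             "delta_tm_C": [np.nan]}
        )
        assert best_condition_per_protein(frame).loc[0, "condition_id"] == "none"


class TestBufferScreenDesign:
    def test_default_design_has_80_conditions(self):
        assert len(make_buffer_screen()) == 80

    def test_single_buffer_no_salts(self):
        design = make_buffer_screen(buffers=(("Tris", 8.0),), salts=(), salt_mM=())
        assert len(design) == 1

    @pytest.mark.parametrize("n_buf,n_salt,n_conc", [(2, 2, 2), (8, 3, 3), (1, 1, 4)])
    def test_cardinality_identity(self, n_buf, n_salt, n_conc):
        buffers = tuple((f"buf{i}", 6.0 + 0.2 * i) for i in range(n_buf))
        salts = tuple(f"salt{i}" for i in range(n_salt))
        concs = tuple(50.0 * (i + 1) for i in range(n_conc))
        design = make_buffer_screen(buffers, salts, concs)
        assert len(design) == n_buf * (1 + n_salt * n_conc)

    def test_duplicate_buffer_ph_rejected(self):
        with pytest.raises(ConfigError):
            make_buffer_screen(buffers=(("Tris", 8.0), ("Tris", 8.0)))
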