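"""Unit and property tests of the regulatory cascade."""

import math

import numpy as np
import pytest
from scipy import stats

from cortigen import (FateDecision, GRNParams, clock_steps_to_threshold,
                      decide_stage_fate, expected_with_apoptosis,
                      expected_without_apoptosis, lineage_replicates, list_presets,
                      run_lineage_cascade, symmetric_amplification)


@pytest.fixture(scope="module")
def human():
    return GRNParams.from_preset("human_temporal")


class TestClock:
    @pytest.mark.parametrize("q0,decay,threshold,expected", [
        (100, 0.01, 65, 43),        # the amplification-phase window
        (100, 0.01, 100, 1),        # first decay already below
        (100, 0.01, 1e-4, 1375),    # matches ceil(log(1e-6)/log(0.99))
    ])
    def test_worked_examples(self, q0, decay, threshold, expected):
        n = clock_steps_to_threshold(q0, decay, threshold)
        assert n == expected
        # definitional check: smallest n with q0*(1-decay)^n < threshold
        assert q0 * (1 - decay) ** n < threshold
        assert n == 1 or q0 * (1 - decay) ** (n - 1) >= threshold

    def test_closed_form_matches_iteration(self):
        for threshold in (65.0, 30.0, 5.0, 0.5):
            n_iter, q = 0, 100.0
            while q >= threshold:
                q *= 0.99
                n_iter += 1
            assert clock_steps_to_threshold(100, 0.01, threshold) == n_iter

    @pytest.mark.parametrize("kw", [
        dict(q0=100, decay=0.01, threshold=0.0),
        dict(q0=100, decay=0.01, threshold=-1.0),
        dict(q0=0, decay=0.01, threshold=5.0),
        dict(q0=100, decay=1.5, threshold=5.0),
    ])
    def test_invalid_parameters(self, kw):
        with pytest.raises(ValueError):
            clock_steps_to_threshold(**kw)


class TestFateDecision:
    def test_certain_commitment(self, rng):
        p = GRNParams(C_M=1.0, C_6=1, C_5=1, C_4=1, C_3=1, C_2=1,
                      P_M=0.5, P_6=0, P_5=0, P_4=0, P_3=0)
        assert all(decide_stage_fate(2, p, rng) is FateDecision.COMMIT for _ in range(50))

    def test_certain_apoptosis(self, rng):
        p = GRNParams(C_M=0.0, C_6=0, C_5=0, C_4=0, C_3=0, C_2=0,
                      P_M=1.0, P_6=1, P_5=1, P_4=1, P_3=1)
        assert all(decide_stage_fate(2, p, rng) is FateDecision.APOPTOSE for _ in range(50))

    def test_outcome_frequencies_match_sequential_probabilities(self, human, rng):
        """Human S2: (C, (1-C)P, (1-C)(1-P)) = (0.16, 0.588, 0.252)."""
        n = 100_000
        draws = [decide_stage_fate(2, human, rng) for _ in range(n)]
        counts = np.array([sum(d is f for d in draws) for f in
                           (FateDecision.COMMIT, FateDecision.APOPTOSE, FateDecision.ADVANCE)])
        expected = np.array([0.16, 0.84 * 0.7, 0.84 * 0.3]) * n
        chi2, p = stats.chisquare(counts, expected)
        assert p > 1e-3

    def test_invalid_stage(self, human, rng):
        for stage in (1, 8, 0):
            with pytest.raises(ValueError):
                decide_stage_fate(stage, human, rng)


class TestAmplification:
    @pytest.mark.parametrize("founders,rounds,expected", [
        (175, 6, 11_200), (175, 0, 175), (1, 10, 1024),
    ])
    def test_pool_size(self, founders, rounds, expected):
        assert symmetric_amplification(founders, rounds) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            symmetric_amplification(0, 3)
        with pytest.raises(ValueError):
            symmetric_amplification(10, -1)


class TestLineageCascade:
    def test_conservation_at_every_stage(self, rng):
        """committed + A1 deaths + advanced == entered; next stage enters 2x advanced."""
        for _ in range(20):
            vals = rng.uniform(0.05, 0.95, size=11)
            p = GRNParams(*vals)
            counts = run_lineage_cascade(p, 200, rng)
            prev_advanced = None
            for tally in counts.stages:
                assert tally.committed + tally.a1_deaths + tally.advanced == tally.entered
                if prev_advanced is not None:
                    assert tally.entered == 2 * prev_advanced
                prev_advanced = tally.advanced
            assert counts.stages[0].entered == 400

    def test_certain_mz_commitment_yields_two_per_progenitor(self, rng):
        p = GRNParams(C_M=1.0, C_6=0.5, C_5=0.5, C_4=0.5, C_3=0.5, C_2=0.5,
                      P_M=0.5, P_6=0.5, P_5=0.5, P_4=0.5, P_3=0.5)
        counts = run_lineage_cascade(p, 500, rng)
        assert counts.n_MZ == 1000
        assert counts.total_neurons == 1000

    def test_terminal_stage_exhausts_cells(self, human, rng):
        counts = run_lineage_cascade(human, 1000, rng)
        last = counts.stages[-1]
        assert last.advanced == 0  # P_2 = 1 - C_2 leaves no survivors at S7

    def test_monte_carlo_mean_matches_closed_form(self, human, rng):
        n_p, n_rep = 2000, 150
        reps = lineage_replicates(human, n_p, n_rep, rng)
        exp = expected_with_apoptosis(human, n_p).as_array()
        se = reps.std(axis=0, ddof=1) / math.sqrt(n_rep)
        assert np.all(np.abs(reps.mean(axis=0) - exp) <= 3.5 * np.maximum(se, 1e-9))

    def test_no_apoptosis_matches_apoptosis_free_equations(self, human, rng):
        p0 = human.without_apoptosis()
        n_p, n_rep = 2000, 150
        reps = lineage_replicates(p0, n_p, n_rep, rng)
        exp = expected_without_apoptosis(human, n_p).as_array()
        se = reps.std(axis=0, ddof=1) / math.sqrt(n_rep)
        assert np.all(np.abs(reps.mean(axis=0) - exp) <= 3.5 * np.maximum(se, 1e-9))

    def test_to_frame_round_trip(self, human, rng):
        df = run_lineage_cascade(human, 100, rng).to_frame()
        assert list(df.columns) == ["stage", "entered", "committed", "a1_deaths", "advanced"]
        assert (df["stage"] == range(2, 2 + len(df))).all()


class TestApoptosisFlexibility:
    """Raising P_k lowers every later layer's expectation, leaves earlier ones alone."""

    @pytest.mark.parametrize("p_name,unchanged,reduced", [
        ("P_M", ["N_1"], ["N_6", "N_5", "N_4", "N_3", "N_2"]),
        ("P_6", ["N_1", "N_6"], ["N_5", "N_4", "N_3", "N_2"]),
        ("P_5", ["N_1", "N_6", "N_5"], ["N_4", "N_3", "N_2"]),
        ("P_4", ["N_1", "N_6", "N_5", "N_4"], ["N_3", "N_2"]),
        ("P_3", ["N_1", "N_6", "N_5", "N_4", "N_3"], ["N_2"]),
    ])
    def test_independent_layer_control(self, human, p_name, unchanged, reduced):
        import dataclasses
        bumped = dataclasses.replace(human, **{p_name: min(1.0, getattr(human, p_name) + 0.2)})
        base = expected_with_apoptosis(human, 1000)
        new = expected_with_apoptosis(bumped, 1000)
        for name in unchanged:
            assert getattr(new, name) == pytest.approx(getattr(base, name))
        for name in reduced:
            assert getattr(new, name) < getattr(base, name)

    def test_strict_coupling_without_apoptosis(self, human):
        """With P=0, raising C_5 necessarily lowers N_4, N_3 and N_2."""
        import dataclasses
        bumped = dataclasses.replace(human, C_5=human.C_5 + 0.2)
        base = expected_without_apoptosis(human, 1000)
        new = expected_without_apoptosis(bumped, 1000)
        assert new.N_5 > base.N_5
        for name in ("N_4", "N_3", "N_2"):
            assert getattr(new, name) < getattr(base, name)


class TestPresets:
    def test_all_four_species_load(self):
        assert set(list_presets()) == {"human_temporal", "rat_somatosensory",
                                       "mouse_barrel", "macaque_visual"}
        for s in list_presets():
            p = GRNParams.from_preset(s)
            assert p.T_SYM == 65
            assert p.P_2 == pytest.approx(1 - p.C_2)

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            GRNParams.from_preset("lizard_tectum")

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            GRNParams(C_M=1.2, C_6=0.1, C_5=0.1, C_4=0.1, C_3=0.1, C_2=0.1,
                      P_M=0.1, P_6=0.1, P_5=0.1, P_4=0.1, P_3=0.1)

    def test_apoptosis_scaling_caps_at_one(self):
        p = GRNParams.from_preset("human_temporal").with_apoptosis_scaled(1.5)
        assert p.P_M == 1.0          # 0.7 * 1.5 capped
        assert p.P_3 == pytest.approx(0.45)
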