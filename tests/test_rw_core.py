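import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ndra.rw_core import (
    EventTable,
    RWParams,
    activation,
    conditional_probs,
    equilibrium_residual,
    rw_update,
    simulate_learning,
    solve_equilibrium,
    zero_weights,
)


def _random_table(rng, n_cues=None, n_outs=None, max_weight=9):
    cues = list("abcdef")[: n_cues or rng.integers(2, 7)]
    outs = list("wxyz")[: n_outs or rng.integers(1, 5)]
    events = []
    for _ in range(rng.integers(3, 10)):
        cs = frozenset(rng.choice(cues, size=rng.integers(1, len(cues) + 1), replace=False))
        os_ = frozenset(rng.choice(outs, size=rng.integers(1, len(outs) + 1), replace=False))
        events.append((cs, os_, int(rng.integers(1, max_weight + 1))))
    # make sure every cue occurs
    events.append((frozenset(cues), frozenset(outs), 1))
    return EventTable(events)


class TestRwUpdate:
    def test_single_cue_outcome_present(self):
        W = zero_weights(["A"], ["O"])
        W2 = rw_update(W, (frozenset("A"), frozenset("O")), RWParams(alpha=1.0, beta1=0.1))
        assert W2.at["A", "O"] == pytest.approx(0.1)

    def test_absent_cue_unchanged(self):
        W = zero_weights(["A", "B"], ["O"])
        W.at["B", "O"] = 0.7
        W2 = rw_update(W, (frozenset("A"), frozenset("O")), RWParams(alpha=1.0, beta1=0.1))
        assert W2.at["B", "O"] == 0.7

    def test_outcome_absent_decrements(self):
        W = zero_weights(["A"], ["O"])
        W.at["A", "O"] = 0.5
        W2 = rw_update(W, (frozenset("A"), frozenset()), RWParams(alpha=1.0, beta2=0.1))
        assert W2.at["A", "O"] == pytest.approx(0.45)

    def test_unindexed_cue_errors(self):
        W = zero_weights(["A"], ["O"])
        with pytest.raises(KeyError):
            rw_update(W, (frozenset("Q"), frozenset("O")), RWParams())


class TestConditionalProbs:
    def test_single_event(self):
        et = EventTable([(frozenset("A"), frozenset("O"), 1)])
        pcc, pco = conditional_probs(et)
        assert pcc.at["A", "A"] == 1.0
        assert pco.at["A", "O"] == 1.0

    def test_weighted_cooccurrence(self):
        et = EventTable(
            [(frozenset("A"), frozenset("O"), 1), (frozenset("AB"), frozenset("O"), 3)]
        )
        pcc, _ = conditional_probs(et)
        assert pcc.at["A", "B"] == pytest.approx(0.75)
        assert pcc.at["B", "A"] == 1.0

    def test_disjoint_cues(self):
        et = EventTable(
            [(frozenset("A"), frozenset("O"), 1), (frozenset("B"), frozenset("P"), 1)]
        )
        pcc, pco = conditional_probs(et)
        assert pcc.at["A", "B"] == 0.0
        assert pco.at["B", "O"] == 0.0


class TestEquilibrium:
    def test_single_cue_reaches_asymptote(self):
        et = EventTable([(frozenset("A"), frozenset("O"), 5)])
        V = solve_equilibrium(et)
        assert V.at["A", "O"] == pytest.approx(1.0)

    @pytest.mark.parametrize("w1,w2", [(1, 1), (3, 5), (100, 7)])
    def test_blocking(self, w1, w2):
        """{A}->O and {A,B}->O: A blocks B for any event weights."""
        et = EventTable(
            [(frozenset("A"), frozenset("O"), w1), (frozenset("AB"), frozenset("O"), w2)]
        )
        V = solve_equilibrium(et)
        assert V.at["A", "O"] == pytest.approx(1.0, abs=1e-10)
        assert V.at["B", "O"] == pytest.approx(0.0, abs=1e-10)

    def test_residual_small_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            et = _random_table(rng)
            V = solve_equilibrium(et)
            assert equilibrium_residual(et, V) < 1e-8

    def test_scale_invariance(self):
        """Multiplying all event weights by a constant leaves V unchanged."""
        rng = np.random.default_rng(8)
        et = _random_table(rng)
        scaled = EventTable([(c, o, w * 13) for c, o, w in et.events])
        pd.testing.assert_frame_equal(
            solve_equilibrium(et), solve_equilibrium(scaled), atol=1e-10, rtol=0
        )

    def test_outcome_independence(self):
        """Adding an unrelated outcome leaves existing columns unchanged."""
        rng = np.random.default_rng(9)
        et = _random_table(rng, n_outs=2)
        extended = EventTable(
            et.events + [(frozenset({"zz_cue"}), frozenset({"zz_out"}), 4)]
        )
        V1 = solve_equilibrium(et)
        V2 = solve_equilibrium(extended)
        for out in et.outcomes:
            np.testing.assert_allclose(
                V2.loc[et.cues, out].to_numpy(), V1[out].to_numpy(), atol=1e-10
            )

    def test_disconnected_cues_get_zero_weight(self):
        """Cues never co-occurring with an outcome carry no association."""
        et = EventTable(
            [(frozenset("AB"), frozenset("O"), 2), (frozenset("CD"), frozenset("P"), 3)]
        )
        V = solve_equilibrium(et)
        assert V.at["C", "O"] == pytest.approx(0.0, abs=1e-12)
        assert V.at["A", "P"] == pytest.approx(0.0, abs=1e-12)


class TestSimulateLearning:
    def test_zero_trials_all_zero(self):
        et = EventTable([(frozenset("A"), frozenset("O"), 1)])
        V = simulate_learning(et, n_trials=0)
        assert (V.to_numpy() == 0).all()

    def test_geometric_convergence_to_asymptote(self):
        et = EventTable([(frozenset("A"), frozenset("O"), 1)])
        V = simulate_learning(
            et, RWParams(alpha=1.0, beta1=0.1, beta2=0.1), n_trials=500, seed=0
        )
        assert V.at["A", "O"] == pytest.approx(1.0, abs=1e-3)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        et = _random_table(rng)
        V1 = simulate_learning(et, n_trials=500, seed=11)
        V2 = simulate_learning(et, n_trials=500, seed=11)
        pd.testing.assert_frame_equal(V1, V2)

    def test_matches_equilibrium_on_small_table(self):
        rng = np.random.default_rng(4)
        et = _random_table(rng)
        Veq = solve_equilibrium(et)
        Vit = simulate_learning(
            et, RWParams(alpha=1.0, beta1=0.005, beta2=0.005), n_trials=200_000, seed=2
        )
        assert np.abs(Veq.to_numpy() - Vit.to_numpy()).max() < 0.05


class TestActivation:
    def test_unknown_cues_backoff_only(self):
        et = EventTable([(frozenset("A"), frozenset("O"), 1)])
        V = solve_equilibrium(et)
        acts = activation(V, {"Q", "Z"}, backoff=0.01)
        assert acts["O"] == pytest.approx(0.01)

    def test_blocking_trained_net(self):
        et = EventTable(
            [(frozenset("A"), frozenset("O"), 1), (frozenset("AB"), frozenset("O"), 1)]
        )
        V = solve_equilibrium(et)
        assert activation(V, {"B"})["O"] == pytest.approx(0.01, abs=1e-9)
        assert activation(V, {"A", "B"})["O"] == pytest.approx(1.01, abs=1e-9)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_equilibrium_residual_property(seed):
    """Equilibrium equations hold to 1e-8 on random full-rank tables."""
    rng = np.random.default_rng(seed)
    et = _random_table(rng)
    V = solve_equilibrium(et)
    assert equilibrium_residual(et, V) < 1e-8
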