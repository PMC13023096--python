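"""Transition-matrix construction, validation, and stochasticity properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemboost import (
    HealthState,
    ParameterError,
    StrategyParameters,
    TransitionMatrix,
    build_transition_matrix,
)
from stemboost.model import DEATH_STATES, N_STATES, STATE_LABELS

S = HealthState

probs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def random_params(draw_tuple):
    pn, pi, pr, pd_, prel, prd = draw_tuple
    # keep the neutropenia pair feasible without renormalization
    total = pi + pr
    if total > 1:
        pi, pr = pi / total, pr / total
    return StrategyParameters(
        p_neutropenia=pn,
        p_infection_given_neutropenia=pi,
        p_recovery_given_neutropenia=pr,
        p_infection_death=pd_,
        p_relapse_monthly=prel,
        p_relapse_death_monthly=prd,
    )


class TestBuildTransitionMatrix:
    def test_base_case_neutropenia_row(self, noboost_params):
        """No-boost: neutropenia resolves 75% recovery / 25% infection."""
        m = build_transition_matrix(noboost_params)
        assert m[S.NEUTROPENIA, S.RECOVERY] == 0.75
        assert m[S.NEUTROPENIA, S.INFECTION] == 0.25
        assert m[S.NEUTROPENIA, S.NEUTROPENIA] == 0.0

    def test_no_event_degenerate_case(self):
        """With all event probabilities zero the cohort flows to recovery and stays."""
        p = StrategyParameters(
            p_neutropenia=0.0,
            p_infection_given_neutropenia=0.0,
            p_recovery_given_neutropenia=1.0,
            p_infection_death=0.0,
            p_relapse_monthly=0.0,
            p_relapse_death_monthly=0.0,
        )
        m = build_transition_matrix(p)
        assert m[S.CAR_T, S.RECOVERY] == 1.0
        assert m[S.RECOVERY, S.RECOVERY] == 1.0
        assert m[S.RELAPSE, S.RELAPSE] == 1.0
        assert m.probs[:, list(DEATH_STATES)].sum() == 2.0  # only self-loops

    def test_residual_stay_mass_from_stress_draw(self, noboost_params):
        """A (recover 0.60, infect 0.15) draw leaves 0.25 'stay' mass."""
        p = noboost_params.with_updates(
            p_recovery_given_neutropenia=0.60, p_infection_given_neutropenia=0.15
        )
        m = build_transition_matrix(p)
        row = m[S.NEUTROPENIA]
        assert row[S.NEUTROPENIA] == pytest.approx(0.25)
        assert row[S.RECOVERY] == pytest.approx(0.60)
        assert row[S.INFECTION] == pytest.approx(0.15)

    def test_overfull_neutropenia_pair_raises_and_renormalizes(self, noboost_params):
        p = noboost_params.with_updates(
            p_recovery_given_neutropenia=0.85, p_infection_given_neutropenia=0.35
        )
        with pytest.raises(ParameterError, match="p_infection_given_neutropenia"):
            build_transition_matrix(p)
        m = build_transition_matrix(p, renormalize=True)
        row = m[S.NEUTROPENIA]
        assert row[S.INFECTION] == pytest.approx(0.35 / 1.20)
        assert row[S.RECOVERY] == pytest.approx(0.85 / 1.20)
        assert row[S.NEUTROPENIA] == pytest.approx(0.0, abs=1e-12)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ParameterError, match="p_neutropenia"):
            StrategyParameters(p_neutropenia=1.2)

    def test_arms_differ_only_in_neutropenia_row(self, noboost_params, boost_params):
        m_nb = build_transition_matrix(noboost_params).probs
        m_b = build_transition_matrix(boost_params).probs
        diff = np.abs(m_nb - m_b)
        assert diff[S.NEUTROPENIA].sum() > 0
        mask = np.ones(N_STATES, dtype=bool)
        mask[S.NEUTROPENIA] = False
        assert np.all(diff[mask] == 0)


class TestMatrixProperties:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.tuples(probs, probs, probs, probs, probs, probs))
    def test_row_stochastic_and_absorbing(self, ps):
        """Every constructed matrix is row-stochastic with absorbing deaths."""
        m = build_transition_matrix(random_params(ps))
        assert np.allclose(m.probs.sum(axis=1), 1.0, atol=1e-12, rtol=0)
        assert (m.probs >= 0).all() and (m.probs <= 1).all()
        for d in DEATH_STATES:
            row = np.zeros(N_STATES)
            row[d] = 1.0
            assert np.array_equal(m[d], row)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.tuples(probs, probs, probs, probs, probs, probs))
    def test_death_mass_nondecreasing_under_iteration(self, ps):
        """Mass in death states never decreases over repeated application."""
        m = build_transition_matrix(random_params(ps))
        occ = np.zeros(N_STATES)
        occ[S.CAR_T] = 1.0
        prev_dead = 0.0
        for _ in range(30):
            occ = occ @ m.probs
            dead = occ[list(DEATH_STATES)].sum()
            assert dead >= prev_dead - 1e-12
            prev_dead = dead

    def test_invalid_matrix_rejected(self):
        bad = np.eye(N_STATES)
        bad[0, 0] = 0.9  # row no longer sums to 1
        with pytest.raises(ParameterError, match="sum to 1"):
            TransitionMatrix(bad)


def test_matrix_csv_round_trip(tmp_path, noboost_params):
    import pandas as pd

    m = build_transition_matrix(noboost_params)
    path = tmp_path / "matrix.csv"
    m.to_csv(path)
    df = pd.read_csv(path, index_col="from_state")
    assert list(df.columns) == list(STATE_LABELS)
    assert np.allclose(df.to_numpy(), m.probs)
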