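"""Markov scheme of the fast Na+ current: topology, rates, master equation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myoburst.ina import (
    SLOW_INACT_STATES,
    full_scheme,
    ina_current,
    ina_occupancy_derivatives,
    ina_rates,
    no_slow_inact_scheme,
    strip_slow_inactivation,
)
from myoburst.parameters import make_parameters


@pytest.fixture(scope="module")
def wt():
    return make_parameters("wt")


class TestTopology:
    def test_full_scheme_states(self):
        s = full_scheme()
        assert s.n_states == 9
        assert set(s.states) == {"C3", "C2", "C1", "O", "IF", "I1", "I2", "IC2", "IC3"}

    def test_stripped_scheme_is_seven_states(self):
        s = no_slow_inact_scheme()
        assert s.n_states == 7
        assert not set(SLOW_INACT_STATES) & set(s.states)

    def test_strip_removes_exactly_incident_edges(self):
        full = full_scheme()
        stripped = strip_slow_inactivation(full)
        incident = {e for e in full.edges if e[0] in SLOW_INACT_STATES or e[1] in SLOW_INACT_STATES}
        assert set(full.edges) - set(stripped.edges) == incident
        assert len(incident) == 4  # IF<->I1 and I1<->I2, both directions

    def test_no_double_stripping(self):
        with pytest.raises(ValueError):
            strip_slow_inactivation(no_slow_inact_scheme())


class TestRates:
    @pytest.mark.parametrize("V", np.linspace(-100.0, 60.0, 17))
    def test_all_rates_nonnegative(self, V):
        rates = ina_rates(float(V), full_scheme())
        assert all(v >= 0.0 for v in rates.values())

    def test_stripped_rate_table_has_no_slow_edges(self):
        rates = ina_rates(-20.0, no_slow_inact_scheme())
        for (src, dst) in rates:
            assert src not in SLOW_INACT_STATES and dst not in SLOW_INACT_STATES

    @pytest.mark.parametrize("V", [-80.0, -40.0, 0.0, 40.0])
    def test_microscopic_reversibility_of_inactivation_loop(self, V):
        """b2 is defined so the C1-O-IF cycle satisfies detailed balance."""
        r = ina_rates(V, full_scheme())
        clockwise = r[("C1", "O")] * r[("O", "IF")] * r[("IF", "C1")]
        counter = r[("O", "C1")] * r[("IF", "O")] * r[("C1", "IF")]
        assert clockwise == pytest.approx(counter, rel=1e-12)

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            ina_rates(float("nan"))


class TestMasterEquation:
    @given(st.lists(st.floats(0.001, 1.0), min_size=9, max_size=9),
           st.floats(-100.0, 60.0))
    @settings(max_examples=50, deadline=None)
    def test_derivatives_sum_to_zero(self, raw, V):
        occ = np.asarray(raw)
        occ = occ / occ.sum()
        d = ina_occupancy_derivatives(occ, V)
        assert abs(d.sum()) < 1e-12

    def test_open_state_decays_at_hyperpolarization(self):
        """All occupancy in O at -100 mV: deactivation dominates, dO/dt < 0."""
        scheme = full_scheme()
        occ = np.zeros(9)
        occ[scheme.state_index("O")] = 1.0
        d = ina_occupancy_derivatives(occ, -100.0, scheme)
        assert d[scheme.state_index("O")] < 0.0

    def test_slow_states_never_populate_in_stripped_scheme(self):
        """Without the I1/I2 edges, no flux can reach slow inactivation."""
        scheme = full_scheme()
        occ = np.zeros(9)
        occ[scheme.state_index("IF")] = 1.0
        # in the full scheme IF feeds I1
        assert ina_occupancy_derivatives(occ, -20.0, scheme)[scheme.state_index("I1")] > 0
        stripped = no_slow_inact_scheme()
        occ7 = np.zeros(7)
        occ7[stripped.state_index("IF")] = 1.0
        d = ina_occupancy_derivatives(occ7, -20.0, stripped)
        assert "I1" not in stripped.states and d.sum() == pytest.approx(0.0, abs=1e-14)

    def test_occupancy_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ina_occupancy_derivatives(np.ones(7) / 7.0, -20.0, full_scheme())


class TestCurrent:
    def test_closed_channel_carries_no_current(self, wt):
        assert ina_current(-20.0, 0.0, 14.2371, wt) == 0.0

    def test_zero_at_reversal(self, wt):
        import math

        RT_F = wt.RGAS * wt.TEMP / wt.F
        Nai, Ki = 14.2371, 143.72
        ENa = RT_F * math.log((0.9 * wt.Nao + 0.1 * wt.Ko) / (0.9 * Nai + 0.1 * Ki))
        assert ina_current(ENa, 0.7, Nai, wt, Ki) == pytest.approx(0.0, abs=1e-12)

    def test_ohmic_scaling(self, wt):
        import math

        RT_F = wt.RGAS * wt.TEMP / wt.F
        Nai, Ki = 14.2371, 143.72
        ENa = RT_F * math.log((0.9 * wt.Nao + 0.1 * wt.Ko) / (0.9 * Nai + 0.1 * Ki))
        assert ina_current(ENa - 10.0, 1.0, Nai, wt, Ki) == pytest.approx(-10.0 * wt.GNa)

    def test_occupancy_bounds(self, wt):
        with pytest.raises(ValueError):
            ina_current(-20.0, 1.5, 14.2, wt)
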