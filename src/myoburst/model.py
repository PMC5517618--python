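"""Whole-cell model surface: states, currents, fluxes, RHS, resting state.

The model describes an isolated mouse ventricular myocyte: 15 membrane
currents, six Ca2+ fluxes between cytosol, subspace, junctional and network
SR, and Ca2+ buffering by troponin, calmodulin and calsequestrin.  Gating
uses Hodgkin-Huxley variables for the K+ currents and Markov chains for
I_Na, I_CaL, I_Kr and the ryanodine receptor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import engine
from .engine import (
    DEFAULT_INITIAL_STATE,
    N_STATES,
    STATE_NAMES,
    COMPLEMENT_STATES,
    TYPICAL_MAGNITUDE,
    pack_parameters,
)
from .parameters import ModelParameters

__all__ = [
    "StateVector",
    "CurrentSet",
    "FluxSet",
    "compute_currents",
    "compute_fluxes",
    "rhs",
    "find_resting_state",
    "nernst_potentials",
]

_STATE_INDEX = {n: i for i, n in enumerate(STATE_NAMES)}


class StateVector:
    """Named view over the 41-entry model state.

    One state per Markov chain (``PC1``, ``C1_CaL``, ``C3_Na``, ``C0_Kr``) is
    stored implicitly as the complement of its chain, so chain occupancies
    sum to one exactly.
    """

    __slots__ = ("array",)

    def __init__(self, array=None):
        if array is None:
            array = DEFAULT_INITIAL_STATE.copy()
        array = np.asarray(array, dtype=np.float64)
        if array.shape != (N_STATES,):
            raise ValueError(f"state vector must have shape ({N_STATES},), got {array.shape}")
        self.array = array.copy()

    def __getattr__(self, name):
        if name in _STATE_INDEX:
            return self.array[_STATE_INDEX[name]]
        if name in COMPLEMENT_STATES:
            return 1.0 - self.array[list(COMPLEMENT_STATES[name])].sum()
        raise AttributeError(name)

    def __getitem__(self, name):
        return getattr(self, name)

    def with_values(self, **updates) -> "StateVector":
        arr = self.array.copy()
        for name, v in updates.items():
            if name not in _STATE_INDEX:
                raise KeyError(f"unknown state variable {name!r}")
            arr[_STATE_INDEX[name]] = v
        return StateVector(arr)

    def chain_sums(self) -> dict:
        """Total occupancy of each Markov chain (exactly 1 by construction)."""
        return {
            "RyR": self.PC1 + self.PO1 + self.PO2 + self.PC2,
            "CaL": self.C1_CaL + sum(self.array[13:20]),
            "Na": self.C3_Na + sum(self.array[20:28]),
            "Kr": self.C0_Kr + sum(self.array[37:41]),
        }

    def validate(self, occ_tol: float = 1e-8):
        """Raise if concentrations are negative, occupancies leave [0,1], or
        any entry is non-finite (the offending field is named)."""
        for i, name in enumerate(STATE_NAMES):
            if not math.isfinite(self.array[i]):
                raise ValueError(f"state variable {name} is not finite")
        for name in ("Cai", "Cass", "CaJSR", "CaNSR", "Nai", "Ki", "LTRPNCa", "HTRPNCa"):
            if self[name] < 0.0:
                raise ValueError(f"concentration {name} is negative: {self[name]}")
        occ_names = list(STATE_NAMES[9:36]) + list(STATE_NAMES[36:]) + list(COMPLEMENT_STATES)
        for name in occ_names:
            v = self[name]
            if v < -occ_tol or v > 1.0 + occ_tol:
                raise ValueError(f"occupancy/gate {name} outside [0,1]: {v}")
        return self

    def to_dict(self) -> dict:
        d = {n: float(self.array[i]) for i, n in enumerate(STATE_NAMES)}
        d.update({n: float(self[n]) for n in COMPLEMENT_STATES})
        return d

    def copy(self) -> "StateVector":
        return StateVector(self.array)


@dataclass(frozen=True)
class CurrentSet:
    """Membrane current densities (pA/pF, outward positive)."""

    INa: float
    ICaL: float
    IpCa: float
    INaCa: float
    IKtof: float
    IKtos: float
    IKr: float
    IKur: float
    IKss: float
    IK1: float
    IKs: float
    INaK: float
    IClCa: float
    ICab: float
    INab: float
    Istim: float

    def total_ionic(self) -> float:
        """Sum of the 15 ionic currents (stimulus excluded)."""
        return sum(getattr(self, f.name) for f in dc_fields(self)) - self.Istim

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass(frozen=True)
class FluxSet:
    """Ca2+ fluxes (uM/ms): Jup cytosol->NSR, Jrel JSR->subspace, Jtr NSR->JSR,
    Jleak NSR->cytosol, Jxfer subspace->cytosol, Jtrpn cytosol->troponin."""

    Jup: float
    Jrel: float
    Jtr: float
    Jleak: float
    Jxfer: float
    Jtrpn: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _as_array(state) -> np.ndarray:
    if isinstance(state, StateVector):
        return state.array
    return StateVector(state).array


def nernst_potentials(state, params: ModelParameters) -> dict:
    """Reversal potentials (mV) from the current intracellular concentrations."""
    s = StateVector(_as_array(state))
    RT_F = params.RGAS * params.TEMP / params.F
    return {
        "ENa": RT_F * math.log((0.9 * params.Nao + 0.1 * params.Ko) / (0.9 * s.Nai + 0.1 * s.Ki)),
        "EK": RT_F * math.log(params.Ko / s.Ki),
        "ECaN": 0.5 * RT_F * math.log(params.Cao / s.Cai),
        "EKr": RT_F * math.log(
            (0.98 * params.Ko + 0.02 * params.Nao) / (0.98 * s.Ki + 0.02 * s.Nai)
        ),
    }


def compute_currents(state, params: ModelParameters, istim: float = 0.0,
                     slow_inactivation: bool = True) -> CurrentSet:
    """Evaluate all membrane currents at ``state`` (validates the state first)."""
    s = StateVector(_as_array(state))
    s.validate()
    p = pack_parameters(params, slow_inactivation)
    vals = engine.currents_core(s.array, p, float(istim))
    return CurrentSet(*[float(v) for v in vals])


def compute_fluxes(state, params: ModelParameters) -> FluxSet:
    """Evaluate the six Ca2+ fluxes at ``state`` (validates the state first)."""
    s = StateVector(_as_array(state))
    s.validate()
    p = pack_parameters(params, True)
    vals = engine.fluxes_core(s.array, p)
    return FluxSet(*[float(v) for v in vals])


def rhs(t: float, state, params: ModelParameters, istim: float = 0.0,
        slow_inactivation: bool = True) -> np.ndarray:
    """Full state derivative at time ``t`` with stimulus density ``istim``."""
    arr = _as_array(state)
    if not np.all(np.isfinite(arr)):
        bad = STATE_NAMES[int(np.argmax(~np.isfinite(arr)))]
        raise ValueError(f"state variable {bad} is not finite")
    p = pack_parameters(params, slow_inactivation)
    return engine.rhs_core(float(t), arr, p, float(istim))


class RestingStateError(RuntimeError):
    """Raised when no quiescent equilibrium can be located."""


_REST_CACHE: dict = {}


def find_resting_state(
    params: ModelParameters,
    slow_inactivation: bool = True,
    settle_time_ms: float = 100_000.0,
    residual_tol: float = 1e-6,
) -> StateVector:
    """Locate the quiescent equilibrium (rhs ~ 0 at Istim = 0).

    Long unstimulated integration from the published initial conditions,
    followed by Newton refinement of the root of the RHS.  The scaled
    residual norm must fall below ``residual_tol`` and the resting potential
    must lie in the physiological diastolic range [-90, -70] mV.
    """
    p = pack_parameters(params, slow_inactivation)
    key = (p.tobytes(), settle_time_ms, residual_tol)
    if key in _REST_CACHE:
        return StateVector(_REST_CACHE[key])
    y0 = DEFAULT_INITIAL_STATE.copy()
    if not slow_inactivation:
        # reassign slow-inactivated occupancy to the fast-inactivated state
        y0[23] += y0[24] + y0[25]
        y0[24] = 0.0
        y0[25] = 0.0

    sol = solve_ivp(
        engine.rhs_core, (0.0, settle_time_ms), y0, method="LSODA",
        args=(p, 0.0), jac=engine.jac_core,
        rtol=1e-8, atol=1e-10 * TYPICAL_MAGNITUDE,
    )
    if not sol.success:
        raise RestingStateError(f"settling integration failed: {sol.message}")
    y_settled = sol.y[:, -1]

    res = root(
        lambda y: engine.rhs_core(0.0, y, p, 0.0) / TYPICAL_MAGNITUDE,
        y_settled,
        jac=lambda y: engine.jac_core(0.0, y, p, 0.0) / TYPICAL_MAGNITUDE[:, None],
        method="hybr",
        tol=1e-12,
    )
    candidate = res.x if res.success else y_settled
    # Newton may wander off the physical simplex near a marginal direction;
    # fall back to the settled trajectory endpoint in that case.
    drift = np.max(np.abs(candidate - y_settled) / TYPICAL_MAGNITUDE)
    if res.success and drift > 0.05:
        candidate = y_settled
    resid = float(np.max(np.abs(engine.rhs_core(0.0, candidate, p, 0.0) / TYPICAL_MAGNITUDE)))
    if resid > residual_tol:
        raise RestingStateError(
            f"resting state did not converge: scaled residual {resid:.3e} > {residual_tol:.1e}"
        )
    state = StateVector(candidate)
    state.validate(occ_tol=1e-6)
    if not -90.0 <= state.V <= -70.0:
        raise RestingStateError(
            f"resting potential {state.V:.2f} mV outside the diastolic range [-90, -70] mV"
        )
    _REST_CACHE[key] = state.array.copy()
    return state
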