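"""Markov scheme of the fast Na+ current I_Na.

The full scheme has nine states: three closed (C3, C2, C1), one open (O),
one fast-inactivated (IF), two slow-inactivated (I1, I2) and two
closed-inactivated (IC2, IC3).  Slow inactivation — occupancy slowly
accumulating in I1/I2 during sustained depolarization — is the burst-pacing
variable of the whole-cell model; a variant scheme with I1 and I2 (and all
their edges) removed is provided to ablate it.

Rates are in 1/ms and depend only on voltage.  The edge topology is
serialized in the packaged parameter JSON so tests can assert graph
structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters, load_parameter_file

__all__ = [
    "INaScheme",
    "full_scheme",
    "no_slow_inact_scheme",
    "strip_slow_inactivation",
    "ina_rates",
    "ina_occupancy_derivatives",
    "ina_current",
]

_SCHEME_DATA = load_parameter_file()["ina_scheme"]
SLOW_INACT_STATES = tuple(_SCHEME_DATA["slow_inactivation_states"])


@dataclass(frozen=True)
class INaScheme:
    """State list and directed edge set of the I_Na Markov chain.

    ``edges`` maps (source, target) -> rate name; rate names are resolved by
    :func:`ina_rates` at a given voltage.
    """

    variant: str                     # "full" | "no_slow_inact"
    states: tuple[str, ...]
    edges: dict                      # (src, dst) -> rate label

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, name: str) -> int:
        return self.states.index(name)


def full_scheme() -> INaScheme:
    """The nine-state scheme with slow inactivation (I1, I2 present)."""
    edges = {(s, t): r for s, t, r in _SCHEME_DATA["edges"]}
    return INaScheme("full", tuple(_SCHEME_DATA["states"]), edges)


def strip_slow_inactivation(scheme: INaScheme) -> INaScheme:
    """Remove the slow-inactivated states I1 and I2 and every incident edge."""
    if scheme.variant != "full":
        raise ValueError("scheme already has slow inactivation removed")
    states = tuple(s for s in scheme.states if s not in SLOW_INACT_STATES)
    edges = {
        (s, t): r for (s, t), r in scheme.edges.items()
        if s not in SLOW_INACT_STATES and t not in SLOW_INACT_STATES
    }
    return INaScheme("no_slow_inact", states, edges)


def no_slow_inact_scheme() -> INaScheme:
    """The seven-state variant without slow inactivation."""
    return strip_slow_inactivation(full_scheme())


def renormalize_occupancy(occ: np.ndarray, scheme: INaScheme) -> np.ndarray:
    """Map full-scheme occupancy onto the stripped scheme.

    Mass in I1/I2 is reassigned to IF (their nearest inactivated neighbour);
    this convention only matters for warm-started simulations.
    """
    full = full_scheme()
    occ = np.asarray(occ, dtype=float)
    if occ.shape != (full.n_states,):
        raise ValueError("expected full-scheme occupancy")
    out = []
    extra = sum(occ[full.state_index(s)] for s in SLOW_INACT_STATES)
    for s in scheme.states:
        v = occ[full.state_index(s)]
        if s == "IF":
            v += extra
        out.append(v)
    return np.array(out)


def _rate_table(V: float) -> dict:
    """All voltage-dependent rate constants of the full scheme (1/ms)."""
    a11 = 3.802 / (0.1027 * math.exp(-(V + 2.5) / 17.0) + 0.20 * math.exp(-(V + 2.5) / 150.0))
    a12 = 3.802 / (0.1027 * math.exp(-(V + 2.5) / 15.0) + 0.23 * math.exp(-(V + 2.5) / 150.0))
    a13 = 3.802 / (0.1027 * math.exp(-(V + 2.5) / 12.0) + 0.25 * math.exp(-(V + 2.5) / 150.0))
    b11 = 0.1917 * math.exp(-(V + 2.5) / 20.3)
    b12 = 0.20 * math.exp(-(V - 2.5) / 20.3)
    b13 = 0.22 * math.exp(-(V - 7.5) / 20.3)
    a3 = 7.0e-7 * math.exp(-(V + 7.0) / 7.7)
    b3 = 0.0084 + 0.00002 * (V + 7.0)
    a2 = 1.0 / (0.188495 * math.exp(-(V + 7.0) / 16.6) + 0.393956)
    # microscopic reversibility around the O-IF-C1 loop fixes b2
    b2 = a13 * a2 * a3 / (b13 * b3)
    a4 = a2 / 1000.0
    b4 = a3
    a5 = a2 / 95000.0
    b5 = a3 / 50.0
    return {"a11": a11, "a12": a12, "a13": a13, "b11": b11, "b12": b12,
            "b13": b13, "a2": a2, "b2": b2, "a3": a3, "b3": b3,
            "a4": a4, "b4": b4, "a5": a5, "b5": b5}


def ina_rates(V: float, scheme: INaScheme | None = None) -> dict:
    """Evaluate every directed-edge rate of ``scheme`` at voltage ``V`` (mV).

    Returns ``{(src, dst): rate}``; edges absent from the scheme are absent
    from the table.
    """
    if not math.isfinite(V):
        raise ValueError("V must be finite")
    if scheme is None:
        scheme = full_scheme()
    table = _rate_table(V)
    return {edge: table[label] for edge, label in scheme.edges.items()}


def ina_occupancy_derivatives(occ, V: float, scheme: INaScheme | None = None) -> np.ndarray:
    """Master-equation derivative of the occupancy vector (sums to zero)."""
    if scheme is None:
        scheme = full_scheme()
    occ = np.asarray(occ, dtype=float)
    if occ.shape != (scheme.n_states,):
        raise ValueError(
            f"occupancy length {occ.shape} does not match the {scheme.variant} "
            f"scheme ({scheme.n_states} states)"
        )
    rates = ina_rates(V, scheme)
    d = np.zeros(scheme.n_states)
    for (src, dst), k in rates.items():
        flow = k * occ[scheme.state_index(src)]
        d[scheme.state_index(src)] -= flow
        d[scheme.state_index(dst)] += flow
    return d


def ina_current(V: float, O_occupancy: float, Nai: float, params: ModelParameters,
                Ki: float = 143.72) -> float:
    """Ohmic I_Na = GNa * O * (V - ENa) with ENa from the Nernst relation (pA/pF)."""
    if not 0.0 <= O_occupancy <= 1.0:
        raise ValueError("O_occupancy must lie in [0, 1]")
    RT_F = params.RGAS * params.TEMP / params.F
    ENa = RT_F * math.log((0.9 * params.Nao + 0.1 * params.Ko) / (0.9 * Nai + 0.1 * Ki))
    return params.GNa * O_occupancy * (V - ENa)
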