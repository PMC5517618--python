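"""Model constants, genotype presets, and the WT->TG interpolation.

The whole-cell model is parameterized by a flat set of named constants
(conductances, pump maxima, compartment volumes, buffer totals, fixed
extracellular concentrations).  Two presets are shipped: ``wt`` (wild type)
and ``tg`` (TNF-alpha overexpressing transgenic, a mouse model of heart
failure).  The presets differ in exactly seven parameters:

* ``v3``       - maximal SERCA uptake rate scaling J_up (uM/ms)
* ``kNaCa``    - Na+/Ca2+ exchanger scaling factor (pA/pF)
* ``GKtof``    - conductance of the fast transient outward K+ current (mS/uF)
* ``GKur``     - conductance of the ultrarapid delayed rectifier (mS/uF)
* ``GK1``      - conductance of the inward rectifier I_K1 (mS/uF)
* ``k1_power`` - power index on the I_K1 rectification denominator (dimensionless)
* ``k1_slope`` - exponential slope of I_K1 rectification (1/mV)

A consolidated bifurcation parameter ``eps`` interpolates the seven values
from WT (eps=0) to TG (eps=1), either linearly in all seven or with one
named parameter following a faster, monotone exponential schedule.

Units throughout: ms, mV, pA/pF (currents normalized by membrane
capacitance), mS/uF; Ca2+ in uM; Na+/K+ in mM.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "ModelParameters",
    "make_parameters",
    "interpolate_parameters",
    "PARAM_NAMES",
    "SEVEN_PARAMETERS",
    "load_parameter_file",
]


def load_parameter_file() -> dict:
    """Return the packaged parameter file (constants, TG overrides, I_Na topology)."""
    with resources.files("myoburst.data").joinpath("model_parameters.json").open() as fh:
        return json.load(fh)


_DATA = load_parameter_file()

#: canonical ordering of the constant set; defines the layout of the packed
#: parameter vector consumed by the compiled right-hand side.
PARAM_NAMES: tuple[str, ...] = tuple(_DATA["constants"].keys())

#: the seven parameters in which the WT and TG presets differ.
SEVEN_PARAMETERS: tuple[str, ...] = tuple(_DATA["seven_parameters"])

# parameters that must be non-negative (conductances, pump maxima, volumes,
# buffer totals, rate constants, concentrations).  Signed shape parameters
# (reversal potentials, slopes) are excluded.
_NONNEGATIVE = tuple(
    n for n in PARAM_NAMES if n not in ("ECl", "ECaL", "k1_slope", "eta")
)


@dataclass(frozen=True)
class ModelParameters:
    """Complete, validated constant set of the myocyte model.

    Parameters are exposed both by attribute access (``params.GNa``) and as
    a packed float64 vector (:meth:`to_vector`) whose layout follows
    :data:`PARAM_NAMES`.
    """

    genotype_tag: str
    constants: Mapping[str, float] = field(repr=False)

    def __post_init__(self):
        missing = set(PARAM_NAMES) - set(self.constants)
        extra = set(self.constants) - set(PARAM_NAMES)
        if missing or extra:
            raise ValueError(
                f"parameter set mismatch: missing={sorted(missing)}, unknown={sorted(extra)}"
            )
        for name in _NONNEGATIVE:
            if not self.constants[name] >= 0.0:
                raise ValueError(f"parameter {name} must be >= 0, got {self.constants[name]}")
        for name, v in self.constants.items():
            if not math.isfinite(v):
                raise ValueError(f"parameter {name} is not finite")
        object.__setattr__(self, "constants", dict(self.constants))

    def __getattr__(self, name: str) -> float:
        try:
            return self.constants[name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return self.constants[name]

    def to_vector(self) -> np.ndarray:
        """Pack the constants into the float64 vector layout of PARAM_NAMES."""
        return np.array([self.constants[n] for n in PARAM_NAMES], dtype=np.float64)

    def replace(self, genotype_tag: str | None = None, **updates: float) -> "ModelParameters":
        """Return a copy with named constants replaced."""
        unknown = set(updates) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        c = dict(self.constants)
        c.update(updates)
        return ModelParameters(genotype_tag or self.genotype_tag, c)

    def differing_from(self, other: "ModelParameters") -> list[str]:
        """Names of constants whose values differ from ``other`` (exact comparison)."""
        return [n for n in PARAM_NAMES if self.constants[n] != other.constants[n]]


def make_parameters(genotype: str) -> ModelParameters:
    """Build the WT or TG parameter preset.

    ``tg`` applies the seven transgenic overrides on top of the wild-type
    constant set; everything else is bit-identical between the presets.
    """
    genotype = genotype.lower()
    if genotype == "wt":
        return ModelParameters("wt", dict(_DATA["constants"]))
    if genotype == "tg":
        c = dict(_DATA["constants"])
        c.update(_DATA["tg_overrides"])
        return ModelParameters("tg", c)
    raise ValueError(f"unknown genotype {genotype!r}; expected 'wt' or 'tg'")


def interpolate_parameters(
    eps: float,
    schedule: str = "linear",
    exponential_param: str | None = None,
    k: float = 5.0,
) -> ModelParameters:
    """Interpolate the seven WT/TG-differing parameters at position ``eps``.

    ``eps=0`` reproduces the WT preset bit-identically, ``eps=1`` the TG
    preset.  With ``schedule='linear'`` every flagged parameter follows
    ``p_WT + eps*(p_TG - p_WT)``.  With ``schedule='exponential'`` the single
    parameter named by ``exponential_param`` instead follows the monotone,
    endpoint-preserving map ``p_WT + (p_TG - p_WT)*(exp(k*eps)-1)/(exp(k)-1)``
    (a faster progression towards the failing value; ``k`` controls how much
    faster), while the remaining six stay linear.
    """
    if not 0.0 <= eps <= 1.0:
        raise ValueError(f"eps must lie in [0, 1], got {eps}")
    if schedule not in ("linear", "exponential"):
        raise ValueError(f"unknown schedule {schedule!r}")
    if schedule == "exponential":
        if exponential_param not in SEVEN_PARAMETERS:
            raise ValueError(
                f"exponential_param must be one of {SEVEN_PARAMETERS}, got {exponential_param!r}"
            )
    wt = make_parameters("wt")
    tg = make_parameters("tg")
    if eps == 0.0:
        return ModelParameters("interpolated", dict(wt.constants))
    if eps == 1.0:
        return ModelParameters("interpolated", dict(tg.constants))
    c = dict(wt.constants)
    for name in SEVEN_PARAMETERS:
        a, b = wt.constants[name], tg.constants[name]
        if schedule == "exponential" and name == exponential_param:
            w = math.expm1(k * eps) / math.expm1(k)
        else:
            w = eps
        c[name] = a + w * (b - a)
    return ModelParameters("interpolated", c)
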