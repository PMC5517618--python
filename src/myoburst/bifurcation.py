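"""Sweep engine and transition-threshold localization.

Brute-force orbit diagrams: for every value of the control parameter
(constant stimulus current, basic cycle length, or the WT->TG interpolation
parameter eps) the model is simulated from its own resting state (cold
start), features are extracted over the analysis window, and the per-point
regime labels are assembled into a diagram with a list of transitions.
Thresholds are then refined by bisection on the control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureSet, extract_features
from .parameters import ModelParameters, interpolate_parameters, make_parameters
from .protocols import SolverFailure, StimulusProtocol, run_simulation

__all__ = [
    "BifurcationDiagram",
    "GridPoint",
    "sweep",
    "find_threshold",
    "make_point_classifier",
    "ca_ap_threshold_split",
    "ThresholdError",
]

CONTROLS = ("istim", "bcl", "epsilon")


@dataclass
class GridPoint:
    control_value: float
    features: FeatureSet | None
    regime: str
    ca_regime: str
    error: str | None = None


@dataclass
class BifurcationDiagram:
    """Per-grid-point feature summaries along one control parameter."""

    control: str
    grid: np.ndarray
    points: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if len(g) > 1 and not (np.all(np.diff(g) > 0) or np.all(np.diff(g) < 0)):
            raise ValueError("grid must be strictly monotone")
        self.grid = g

    def regimes(self, observable: str = "ap") -> list:
        attr = "regime" if observable == "ap" else "ca_regime"
        return [getattr(pt, attr) for pt in self.points]

    def transitions(self, observable: str = "ap") -> list:
        """Ordered (control value, from-regime, to-regime) where labels change."""
        labels = self.regimes(observable)
        out = []
        for i in range(1, len(labels)):
            if labels[i] != labels[i - 1] and self.points[i].error is None:
                out.append((float(self.grid[i]), labels[i - 1], labels[i]))
        return out

    def to_frame(self):
        """Tidy table: one row per grid point x extremum branch."""
        import pandas as pd

        rows = []
        for pt in self.points:
            base = {"control": self.control, "value": pt.control_value,
                    "regime": pt.regime, "ca_regime": pt.ca_regime,
                    "error": pt.error}
            if pt.features is None:
                rows.append({**base, "observable": None, "branch": np.nan})
                continue
            f = pt.features
            for name, branches in (
                ("v_max", f.v_max_branches), ("v_min", f.v_min_branches),
                ("ca_peak", f.ca_peak_branches), ("ca_min", f.ca_min_branches),
            ):
                for b in branches:
                    rows.append({**base, "observable": name, "branch": float(b),
                                 "mean_isi": f.mean_isi})
        return pd.DataFrame(rows)


def _point_setup(control, value, genotype="wt", istim=None, scheme="full",
                 eps_schedule="linear", exponential_param=None,
                 total_duration=50.0, analysis_window=None, protocol_kwargs=None):
    """Build (params, protocol) for one grid point of a sweep."""
    protocol_kwargs = dict(protocol_kwargs or {})
    if control == "istim":
        params = make_parameters(genotype)
        protocol = StimulusProtocol.constant(
            amplitude=value, total_duration=total_duration,
            analysis_window=analysis_window, **protocol_kwargs)
    elif control == "bcl":
        params = make_parameters(genotype)
        if analysis_window is None:
            analysis_window = (max(0.0, total_duration - 2.0), total_duration)
        protocol = StimulusProtocol.pulsed(
            bcl=value, total_duration=total_duration,
            analysis_window=analysis_window, **protocol_kwargs)
    elif control == "epsilon":
        if istim is None:
            raise ValueError("epsilon sweep requires the istim level")
        params = interpolate_parameters(value, eps_schedule, exponential_param)
        protocol = StimulusProtocol.constant(
            amplitude=istim, total_duration=total_duration,
            analysis_window=analysis_window, **protocol_kwargs)
    else:
        raise ValueError(f"unknown control {control!r}; expected one of {CONTROLS}")
    return params, protocol


def evaluate_point(control, value, scheme="full", rtol=1e-6, **setup) -> GridPoint:
    """Simulate one grid point (cold start) and classify it."""
    params, protocol = _point_setup(control, value, scheme=scheme, **setup)
    try:
        trace = run_simulation(params, protocol, scheme=scheme, rtol=rtol)
        feats = extract_features(trace, window=protocol.analysis_window)
        return GridPoint(float(value), feats, feats.regime, feats.ca_regime)
    except SolverFailure as exc:  # point flagged, sweep continues
        return GridPoint(float(value), None, "failed", "failed", error=str(exc))


def sweep(control, grid, scheme="full", rtol=1e-6, **setup) -> BifurcationDiagram:
    """Run one simulation + feature extraction per grid value (grid order)."""
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0:
        raise ValueError("empty sweep grid")
    _validate_range(control, grid)
    points = [evaluate_point(control, v, scheme=scheme, rtol=rtol, **setup) for v in grid]
    meta = {"control": control, "scheme": scheme, **{k: str(v) for k, v in setup.items()}}
    return BifurcationDiagram(control, grid, points, meta)


_RANGES = {"istim": (0.0, 1.0), "bcl": (30.0, 150.0), "epsilon": (0.0, 1.0)}


def _validate_range(control, grid):
    lo, hi = _RANGES.get(control, (-np.inf, np.inf))
    if np.min(grid) < lo - 1e-12 or np.max(grid) > hi + 1e-12:
        raise ValueError(f"{control} grid must lie within [{lo}, {hi}]")


class ThresholdError(RuntimeError):
    pass


def make_point_classifier(control, observable="ap", scheme="full", rtol=1e-6, **setup):
    """Classifier ``value -> regime label`` for :func:`find_threshold` (cached)."""
    cache = {}

    def classify(value):
        v = round(float(value), 12)
        if v not in cache:
            pt = evaluate_point(control, v, scheme=scheme, rtol=rtol, **setup)
            cache[v] = pt.regime if observable == "ap" else pt.ca_regime
        return cache[v]

    classify.cache = cache
    return classify


def find_threshold(classify, bracket, transition, tol: float = 0.005) -> float:
    """Bisect the control until the from->to transition is bracketed to ``tol``.

    ``classify`` maps a control value to a regime label; the bracket
    endpoints must classify to the transition's from/to regimes.  A midpoint
    classifying to neither label is a non-monotone classification and raises
    with the offending evaluations.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    frm, to = transition
    c_lo, c_hi = classify(lo), classify(hi)
    if c_lo != frm or c_hi != to:
        raise ThresholdError(
            f"bracket endpoints do not match transition {frm}->{to}: "
            f"classify({lo})={c_lo}, classify({hi})={c_hi}"
        )
    evals = [(lo, c_lo), (hi, c_hi)]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        c_mid = classify(mid)
        evals.append((mid, c_mid))
        if c_mid == frm:
            lo = mid
        elif c_mid == to:
            hi = mid
        else:
            raise ThresholdError(
                f"non-monotone classification inside bracket for {frm}->{to}: {evals}"
            )
    return 0.5 * (lo + hi)


def ca_ap_threshold_split(diagram_ap: BifurcationDiagram, diagram_ca: BifurcationDiagram):
    """Per-observable transition table; reports where Ca and AP transitions differ.

    Both diagrams must share a grid.  Returns a dict with the AP transition
    list (from ``diagram_ap``'s voltage labels), the Ca transition list (from
    ``diagram_ca``'s calcium labels), and their symmetric difference.
    """
    if len(diagram_ap.grid) != len(diagram_ca.grid) or not np.allclose(
            diagram_ap.grid, diagram_ca.grid):
        raise ValueError("diagrams do not share a grid")
    ap_tr = diagram_ap.transitions("ap")
    ca_tr = diagram_ca.transitions("ca")
    ap_set, ca_set = set(ap_tr), set(ca_tr)
    differences = sorted(ap_set.symmetric_difference(ca_set))
    return {"ap": ap_tr, "ca": ca_tr, "differences": differences}
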