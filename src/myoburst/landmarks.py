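"""Characteristic transition thresholds of the WT/TG models.

High-level wrappers that locate, by bisection or grid scan, the stimulus
currents, interpolation positions and cycle lengths at which the cell's
regime changes: the rheobase-like onset of activity under constant current,
the onsets of alternans/bursting/depolarized block, the irregular-calcium
pacing windows, and SR-content extrema.  These are the quantities a
bifurcation study of the WT -> TG (heart-failure) transition reports.
"""

from __future__ import annotations

import numpy as np

from .bifurcation import (
    ThresholdError,
    evaluate_point,
    find_threshold,
    make_point_classifier,
    sweep,
)
from .features import extract_features
from .parameters import interpolate_parameters, make_parameters
from .protocols import StimulusProtocol, run_simulation

__all__ = [
    "activity_onset",
    "regime_sequence",
    "block_onset",
    "bursting_onset",
    "epsilon_thresholds",
    "ca_irregular_bcl_lower_bound",
    "max_sr_content",
    "mean_spiking_isi",
]

QUIESCENT = "quiescent"
BLOCK = "depolarized-block"


def _collapse(labels):
    out = []
    for lab in labels:
        if not out or out[-1] != lab:
            out.append(lab)
    return out


def _binary_classifier(control, predicate, **setup):
    """Wrap a point classifier into a two-label (false/true) classifier."""
    base = make_point_classifier(control, **setup)

    def classify(value):
        return "true" if predicate(base(value)) else "false"

    classify.base = base
    return classify


def activity_onset(control="istim", bracket=(0.0, 1.0), tol=0.005, **setup) -> float:
    """Smallest control value at which the cell leaves the quiescent state.

    Bisects the boundary between ``quiescent`` and any active/depolarized
    label (spiking, alternans, bursting, irregular, depolarized-block).
    """
    classify = _binary_classifier(control, lambda lab: lab != QUIESCENT, **setup)
    return find_threshold(classify, bracket, ("false", "true"), tol)


def block_onset(control="istim", bracket=(0.0, 1.0), tol=0.005, **setup) -> float:
    """Smallest control value at which only the depolarized block remains."""
    classify = _binary_classifier(control, lambda lab: lab == BLOCK, **setup)
    return find_threshold(classify, bracket, ("false", "true"), tol)


def bursting_onset(control="istim", bracket=(0.0, 1.0), tol=0.005,
                   observable="ap", **setup) -> float:
    """Smallest control value classified as bursting (raises if absent)."""
    classify = _binary_classifier(
        control, lambda lab: lab == "bursting", observable=observable, **setup)
    return find_threshold(classify, bracket, ("false", "true"), tol)


def regime_sequence(control, grid, observable="ap", **setup):
    """Collapsed ordered regime labels along a control grid, plus the diagram."""
    diagram = sweep(control, grid, **setup)
    return _collapse(diagram.regimes(observable)), diagram


def epsilon_thresholds(istim=0.55, tol=0.01, grid_step=0.1, **setup) -> dict:
    """Transition positions along the WT->TG interpolation at fixed current.

    Returns the onset of activity (loss of the resting steady state), the
    alternans onset and the bursting onset.  Where a stage is absent from
    the route, the onset of the next stage that does occur is reported and
    flagged in ``missing``.
    """
    setup = {"istim": istim, **setup}
    labels, diagram = regime_sequence("epsilon", np.arange(0.0, 1.0001, grid_step),
                                      **setup)
    onset = activity_onset("epsilon", (0.0, 1.0), tol, **setup)
    result = {"onset": onset, "route": labels, "missing": []}

    def _stage(stage_label):
        present = [pt.control_value for pt in diagram.points if pt.regime == stage_label]
        if not present:
            result["missing"].append(stage_label)
            return None
        lo = max([g for g in diagram.grid if g < present[0]], default=0.0)
        classify = _binary_classifier(
            "epsilon", lambda lab: lab == stage_label, **setup)
        try:
            return find_threshold(classify, (lo, present[0]), ("false", "true"), tol)
        except ThresholdError:
            return present[0]

    result["alternans"] = _stage("alternans")
    result["bursting"] = _stage("bursting")
    if result["alternans"] is None:
        result["alternans"] = onset
    if result["bursting"] is None:
        # fall back to the onset of the terminal (eps -> 1) regime
        terminal = labels[-1]
        classify = _binary_classifier("epsilon", lambda lab: lab == terminal, **setup)
        try:
            result["bursting"] = find_threshold(classify, (0.0, 1.0),
                                                ("false", "true"), tol)
        except ThresholdError:
            result["bursting"] = onset
    return result


def ca_irregular_bcl_lower_bound(genotype, bcl_grid, total_duration=50.0,
                                 rtol=1e-6) -> float | None:
    """Smallest BCL (scanning upward) whose Ca2+ regime is non-periodic.

    Pacing at 60 pA/pF, 1 ms pulses; features from the final 2 s of the run.
    Returns None if every grid point is periodic/steady.
    """
    for bcl in bcl_grid:
        pt = evaluate_point("bcl", float(bcl), genotype=genotype,
                            total_duration=total_duration, rtol=rtol)
        if pt.error is None and pt.ca_regime not in ("periodic", "steady"):
            return float(bcl)
    return None


def max_sr_content(genotype, istim, total_duration=50.0, window=(40.0, 50.0),
                   rtol=1e-6) -> float:
    """Maximum network-SR Ca2+ concentration (uM) over the analysis window."""
    params = make_parameters(genotype)
    protocol = StimulusProtocol.constant(istim, total_duration=total_duration,
                                         analysis_window=window)
    trace = run_simulation(params, protocol, rtol=rtol)
    return float(trace.CaNSR[trace.window_mask(window)].max())


def mean_spiking_isi(genotype, istim, scheme="full", total_duration=30.0,
                     window=(20.0, 30.0), rtol=1e-6) -> float:
    """Mean interspike interval (ms) in the window under constant current."""
    params = make_parameters(genotype)
    protocol = StimulusProtocol.constant(istim, total_duration=total_duration,
                                         analysis_window=window)
    trace = run_simulation(params, protocol, scheme=scheme, rtol=rtol)
    feats = extract_features(trace, window=window)
    return feats.mean_isi
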