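"""Feature extraction from simulated traces and regime classification.

Spikes are upward crossings of a threshold voltage (V_th = -40 mV by
default) with hysteresis: after a crossing, the voltage must fall below a
reset level (-50 mV) before a new spike can be counted, so plateau ripples
during bursts are not double-counted.  Crossing times are refined by linear
interpolation between samples.

Regimes are assigned from the interspike-interval (ISI) distribution and
the clustered branches of local extrema:

* ``quiescent``          - no spikes, settled, V below -60 mV
* ``depolarized-block``  - no spikes, settled above -55 mV
* ``spiking``            - one ISI cluster and one AP-amplitude branch
* ``alternans``          - two interleaved amplitude or ISI branches
* ``bursting``           - bimodal ISIs (gap factor >= 3) with >= 2 spikes per train
* ``irregular``          - anything that fits none of the above

Every classification carries a diagnostics dict with the criteria values
that produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "FeatureSet",
    "detect_spikes",
    "interspike_intervals",
    "ap_metrics",
    "extrema_branches",
    "cluster_1d",
    "classify_regime",
    "classify_ca_regime",
    "ca_transient_stats",
    "extract_features",
]

# default thresholds; every classification logs the values it used.
V_THRESHOLD = -40.0        # mV, spike detection (ISI threshold potential)
RESET_LEVEL = -50.0        # mV, hysteresis re-arm level
V_CLUSTER_TOL = 0.5        # mV, branch clustering of V extrema
CA_CLUSTER_REL_TOL = 0.02  # relative, branch clustering of Ca extrema
BURST_GAP_FACTOR = 3.0     # interburst ISI >= factor * median ISI
ALTERNANS_MIN_EVENTS = 5   # events per branch for an alternans call
SETTLE_DVDT_TOL = 0.02     # mV/ms, "settled" criterion for spikeless traces
CA_IRREGULAR_SPREAD = 0.15 # relative peak spread for an irregular-Ca call


def _trace_arrays(trace, signal="V"):
    if hasattr(trace, "t"):
        return np.asarray(trace.t), np.asarray(getattr(trace, signal))
    t, x = trace
    return np.asarray(t), np.asarray(x)


def detect_spikes(trace, v_th: float = V_THRESHOLD, reset_level: float = RESET_LEVEL):
    """Spike times (ms): interpolated upward crossings of ``v_th`` with hysteresis."""
    if reset_level >= v_th:
        raise ValueError("reset_level must be below v_th")
    t, V = _trace_arrays(trace)
    up = np.flatnonzero((V[:-1] < v_th) & (V[1:] >= v_th))
    down = np.flatnonzero((V[:-1] >= reset_level) & (V[1:] < reset_level))
    spikes = []
    armed = V[0] < v_th
    events = []
    for i in up:
        events.append((i, "up"))
    for i in down:
        events.append((i, "down"))
    events.sort()
    for i, kind in events:
        if kind == "down":
            armed = True
        elif armed:
            frac = (v_th - V[i]) / (V[i + 1] - V[i])
            spikes.append(t[i] + frac * (t[i + 1] - t[i]))
            armed = False
    return np.asarray(spikes)


def interspike_intervals(spike_times, window: tuple | None = None):
    """ISIs (ms) between consecutive spikes whose earlier spike lies in ``window`` (s).

    Returns ``(isis, mean_isi)``; with fewer than two qualifying spikes the
    ISI list is empty and the mean is flagged undefined (NaN).
    """
    st = np.asarray(spike_times, dtype=float)
    if np.any(np.diff(st) < 0):
        raise ValueError("spike times must be sorted")
    isis = np.diff(st)
    if window is not None:
        w0, w1 = window[0] * 1000.0, window[1] * 1000.0
        keep = (st[:-1] >= w0) & (st[:-1] <= w1)
        isis = isis[keep]
    if len(isis) == 0:
        return isis, float("nan")
    return isis, float(np.mean(isis))


def ap_metrics(trace, spike_times, window: tuple | None = None):
    """Per-AP amplitude and APD50.

    Amplitude is peak V minus the preceding diastolic minimum; APD50 runs
    from the upstroke (time of maximal dV/dt preceding the peak) until V
    first repolarizes below ``peak - 0.5*amplitude``.  APs truncated by the
    end of the trace are omitted.
    """
    t, V = _trace_arrays(trace)
    st = np.asarray(spike_times, dtype=float)
    out = {"amplitude": [], "apd50": [], "peak_time": [], "peak_v": [],
           "diastolic_v": [], "upstroke_time": []}
    if len(st) == 0:
        return {k: np.asarray(v) for k, v in out.items()}
    dV = np.diff(V) / np.diff(t)
    cross_idx = np.searchsorted(t, st)
    for k, s in enumerate(st):
        i_cross = cross_idx[k]
        i_end = cross_idx[k + 1] if k + 1 < len(st) else len(V)
        seg = slice(i_cross, i_end)
        i_peak = i_cross + int(np.argmax(V[seg]))
        i_prev = cross_idx[k - 1] + int(np.argmax(V[cross_idx[k - 1]:i_cross])) if k > 0 else 0
        i_min = i_prev + int(np.argmin(V[i_prev:i_cross + 1]))
        peak_v = V[i_peak]
        dia_v = V[i_min]
        amp = peak_v - dia_v
        if i_min >= i_peak:
            continue
        i_up = i_min + int(np.argmax(dV[i_min:i_peak])) if i_peak > i_min else i_min
        t_up = t[i_up]
        level = peak_v - 0.5 * amp
        below = np.flatnonzero(V[i_peak:i_end] < level)
        if len(below) == 0:
            continue  # truncated AP
        j = i_peak + below[0]
        frac = (level - V[j - 1]) / (V[j] - V[j - 1])
        t50 = t[j - 1] + frac * (t[j] - t[j - 1])
        out["amplitude"].append(amp)
        out["apd50"].append(t50 - t_up)
        out["peak_time"].append(t[i_peak])
        out["peak_v"].append(peak_v)
        out["diastolic_v"].append(dia_v)
        out["upstroke_time"].append(t_up)
    res = {k: np.asarray(v) for k, v in out.items()}
    if window is not None and len(res["peak_time"]):
        # metrics are computed on the full train (each AP needs its true
        # preceding diastole) and only then restricted to the window
        keep = ((res["peak_time"] >= window[0] * 1000.0)
                & (res["peak_time"] <= window[1] * 1000.0))
        res = {k: v[keep] for k, v in res.items()}
    return res


def cluster_1d(values, tol: float):
    """Greedy 1-D clustering: sorted values split where the gap exceeds ``tol``.

    Returns ``(representatives, assignment)`` where representatives are
    cluster means and assignment maps each input value to its cluster.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        return np.asarray([]), np.asarray([], dtype=int)
    order = np.argsort(values)
    sorted_v = values[order]
    cluster_of_sorted = np.zeros(len(values), dtype=int)
    c = 0
    for i in range(1, len(sorted_v)):
        if sorted_v[i] - sorted_v[i - 1] > tol:
            c += 1
        cluster_of_sorted[i] = c
    assignment = np.empty(len(values), dtype=int)
    assignment[order] = cluster_of_sorted
    reps = np.array([values[assignment == k].mean() for k in range(c + 1)])
    return reps, assignment


def _local_extrema(x):
    """Indices of interior local maxima and minima (plateau-safe)."""
    dx = np.diff(x)
    rising = dx > 0
    falling = dx < 0
    maxima, minima = [], []
    last_dir = 0
    for i in range(len(dx)):
        if rising[i]:
            if last_dir < 0:
                minima.append(i)
            last_dir = 1
        elif falling[i]:
            if last_dir > 0:
                maxima.append(i)
            last_dir = -1
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def extrema_branches(trace, window: tuple | None = None, cluster_tol: float = V_CLUSTER_TOL,
                     relative: bool = False, signal: str = "V"):
    """Clustered local-extrema branches of a series (the orbit-diagram points).

    Returns a dict with branch representatives and the raw extremum values.
    A series without interior extrema yields one max branch = one min branch
    (its extreme values).
    """
    t, x = _trace_arrays(trace, signal)
    if window is not None:
        m = (t >= window[0] * 1000.0) & (t <= window[1] * 1000.0)
        t, x = t[m], x[m]
    imax, imin = _local_extrema(x)
    vmax = x[imax] if len(imax) else np.array([x.max()])
    vmin = x[imin] if len(imin) else np.array([x.min()])
    tol_max = cluster_tol * max(abs(np.median(vmax)), 1e-30) if relative else cluster_tol
    tol_min = cluster_tol * max(abs(np.median(vmin)), 1e-30) if relative else cluster_tol
    max_branches, max_assign = cluster_1d(vmax, tol_max)
    min_branches, min_assign = cluster_1d(vmin, tol_min)
    return {
        "max_branches": max_branches, "min_branches": min_branches,
        "max_values": vmax, "min_values": vmin,
        "max_assignment": max_assign, "min_assignment": min_assign,
    }


def _interleaved(assignment) -> bool:
    """True if a two-branch assignment strictly alternates (>=90% of steps)."""
    a = np.asarray(assignment)
    if len(a) < 2:
        return False
    return float(np.mean(a[1:] != a[:-1])) >= 0.9


def _burst_structure(isis, gap_factor):
    """Split an ISI sequence into spike trains separated by long gaps."""
    isis = np.asarray(isis, dtype=float)
    med = float(np.median(isis))
    long_mask = isis >= gap_factor * med
    runs = []
    count = 1
    for flag in long_mask:
        if flag:
            runs.append(count)
            count = 1
        else:
            count += 1
    runs.append(count)
    return med, long_mask, runs


@dataclass
class FeatureSet:
    """All extracted AP/Ca features plus the regime labels and diagnostics."""

    spike_times: np.ndarray
    isis: np.ndarray
    mean_isi: float
    amplitudes: np.ndarray
    apd50: np.ndarray
    v_max_branches: np.ndarray
    v_min_branches: np.ndarray
    ca_peak_branches: np.ndarray
    ca_min_branches: np.ndarray
    ca_amplitudes: np.ndarray
    ca_diastolic: float
    regime: str
    ca_regime: str
    burst: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def classify_regime(
    t, V, spike_times, isis, amplitudes,
    gap_factor: float = BURST_GAP_FACTOR,
    alternans_min_events: int = ALTERNANS_MIN_EVENTS,
    settle_tol: float = SETTLE_DVDT_TOL,
):
    """Assign a voltage regime label; returns ``(label, burst_dict, diagnostics)``."""
    diag = {"n_spikes": int(len(spike_times)), "gap_factor": gap_factor,
            "alternans_min_events": alternans_min_events, "settle_tol": settle_tol}
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    if len(spike_times) < 2:
        tail = slice(int(0.5 * len(V)), None)
        dvdt = np.abs(np.diff(V[tail]) / np.diff(t[tail]))
        mean_dvdt = float(np.mean(dvdt))
        v_settle = float(np.mean(V[int(0.9 * len(V)):]))
        v_min = float(np.min(V))
        diag.update(mean_dvdt=mean_dvdt, v_settle=v_settle, v_min=v_min)
        if mean_dvdt < settle_tol and len(spike_times) == 0:
            if v_min < -60.0:
                return "quiescent", {}, diag
            if v_settle > -55.0:
                return "depolarized-block", {}, diag
        return "irregular", {}, diag

    med, long_mask, runs = _burst_structure(isis, gap_factor)
    diag.update(median_isi=med, n_long_gaps=int(long_mask.sum()),
                spikes_per_train=runs)
    if long_mask.sum() >= 2 and np.median(runs) >= 2:
        trains = [r for r in runs if r >= 2]
        st = np.asarray(spike_times)
        gap_isis = np.asarray(isis)[long_mask]
        burst = {
            "spikes_per_burst": float(np.median(runs)),
            "interburst_interval_ms": float(np.mean(gap_isis)),
            "n_bursts": int(long_mask.sum()) + 1,
        }
        # burst duration: span of a median train at the median short ISI
        short = np.asarray(isis)[~long_mask]
        if len(short):
            burst["burst_duration_ms"] = float(np.median(runs) - 1) * float(np.median(short))
        return "bursting", burst, diag

    amp_tol = max(1.0, 0.02 * float(np.median(amplitudes))) if len(amplitudes) else 1.0
    isi_tol = max(2.0, 0.05 * med)
    amp_reps, amp_assign = cluster_1d(amplitudes, amp_tol)
    isi_reps, isi_assign = cluster_1d(isis, isi_tol)
    diag.update(n_amp_branches=len(amp_reps), n_isi_branches=len(isi_reps),
                amp_tol=amp_tol, isi_tol=isi_tol)
    for reps, assign in ((amp_reps, amp_assign), (isi_reps, isi_assign)):
        if len(reps) == 2 and _interleaved(assign):
            counts = np.bincount(assign)
            if counts.min() >= alternans_min_events:
                return "alternans", {}, diag
    if len(amp_reps) == 1 and len(isi_reps) == 1:
        return "spiking", {}, diag
    return "irregular", {}, diag


def classify_ca_regime(
    peak_values,
    rel_tol: float = CA_CLUSTER_REL_TOL,
    irregular_spread: float = CA_IRREGULAR_SPREAD,
    alternans_min_events: int = ALTERNANS_MIN_EVENTS,
):
    """Classify the beat-to-beat Ca2+ transient pattern.

    ``periodic``: one peak branch; ``alternans``: two interleaved branches;
    ``bursting``/``irregular``: more branches with a large relative spread
    (the operational stand-in for the visually-identified irregular windows);
    ``steady``: no resolvable transients.
    """
    peaks = np.asarray(peak_values, dtype=float)
    diag = {"n_peaks": int(len(peaks)), "rel_tol": rel_tol,
            "irregular_spread": irregular_spread}
    if len(peaks) < 2:
        return "steady", diag
    mean_peak = float(np.mean(peaks))
    spread = float((peaks.max() - peaks.min()) / max(mean_peak, 1e-30))
    tol = rel_tol * max(abs(np.median(peaks)), 1e-30)
    reps, assign = cluster_1d(peaks, tol)
    diag.update(n_branches=len(reps), spread=spread)
    if len(reps) == 1 or spread <= rel_tol:
        return "periodic", diag
    if len(reps) == 2 and _interleaved(assign) and np.bincount(assign).min() >= alternans_min_events:
        return "alternans", diag
    if spread > irregular_spread:
        # bimodal large/small transients in trains -> bursting; otherwise irregular
        if len(reps) >= 2 and reps.max() >= 2.0 * reps.min():
            return "bursting", diag
        return "irregular", diag
    if len(reps) == 2:
        # two close branches that do not alternate: treat as periodic jitter
        return "periodic", diag
    return "irregular", diag


def ca_transient_stats(trace, window: tuple | None = None,
                       rel_tol: float = CA_CLUSTER_REL_TOL):
    """Peak/min [Ca2+]_i branches plus per-beat transient amplitudes."""
    t, ca = _trace_arrays(trace, "Cai")
    if window is not None:
        m = (t >= window[0] * 1000.0) & (t <= window[1] * 1000.0)
        t, ca = t[m], ca[m]
    imax, imin = _local_extrema(ca)
    peaks = ca[imax] if len(imax) else np.array([ca.max()])
    mins = ca[imin] if len(imin) else np.array([ca.min()])
    tolp = rel_tol * max(abs(np.median(peaks)), 1e-30)
    tolm = rel_tol * max(abs(np.median(mins)), 1e-30)
    peak_branches, _ = cluster_1d(peaks, tolp)
    min_branches, _ = cluster_1d(mins, tolm)
    # per-beat amplitude: each peak minus the preceding local minimum
    amps = []
    for i in imax:
        prev = imin[imin < i]
        base = ca[prev[-1]] if len(prev) else ca[0]
        amps.append(ca[i] - base)
    return {
        "peak_branches": peak_branches, "min_branches": min_branches,
        "peak_values": peaks, "min_values": mins,
        "amplitudes": np.asarray(amps),
        "diastolic": float(np.median(mins)),
    }


def extract_features(
    trace,
    window: tuple | None = None,
    v_th: float = V_THRESHOLD,
    reset_level: float = RESET_LEVEL,
    v_cluster_tol: float = V_CLUSTER_TOL,
    ca_rel_tol: float = CA_CLUSTER_REL_TOL,
) -> FeatureSet:
    """Full feature extraction over the trace's analysis window."""
    if window is None:
        window = trace.analysis_window if hasattr(trace, "analysis_window") else None
    t, V = _trace_arrays(trace, "V")
    if window is None:
        window = (t[0] / 1000.0, t[-1] / 1000.0)
    spikes_all = detect_spikes(trace, v_th, reset_level)
    w0, w1 = window
    spikes = spikes_all[(spikes_all >= w0 * 1000.0) & (spikes_all <= w1 * 1000.0)]
    isis, mean_isi = interspike_intervals(spikes_all, window)
    ap = ap_metrics(trace, spikes_all, window)
    vb = extrema_branches(trace, window, v_cluster_tol, signal="V")
    ca = ca_transient_stats(trace, window, ca_rel_tol)
    m = (t >= w0 * 1000.0) & (t <= w1 * 1000.0)
    regime, burst, diag = classify_regime(t[m], V[m], spikes, isis, ap["amplitude"])
    ca_regime, ca_diag = classify_ca_regime(ca["peak_values"], ca_rel_tol)
    diag["ca"] = ca_diag
    diag["window_s"] = [w0, w1]
    diag["v_th"] = v_th
    diag["reset_level"] = reset_level
    return FeatureSet(
        spike_times=spikes, isis=isis, mean_isi=mean_isi,
        amplitudes=ap["amplitude"], apd50=ap["apd50"],
        v_max_branches=vb["max_branches"], v_min_branches=vb["min_branches"],
        ca_peak_branches=ca["peak_branches"], ca_min_branches=ca["min_branches"],
        ca_amplitudes=ca["amplitudes"], ca_diastolic=ca["diastolic"],
        regime=regime, ca_regime=ca_regime, burst=burst, diagnostics=diag,
    )
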