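"""Trace and diagram persistence (HDF5 + CSV) and deterministic fixtures.

HDF5 layout for traces::

    /time            ms, float64
    /state/V         mV
    /state/Cai       uM
    /state/CaNSR     uM
    /state/<extra>   any additionally recorded state variables
    /meta            attrs: JSON-encoded protocol, parameters, solver settings

CSV export carries (t, V, Cai) at 12 significant digits.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np

from .protocols import SimulationTrace

__all__ = ["save_trace_hdf5", "load_trace_hdf5", "export_trace_csv",
           "export_diagram_csv", "make_fixtures"]


def save_trace_hdf5(trace: SimulationTrace, path) -> Path:
    import h5py

    path = Path(path)
    # track_times=False keeps regenerated fixture files byte-identical
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=trace.t, track_times=False)
        g = f.create_group("state")
        g.create_dataset("V", data=trace.V, track_times=False)
        g.create_dataset("Cai", data=trace.Cai, track_times=False)
        g.create_dataset("CaNSR", data=trace.CaNSR, track_times=False)
        for name, arr in trace.signals.items():
            g.create_dataset(name, data=arr, track_times=False)
        meta = f.create_group("meta")
        meta.attrs["json"] = json.dumps(trace.metadata)
        if trace.final_state is not None:
            f.create_dataset("final_state", data=trace.final_state, track_times=False)
    return path


def load_trace_hdf5(path) -> SimulationTrace:
    import h5py

    with h5py.File(path, "r") as f:
        t = f["time"][:]
        V = f["state/V"][:]
        Cai = f["state/Cai"][:]
        CaNSR = f["state/CaNSR"][:]
        signals = {k: f["state"][k][:] for k in f["state"]
                   if k not in ("V", "Cai", "CaNSR")}
        metadata = json.loads(f["meta"].attrs["json"])
        final = f["final_state"][:] if "final_state" in f else None
    return SimulationTrace(t=t, V=V, Cai=Cai, CaNSR=CaNSR, signals=signals,
                           metadata=metadata, final_state=final)


def export_trace_csv(trace: SimulationTrace, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("t_ms,V_mV,Cai_uM\n")
        for t, v, c in zip(trace.t, trace.V, trace.Cai):
            fh.write(f"{t:.12g},{v:.12g},{c:.12g}\n")
    return path


def export_diagram_csv(diagram, path) -> Path:
    path = Path(path)
    diagram.to_frame().to_csv(path, index=False)
    return path


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def make_fixtures(directory, duration_s: float = 2.0) -> dict:
    """Deterministic short reference traces with checksums.

    Writes a WT resting run, a WT paced (BCL 100 ms) run, and synthetic
    analytic waveforms (square-pulse spike train, triangular AP) used as
    closed-form oracles for the feature extractors.
    """
    from .parameters import make_parameters
    from .protocols import StimulusProtocol, run_simulation

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}

    wt = make_parameters("wt")
    rest_protocol = StimulusProtocol.constant(
        amplitude=0.0, total_duration=duration_s, analysis_window=(0.0, duration_s))
    trace = run_simulation(wt, rest_protocol)
    out["wt_rest"] = str(save_trace_hdf5(trace, directory / "wt_rest.h5"))

    paced = StimulusProtocol.pulsed(bcl=100.0, total_duration=duration_s,
                                    analysis_window=(0.0, duration_s))
    trace = run_simulation(wt, paced)
    out["wt_paced_bcl100"] = str(save_trace_hdf5(trace, directory / "wt_paced_bcl100.h5"))
    export_trace_csv(trace, directory / "wt_paced_bcl100.csv")

    # synthetic square-wave train: spikes of known count by construction
    t = np.arange(0.0, duration_s * 1000.0, 0.05)
    v = np.where((t % 100.0) < 2.0, 20.0, -80.0)
    ca = 0.1 + 0.4 * ((t % 100.0) < 10.0)
    synth = SimulationTrace(t=t, V=v.astype(float), Cai=ca.astype(float),
                            CaNSR=np.full_like(t, 1000.0),
                            metadata={"synthetic": "square-wave train, period 100 ms"})
    out["synthetic_square"] = str(save_trace_hdf5(synth, directory / "synthetic_square.h5"))

    checksums = {k: _checksum(v) for k, v in out.items()}
    (directory / "checksums.json").write_text(json.dumps(checksums, indent=2))
    out["checksums"] = checksums
    return out
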