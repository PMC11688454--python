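"""File formats: CSV traces, YAML parameter blocks, HDF5 TA maps, JSON.

Trace interchange is plain CSV with ``# key=value`` metadata header lines
followed by a column-header row and data rows.  Floats are serialised
with the shortest representation that round-trips binary64 exactly.
No binary electrophysiology formats are read or written.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from photodipole.membrane_circuit import TimeTrace, MembraneCircuitParams
from photodipole.photokinetics import (PopulationTrace, PhotoswitchParams,
                                       LightProtocol)
from photodipole.spectrofit import TAMap

__all__ = [
    "TraceFormatError",
    "write_trace", "read_trace",
    "write_population_trace", "read_population_trace",
    "save_params_yaml", "load_photoswitch_params", "load_circuit_params",
    "load_protocol", "save_protocol",
    "write_tamap_hdf5", "read_tamap_hdf5",
    "write_tamap_csv", "read_tamap_csv",
    "save_ensemble", "load_ensemble_traces",
    "write_json",
]

_FMT = "%.17g"


class TraceFormatError(ValueError):
    """Malformed trace file; the message carries the offending line number."""


def _fmt_meta_value(v):
    if isinstance(v, float):
        return _FMT % v
    return str(v)


def _parse_meta_value(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    if s in ("True", "False"):
        return s == "True"
    return s


def _write_csv(path, meta: dict, header: str, columns: list[np.ndarray]) -> None:
    # data block written by pyarrow: C-speed and floats serialised with
    # the shortest representation that round-trips binary64 exactly
    import pyarrow as pa
    import pyarrow.csv as pacsv
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = header.split(",")
    table = pa.table({n: np.asarray(c, dtype=float)
                      for n, c in zip(names, columns)})
    with open(path, "wb") as fh:
        for k, v in meta.items():
            if isinstance(v, (str, int, float, bool, np.floating, np.integer)):
                fh.write(f"# {k}={_fmt_meta_value(v)}\n".encode())
        pacsv.write_csv(table, fh)


def _read_csv(path, expected_cols: int):
    import pyarrow.csv as pacsv
    import pyarrow.types as patypes
    meta: dict = {}
    n_meta = 0
    with open(path, "rb") as fh:
        while True:
            pos = fh.tell()
            raw = fh.readline()
            line = raw.decode("utf-8", errors="replace").strip()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            n_meta += 1
            body = line[1:].strip()
            if "=" not in body:
                raise TraceFormatError(
                    f"{path}:{n_meta}: metadata line without '='")
            k, v = body.split("=", 1)
            meta[k.strip()] = _parse_meta_value(v.strip())
        try:
            table = pacsv.read_csv(fh)
        except Exception as exc:
            raise TraceFormatError(
                f"{path}: after line {n_meta}: {exc}") from None
    if table.num_columns != expected_cols:
        raise TraceFormatError(
            f"{path}:{n_meta + 1}: expected {expected_cols} columns, "
            f"got {table.num_columns}")
    if table.num_rows == 0:
        raise TraceFormatError(f"{path}: no data rows")
    cols = []
    for name in table.column_names:
        col = table[name]
        if not (patypes.is_floating(col.type) or patypes.is_integer(col.type)):
            raise TraceFormatError(
                f"{path}: column {name!r} is not numeric")
        cols.append(col.to_numpy().astype(float))
    return meta, list(table.column_names), np.column_stack(cols)


def write_trace(trace: TimeTrace, path) -> None:
    """Write a voltage/current trace as headered CSV (time_s,value)."""
    meta = {"units": trace.units, **trace.meta}
    _write_csv(path, meta, "time_s,value", [trace.t, trace.y])


def read_trace(path) -> TimeTrace:
    """Read a headered CSV trace; validates units and grid uniformity."""
    meta, _, arr = _read_csv(path, 2)
    units = meta.pop("units", None)
    if units not in ("V", "A"):
        raise TraceFormatError(f"{path}: missing or invalid '# units=' header")
    t, y = arr[:, 0], arr[:, 1]
    steps = np.diff(t)
    if t.size < 2 or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-15) \
            or steps[0] <= 0:
        raise TraceFormatError(f"{path}: non-uniform grid in time column")
    return TimeTrace(t=t, y=y, units=units, meta=meta)


def write_population_trace(pop: PopulationTrace, path) -> None:
    _write_csv(path, pop.meta, "time_s,n_trans,n_cis",
               [pop.t, pop.n_trans, pop.n_cis])


def read_population_trace(path) -> PopulationTrace:
    meta, _, arr = _read_csv(path, 3)
    return PopulationTrace(t=arr[:, 0], n_trans=arr[:, 1], n_cis=arr[:, 2],
                           meta=meta)


def save_params_yaml(obj, path) -> None:
    """Serialise a parameter dataclass (or dict) as YAML."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        payload = {"type": type(obj).__name__, **dataclasses.asdict(obj)}
    else:
        payload = dict(obj)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def _load_yaml(path) -> dict:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    d.pop("type", None)
    return d


def load_photoswitch_params(path) -> PhotoswitchParams:
    return PhotoswitchParams(**_load_yaml(path))


def load_circuit_params(path) -> MembraneCircuitParams:
    return MembraneCircuitParams(**_load_yaml(path))


def save_protocol(protocol: LightProtocol, path) -> None:
    save_params_yaml({"type": "LightProtocol",
                      "wavelength_nm": protocol.wavelength_nm,
                      "segments": [list(s) for s in protocol.segments]}, path)


def load_protocol(path) -> LightProtocol:
    d = _load_yaml(path)
    return LightProtocol(segments=tuple(tuple(s) for s in d["segments"]),
                         wavelength_nm=d.get("wavelength_nm", 470.0))


def write_tamap_hdf5(tamap: TAMap, path) -> None:
    import h5py
    with h5py.File(path, "w") as fh:
        fh.create_dataset("wavelengths_nm", data=tamap.wavelengths)
        fh.create_dataset("delays_s", data=tamap.delays)
        fh.create_dataset("dTT", data=tamap.dTT)
        for k, v in tamap.meta.items():
            if v is not None and isinstance(v, (str, int, float, bool)):
                fh.attrs[k] = v


def read_tamap_hdf5(path) -> TAMap:
    import h5py
    with h5py.File(path, "r") as fh:
        return TAMap(wavelengths=fh["wavelengths_nm"][:],
                     delays=fh["delays_s"][:],
                     dTT=fh["dTT"][:],
                     meta=dict(fh.attrs))


def write_tamap_csv(tamap: TAMap, path) -> None:
    """Long-format text alternative: delay_s,wavelength_nm,dTT rows."""
    D, W = np.meshgrid(tamap.delays, tamap.wavelengths, indexing="ij")
    _write_csv(path, tamap.meta, "delay_s,wavelength_nm,dTT",
               [D.ravel(), W.ravel(), tamap.dTT.ravel()])


def read_tamap_csv(path) -> TAMap:
    meta, _, arr = _read_csv(path, 3)
    delays = np.unique(arr[:, 0])
    wl = np.unique(arr[:, 1])
    dTT = arr[:, 2].reshape(delays.size, wl.size)
    return TAMap(wavelengths=wl, delays=delays, dTT=dTT, meta=meta)


def save_ensemble(ensemble, out_dir) -> Path:
    """Write an ensemble as one CSV per trace plus ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = []
    for key, traces in ensemble.traces.items():
        for j, tr in enumerate(traces):
            name = f"{key}_trace{j:03d}.csv"
            write_trace(tr, out / name)
            index.append({"group": key, "file": name})
    manifest = {**ensemble.manifest, "t_on_s": ensemble.t_on,
                "index": index}
    write_json(manifest, out / "manifest.json")
    return out


def load_ensemble_traces(in_dir) -> tuple[dict, dict]:
    """Read back a saved ensemble directory -> (traces by group, manifest)."""
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    traces: dict = {}
    for entry in manifest["index"]:
        traces.setdefault(entry["group"], []).append(
            read_trace(in_dir / entry["file"]))
    return traces, manifest


def load_ensemble(in_dir):
    """Rebuild a :class:`~photodipole.synthetic_data.TraceEnsemble` from disk."""
    from photodipole.synthetic_data import (TraceEnsemble, EnsembleDesign,
                                            GroupSpec, GeneratorTruth)
    from photodipole.photokinetics import PhotoswitchParams
    traces, manifest = load_ensemble_traces(in_dir)
    d = manifest["design"]
    design = EnsembleDesign(
        groups=tuple(GroupSpec(**g) for g in d["groups"]),
        sampling_rate_hz=d["sampling_rate_hz"],
        filter_cutoff_hz=d["filter_cutoff_hz"],
        pre_s=d["pre_s"], post_s=d["post_s"], seed=d["seed"])
    tr = dict(manifest.get("truth", {}))
    ps = tr.pop("photoswitch", None)
    circ = tr.pop("circuit", None)
    truth = GeneratorTruth(
        **tr,
        photoswitch=PhotoswitchParams(**ps) if ps else PhotoswitchParams(),
        circuit=MembraneCircuitParams(**circ) if circ else MembraneCircuitParams())
    return TraceEnsemble(design=design, truth=truth, traces=traces,
                         kind=manifest["kind"], t_on=manifest["t_on_s"],
                         manifest=manifest)


def write_json(payload: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=default)
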