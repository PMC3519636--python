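"""Episodic-sweep text format and protocol JSON I/O.

The sweep file is tab-delimited text: ``#key<TAB>value`` metadata
lines (protocol geometry, sampling interval, solutions, units),
followed by a column header ``time_ms`` + one ``sweep_<k>_nA`` column
per sweep, then the samples.  Values are printed at 9 significant
digits, so write -> read -> write round-trips bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .gating import SolutionPair
from .vclamp import Epoch, SweepRecording, VoltageProtocol

__all__ = [
    "read_sweeps",
    "write_sweeps",
    "read_protocol",
    "write_protocol",
    "SweepParseError",
]

_FMT = "%.9g"


class SweepParseError(ValueError):
    """Malformed episodic-sweep file; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def protocol_to_dict(protocol: VoltageProtocol) -> dict:
    epochs = []
    for e in protocol.epochs:
        d = {"duration": e.duration}
        if e.voltage is not None:
            d["voltage"] = e.voltage
        else:
            d["start"] = e.start
            d["increment"] = e.increment
        epochs.append(d)
    return {
        "name": protocol.name,
        "dt": protocol.dt,
        "holding": protocol.holding,
        "n_sweeps": protocol.n_sweeps,
        "epochs": epochs,
        "roles": dict(protocol.roles),
    }


def protocol_from_dict(d: dict) -> VoltageProtocol:
    return VoltageProtocol(
        name=d["name"],
        dt=d["dt"],
        holding=d["holding"],
        n_sweeps=d["n_sweeps"],
        epochs=tuple(Epoch(**e) for e in d["epochs"]),
        roles=dict(d.get("roles", {})),
    )


def write_protocol(protocol: VoltageProtocol, path) -> None:
    Path(path).write_text(json.dumps(protocol_to_dict(protocol), indent=1))


def read_protocol(path) -> VoltageProtocol:
    return protocol_from_dict(json.loads(Path(path).read_text()))


def write_sweeps(recording: SweepRecording, path) -> None:
    """Write a recording in the episodic-sweep text dialect."""
    proto = recording.protocol
    sol = recording.solutions
    lines = [
        f"#format\tkvclamp-episodic-1",
        f"#protocol\t{json.dumps(protocol_to_dict(proto))}",
        f"#dt\t{_FMT % proto.dt}",
        f"#n_sweeps\t{proto.n_sweeps}",
        f"#k_in_mM\t{_FMT % sol.k_in}",
        f"#k_out_mM\t{_FMT % sol.k_out}",
        f"#temperature_K\t{_FMT % sol.temperature}",
        f"#units\ttime=ms current=nA",
    ]
    for key in ("mode", "seed", "leak_subtracted"):
        if recording.provenance.get(key) is not None:
            lines.append(f"#{key}\t{recording.provenance[key]}")
    model = recording.provenance.get("model")
    if model is not None:
        lines.append(f"#model\t{getattr(model, 'name', model)}")

    header = ["time_ms"] + [f"sweep_{k}_nA" for k in range(proto.n_sweeps)]
    lines.append("\t".join(header))
    mat = np.column_stack([recording.time, recording.currents.T])
    for row in mat:
        lines.append("\t".join(_FMT % x for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sweeps(path) -> SweepRecording:
    """Read an episodic-sweep file back into a :class:`SweepRecording`."""
    meta: dict[str, str] = {}
    data_rows: list[list[float]] = []
    n_cols = None
    header_seen = False

    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t", 1)
                if len(parts) != 2:
                    raise SweepParseError("metadata line lacks a tab", ln)
                meta[parts[0]] = parts[1]
                continue
            cols = line.split("\t")
            if not header_seen:
                if cols[0] != "time_ms":
                    raise SweepParseError(
                        "expected column header starting with 'time_ms'", ln
                    )
                n_cols = len(cols)
                header_seen = True
                continue
            if len(cols) != n_cols:
                raise SweepParseError(
                    f"expected {n_cols} columns, found {len(cols)}", ln
                )
            try:
                data_rows.append([float(c) for c in cols])
            except ValueError as exc:
                raise SweepParseError(str(exc), ln) from None

    for required in ("dt", "n_sweeps", "protocol"):
        if required not in meta:
            raise SweepParseError(f"missing '#{required}' metadata key", 0)
    if not data_rows:
        raise SweepParseError("file contains no samples", 0)

    protocol = protocol_from_dict(json.loads(meta["protocol"]))
    n_sweeps = int(meta["n_sweeps"])
    if n_sweeps != protocol.n_sweeps:
        raise SweepParseError("#n_sweeps disagrees with the protocol", 0)

    mat = np.asarray(data_rows)
    if mat.shape[1] != n_sweeps + 1:
        raise SweepParseError(
            f"expected {n_sweeps + 1} columns, found {mat.shape[1]}", 0
        )
    solutions = SolutionPair(
        k_in=float(meta.get("k_in_mM", 140.0)),
        k_out=float(meta.get("k_out_mM", 2.0)),
        temperature=float(meta.get("temperature_K", 295.0)),
    )
    prov = {"source": str(path)}
    for key in ("mode", "model", "seed", "leak_subtracted"):
        if key in meta:
            prov[key] = meta[key]
    return SweepRecording(
        time=mat[:, 0],
        currents=mat[:, 1:].T,
        protocol=protocol,
        solutions=solutions,
        provenance=prov,
    )
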