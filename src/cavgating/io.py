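"""File formats and run configuration.

Two trace dialects are supported:

* a tab-separated text format (Axon-Text-File style): ``#``-prefixed
  metadata header (JSON payloads), then one or more column blocks (time +
  one current column per sweep).  This is the interchange format.
* an HDF5 container holding the same content in binary.

Round-trips are lossless to 1e-6 pA; writing a freshly-read recording
reproduces the text file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .protocols import VoltageProtocol
from .recording import Recording, Sweep

__all__ = [
    "write_traces_text",
    "read_traces_text",
    "write_traces_h5",
    "read_traces_h5",
    "RunConfig",
    "load_config",
    "config_hash",
]

_MAGIC = "# cavgating traces v1"
_TIME_FMT = "%.4f"
_CURR_FMT = "%.6f"

_META_KEYS = ("dt", "c_m", "cell_id", "construct", "seed", "ljp")


def _jdump(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def _protocol_to_dict(p: VoltageProtocol) -> dict:
    d = dataclasses.asdict(p)
    d["voltage_range"] = list(d["voltage_range"])
    return d


def _protocol_from_dict(d: dict) -> VoltageProtocol:
    d = dict(d)
    d["voltage_range"] = tuple(d["voltage_range"])
    return VoltageProtocol(**d)


def _sweep_meta(sw: Sweep) -> dict:
    return {
        "kind": sw.kind,
        "segments": [[d, v] for d, v in sw.segments],
        "test_voltage": sw.test_voltage,
        "test_window": list(sw.test_window) if sw.test_window else None,
        "control_window": list(sw.control_window) if sw.control_window else None,
        "conditioning_voltage": sw.conditioning_voltage,
        "sub_segments": [[[d, v] for d, v in segs] for segs in sw.sub_segments] or None,
    }


def _sweep_from_meta(m: dict, current: np.ndarray, subs: list) -> Sweep:
    return Sweep(
        segments=[(d, v) for d, v in m["segments"]],
        current=current,
        kind=m["kind"],
        test_voltage=m["test_voltage"],
        test_window=tuple(m["test_window"]) if m["test_window"] else None,
        control_window=tuple(m["control_window"]) if m["control_window"] else None,
        conditioning_voltage=m["conditioning_voltage"],
        subsweeps=subs,
        sub_segments=[[(d, v) for d, v in segs] for segs in m["sub_segments"]] if m["sub_segments"] else [],
    )


def _write_block(lines: list, name: str, dt: float, columns: list) -> None:
    lines.append(f"# block {name}")
    n = len(columns[0])
    for col in columns:
        if len(col) != n:
            raise ValueError(f"block {name}: inconsistent sweep lengths")
    header = "time\t" + "\t".join(f"sw{j:03d}" for j in range(len(columns)))
    lines.append(header)
    for k in range(n):
        t = _TIME_FMT % (k * dt)
        lines.append(t + "\t" + "\t".join(_CURR_FMT % col[k] for col in columns))


def write_traces_text(path, rec: Recording) -> None:
    lines = [_MAGIC]
    meta = {
        "dt": rec.dt,
        "c_m": rec.c_m,
        "cell_id": rec.cell_id,
        "construct": rec.construct,
        "seed": rec.seed,
        "ljp": rec.ljp,
        "protocol": _protocol_to_dict(rec.protocol),
    }
    lines.append("# meta " + _jdump(meta))
    for j, sw in enumerate(rec.sweeps):
        lines.append(f"# sweep {j} " + _jdump(_sweep_meta(sw)))
    if rec.leak_ref is not None:
        lines.append("# leak_ref " + _jdump(_sweep_meta(rec.leak_ref)))
    _write_block(lines, "main", rec.dt, [sw.current for sw in rec.sweeps])
    if rec.leak_ref is not None:
        _write_block(lines, "leak_ref", rec.dt, [rec.leak_ref.current])
    for j, sw in enumerate(rec.sweeps):
        if sw.subsweeps:
            _write_block(lines, f"p4_{j}", rec.dt, sw.subsweeps)
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_blocks(lines):
    blocks, name, rows = {}, None, None
    for ln in lines:
        if ln.startswith("# block "):
            if name is not None:
                blocks[name] = rows
            name, rows = ln[len("# block ") :].strip(), []
        elif name is not None and ln and not ln.startswith(("time", "#")):
            rows.append(ln.split("\t"))
    if name is not None:
        blocks[name] = rows
    out = {}
    for name, rows in blocks.items():
        ncol = len(rows[0])
        for r in rows:
            if len(r) != ncol:
                raise ValueError(f"block {name}: inconsistent column counts")
        arr = np.array(rows, dtype=float)
        out[name] = [arr[:, j] for j in range(1, ncol)]
    return out


def read_traces_text(path) -> Recording:
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or lines[0] != _MAGIC:
        raise ValueError(f"{path}: not a cavgating trace file (bad magic line)")
    meta = None
    sweep_meta = {}
    leak_meta = None
    for ln in lines:
        if ln.startswith("# meta "):
            meta = json.loads(ln[len("# meta ") :])
        elif ln.startswith("# sweep "):
            idx_str, payload = ln[len("# sweep ") :].split(" ", 1)
            sweep_meta[int(idx_str)] = json.loads(payload)
        elif ln.startswith("# leak_ref "):
            leak_meta = json.loads(ln[len("# leak_ref ") :])
    if meta is None:
        raise ValueError(f"{path}: malformed header (missing '# meta' line)")
    for key in _META_KEYS:
        if key not in meta:
            raise ValueError(f"{path}: missing metadata key {key!r}")
    blocks = _parse_blocks(lines)
    if "main" not in blocks:
        raise ValueError(f"{path}: missing main sweep block")
    main_cols = blocks["main"]
    if len(main_cols) != len(sweep_meta):
        raise ValueError(f"{path}: {len(sweep_meta)} sweep headers but {len(main_cols)} columns")
    sweeps = []
    for j in range(len(main_cols)):
        subs = blocks.get(f"p4_{j}", [])
        sweeps.append(_sweep_from_meta(sweep_meta[j], main_cols[j], subs))
    leak_ref = None
    if leak_meta is not None:
        leak_ref = _sweep_from_meta(leak_meta, blocks["leak_ref"][0], [])
    return Recording(
        sweeps=sweeps,
        dt=meta["dt"],
        c_m=meta["c_m"],
        protocol=_protocol_from_dict(meta["protocol"]),
        cell_id=meta["cell_id"],
        construct=meta["construct"],
        seed=meta["seed"],
        ljp=meta["ljp"],
        leak_ref=leak_ref,
    )


def write_traces_h5(path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "cavgating-traces-v1"
        for key in _META_KEYS:
            f.attrs[key] = getattr(rec, key if key != "c_m" else "c_m")
        f.attrs["protocol"] = _jdump(_protocol_to_dict(rec.protocol))
        for j, sw in enumerate(rec.sweeps):
            g = f.create_group(f"sweeps/{j:04d}")
            g.create_dataset("current", data=sw.current)
            g.attrs["meta"] = _jdump(_sweep_meta(sw))
            for k, sub in enumerate(sw.subsweeps):
                g.create_dataset(f"p4/{k}", data=sub)
        if rec.leak_ref is not None:
            g = f.create_group("leak_ref")
            g.create_dataset("current", data=rec.leak_ref.current)
            g.attrs["meta"] = _jdump(_sweep_meta(rec.leak_ref))


def read_traces_h5(path) -> Recording:
    with h5py.File(path, "r") as f:
        sweeps = []
        for key in sorted(f["sweeps"]):
            g = f[f"sweeps/{key}"]
            meta = json.loads(g.attrs["meta"])
            subs = [g[f"p4/{k}"][...] for k in sorted(g["p4"])] if "p4" in g else []
            sweeps.append(_sweep_from_meta(meta, g["current"][...], subs))
        leak_ref = None
        if "leak_ref" in f:
            leak_ref = _sweep_from_meta(json.loads(f["leak_ref"].attrs["meta"]), f["leak_ref/current"][...], [])
        return Recording(
            sweeps=sweeps,
            dt=float(f.attrs["dt"]),
            c_m=float(f.attrs["c_m"]),
            protocol=_protocol_from_dict(json.loads(f.attrs["protocol"])),
            cell_id=str(f.attrs["cell_id"]),
            construct=str(f.attrs["construct"]),
            seed=int(f.attrs["seed"]),
            ljp=float(f.attrs["ljp"]),
            leak_ref=leak_ref,
        )


# ---------------------------------------------------------------------------
# Run configuration


class CohortConfig(BaseModel):
    """One construct: either a bundled reference row or explicit parameters."""

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    construct_label: str = Field(alias="construct")
    table: str | None = None  # key into reference.GATING_TABLES
    row: str | None = None  # row label in that table (defaults to construct)
    n_cells: int | None = None
    params: dict | None = None  # explicit GatingRow fields (overrides table)
    qc_outlier_fraction: float = 0.0
    g_max_sigma: float = 0.3


class ProtocolOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kinds: list[str] = Field(default_factory=lambda: ["IV", "SSI", "INACT5S"])
    iv_step_ms: float = 20.0


class PreprocessOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    ljp: float = -9.3
    leak: str = "offline"  # 'offline' | 'p4' | 'none'
    settle_ms: float = 2.5
    smooth_ms: float = 0.2
    dt: float = 0.05


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected).

    Voltages inside are nominal (pre-correction); the junction potential is
    applied once during preprocessing.
    """

    model_config = ConfigDict(extra="forbid")

    cohorts: list[CohortConfig]
    protocols: ProtocolOptions = Field(default_factory=ProtocolOptions)
    preprocess: PreprocessOptions = Field(default_factory=PreprocessOptions)
    comparisons: str = "reference"  # 'reference' | 'allpairs'
    seed: int = 0
    out_dir: str = "cavgating_out"


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    import hashlib

    payload = _jdump(config.model_dump())
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
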