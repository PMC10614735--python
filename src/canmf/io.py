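"""Readers and writers for traces, rasters, ground truth and fitted models.

Delimited-text formats only: CSV with a header row of neuron IDs, one row
per time point, optional ``#``-prefixed metadata lines (``# dt=0.0333``)
before the header. Ground truth and fit metadata go to JSON sidecars; large
arrays referenced from JSON are stored as separate CSVs next to it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .decompose import Decomposition, RankScanResult
from .simulate import GroundTruth, SpikeRaster, TraceMatrix

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "write_spike_csv",
    "read_spike_csv",
    "write_ground_truth",
    "read_ground_truth",
    "write_decomposition",
    "read_decomposition",
    "write_rank_scan",
    "write_manifest",
]


class TraceParseError(ValueError):
    """Raised for malformed trace files, naming the offending line."""


def _parse_metadata(lines: list[str]) -> tuple[dict, int]:
    meta: dict = {}
    i = 0
    for line in lines:
        stripped = line.strip()
        if not stripped.startswith("#"):
            break
        body = stripped.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
        i += 1
    return meta, i


def read_trace_csv(path, dt: float | None = None) -> TraceMatrix:
    """Read a trace matrix from delimited text.

    Expects an optional ``# dt=...`` comment, then a header row of neuron
    IDs, then one numeric row per time point. ``dt`` overrides the header
    comment; if neither is present the default frame interval (1/30 s) is
    assumed.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise TraceParseError(f"{path}: file is empty")
    meta, start = _parse_metadata(lines)
    if start >= len(lines):
        raise TraceParseError(f"{path}: no header row found")
    header = [c.strip() for c in lines[start].split(",")]
    n_cols = len(header)
    rows = []
    for lineno, line in enumerate(lines[start + 1 :], start=start + 2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != n_cols:
            raise TraceParseError(
                f"{path}:{lineno}: expected {n_cols} columns, found {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError:
            bad = next(
                i for i, c in enumerate(cells) if not _is_number(c)
            )
            raise TraceParseError(
                f"{path}:{lineno}: non-numeric value {cells[bad].strip()!r} "
                f"in column {header[bad]!r}"
            ) from None
    if not rows:
        raise TraceParseError(f"{path}: no data rows")
    if dt is None:
        dt = float(meta.get("dt", 1.0 / 30.0))
    return TraceMatrix(np.asarray(rows, dtype=float), dt=dt)


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def _write_matrix_csv(path, values: np.ndarray, dt: float, fmt: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = ",".join(f"n{i}" for i in range(values.shape[1]))
    with path.open("w") as fh:
        fh.write(f"# dt={dt!r}\n")
        fh.write(header + "\n")
        np.savetxt(fh, values, fmt=fmt, delimiter=",")


def write_trace_csv(path, traces: TraceMatrix) -> None:
    """Write traces with full float precision so read-back is bit-identical."""
    _write_matrix_csv(path, traces.values, traces.dt, fmt="%.17g")


def write_spike_csv(path, raster: SpikeRaster) -> None:
    _write_matrix_csv(path, raster.values, raster.dt, fmt="%d")


def read_spike_csv(path, dt: float | None = None) -> SpikeRaster:
    traces = read_trace_csv(path, dt=dt)
    return SpikeRaster(traces.values.astype(np.uint8), dt=traces.dt)


def write_ground_truth(path, truth: GroundTruth) -> None:
    """Ground truth to JSON; a process raster goes to a CSV referenced by it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc: dict = {"kind": truth.kind}
    if truth.kind == "nodal":
        doc["node_membership"] = truth.node_membership.tolist()
    else:
        doc["process_weights"] = truth.process_weights.tolist()
        raster_path = path.with_suffix(".process_raster.csv")
        write_spike_csv(raster_path, truth.process_raster)
        doc["process_raster_file"] = raster_path.name
    path.write_text(json.dumps(doc, indent=1))


def read_ground_truth(path) -> GroundTruth:
    path = Path(path)
    doc = json.loads(path.read_text())
    if doc["kind"] == "nodal":
        return GroundTruth(kind="nodal", node_membership=np.asarray(doc["node_membership"]))
    raster = read_spike_csv(path.parent / doc["process_raster_file"])
    return GroundTruth(
        kind="process",
        process_weights=np.asarray(doc["process_weights"]),
        process_raster=raster,
    )


def write_decomposition(out_dir, decomposition: Decomposition) -> Path:
    """Write W/H as CSVs plus a JSON sidecar with the fit metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "weights_H.csv", decomposition.weights, delimiter=",", fmt="%.17g")
    if decomposition.activities is not None:
        np.savetxt(
            out_dir / "activities_W.csv",
            decomposition.activities,
            delimiter=",",
            fmt="%.17g",
        )
    sidecar = {
        "method": decomposition.method,
        "k": decomposition.k,
        "r_squared": decomposition.r_squared,
        "aic": decomposition.aic,
        "converged": decomposition.converged,
        "n_iter": decomposition.n_iter,
        "seed": decomposition.seed,
        "variance_explained_per_component": _listify(
            decomposition.variance_explained_per_component
        ),
    }
    (out_dir / "model.json").write_text(json.dumps(sidecar, indent=1))
    return out_dir


def read_decomposition(model_dir) -> Decomposition:
    model_dir = Path(model_dir)
    sidecar = json.loads((model_dir / "model.json").read_text())
    weights = np.atleast_2d(
        np.loadtxt(model_dir / "weights_H.csv", delimiter=",")
    )
    activities_path = model_dir / "activities_W.csv"
    activities = None
    if activities_path.exists():
        activities = np.loadtxt(activities_path, delimiter=",")
        if activities.ndim == 1:
            activities = activities[:, None]
    vexp = sidecar.get("variance_explained_per_component")
    return Decomposition(
        method=sidecar["method"],
        k=sidecar["k"],
        weights=weights,
        activities=activities,
        r_squared=sidecar.get("r_squared"),
        aic=sidecar.get("aic"),
        converged=sidecar.get("converged", True),
        n_iter=sidecar.get("n_iter"),
        seed=sidecar.get("seed"),
        variance_explained_per_component=(
            np.asarray(vexp) if vexp is not None else None
        ),
    )


def write_rank_scan(path, scan: RankScanResult) -> None:
    doc = {
        "k_values": scan.k_values,
        "aic_values": scan.aic_values,
        "r2_values": scan.r2_values,
        "selected_k": scan.selected_k,
        "exhausted": scan.exhausted,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _listify(values):
    if values is None:
        return None
    return np.asarray(values).tolist()


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir, config: dict | object, seed: int | None, files=()) -> Path:
    """Emit the run manifest: version, resolved config, seed, file digests."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if is_dataclass(config) and not isinstance(config, type):
        config = asdict(config)
    doc = {
        "tool": "canmf",
        "version": __version__,
        "config": _jsonable(config),
        "seed": seed,
        "files": {Path(f).name: file_digest(f) for f in files},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(doc, indent=1))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    return obj
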