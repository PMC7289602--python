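"""File round-tripping for photon streams, kymographs, correlation sets and reports.

Photon streams travel either as delimited text with ``# key=value`` header
lines (human-readable, formatted-precision exact) or as an ``.npz`` binary
container (bit-exact).  Kymographs are written as a multi-page TIFF (one
plane per channel and per raw/rescaled matrix) with a JSON sidecar carrying
the z calibration; correlation sets are plain TSV tables with a metadata
header.
"""

from __future__ import annotations

import json
import math
import os
from typing import Dict, Optional, Tuple

import numpy as np

from .correlation import CorrelationSet
from .photonproc import Kymograph, ZMapping
from .simkymo import OpticsConfig, PhotonStream

__all__ = [
    "ParseError",
    "write_photon_stream",
    "read_photon_stream",
    "write_kymographs",
    "read_kymographs",
    "write_correlation_set",
    "read_correlation_set",
    "write_report",
    "read_report",
]

STREAM_COLUMNS = ("macro_time_ns", "micro_time_ns", "tag_cycle", "tag_phase")


class ParseError(ValueError):
    """Malformed input file; carries the offending path and line number."""

    def __init__(self, path: str, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


def _format_header_value(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_photon_stream(stream: PhotonStream, path: str) -> None:
    """Write a stream as TSV (``.tsv``/``.txt``) or npz binary (``.npz``)."""
    if path.endswith(".npz"):
        np.savez_compressed(
            path,
            macro_time_ns=stream.macro_time_ns,
            micro_time_ns=stream.micro_time_ns,
            tag_cycle=stream.tag_cycle,
            tag_phase=stream.tag_phase,
            header_json=np.array(json.dumps(stream.header)),
        )
        return
    with open(path, "w") as fh:
        for k in sorted(stream.header):
            fh.write(f"# {k}={_format_header_value(stream.header[k])}\n")
        fh.write("\t".join(STREAM_COLUMNS) + "\n")
        for i in range(len(stream)):
            fh.write(
                f"{stream.macro_time_ns[i]:.3f}\t{stream.micro_time_ns[i]:.4f}\t"
                f"{stream.tag_cycle[i]:d}\t{stream.tag_phase[i]:.9f}\n"
            )


def read_photon_stream(path: str) -> PhotonStream:
    if path.endswith(".npz"):
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(str(data["header_json"]))
            return PhotonStream(
                macro_time_ns=data["macro_time_ns"],
                micro_time_ns=data["micro_time_ns"],
                tag_cycle=data["tag_cycle"],
                tag_phase=data["tag_phase"],
                header=header,
            )
    header: Dict[str, float] = {}
    rows = []
    saw_columns = False
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise ParseError(path, line_no, "header line without key=value")
                k, v = body.split("=", 1)
                try:
                    header[k.strip()] = float(v)
                except ValueError:
                    header[k.strip()] = v.strip()  # type: ignore[assignment]
                continue
            if not saw_columns:
                if tuple(line.split("\t")) != STREAM_COLUMNS:
                    raise ParseError(path, line_no, f"expected columns {STREAM_COLUMNS}")
                saw_columns = True
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(path, line_no, f"expected 4 columns, got {len(parts)}")
            try:
                rows.append((float(parts[0]), float(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise ParseError(path, line_no, f"bad value: {exc}") from None
    if not saw_columns:
        raise ParseError(path, 1, "missing column header line")
    arr = np.asarray(rows, dtype=float) if rows else np.zeros((0, 4))
    return PhotonStream(
        macro_time_ns=arr[:, 0],
        micro_time_ns=arr[:, 1],
        tag_cycle=arr[:, 2].astype(np.int64),
        tag_phase=arr[:, 3],
        header=header,
    )


def write_kymographs(kymos: Dict[str, Kymograph], path: str) -> None:
    """Multi-page TIFF (rescaled + raw plane per channel) plus JSON sidecar."""
    import tifffile

    channels = sorted(kymos)
    planes = []
    labels = []
    for ch in channels:
        planes.append(kymos[ch].counts.astype(np.float64))
        labels.append(f"{ch}_counts")
        planes.append(kymos[ch].raw_counts.astype(np.float64))
        labels.append(f"{ch}_raw")
    tifffile.imwrite(path, np.stack(planes), photometric="minisblack")
    any_k = kymos[channels[0]]
    sidecar = {
        "planes": labels,
        "line_time_s": any_k.line_time_s,
        "pixel_edges_um": any_k.mapping.pixel_edges.tolist(),
        "dwell_weight": any_k.mapping.dwell_weight.tolist(),
        "optics": any_k.mapping.optics.to_header(),
        "empty": {ch: kymos[ch].empty for ch in channels},
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def _sidecar_path(path: str) -> str:
    return os.path.splitext(path)[0] + ".json"


def read_kymographs(path: str) -> Dict[str, Kymograph]:
    import tifffile

    with open(_sidecar_path(path)) as fh:
        sidecar = json.load(fh)
    planes = tifffile.imread(path)
    optics = OpticsConfig.from_header(sidecar["optics"])
    mapping = ZMapping(
        optics,
        pixel_edges=np.asarray(sidecar["pixel_edges_um"]),
        dwell_weight=np.asarray(sidecar["dwell_weight"]),
    )
    out: Dict[str, Kymograph] = {}
    labels = sidecar["planes"]
    for i in range(0, len(labels), 2):
        ch = labels[i].split("_")[0]
        out[ch] = Kymograph(
            counts=planes[i],
            raw_counts=planes[i + 1],
            line_time_s=sidecar["line_time_s"],
            mapping=mapping,
            channel=ch,
            empty=bool(sidecar.get("empty", {}).get(ch, False)),
        )
    return out


def write_correlation_set(cs: CorrelationSet, path: str) -> None:
    with open(path, "w") as fh:
        for k in sorted(cs.meta):
            fh.write(f"# {k}={_format_header_value(cs.meta[k])}\n")
        fh.write("tau_s\tG_G\terr_G\tG_R\terr_R\tG_x\terr_x\n")
        for i in range(len(cs.tau_s)):
            fh.write(
                f"{cs.tau_s[i]:.9e}\t{cs.g_g[i]:.9e}\t{cs.err_g[i]:.9e}\t"
                f"{cs.g_r[i]:.9e}\t{cs.err_r[i]:.9e}\t{cs.g_x[i]:.9e}\t{cs.err_x[i]:.9e}\n"
            )


def read_correlation_set(path: str) -> CorrelationSet:
    meta: Dict[str, float] = {}
    rows = []
    saw_columns = False
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise ParseError(path, line_no, "header line without key=value")
                k, v = body.split("=", 1)
                try:
                    meta[k.strip()] = float(v)
                except ValueError:
                    meta[k.strip()] = v.strip()  # type: ignore[assignment]
                continue
            if not saw_columns:
                saw_columns = True
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ParseError(path, line_no, f"expected 7 columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(path, line_no, f"bad value: {exc}") from None
    if not rows:
        raise ParseError(path, 1, "no correlation rows found")
    arr = np.asarray(rows)
    return CorrelationSet(
        tau_s=arr[:, 0], g_g=arr[:, 1], err_g=arr[:, 2], g_r=arr[:, 3],
        err_r=arr[:, 4], g_x=arr[:, 5], err_x=arr[:, 6], meta=meta,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def write_report(report: Dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=1)


def read_report(path: str) -> Dict:
    with open(path) as fh:
        return json.load(fh)
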