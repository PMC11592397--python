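"""NRRD volume I/O.

A small, self-contained reader/writer for the subset of NRRD used by the
pipeline: 3D arrays, raw / gzip / ascii encodings, attached or detached
headers, geometry via ``space directions``/``space origin`` (or legacy
``spacings``).  Round-trips are lossless for array values, spacing and
origin.
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path

import numpy as np

from .core import Volume

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask"]

_NRRD_MAGIC = "NRRD"

# NRRD type name -> numpy dtype (little-endian fixed on write)
_TYPE_TO_DTYPE = {
    "signed char": np.int8,
    "int8": np.int8,
    "uchar": np.uint8,
    "unsigned char": np.uint8,
    "uint8": np.uint8,
    "short": np.int16,
    "int16": np.int16,
    "ushort": np.uint16,
    "uint16": np.uint16,
    "int": np.int32,
    "int32": np.int32,
    "uint": np.uint32,
    "uint32": np.uint32,
    "long long": np.int64,
    "int64": np.int64,
    "uint64": np.uint64,
    "float": np.float32,
    "double": np.float64,
}

_DTYPE_TO_TYPE = {
    np.dtype(np.uint8): "uint8",
    np.dtype(np.int16): "int16",
    np.dtype(np.int32): "int32",
    np.dtype(np.int64): "int64",
    np.dtype(np.float32): "float",
    np.dtype(np.float64): "double",
}


class NrrdError(ValueError):
    """Malformed NRRD header or data."""


def _parse_vector(text: str, field: str) -> tuple[float, ...]:
    text = text.strip()
    if not (text.startswith("(") and text.endswith(")")):
        raise NrrdError(f"malformed NRRD field {field!r}: expected '(…)', got {text!r}")
    try:
        return tuple(float(t) for t in text[1:-1].split(","))
    except ValueError as exc:
        raise NrrdError(f"malformed NRRD field {field!r}: {text!r}") from exc


def _parse_header(stream) -> tuple[dict, bytes | None]:
    """Parse header lines; returns (fields, remaining-bytes-or-None)."""
    magic = stream.readline().decode("ascii", errors="replace").rstrip("\r\n")
    if not magic.startswith(_NRRD_MAGIC):
        raise NrrdError(f"not an NRRD file: magic line {magic!r}")
    fields: dict[str, str] = {}
    while True:
        raw = stream.readline()
        if raw in (b"", b"\n", b"\r\n"):
            break
        line = raw.decode("ascii", errors="replace").rstrip("\r\n")
        if line.startswith("#"):
            continue
        if ":" not in line:
            raise NrrdError(f"malformed NRRD header line: {line!r}")
        key, _, value = line.partition(":")
        # key-value pairs use ':=' — treat uniformly
        if value.startswith("="):
            value = value[1:]
        fields[key.strip().lower()] = value.strip()
    return fields, stream.read()


def _decode_data(blob: bytes, fields: dict, shape: tuple[int, ...], dtype: np.dtype) -> np.ndarray:
    encoding = fields.get("encoding", "raw").lower()
    count = int(np.prod(shape))
    if encoding in ("gzip", "gz"):
        blob = gzip.decompress(blob)
    if encoding in ("txt", "text", "ascii"):
        flat = np.array(blob.split(), dtype=dtype)
    else:
        if encoding not in ("raw", "gzip", "gz"):
            raise NrrdError(f"unsupported NRRD encoding {encoding!r}")
        endian = fields.get("endian", "little").lower()
        dt = dtype.newbyteorder("<" if endian == "little" else ">")
        flat = np.frombuffer(blob, dtype=dt, count=count).astype(dtype)
    if flat.size != count:
        raise NrrdError(f"NRRD data size {flat.size} != product of sizes {count}")
    # NRRD stores the first listed axis fastest
    return flat.reshape(shape, order="F")


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a 3D NRRD file (attached or detached header) into a :class:`Volume`."""
    path = Path(path)
    with open(path, "rb") as fh:
        fields, blob = _parse_header(fh)

    for required in ("type", "dimension", "sizes"):
        if required not in fields:
            raise NrrdError(f"missing required NRRD field {required!r} in {path}")
    if int(fields["dimension"]) != 3:
        raise NrrdError(f"expected dimension 3, got {fields['dimension']!r}")
    type_name = fields["type"].lower()
    if type_name not in _TYPE_TO_DTYPE:
        raise NrrdError(f"unsupported NRRD type {fields['type']!r}")
    dtype = np.dtype(_TYPE_TO_DTYPE[type_name])
    shape = tuple(int(s) for s in fields["sizes"].split())

    if "data file" in fields or "datafile" in fields:
        data_path = path.parent / fields.get("data file", fields.get("datafile", ""))
        with open(data_path, "rb") as fh:
            blob = fh.read()
    if blob is None:
        raise NrrdError(f"no data found in {path}")
    values = _decode_data(blob, fields, shape, dtype)

    if "space directions" in fields:
        vecs = _split_vectors(fields["space directions"])
        spacing = tuple(float(np.linalg.norm(v)) for v in vecs)
    elif "spacings" in fields:
        spacing = tuple(float(s) for s in fields["spacings"].split())
    else:
        spacing = (1.0, 1.0, 1.0)
    if "space origin" in fields:
        origin = _parse_vector(fields["space origin"], "space origin")
    else:
        origin = (0.0, 0.0, 0.0)
    return Volume(values=values, spacing_mm=spacing, origin_mm=origin)


def _split_vectors(text: str) -> list[tuple[float, ...]]:
    """Split e.g. '(2,0,0) (0,2,0) (0,0,3)' into vectors; 'none' entries skipped."""
    out = []
    for tok in text.replace(") (", ")|(").split("|"):
        tok = tok.strip()
        if tok.lower() == "none":
            continue
        out.append(_parse_vector(tok, "space directions"))
    return out


def write_volume(path: str | os.PathLike, volume: Volume, encoding: str = "gzip") -> None:
    """Write a :class:`Volume` as NRRD (attached header)."""
    path = Path(path)
    values = np.ascontiguousarray(volume.values)
    if values.dtype not in _DTYPE_TO_TYPE:
        values = values.astype(np.float64)
    type_name = _DTYPE_TO_TYPE[values.dtype]
    sx, sy, sz = volume.spacing_mm
    ox, oy, oz = volume.origin_mm
    header = [
        "NRRD0004",
        "# written by petrad",
        f"type: {type_name}",
        "dimension: 3",
        f"sizes: {values.shape[0]} {values.shape[1]} {values.shape[2]}",
        "space dimension: 3",
        f"space directions: ({sx!r},0,0) (0,{sy!r},0) (0,0,{sz!r})",
        f"space origin: ({ox!r},{oy!r},{oz!r})",
        "endian: little",
        f"encoding: {encoding}",
    ]
    flat = values.astype(values.dtype.newbyteorder("<")).ravel(order="F")
    if encoding == "gzip":
        blob = gzip.compress(flat.tobytes(), mtime=0)
    elif encoding == "raw":
        blob = flat.tobytes()
    elif encoding in ("ascii", "text", "txt"):
        blob = " ".join(repr(v) for v in flat.tolist()).encode("ascii")
    else:
        raise NrrdError(f"unsupported encoding {encoding!r}")
    try:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n\n").encode("ascii"))
            fh.write(blob)
    except OSError as exc:
        raise OSError(f"failed writing NRRD to {path}: {exc}") from exc


def read_mask(path: str | os.PathLike) -> Volume:
    """Read a binary mask; values coerced to uint8 0/1."""
    vol = read_volume(path)
    vals = np.asarray(vol.values)
    if not np.isin(np.unique(vals), (0, 1)).all():
        raise NrrdError(f"mask {path} contains values other than 0/1")
    return Volume(vals.astype(np.uint8), vol.spacing_mm, vol.origin_mm)


def write_mask(path: str | os.PathLike, mask: Volume, encoding: str = "gzip") -> None:
    write_volume(
        path,
        Volume((np.asarray(mask.values) > 0).astype(np.uint8), mask.spacing_mm, mask.origin_mm),
        encoding=encoding,
    )
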