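"""STL surface I/O (binary and ASCII), backed by trimesh.

Round-tripping preserves triangle count exactly and vertex coordinates to
float32 STL precision. Malformed files raise :class:`STLParseError` naming
the byte or line offset where parsing failed.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import trimesh

from .geometry import SurfaceMesh

__all__ = ["read_stl", "write_stl", "STLParseError"]


class STLParseError(ValueError):
    """Raised when an STL file cannot be parsed; the message names the offset."""


def _validate_binary(path: Path, data: bytes) -> None:
    if len(data) < 84:
        raise STLParseError(
            f"{path}: binary STL truncated at byte {len(data)} (header needs 84 bytes)"
        )
    (n_tri,) = struct.unpack("<I", data[80:84])
    expected = 84 + 50 * n_tri
    if len(data) != expected:
        raise STLParseError(
            f"{path}: byte count {len(data)} does not match header triangle count "
            f"{n_tri} (expected {expected}); file ends at byte offset {len(data)}"
        )


def _validate_ascii(path: Path, text: str) -> None:
    tokens = {"facet", "outer", "vertex", "endloop", "endfacet", "endsolid", "normal", "loop"}
    n_vertex = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        word = parts[0].lower()
        if lineno == 1:
            if word != "solid":
                raise STLParseError(f"{path}: line 1: expected 'solid', got {parts[0]!r}")
            continue
        if word == "vertex":
            if len(parts) != 4:
                raise STLParseError(f"{path}: line {lineno}: vertex needs 3 coordinates")
            try:
                [float(x) for x in parts[1:]]
            except ValueError:
                raise STLParseError(
                    f"{path}: line {lineno}: non-numeric vertex coordinate"
                ) from None
            n_vertex += 1
        elif word not in tokens and word != "solid":
            raise STLParseError(f"{path}: line {lineno}: unexpected token {parts[0]!r}")
    if n_vertex % 3 != 0:
        raise STLParseError(f"{path}: vertex count {n_vertex} is not a multiple of 3")


def read_stl(path) -> SurfaceMesh:
    """Read a binary or ASCII STL file into a :class:`SurfaceMesh`."""
    path = Path(path)
    data = path.read_bytes()
    is_ascii = data[:5].lower() == b"solid" and b"facet" in data[:1024].lower()
    if is_ascii:
        _validate_ascii(path, data.decode("ascii", errors="replace"))
    else:
        _validate_binary(path, data)
    try:
        tm = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # pragma: no cover - defensive
        raise STLParseError(f"{path}: STL parse failed at unknown offset: {exc}") from exc
    surf = SurfaceMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        triangles=np.asarray(tm.faces, dtype=np.int64),
    )
    surf.watertight = surf.check_watertight()
    return surf


def write_stl(surface: SurfaceMesh, path, binary: bool = True) -> None:
    """Write a :class:`SurfaceMesh` to STL (binary by default)."""
    path = Path(path)
    tm = trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.triangles, process=False
    )
    data = tm.export(file_type="stl" if binary else "stl_ascii")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
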