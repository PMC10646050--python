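"""On-disk I/O for HS cubes, label maps, manifests and derived rasters.

Cubes travel as an ENVI-style pair: a plain-text ``.hdr`` with ``key = value``
lines and a raw band-sequential (BSQ) little-endian binary payload. The
dialect written here is the minimal subset the acquisition-camera family
emits: ``samples``, ``lines``, ``bands``, ``data type``, ``interleave``,
``byte order`` and a ``wavelength = { ... }`` list.

Label maps are paletted PNGs (red=TT, green=NT, blue=BV, black=BG,
white=unlabelled) with a JSON sidecar recording the palette. Manifests are
UTF-8 CSV with a header row.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .core import (
    DEFAULT_PALETTE,
    CorruptionError,
    FormatError,
    HSCube,
    LabelMap,
)

# ENVI data-type codes used by this dialect.
_DTYPES = {4: np.dtype("<f4"), 5: np.dtype("<f8"), 3: np.dtype("<i4")}
_DTYPE_CODES = {v: k for k, v in _DTYPES.items()}


def _header_path(path: str | Path) -> Path:
    p = Path(path)
    return p if p.suffix == ".hdr" else p.with_suffix(".hdr")


def _data_path(hdr: Path) -> Path:
    for suffix in (".bsq", ".raw", ".img"):
        cand = hdr.with_suffix(suffix)
        if cand.exists():
            return cand
    return hdr.with_suffix(".bsq")


def _parse_header(text: str) -> dict:
    """Parse the ENVI-dialect header into a dict of strings/lists."""
    # Collapse { ... } blocks (possibly multi-line) before line parsing.
    text = re.sub(
        r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text, flags=re.S
    )
    fields: dict[str, object] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.upper() == "ENVI" or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            inner = value.strip("{}").strip()
            fields[key] = [v.strip() for v in inner.split(",") if v.strip()]
        else:
            fields[key] = value
    return fields


def read_cube(path: str | Path) -> HSCube:
    """Read an ENVI-style ``.hdr``/``.bsq`` pair into an :class:`HSCube`.

    Raises
    ------
    FormatError
        If the header lacks a wavelength list or mandatory geometry keys.
    CorruptionError
        If the binary payload size disagrees with the declared geometry.
    """
    hdr = _header_path(path)
    if not hdr.exists():
        raise FileNotFoundError(hdr)
    fields = _parse_header(hdr.read_text())
    try:
        rows = int(fields["lines"])  # type: ignore[arg-type]
        cols = int(fields["samples"])  # type: ignore[arg-type]
        bands = int(fields["bands"])  # type: ignore[arg-type]
    except KeyError as exc:
        raise FormatError(f"header {hdr} missing field {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError(f"header {hdr} has no wavelength list")
    wavelengths = np.array([float(w) for w in fields["wavelength"]])
    dtype = _DTYPES.get(int(fields.get("data type", 4)))  # type: ignore[arg-type]
    if dtype is None:
        raise FormatError(f"unsupported data type in {hdr}")
    interleave = str(fields.get("interleave", "bsq")).lower()
    if interleave != "bsq":
        raise FormatError(f"only BSQ interleave supported, got {interleave!r}")

    payload = _data_path(hdr).read_bytes()
    expected = rows * cols * bands * dtype.itemsize
    if len(payload) != expected:
        raise CorruptionError(
            f"{hdr}: payload is {len(payload)} bytes, header implies {expected}"
        )
    # BSQ: band-major on disk -> move band axis last.
    data = (
        np.frombuffer(payload, dtype=dtype)
        .reshape(bands, rows, cols)
        .transpose(1, 2, 0)
        .astype(np.float64)
    )
    return HSCube(
        data=data,
        wavelengths=wavelengths,
        stage=str(fields.get("hsibrain stage", "raw")),
        patient_id=str(fields.get("hsibrain patient", "")),
        capture_id=str(fields.get("hsibrain capture", "")),
    )


def write_cube(cube: HSCube, path: str | Path) -> None:
    """Write a cube as a float32 BSQ pair (lossless for float32 payloads)."""
    hdr = _header_path(path)
    hdr.parent.mkdir(parents=True, exist_ok=True)
    _write_envi(
        cube.data.astype("<f4"),
        hdr,
        wavelengths=cube.wavelengths,
        extra={
            "hsibrain stage": cube.stage,
            "hsibrain patient": cube.patient_id,
            "hsibrain capture": cube.capture_id,
        },
    )


def _write_envi(
    data: np.ndarray,
    hdr: Path,
    wavelengths: np.ndarray | None = None,
    extra: dict | None = None,
) -> None:
    rows, cols, bands = data.shape
    dtype = np.dtype(data.dtype).newbyteorder("<")
    code = _DTYPE_CODES[dtype]
    lines = [
        "ENVI",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        f"data type = {code}",
        "interleave = bsq",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:.6f}" for w in wavelengths)
        lines.append("wavelength = { " + wl + " }")
    for key, value in (extra or {}).items():
        if value:
            lines.append(f"{key} = {value}")
    hdr.write_text("\n".join(lines) + "\n")
    payload = np.ascontiguousarray(data.transpose(2, 0, 1)).astype(dtype)
    hdr.with_suffix(".bsq").write_bytes(payload.tobytes())


def write_raster(arr: np.ndarray, path: str | Path) -> None:
    """Write a derived raster (probability map, cluster map, guide image).

    Integer rasters round-trip exactly (int32); real rasters round-trip to
    float32 precision. 2-D inputs are stored as single-band cubes.
    """
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError("raster must be 2-D or 3-D")
    hdr = _header_path(path)
    hdr.parent.mkdir(parents=True, exist_ok=True)
    if np.issubdtype(arr.dtype, np.integer):
        _write_envi(arr.astype("<i4"), hdr)
    else:
        _write_envi(arr.astype("<f4"), hdr)


def read_raster(path: str | Path) -> np.ndarray:
    """Read back a raster written by :func:`write_raster`."""
    hdr = _header_path(path)
    fields = _parse_header(hdr.read_text())
    rows = int(fields["lines"])  # type: ignore[arg-type]
    cols = int(fields["samples"])  # type: ignore[arg-type]
    bands = int(fields["bands"])  # type: ignore[arg-type]
    dtype = _DTYPES[int(fields.get("data type", 4))]  # type: ignore[arg-type]
    payload = _data_path(hdr).read_bytes()
    expected = rows * cols * bands * dtype.itemsize
    if len(payload) != expected:
        raise CorruptionError(f"{hdr}: payload size mismatch")
    data = np.frombuffer(payload, dtype=dtype).reshape(bands, rows, cols)
    out = data.transpose(1, 2, 0)
    return out[:, :, 0] if bands == 1 else out


class LabelFormatError(FormatError):
    """Label image uses colours outside the declared palette."""


def read_label_map(
    path: str | Path, palette: dict[tuple[int, int, int], int] | None = None
) -> LabelMap:
    """Read a PNG ground-truth image into a :class:`LabelMap`.

    Every pixel colour must be one of the palette colours; otherwise a
    :class:`LabelFormatError` names the offending pixel coordinates.
    """
    palette = palette or DEFAULT_PALETTE
    rgb = np.asarray(Image.open(path).convert("RGB"))
    labels = np.full(rgb.shape[:2], -1, dtype=np.int64)
    for colour, code in palette.items():
        labels[np.all(rgb == np.array(colour), axis=-1)] = code
    bad = np.argwhere(labels < 0)
    if len(bad):
        shown = ", ".join(f"({r},{c})" for r, c in bad[:10])
        raise LabelFormatError(
            f"{len(bad)} pixel(s) with off-palette colours, e.g. at {shown}"
        )
    return LabelMap(labels)


def write_label_map(
    labels: LabelMap | np.ndarray,
    path: str | Path,
    palette: dict[tuple[int, int, int], int] | None = None,
) -> None:
    """Write a label map as an RGB PNG plus a JSON palette sidecar."""
    palette = palette or DEFAULT_PALETTE
    arr = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    code_to_colour = {code: colour for colour, code in palette.items()}
    rgb = np.zeros((*arr.shape, 3), dtype=np.uint8)
    for code, colour in code_to_colour.items():
        rgb[arr == code] = colour
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(rgb).save(path)
    sidecar = path.with_suffix(".palette.json")
    sidecar.write_text(
        json.dumps({str(code): list(col) for col, code in palette.items()}, indent=1)
    )


def write_tmd_png(rgb: np.ndarray, path: str | Path) -> None:
    """Write a density map as 8-bit RGB: channel = round(255 * fraction)."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("TMD image must be rows x cols x 3")
    img = np.rint(np.clip(rgb, 0.0, 1.0) * 255).astype(np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img).save(path)


@dataclass
class Manifest:
    """Patient/capture roster: one row per HS capture with file locations."""

    table: pd.DataFrame

    REQUIRED = ("patient_id", "capture_id", "cube_path", "gt_path")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"manifest missing columns: {missing}")
        keys = self.table[["patient_id", "capture_id"]]
        if keys.duplicated().any():
            raise FormatError("duplicate (patient_id, capture_id) rows in manifest")

    @property
    def patients(self) -> list[str]:
        return sorted(self.table["patient_id"].unique().tolist())

    def captures(self, patient_id: str | None = None) -> pd.DataFrame:
        if patient_id is None:
            return self.table
        return self.table[self.table["patient_id"] == patient_id]


def read_manifest(path: str | Path, check_paths: bool = True) -> Manifest:
    table = pd.read_csv(path, dtype=str)
    base = Path(path).parent
    if check_paths:
        for col in ("cube_path", "gt_path"):
            for value in table[col]:
                p = Path(value)
                if not p.is_absolute():
                    p = base / p
                if not _header_path(p).exists() and not p.exists():
                    raise FormatError(f"manifest path not resolvable: {value}")
    return Manifest(table)


def write_manifest(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def resolve_path(manifest_path: str | Path, entry: str) -> Path:
    p = Path(entry)
    return p if p.is_absolute() else Path(manifest_path).parent / p
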