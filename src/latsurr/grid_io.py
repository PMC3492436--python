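"""Lattice container and I/O.

A :class:`Lattice` is a complete rectangular grid of real values — the
universal unit every other module consumes.  Grids are addressed
``(row, col)``, 0-based, row 0 at the top.  Three on-disk formats are
supported: delimited text (whitespace or comma separated, ``#`` comments),
NumPy ``.npy`` binary arrays, and TIFF rasters (georeferencing metadata, if
any, is ignored by the statistics).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Lattice",
    "GridFormatError",
    "DegenerateLatticeError",
    "read_lattice",
    "write_lattice",
    "center_normalize",
]


class GridFormatError(ValueError):
    """A grid file is ragged, non-numeric, or has missing cells."""


class DegenerateLatticeError(ValueError):
    """The operation is undefined for a constant (zero-variance) lattice."""


@dataclass(frozen=True)
class Lattice:
    """A complete 2-D grid of real values.

    Parameters
    ----------
    values
        2-D float array, at least 2x2, no missing values.
    kind
        ``"binary"`` if every cell is exactly 0 or 1, else ``"continuous"``.
        Inferred when not given.
    """

    values: np.ndarray
    kind: str = field(default="")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise GridFormatError(f"lattice must be 2-D, got shape {v.shape}")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise GridFormatError(f"lattice must be at least 2x2, got {v.shape}")
        if not np.all(np.isfinite(v)):
            r, c = np.argwhere(~np.isfinite(v))[0]
            raise GridFormatError(f"missing value at ({r},{c})")
        object.__setattr__(self, "values", v)
        inferred = "binary" if np.isin(v, (0.0, 1.0)).all() else "continuous"
        if not self.kind:
            object.__setattr__(self, "kind", inferred)
        elif self.kind == "binary" and inferred != "binary":
            raise GridFormatError("kind='binary' but values outside {0,1}")
        elif self.kind not in ("binary", "continuous"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


_TEXT_EXT = {".grid", ".txt", ".csv", ".tsv", ".dat"}
_BINARY_EXT = {".npy"}
_TIFF_EXT = {".tif", ".tiff"}


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in _BINARY_EXT:
        return "binary-array"
    if ext in _TIFF_EXT:
        return "geotiff"
    return "delimited-text"


def _parse_text(path: str) -> np.ndarray:
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            cells = body.split(",") if "," in body else body.split()
            r = len(rows)
            parsed: list[float] = []
            for c, cell in enumerate(cells):
                cell = cell.strip()
                if not cell:
                    raise GridFormatError(f"missing value at ({r},{c})")
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise GridFormatError(
                        f"non-numeric cell {cell!r} at ({r},{c}) (line {lineno})"
                    ) from None
            if width is None:
                width = len(parsed)
            elif len(parsed) != width:
                raise GridFormatError(
                    f"ragged row {r}: expected {width} cells, got {len(parsed)}"
                )
            rows.append(parsed)
    if not rows:
        raise GridFormatError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def read_lattice(path: str, format: str | None = None) -> Lattice:
    """Read a lattice from disk; ``kind`` is inferred from the values."""
    fmt = format or _infer_format(path)
    if fmt == "delimited-text":
        values = _parse_text(path)
    elif fmt == "binary-array":
        values = np.load(path, allow_pickle=False)
    elif fmt == "geotiff":
        try:
            import tifffile
        except ImportError as exc:  # pragma: no cover
            raise GridFormatError("TIFF support requires the tifffile package") from exc
        values = np.squeeze(tifffile.imread(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return Lattice(np.asarray(values, dtype=float))


def write_lattice(path: str, lattice: Lattice, format: str | None = None) -> None:
    """Write a lattice; text at full double precision, binary bit-exact."""
    fmt = format or _infer_format(path)
    if fmt == "delimited-text":
        np.savetxt(path, lattice.values, fmt="%.17g")
    elif fmt == "binary-array":
        np.save(path, lattice.values)
    else:
        raise ValueError(f"cannot write format {fmt!r}")


def center_normalize(x: Lattice | np.ndarray) -> Lattice:
    """Shift to mean 0 and scale to (population) standard deviation 1.

    Raises :class:`DegenerateLatticeError` on a constant lattice.  The
    result is always of continuous kind.
    """
    v = x.values if isinstance(x, Lattice) else np.asarray(x, dtype=float)
    sd = v.std()
    if sd == 0:
        raise DegenerateLatticeError("constant lattice has no scale")
    return Lattice((v - v.mean()) / sd, kind="continuous")
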