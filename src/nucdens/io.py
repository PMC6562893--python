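"""File formats: XYZ, plain-text Hessian, JSON system bundles, Gaussian
cube volumetric output and delimited-text cuts, plus run configuration."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constants import ANGSTROM_PER_BOHR, ATOMIC_NUMBERS, BOHR_PER_ANGSTROM, ME_PER_AMU
from .density import DensityGrid
from .system import HessianMatrix, MolecularSystem


class FileFormatError(ValueError):
    """Malformed input file; message carries file and line context."""


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_xyz(path, masses=None) -> MolecularSystem:
    """Standard XYZ file (count line, comment, ``element x y z`` in Angstrom).

    Coordinates are converted to bohr.  ``masses`` (m_e) optionally
    overrides the per-label mass lookup, enabling isotope substitution
    without relabelling.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FileFormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise FileFormatError(f"{path}:1: expected the atom count") from None
    if len(lines) < n + 2:
        raise FileFormatError(f"{path}: expected {n} atom lines, file too short")
    labels, coords = [], []
    for i, line in enumerate(lines[2 : n + 2], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise FileFormatError(f"{path}:{i}: expected 'element x y z'")
        labels.append(parts[0])
        try:
            coords.extend(float(v) for v in parts[1:4])
        except ValueError:
            raise FileFormatError(f"{path}:{i}: non-numeric coordinate") from None
    x_eq = np.array(coords) * BOHR_PER_ANGSTROM
    return MolecularSystem(labels, x_eq, masses=masses)


def read_hessian_text(path, n_coords: int | None = None) -> HessianMatrix:
    """Whitespace-delimited 3N x 3N Hessian, E_h/bohr^2, row-major,
    coordinate order x1 y1 z1 x2 ...; ``#`` lines are comments."""
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        try:
            rows.append(([float(v) for v in stripped.split()], lineno))
        except ValueError:
            raise FileFormatError(f"{path}:{lineno}: non-numeric token") from None
    if not rows:
        raise FileFormatError(f"{path}: no numeric data")
    # allow the matrix to be wrapped over several lines: flatten and reshape
    width = len(rows[0][0])
    if all(len(r[0]) == width for r in rows) and len(rows) == width:
        matrix = np.array([r[0] for r in rows])
    else:
        for vals, lineno in rows:
            if len(vals) != width:
                raise FileFormatError(
                    f"{path}:{lineno}: row has {len(vals)} columns, expected {width}"
                )
        raise FileFormatError(f"{path}: expected a square matrix, got {len(rows)}x{width}")
    if n_coords is not None and matrix.shape[0] != n_coords:
        raise FileFormatError(
            f"{path}: Hessian side {matrix.shape[0]} does not match 3N = {n_coords}"
        )
    try:
        return HessianMatrix(matrix)
    except ValueError as exc:
        raise FileFormatError(f"{path}: {exc}") from None


def read_system_json(path) -> tuple[MolecularSystem, HessianMatrix]:
    """JSON bundle with geometry, masses and Hessian.

    Keys: ``labels`` (list of element/isotope tags), ``geometry_bohr`` or
    ``geometry_angstrom`` (flat 3N list), optional ``masses_amu`` or
    ``masses_me``, and ``hessian`` (3N x 3N nested list, E_h/bohr^2).
    """
    path = Path(path)
    data = json.loads(path.read_text())
    try:
        labels = data["labels"]
        if "geometry_bohr" in data:
            x = np.asarray(data["geometry_bohr"], dtype=float)
        else:
            x = np.asarray(data["geometry_angstrom"], dtype=float) * BOHR_PER_ANGSTROM
        masses = None
        if "masses_me" in data:
            masses = np.asarray(data["masses_me"], dtype=float)
        elif "masses_amu" in data:
            masses = np.asarray(data["masses_amu"], dtype=float) * ME_PER_AMU
        hess = np.asarray(data["hessian"], dtype=float)
    except KeyError as exc:
        raise FileFormatError(f"{path}: missing key {exc}") from None
    try:
        return MolecularSystem(labels, x, masses=masses), HessianMatrix(hess)
    except ValueError as exc:
        raise FileFormatError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# Gaussian cube format
# ---------------------------------------------------------------------------

def write_cube(path, grid: DensityGrid, system: MolecularSystem, comment: str = "") -> None:
    """Write a 3D density grid in Gaussian cube format (all values in bohr).

    Header: two comment lines; atom count + origin; three axis records
    (positive counts = bohr); atom records with nuclear charge; then values
    with the last grid index fastest, six per line.
    """
    if len(grid.shape) != 3:
        raise ValueError("cube files require a 3D grid")
    lines = [comment or "one-nucleus density", "values in bohr^-3, axes in bohr"]
    n = system.n_nuclei
    lines.append(f"{n:5d}{grid.origin[0]:12.6f}{grid.origin[1]:12.6f}{grid.origin[2]:12.6f}")
    for k in range(3):
        a = grid.axes[k]
        lines.append(f"{grid.shape[k]:5d}{a[0]:12.6f}{a[1]:12.6f}{a[2]:12.6f}")
    for lab, pos in zip(system.labels, system.positions):
        z = ATOMIC_NUMBERS.get(lab, 0)
        lines.append(f"{z:5d}{float(z):12.6f}{pos[0]:12.6f}{pos[1]:12.6f}{pos[2]:12.6f}")
    flat = grid.values.ravel()  # C order: last index fastest, as cube requires
    for start in range(0, flat.size, 6):
        lines.append("".join(f"{v:13.5E}" for v in flat[start : start + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path) -> tuple[DensityGrid, list]:
    """Read a cube file; returns the grid and a list of (Z, x, y, z) atoms."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise FileFormatError(f"{path}: truncated cube header")
    try:
        parts = lines[2].split()
        natoms = int(parts[0])
        origin = np.array([float(v) for v in parts[1:4]])
        shape, axes = [], []
        for k in range(3):
            p = lines[3 + k].split()
            shape.append(int(p[0]))
            axes.append([float(v) for v in p[1:4]])
        atoms = []
        for i in range(abs(natoms)):
            p = lines[6 + i].split()
            atoms.append((int(p[0]), float(p[2]), float(p[3]), float(p[4])))
        values = []
        for line in lines[6 + abs(natoms) :]:
            values.extend(float(v) for v in line.split())
    except (IndexError, ValueError):
        raise FileFormatError(f"{path}: malformed cube file") from None
    shape = tuple(shape)
    expected = int(np.prod(shape))
    if len(values) != expected:
        raise FileFormatError(
            f"{path}: expected {expected} values for shape {shape}, got {len(values)}"
        )
    grid = DensityGrid(
        origin=origin,
        axes=np.array(axes),
        shape=shape,
        values=np.array(values).reshape(shape),
    )
    return grid, atoms


def write_table(path, grid: DensityGrid, comment: str = "") -> None:
    """Delimited-text writer for 1D/2D cuts: header with geometry, then values.

    2D grids are written as a matrix (row = first grid index); 1D grids as
    one value per line.
    """
    if len(grid.shape) not in (1, 2):
        raise ValueError("use write_cube for 3D grids")
    hdr = [
        f"# {comment or 'density cut'}",
        f"# origin_bohr: {' '.join(f'{v:.10g}' for v in grid.origin)}",
    ]
    for k in range(len(grid.shape)):
        hdr.append(f"# axis{k}_bohr: {' '.join(f'{v:.10g}' for v in grid.axes[k])}")
    hdr.append(f"# shape: {' '.join(str(s) for s in grid.shape)}")
    body = np.atleast_2d(grid.values)
    rows = ["\t".join(f"{v:.10E}" for v in row) for row in body]
    Path(path).write_text("\n".join(hdr + rows) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration mirroring the CLI flags; loadable from YAML or JSON."""

    geometry: str | None = None
    hessian: str | None = None
    state: tuple = ()
    nuclei: str | tuple = "all"
    plane: str = "xy"
    half_width: float = 2.5
    n_points: int = 301
    output_format: str = "text"  # text | cube | json
    out_prefix: str = "density"
    trans_rot_frequency: float = 0.5
    cos_thresh: float = 0.9
    mask_variance_ratio: float = 2.0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in data.items() if k in known}
        if "state" in kwargs:
            kwargs["state"] = tuple(int(v) for v in kwargs["state"])
        extra = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs, extra=extra)


def read_config(path) -> RunConfig:
    """Load a YAML (or JSON) run configuration."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FileFormatError(f"{path}: {exc}") from None
    if not isinstance(data, dict):
        raise FileFormatError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)
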