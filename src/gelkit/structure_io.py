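"""Readers and writers for atomic structures, trajectories and thermo tables.

Coordinates are in Angstrom throughout. Energies default to kcal/mol and are
converted to SI only at the analysis boundary (see :mod:`gelkit.solubility`).
Readers are total on the corresponding writers' output and never reorder
atoms or records.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AVOGADRO = 6.02214076e23

#: Atomic masses (g/mol) for the supported element set; extend as needed.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

#: Bondi van-der-Waals radii (Angstrom).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}


@dataclass(frozen=True)
class Atom:
    """Single atom: chemical symbol and Cartesian position in Angstrom."""

    element: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.element not in ATOMIC_MASSES:
            raise ValueError(f"unsupported element {self.element!r}")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError("atom coordinates must be finite")


@dataclass(frozen=True)
class Box:
    """Orthorhombic simulation box."""

    lengths: tuple[float, float, float]
    periodic: bool = True

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.lengths):
            raise ValueError("box edge lengths must be positive")

    @property
    def volume(self) -> float:
        a, b, c = self.lengths
        return a * b * c


@dataclass
class Frame:
    """Collection of atoms in a (possibly periodic) box."""

    atoms: list[Atom]
    box: Box | None = None
    label: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) float array of coordinates in Angstrom."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def mass(self) -> float:
        """Total mass in g/mol."""
        return sum(ATOMIC_MASSES[a.element] for a in self.atoms)

    def density(self) -> float:
        """Mass density in g/cm^3 (requires a box)."""
        if self.box is None:
            raise ValueError("density requires a simulation box")
        return self.mass / (AVOGADRO * self.box.volume * 1e-24)


def pair_distances(frame: Frame) -> np.ndarray:
    """Condensed upper-triangle pair distance vector.

    Uses minimum-image distances when the frame box is periodic.
    """
    pos = frame.positions
    n = len(pos)
    if n < 2:
        return np.zeros(0)
    diff = pos[None, :, :] - pos[:, None, :]
    if frame.box is not None and frame.box.periodic:
        L = np.asarray(frame.box.lengths)
        diff -= L * np.round(diff / L)
    iu = np.triu_indices(n, k=1)
    return np.linalg.norm(diff[iu], axis=-1)


# --------------------------------------------------------------------------
# PDB


def read_pdb(text: str) -> Frame:
    """Parse ATOM/HETATM records (and CRYST1 into a periodic box)."""
    atoms: list[Atom] = []
    box: Box | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            try:
                a = float(line[6:15])
                b = float(line[15:24])
                c = float(line[24:33])
            except ValueError as exc:
                raise ValueError(f"unparseable CRYST1 record on line {lineno}") from exc
            box = Box((a, b, c), periodic=True)
        elif rec in ("ATOM", "HETATM"):
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ValueError(
                    f"unparseable coordinate field on line {lineno}"
                ) from exc
            element = line[76:78].strip()
            if not element:
                # fall back to the first alphabetic character of the atom name
                name = line[12:16].strip()
                element = next((ch for ch in name if ch.isalpha()), "")
            atoms.append(Atom(element.capitalize(), (x, y, z)))
    return Frame(atoms=atoms, box=box)


def write_pdb(frame: Frame) -> str:
    lines = []
    if frame.box is not None:
        a, b, c = frame.box.lengths
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}  90.00  90.00  90.00 P 1           1"
        )
    for i, atom in enumerate(frame.atoms, start=1):
        x, y, z = atom.position
        lines.append(
            f"HETATM{i:>5d} {atom.element:<4s}MOL A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {atom.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# XYZ / LAMMPS dump trajectories

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')


def _read_xyz(text: str) -> list[Frame]:
    lines = text.splitlines()
    frames: list[Frame] = []
    i = 0
    n_expected: int | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"expected atom count on line {i + 1}") from exc
        if n_expected is not None and n != n_expected:
            raise ValueError(
                f"inconsistent atom count across XYZ frames: {n} vs {n_expected}"
            )
        n_expected = n
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        box = None
        m = _LATTICE_RE.search(comment)
        if m:
            vals = [float(v) for v in m.group(1).split()]
            box = Box((vals[0], vals[4], vals[8]), periodic=True)
        atoms = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            atoms.append(
                Atom(parts[0].capitalize(), (float(parts[1]), float(parts[2]), float(parts[3])))
            )
        frames.append(Frame(atoms=atoms, box=box, label=comment.strip()))
        i += 2 + n
    return frames


def _read_dump(text: str, type_map: Mapping[int, str] | None = None) -> list[Frame]:
    lines = text.splitlines()
    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        line = lines[i]
        if not line.startswith("ITEM: TIMESTEP"):
            i += 1
            continue
        timestep = lines[i + 1].strip()
        assert lines[i + 2].startswith("ITEM: NUMBER OF ATOMS")
        n = int(lines[i + 3])
        assert lines[i + 4].startswith("ITEM: BOX BOUNDS")
        bounds = [tuple(float(v) for v in lines[i + 5 + k].split()[:2]) for k in range(3)]
        box = Box(tuple(hi - lo for lo, hi in bounds), periodic=True)
        header = lines[i + 8]
        if not header.startswith("ITEM: ATOMS"):
            raise ValueError(f"expected 'ITEM: ATOMS' header on line {i + 9}")
        cols = header.split()[2:]
        idx = {name: k for k, name in enumerate(cols)}
        if not {"x", "y", "z"} <= idx.keys():
            raise ValueError("dump ATOMS section must provide x y z columns")
        atoms = []
        for j in range(n):
            parts = lines[i + 9 + j].split()
            if "element" in idx:
                el = parts[idx["element"]].capitalize()
            elif "type" in idx and type_map is not None:
                el = type_map[int(parts[idx["type"]])]
            else:
                raise ValueError(
                    "dump lacks an 'element' column; supply type_map for 'type'"
                )
            atoms.append(
                Atom(el, (float(parts[idx["x"]]), float(parts[idx["y"]]), float(parts[idx["z"]])))
            )
        frames.append(Frame(atoms=atoms, box=box, label=f"timestep {timestep}"))
        i += 9 + n
    if not frames:
        raise ValueError("no ITEM: TIMESTEP blocks found in dump text")
    return frames


def read_frames(
    text: str, format: str = "xyz", type_map: Mapping[int, str] | None = None
) -> list[Frame]:
    """Read a multi-frame trajectory from XYZ or LAMMPS-dump style text."""
    if format == "xyz":
        return _read_xyz(text)
    if format == "dump":
        return _read_dump(text, type_map=type_map)
    raise ValueError(f"unknown trajectory format {format!r}")


def write_frames(frames: Sequence[Frame], format: str = "xyz") -> str:
    """Write frames as (extended) XYZ text; periodic boxes emit a Lattice tag."""
    if format != "xyz":
        raise ValueError("only xyz output is supported")
    out = StringIO()
    for frame in frames:
        out.write(f"{frame.n_atoms}\n")
        comment = frame.label
        if frame.box is not None:
            a, b, c = frame.box.lengths
            comment = (
                f'Lattice="{a:.6f} 0.0 0.0 0.0 {b:.6f} 0.0 0.0 0.0 {c:.6f}" '
                + comment
            )
        out.write(comment.rstrip() + "\n")
        for atom in frame.atoms:
            x, y, z = atom.position
            out.write(f"{atom.element} {x:.8f} {y:.8f} {z:.8f}\n")
    return out.getvalue()


# --------------------------------------------------------------------------
# Thermodynamic tables

CANONICAL_THERMO_COLUMNS = ("temperature", "volume", "density", "nonbonded_energy")

DEFAULT_THERMO_UNITS = {
    "temperature": "K",
    "volume": "A^3",
    "density": "g/cm^3",
    "nonbonded_energy": "kcal/mol",
}


@dataclass
class ThermoSeries:
    """Per-frame/per-run thermodynamic records.

    ``data`` holds any subset of the canonical columns ``temperature``,
    ``volume``, ``density``, ``nonbonded_energy`` plus an optional ``label``.
    ``units`` declares the unit for each physical column.
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_THERMO_UNITS))

    def __post_init__(self) -> None:
        if "temperature" in self.data and (self.data["temperature"] <= 0).any():
            raise ValueError("temperatures must be positive (K)")
        if "density" in self.data and (self.data["density"] <= 0).any():
            raise ValueError("densities must be positive")
        if "volume" in self.data and (self.data["volume"] <= 0).any():
            raise ValueError("volumes must be positive")

    def __len__(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def check_mass_consistency(self, total_mass: float, rtol: float = 1e-6) -> bool:
        """Verify rho = M/V (M in g/mol, V in A^3, rho in g/cm^3)."""
        rho = self.column("density")
        vol = self.column("volume")
        expected = total_mass / (AVOGADRO * vol * 1e-24)
        return bool(np.allclose(rho, expected, rtol=rtol))


def read_thermo(
    text: str,
    column_map: Mapping[str, str],
    units: Mapping[str, str] | None = None,
    total_mass: float | None = None,
    sep: str | None = None,
) -> ThermoSeries:
    """Read a delimited thermo table.

    ``column_map`` maps canonical names (``temperature``, ``volume``,
    ``density``, ``nonbonded_energy``) to file column headers. If ``density``
    is unmapped but ``volume`` is present and ``total_mass`` (g/mol) is
    given, density is derived as M/V.
    """
    try:
        df = pd.read_csv(StringIO(text), sep=sep, engine="python")
    except Exception as exc:
        raise ValueError(f"cannot parse thermo table: {exc}") from exc
    out = pd.DataFrame(index=df.index)
    for canonical, source in column_map.items():
        if canonical not in CANONICAL_THERMO_COLUMNS + ("label",):
            raise ValueError(f"unknown canonical column {canonical!r}")
        if source not in df.columns:
            raise ValueError(f"mapped column {source!r} not found in table header")
        col = df[source]
        if canonical != "label":
            numeric = pd.to_numeric(col, errors="coerce")
            bad = numeric.isna() & col.notna()
            if bad.any():
                row = int(bad.idxmax())
                raise ValueError(
                    f"malformed numeric cell in column {source!r} at row {row}"
                )
            col = numeric
        out[canonical] = col
    if "density" not in out and "volume" in out and total_mass is not None:
        out["density"] = total_mass / (AVOGADRO * out["volume"] * 1e-24)
    resolved_units = dict(DEFAULT_THERMO_UNITS)
    if units:
        resolved_units.update(units)
    return ThermoSeries(data=out, units=resolved_units)


def write_thermo(series: ThermoSeries) -> str:
    """Write a ThermoSeries as CSV with canonical headers."""
    return series.data.to_csv(index=False)
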