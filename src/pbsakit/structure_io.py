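"""Molecular structure input/output.

Reads rigid single-conformation structures from PDB files into a flat
sphere-set representation (one van-der-Waals sphere per atom) together with an
axis-aligned sampling cell, and assigns per-element vdW radii from a published
table.  The sphere set plus cell is everything the Monte-Carlo surface/volume
estimators need; charges, bonds and topology are deliberately out of scope.

Policies follow common SASA-code practice: hydrogens are kept when present and
never added, the first alternate location is kept (with a warning), and only
the first model of a multi-model file is read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import EmptyInputError, FormatError, GeometryError, LookupTableError

__all__ = [
    "AtomSphere",
    "MolecularStructure",
    "RadiiTable",
    "read_pdb",
    "write_pdb",
    "assign_radii",
    "check_cell",
]


@dataclass(frozen=True)
class AtomSphere:
    """A single atom viewed as a hard sphere (element, centre in Å, vdW radius in Å)."""

    element: str
    center: np.ndarray
    radius: float


@dataclass(frozen=True)
class MolecularStructure:
    """An ordered set of atom spheres plus an axis-aligned sampling cell.

    Attributes
    ----------
    elements : (n,) array of str
        Normalised element symbols ("C", "Cl", ...).
    centers : (n, 3) float array
        Cartesian coordinates, Å.
    radii : (n,) float array
        vdW radii, Å; 0.0 means "not yet assigned".
    cell_min, cell_max : (3,) float arrays
        Corners of the axis-aligned sampling cell, Å.
    """

    elements: np.ndarray
    centers: np.ndarray
    radii: np.ndarray
    cell_min: np.ndarray
    cell_max: np.ndarray

    def __post_init__(self):
        if len(self.elements) == 0:
            raise EmptyInputError("structure contains no atoms")
        if not np.all(np.isfinite(self.centers)):
            raise GeometryError("non-finite atom coordinates")
        if np.any(self.cell_max <= self.cell_min):
            raise GeometryError("sampling cell has non-positive extent")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.cell_max - self.cell_min))

    @property
    def atoms(self) -> list[AtomSphere]:
        return [
            AtomSphere(e, c.copy(), float(r))
            for e, c, r in zip(self.elements, self.centers, self.radii)
        ]

    def translated(self, shift) -> "MolecularStructure":
        """Rigidly translate atoms and cell together."""
        shift = np.asarray(shift, dtype=float)
        return replace(
            self,
            centers=self.centers + shift,
            cell_min=self.cell_min + shift,
            cell_max=self.cell_max + shift,
        )


def _normalize_element(sym: str) -> str:
    return sym.strip().capitalize()


_BONDI_CACHE: "RadiiTable | None" = None


@dataclass(frozen=True)
class RadiiTable:
    """Element → vdW radius (Å) mapping with an optional fallback radius."""

    radii: dict[str, float] = field(default_factory=dict)
    fallback: float | None = None

    def __post_init__(self):
        bad = [e for e, r in self.radii.items() if not r > 0]
        if bad or (self.fallback is not None and not self.fallback > 0):
            raise LookupTableError(f"non-positive radii for: {bad or 'fallback'}")

    @classmethod
    def from_file(cls, path, fallback: float | None = None) -> "RadiiTable":
        """Load a two-column (element, radius) whitespace-delimited table."""
        radii = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 'element radius'")
            try:
                radii[_normalize_element(parts[0])] = float(parts[1])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: radius not numeric") from None
        if not radii:
            raise EmptyInputError(f"{path}: no radii entries")
        return cls(radii=radii, fallback=fallback)

    @classmethod
    def bondi(cls, fallback: float | None = None) -> "RadiiTable":
        """The bundled Bondi (1964) vdW radii set — the de-facto SASA standard."""
        global _BONDI_CACHE
        if _BONDI_CACHE is None:
            ref = resources.files("pbsakit.data").joinpath("bondi_radii.tsv")
            with resources.as_file(ref) as p:
                _BONDI_CACHE = cls.from_file(p)
        if fallback is None:
            return _BONDI_CACHE
        return cls(radii=dict(_BONDI_CACHE.radii), fallback=fallback)

    def lookup(self, element: str) -> float | None:
        r = self.radii.get(_normalize_element(element))
        if r is None:
            r = self.fallback
        return r


def _cell_from_bbox(centers, radii, margin, probe_radius):
    pad = margin + probe_radius
    lo = (centers - radii[:, None]).min(axis=0) - pad
    hi = (centers + radii[:, None]).max(axis=0) + pad
    return lo, hi


def read_pdb(path, *, margin: float = 5.0, probe_radius: float = 1.4) -> MolecularStructure:
    """Read ATOM/HETATM records from a PDB file into a :class:`MolecularStructure`.

    Radii are left unassigned (0.0) until :func:`assign_radii`.  The sampling
    cell is the coordinate bounding box padded by ``margin + probe_radius`` on
    every side, which guarantees the cell-containment invariant once radii of
    typical magnitude are assigned.

    Raises
    ------
    FormatError
        On an unparsable record (the message names the line number).
    EmptyInputError
        If the file contains no ATOM/HETATM records.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
        if n_models == 0:
            raise EmptyInputError(f"{path}: no ATOM/HETATM records")
        array = pdb.get_structure(model=1, altloc="first")
    except (EmptyInputError, FormatError):
        raise
    except Exception as exc:  # biotite raises InvalidFileError/ValueError
        raise FormatError(f"{path}: {_locate_bad_record(path)}: {exc}") from exc
    if n_models > 1:
        warnings.warn(f"{path}: {n_models} models present; keeping MODEL 1 only")
    altlocs = {
        line[16]
        for line in path.read_text().splitlines()
        if line.startswith(("ATOM", "HETATM")) and len(line) > 16 and line[16] != " "
    }
    if len(altlocs) > 1:
        warnings.warn(f"{path}: alternate locations {sorted(altlocs)}; keeping the first")
    if array.array_length() == 0:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")

    elements = np.array([_normalize_element(e) for e in array.element], dtype=object)
    centers = np.asarray(array.coord, dtype=float)
    radii = np.zeros(len(elements))
    lo, hi = _cell_from_bbox(centers, radii, margin, probe_radius)
    return MolecularStructure(elements, centers, radii, lo, hi)


def _locate_bad_record(path) -> str:
    """Best-effort line number of the first malformed ATOM/HETATM record."""
    try:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    [float(line[c : c + 8]) for c in (30, 38, 46)]
                except (ValueError, IndexError):
                    return f"line {lineno}"
    except OSError:
        pass
    return "unknown line"


def write_pdb(structure: MolecularStructure, path) -> None:
    """Write the sphere set back out as single-model PDB ATOM records."""
    n = structure.n_atoms
    array = struc.AtomArray(n)
    array.coord = np.asarray(structure.centers, dtype=np.float32)
    array.element = np.array([e.upper() for e in structure.elements], dtype="U2")
    array.atom_name = np.array([e.upper() for e in structure.elements], dtype="U4")
    array.res_name = np.full(n, "SPH", dtype="U3")
    array.res_id = np.ones(n, dtype=int)
    array.chain_id = np.full(n, "A", dtype="U1")
    array.hetero = np.ones(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(array)
    pdb.write(str(path))


def assign_radii(
    structure: MolecularStructure, table: RadiiTable | None = None
) -> MolecularStructure:
    """Return a copy of ``structure`` with vdW radii looked up per element.

    Unknown elements take the table's fallback radius (with a warning); if no
    fallback is configured a :class:`LookupTableError` lists the offenders.
    """
    if table is None:
        table = RadiiTable.bondi()
    radii = np.empty(structure.n_atoms)
    unknown = []
    for i, el in enumerate(structure.elements):
        r = table.lookup(el)
        if r is None:
            unknown.append(el)
            r = np.nan
        radii[i] = r
    if unknown:
        if table.fallback is None:
            raise LookupTableError(
                f"no vdW radius for elements {sorted(set(unknown))} and no fallback set"
            )
    fell_back = [
        el
        for el in structure.elements
        if _normalize_element(el) not in table.radii
    ]
    if fell_back:
        warnings.warn(
            f"fallback radius {table.fallback} used for elements {sorted(set(fell_back))}"
        )
    return replace(structure, radii=radii)


def check_cell(structure: MolecularStructure, probe_radius: float) -> None:
    """Verify every probe-inflated atom sphere lies strictly inside the cell.

    Raises :class:`GeometryError` otherwise; the MC volume estimators call this
    before sampling so that the pore-volume subtraction is well defined.
    """
    lo = structure.centers - (structure.radii + probe_radius)[:, None]
    hi = structure.centers + (structure.radii + probe_radius)[:, None]
    if np.any(lo <= structure.cell_min) or np.any(hi >= structure.cell_max):
        raise GeometryError(
            "a probe-inflated atom sphere extends outside the sampling cell; "
            "increase the cell padding"
        )
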