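"""Atomic-model I/O, crystal metadata, and fibril-scale assembly building.

Coordinate files (PDB or mmCIF) are parsed with :mod:`gemmi`; atoms are held
as plain :class:`AtomSite` records with Cartesian positions in Å.  Fractional
coordinates are used only at the symmetry boundary: :func:`expand_symmetry`
applies space-group operators plus lattice translations to tile one
asymmetric unit into a block of strand copies, and :func:`build_assembly`
groups those copies into β-sheets by backbone proximity along the stacking
direction (the ~4.7–4.8 Å cross-β repeat).
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: Van der Waals radii (Å) used to validate that every element is resolvable.
VDW_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "P": 1.80, "S": 1.80, "CL": 1.75, "SE": 1.90,
    "BR": 1.85, "I": 1.98, "NA": 2.27, "MG": 1.73, "K": 2.75,
    "CA": 2.31, "ZN": 1.39, "FE": 2.00, "MN": 2.00, "CU": 1.40,
}


class FormatError(ValueError):
    """A coordinate file could not be parsed in the requested format."""


class UnknownElementError(ValueError):
    """An atom's element has no entry in the van der Waals radius table."""


@dataclass
class AtomSite:
    """One atom of a crystal model; positions are Cartesian Å."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str | None = None
    is_water: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name} {self.serial}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1] for atom {self.serial}")


@dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell; lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("unit cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("unit cell angles must lie in (0, 180)")
        if self.volume <= 0:
            raise ValueError("unit cell has non-positive volume")

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """3×3 matrix M with cartesian = M @ fractional (PDB convention)."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
        sg = math.sin(ga)
        v = math.sqrt(max(0.0, 1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg))
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    @property
    def fractionalization_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization_matrix)

    @property
    def volume(self) -> float:
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
        return self.a * self.b * self.c * math.sqrt(max(0.0, arg))

    def to_cartesian(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, float) @ self.orthogonalization_matrix.T

    def to_fractional(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, float) @ self.fractionalization_matrix.T

    @property
    def reciprocal_matrix(self) -> np.ndarray:
        """Rows are the reciprocal basis vectors a*, b*, c* (Å⁻¹, Cartesian)."""
        return np.linalg.inv(self.orthogonalization_matrix)


@dataclass(frozen=True)
class SymmetryOp:
    """Space-group operator in the fractional basis: x' = R x + t."""

    rotation: tuple[tuple[float, ...], ...]
    translation: tuple[float, float, float]

    @property
    def rot(self) -> np.ndarray:
        return np.asarray(self.rotation, float)

    @property
    def tran(self) -> np.ndarray:
        return np.asarray(self.translation, float)

    def __post_init__(self) -> None:
        det = float(np.linalg.det(self.rot))
        if abs(abs(det) - 1.0) > 1e-9:
            raise ValueError(f"symmetry rotation determinant {det} is not ±1")

    @classmethod
    def identity(cls) -> "SymmetryOp":
        return cls(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.0, 0.0, 0.0))


IDENTITY_OP = SymmetryOp.identity()


@dataclass
class CrystalModel:
    """Atoms plus crystal metadata; the container for one coordinate file."""

    atoms: list[AtomSite]
    cell: UnitCell | None = None
    space_group: str = "P 1"
    ops: list[SymmetryOp] = field(default_factory=lambda: [IDENTITY_OP])
    id: str = ""

    def __post_init__(self) -> None:
        if not self.ops:
            self.ops = [IDENTITY_OP]

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms]) if self.atoms else np.empty((0, 3))

    def non_water_atoms(self) -> list[AtomSite]:
        return [a for a in self.atoms if not a.is_water]


@dataclass
class PlacedCopy:
    """One symmetry copy of the asymmetric unit, tagged with its generator."""

    atoms: list[AtomSite]
    op_index: int
    translation: tuple[int, int, int]

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


# ---------------------------------------------------------------------------
# Reading and writing


def _resolve_element(name: str, serial: int) -> str:
    sym = name.strip().upper()
    if sym in VDW_RADII:
        return sym
    raise UnknownElementError(
        f"atom serial {serial}: element {name!r} has no van der Waals radius entry"
    )


def _ops_for_space_group(symbol: str) -> list[SymmetryOp]:
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        logger.warning("unknown space group %r; using identity only", symbol)
        return [IDENTITY_OP]
    ops = []
    for op in sg.operations():
        rot = tuple(tuple(v / op.DEN for v in row) for row in op.rot)
        tran = tuple(v / op.DEN for v in op.tran)
        ops.append(SymmetryOp(rot, tran))
    return ops


def _keep_best_altloc(atoms: list[AtomSite]) -> list[AtomSite]:
    """Keep the highest-occupancy conformer for every alternate-location group."""
    best: dict[tuple, AtomSite] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (atom.chain_id, atom.residue_number, atom.residue_name, atom.name)
        if key not in best:
            best[key] = atom
            order.append(key)
        elif atom.occupancy > best[key].occupancy:
            best[key] = atom
    kept = [best[k] for k in order]
    for atom in kept:
        atom.altloc = None
    return kept


def read_structure(source: str | Path, format: str | None = None) -> CrystalModel:
    """Read a PDB or mmCIF model into a :class:`CrystalModel`.

    ``source`` may be a path or the file text itself.  ``format`` is
    ``"pdb"`` or ``"mmcif"``; if omitted it is inferred from the path suffix
    (text input defaults to PDB).  Waters are flagged, alternate conformers
    are reduced to the highest-occupancy one, and symmetry operators are
    taken from the space-group tables for the named group.
    """
    text: str
    name = ""
    path = Path(str(source))
    is_path = "\n" not in str(source) and path.exists()
    if is_path:
        text = path.read_text()
        name = path.stem
        if format is None:
            format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    else:
        text = str(source)
        if format is None:
            format = "pdb"

    try:
        if format == "pdb":
            st = gemmi.read_pdb_string(text)
        elif format == "mmcif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise FormatError(f"could not parse {format} input: {exc}") from exc

    atoms: list[AtomSite] = []
    serial = 0
    if len(st) == 0:
        raise FormatError("no model block found in input")
    for chain in st[0]:
        for residue in chain:
            for atom in residue:
                serial += 1
                el = atom.element.name.upper()
                if el in {"X", ""}:
                    el = _resolve_element(atom.name[:1], serial)
                elif el not in VDW_RADII:
                    raise UnknownElementError(
                        f"atom {atom.name} (serial {serial}): unknown element {el!r}"
                    )
                atoms.append(AtomSite(
                    serial=serial,
                    name=atom.name,
                    element=el,
                    residue_name=residue.name,
                    residue_number=residue.seqid.num,
                    chain_id=chain.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=min(1.0, max(0.0, atom.occ)),
                    b_factor=atom.b_iso,
                    altloc=atom.altloc or None,
                    is_water=residue.name.upper() in WATER_NAMES,
                ))
    atoms = _keep_best_altloc(atoms)

    cell = None
    if st.cell and st.cell.a > 1.0 and st.cell.volume > 1.0:
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg_symbol = st.spacegroup_hm or "P 1"
    ops = _ops_for_space_group(sg_symbol)
    return CrystalModel(atoms=atoms, cell=cell, space_group=sg_symbol,
                        ops=ops, id=st.name or name)


def write_pdb(model: CrystalModel, destination: str | Path | None = None) -> str:
    """Serialize a model to PDB text; optionally write it to ``destination``."""
    out = io.StringIO()
    if model.cell is not None:
        c = model.cell
        out.write(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} {model.space_group:<11s}\n"
        )
    for i, atom in enumerate(model.atoms, start=1):
        record = "HETATM" if atom.is_water else "ATOM  "
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        x, y, z = atom.position
        out.write(
            f"{record}{i % 100000:5d} {name:<4s}{'':1s}{atom.residue_name:>3s} "
            f"{atom.chain_id[:1]:1s}{atom.residue_number % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
            f"          {atom.element:>2s}\n"
        )
    out.write("END\n")
    text = out.getvalue()
    if destination is not None:
        Path(destination).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Symmetry expansion


def expand_symmetry(model: CrystalModel,
                    cell_range: int | tuple[int, int, int]) -> list[PlacedCopy]:
    """Tile the asymmetric unit by every (space-group op × lattice translation).

    ``cell_range`` gives the ± extent of lattice translations per axis; an
    integer applies to all three axes.  Each returned copy carries its
    generating operator index and translation; interatomic distances within
    a copy equal those of the input model.
    """
    if model.cell is None:
        raise ValueError("symmetry expansion needs a unit cell; model has none")
    if isinstance(cell_range, int):
        cell_range = (cell_range, cell_range, cell_range)
    na, nb, nc = cell_range
    frac = model.cell.to_fractional(model.positions)
    copies: list[PlacedCopy] = []
    for op_index, op in enumerate(model.ops):
        base = frac @ op.rot.T + op.tran
        for ta in range(-na, na + 1):
            for tb in range(-nb, nb + 1):
                for tc in range(-nc, nc + 1):
                    shifted = base + np.array([ta, tb, tc], float)
                    cart = model.cell.to_cartesian(shifted)
                    atoms = [replace(a, position=cart[i])
                             for i, a in enumerate(model.atoms)]
                    copies.append(PlacedCopy(atoms, op_index, (ta, tb, tc)))
    return copies


# ---------------------------------------------------------------------------
# Sheet grouping

#: Default parameters for grouping strand copies into β-sheets.
DEFAULT_GROUPING = {
    "rise_min": 4.0,     # Å, lower bound on median nearest-Cα inter-strand spacing
    "rise_max": 6.0,     # Å, upper bound (cross-β stacking is ~4.2–5.5 Å)
    "min_cos": 0.65,     # |cos| between strand directions to count as aligned
    "min_residues": 3,   # shortest chain treated as a strand
}


def _strand_ca(atoms: Sequence[AtomSite]) -> np.ndarray:
    return np.array([a.position for a in atoms if a.name.strip() == "CA"])


def strand_direction(atoms: Sequence[AtomSite]) -> np.ndarray:
    """Unit vector from first to last Cα (the N→C strand direction)."""
    ca = _strand_ca(atoms)
    if len(ca) < 2:
        raise ValueError("strand direction needs at least two CA atoms")
    v = ca[-1] - ca[0]
    return v / np.linalg.norm(v)


def _split_into_strands(copies: Iterable[PlacedCopy | Sequence[AtomSite]],
                        min_residues: int) -> list[list[AtomSite]]:
    strands = []
    for copy in copies:
        atoms = copy.atoms if isinstance(copy, PlacedCopy) else list(copy)
        by_chain: dict[str, list[AtomSite]] = {}
        for a in atoms:
            if a.is_water:
                continue
            by_chain.setdefault(a.chain_id, []).append(a)
        for chain_atoms in by_chain.values():
            n_res = len({a.residue_number for a in chain_atoms})
            if n_res >= min_residues and len(_strand_ca(chain_atoms)) >= 2:
                strands.append(chain_atoms)
    return strands


def _adjacent(ca_i: np.ndarray, ca_j: np.ndarray, d_i: np.ndarray, d_j: np.ndarray,
              params: dict) -> bool:
    if abs(float(d_i @ d_j)) < params["min_cos"]:
        return False
    dists = np.linalg.norm(ca_i[:, None, :] - ca_j[None, :, :], axis=-1)
    med = float(np.median(dists.min(axis=1)))
    return params["rise_min"] <= med <= params["rise_max"]


def build_assembly(copies: Sequence[PlacedCopy | Sequence[AtomSite]],
                   grouping: dict | None = None) -> list:
    """Group strand copies into sheets; returns a list of ``SheetAssembly``.

    Two strands belong to the same sheet when their directions are aligned
    (parallel or antiparallel) and the median nearest-Cα distance between
    them falls in the cross-β stacking range.  Within each sheet, strands
    are ordered along the stacking (fiber) direction.
    """
    from .geometry import SheetAssembly  # local import to avoid a cycle

    params = dict(DEFAULT_GROUPING)
    if grouping:
        params.update(grouping)
    strands = _split_into_strands(copies, params["min_residues"])
    if len(strands) < 1:
        logger.warning("no groupable strands found")
        return []

    cas = [_strand_ca(s) for s in strands]
    dirs = [strand_direction(s) for s in strands]
    n = len(strands)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _adjacent(cas[i], cas[j], dirs[i], dirs[j], params):
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    sheets = []
    for k, members in enumerate(sorted(groups.values(), key=lambda m: m[0])):
        centroids = np.array([cas[i].mean(axis=0) for i in members])
        if len(members) > 1:
            centered = centroids - centroids.mean(axis=0)
            _, _, vt = np.linalg.svd(centered)
            axis = vt[0]
            # orient along increasing order of appearance
            if centered[-1] @ axis < centered[0] @ axis:
                axis = -axis
        else:
            axis = dirs[members[0]]
        order = np.argsort(centroids @ axis)
        sheets.append(SheetAssembly(
            strands=[strands[members[i]] for i in order],
            fiber_axis=axis,
            id=f"sheet{k}",
        ))
    return sheets
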