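"""Geometric analysis of β-sheets: planarity, torsions, registry, and tilt.

A sheet is an ordered stack of β-strands.  The metrics here quantify how the
stack deviates from the idealized cross-β picture: ``sheet_planarity_rmsd``
measures sheet curvature as the RMS perpendicular distance of Cα atoms from
their least-squares plane, ``backbone_torsions`` reports (φ, ψ) with
Ramachandran region labels, ``strand_registry`` determines parallel vs
antiparallel orientation and the residue-index registry shift between
stacked strands, and ``strand_tilt`` measures how far strands lean away
from perpendicular to the fiber axis (out-of-register sheets stack at an
angle; in-register sheets do not).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from matplotlib.path import Path as MplPath

from .model_io import AtomSite, strand_direction

logger = logging.getLogger(__name__)


@dataclass
class SheetAssembly:
    """An ordered stack of β-strands (each a list of :class:`AtomSite`)."""

    strands: list[list[AtomSite]]
    fiber_axis: np.ndarray
    id: str = ""
    rise: float | None = None  # Å stacking repeat, when known (builder output)

    def __post_init__(self) -> None:
        if not self.strands:
            raise ValueError("a sheet needs at least one strand")
        axis = np.asarray(self.fiber_axis, float)
        self.fiber_axis = axis / np.linalg.norm(axis)

    @property
    def n_strands(self) -> int:
        return len(self.strands)

    @property
    def atoms(self) -> list[AtomSite]:
        return [a for s in self.strands for a in s]

    def ca_positions(self, strand: int | None = None) -> np.ndarray:
        strands = self.strands if strand is None else [self.strands[strand]]
        return np.array([a.position for s in strands for a in s
                         if a.name.strip() == "CA"])


@dataclass
class ZipperAssembly:
    """Two β-sheets paired across a labeled interface."""

    sheet_a: SheetAssembly
    sheet_b: SheetAssembly
    id: str = ""

    @property
    def atoms(self) -> list[AtomSite]:
        return self.sheet_a.atoms + self.sheet_b.atoms


@dataclass(frozen=True)
class PlaneFit:
    normal: np.ndarray
    centroid: np.ndarray
    rmsd: float
    n_points: int


@dataclass(frozen=True)
class TorsionPair:
    residue_number: int
    residue_name: str
    phi: float | None
    psi: float | None
    region: str  # favored | allowed | outlier | undefined


@dataclass
class RegistryReport:
    orientation: str  # parallel | antiparallel | mixed
    shift: int
    stacked_pairs: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Plane fitting and planarity


def fit_plane(points: Iterable[Sequence[float]]) -> PlaneFit:
    """Least-squares plane through 3D points via SVD.

    The returned ``rmsd`` is the root-mean-square perpendicular distance,
    which the SVD minimizes over all planes.
    """
    pts = np.asarray(list(points), float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("plane fitting needs at least three 3D points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("points are collinear; plane is degenerate")
    normal = vt[2]
    rmsd = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return PlaneFit(normal=normal, centroid=centroid, rmsd=rmsd, n_points=len(pts))


def sheet_planarity_rmsd(sheet: SheetAssembly,
                         selection: frozenset[str] | set[str] = frozenset({"CA"})) -> float:
    """RMS deviation (Å) of the selected atoms of all strands from one plane."""
    if not selection:
        raise ValueError("empty atom selection")
    if sheet.n_strands < 2:
        raise ValueError("planarity needs at least two strands")
    pts = [a.position for a in sheet.atoms if a.name.strip() in selection]
    if len(pts) < 3:
        raise ValueError(f"selection {sorted(selection)} matched fewer than 3 atoms")
    return fit_plane(pts).rmsd


# ---------------------------------------------------------------------------
# Backbone torsions and Ramachandran regions


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, in (−180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


def _load_rama() -> dict:
    with resources.files("crossbeta.data").joinpath("ramachandran.json").open() as fh:
        return json.load(fh)


_RAMA = None


def _rama_paths() -> dict:
    global _RAMA
    if _RAMA is None:
        raw = _load_rama()
        _RAMA = {
            kind: {level: [MplPath(np.asarray(poly, float)) for poly in polys]
                   for level, polys in levels.items() if not kind.startswith("_")}
            for kind, levels in raw.items() if not kind.startswith("_")
        }
    return _RAMA


def ramachandran_region(phi: float | None, psi: float | None,
                        residue_name: str = "ALA") -> str:
    """Classify (φ, ψ) as favored / allowed / outlier for the residue type.

    Glycine uses glycine contours (its lack of Cβ admits regions, such as
    the positive-ψ bridge near φ ≈ −100°, that are outliers for any other
    residue type); proline uses proline contours; everything else uses the
    general contours.
    """
    if phi is None or psi is None:
        return "undefined"
    kind = {"GLY": "glycine", "PRO": "proline"}.get(residue_name.upper(), "general")
    tables = _rama_paths()[kind]
    point = (phi, psi)
    for level in ("favored", "allowed"):
        for path in tables.get(level, []):
            if path.contains_point(point, radius=1e-9):
                return level
    return "outlier"


def backbone_torsions(strand: Sequence[AtomSite]) -> list[TorsionPair]:
    """Per-residue (φ, ψ) with Ramachandran labels; terminal angles are None."""
    residues: dict[int, dict[str, AtomSite]] = {}
    order: list[int] = []
    for a in strand:
        if a.residue_number not in residues:
            residues[a.residue_number] = {}
            order.append(a.residue_number)
        residues[a.residue_number][a.name.strip()] = a
    out: list[TorsionPair] = []
    for idx, num in enumerate(order):
        res = residues[num]
        name = next(iter(res.values())).residue_name
        phi = psi = None
        has_bb = all(k in res for k in ("N", "CA", "C"))
        if not has_bb:
            logger.warning("residue %s %d misses backbone atoms; torsions undefined",
                           name, num)
        else:
            if idx > 0 and "C" in residues[order[idx - 1]]:
                phi = dihedral(residues[order[idx - 1]]["C"].position,
                               res["N"].position, res["CA"].position, res["C"].position)
            if idx < len(order) - 1 and "N" in residues[order[idx + 1]]:
                psi = dihedral(res["N"].position, res["CA"].position,
                               res["C"].position, residues[order[idx + 1]]["N"].position)
        region = ("undefined" if phi is None or psi is None
                  else ramachandran_region(phi, psi, name))
        out.append(TorsionPair(num, name, phi, psi, region))
    return out


# ---------------------------------------------------------------------------
# Registry and tilt


def _aligned_directions(sheet: SheetAssembly) -> list[np.ndarray]:
    return [strand_direction(s) for s in sheet.strands]


def _stacking_axis(sheet: SheetAssembly) -> np.ndarray:
    """Inter-strand stacking direction: the component of the mean
    adjacent-strand centroid difference perpendicular to the strand axis."""
    cents = np.array([sheet.ca_positions(i).mean(axis=0)
                      for i in range(sheet.n_strands)])
    d0 = strand_direction(sheet.strands[0])
    acc = np.zeros(3)
    for i in range(sheet.n_strands - 1):
        v = cents[i + 1] - cents[i]
        perp = v - (v @ d0) * d0
        if np.linalg.norm(perp) > 1e-9:
            acc += perp / np.linalg.norm(perp)
    norm = np.linalg.norm(acc)
    if norm < 1e-9:
        raise ValueError("stacking axis undefined (strands are collinear)")
    return acc / norm


def strand_registry(sheet: SheetAssembly) -> RegistryReport:
    """Orientation and residue registry shift of a sheet.

    Orientation comes from dot products of consecutive strand directions.
    The shift is the modal residue-index offset of the nearest Cα on the
    closest same-direction strand, measured after projecting out the
    stacking direction — the operational form of "residue X of strand i
    sits directly above residue Y of strand i+2".
    """
    dirs = _aligned_directions(sheet)
    n = sheet.n_strands
    if n < 2:
        raise ValueError("registry needs at least two strands")
    cos = [float(dirs[i] @ dirs[i + 1]) for i in range(n - 1)]
    if all(c > 0.5 for c in cos):
        orientation, step = "parallel", 1
    elif all(c < -0.5 for c in cos):
        orientation, step = "antiparallel", 2
    else:
        logger.warning("mixed strand orientations in sheet %s", sheet.id)
        orientation, step = "mixed", 1
    if orientation == "antiparallel" and n < 3:
        raise ValueError("antiparallel registry needs ≥3 strands "
                         "(same-direction comparison is between strands i and i+2)")
    if n <= step:
        return RegistryReport(orientation, 0, [])

    s_axis = _stacking_axis(sheet)
    proj = np.eye(3) - np.outer(s_axis, s_axis)
    offsets: Counter[int] = Counter()
    evidence: dict[int, list[tuple[str, str]]] = {}
    for i in range(n - step):
        a = [x for x in sheet.strands[i] if x.name.strip() == "CA"]
        b = [x for x in sheet.strands[i + step] if x.name.strip() == "CA"]
        pa = np.array([x.position for x in a]) @ proj.T
        pb = np.array([x.position for x in b]) @ proj.T
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
        nearest = d.argmin(axis=1)
        for j, jn in enumerate(nearest):
            off = b[jn].residue_number - a[j].residue_number
            offsets[off] += 1
            evidence.setdefault(off, []).append(
                (f"{a[j].residue_name}{a[j].residue_number}",
                 f"{b[jn].residue_name}{b[jn].residue_number}"))
    mode = offsets.most_common(1)[0][0]
    return RegistryReport(orientation, abs(mode), evidence.get(mode, [])[:10])


def strand_tilt(sheet: SheetAssembly) -> float:
    """Angle (degrees) between the mean strand direction and the plane
    normal to the fiber axis; 0 when strands are perpendicular to the axis."""
    if sheet.n_strands < 2:
        raise ValueError("tilt needs a fiber axis defined by ≥2 strands")
    dirs = _aligned_directions(sheet)
    ref = dirs[0]
    mean = np.mean([d if d @ ref > 0 else -d for d in dirs], axis=0)
    mean /= np.linalg.norm(mean)
    sin_t = abs(float(mean @ sheet.fiber_axis))
    return float(np.degrees(np.arcsin(min(1.0, sin_t))))
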