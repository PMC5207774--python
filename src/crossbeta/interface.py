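"""Steric-zipper interface panel: SASA, buried area, shape complementarity,
hydrogen bonds, solvation energy, and zipper classification.

Solvent-accessible surface areas use Shrake–Rupley spherical sampling with a
deterministic Fibonacci-lattice point set (probe 1.4 Å), so every number in
the panel is bit-reproducible.  Buried area follows the standard difference
convention, SASA(A) + SASA(B) − SASA(A∪B), normalized per strand and per
sheet side, with edge strands trimmed so the reported value describes the
repeating interior of the fibril.  Shape complementarity is the
Lawrence–Colman-style statistic: the median, over interface surface points
of both molecular surfaces, of the distance-weighted agreement of opposing
surface normals (1 = perfectly complementary).  The dry/wet call is made on
per-residue burial: tightly mated zipper interfaces bury ≥ ~20 Å²/residue,
loose crystal-packing contacts bury ~10 Å²/residue.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import SheetAssembly, ZipperAssembly, strand_registry, _stacking_axis
from .model_io import AtomSite, VDW_RADII, UnknownElementError, strand_direction

logger = logging.getLogger(__name__)

#: Per-residue burial (Å²) at or above which an interface is called dry.
DRY_THRESHOLD = 15.0


@dataclass(frozen=True)
class RadiusTable:
    """Van der Waals radii (Å) plus the solvent probe radius.

    ``cb_radius`` optionally enlarges Cβ atoms to mimic side-chain bulk in
    backbone-plus-Cβ synthetic models.
    """

    radii: dict = field(default_factory=lambda: dict(VDW_RADII))
    probe_radius: float = 1.4
    cb_radius: float | None = None

    def radius_for(self, atom: AtomSite) -> float:
        if self.cb_radius is not None and atom.name.strip() == "CB":
            return self.cb_radius
        try:
            r = self.radii[atom.element.upper()]
        except KeyError:
            raise UnknownElementError(
                f"no van der Waals radius for element {atom.element!r} "
                f"(atom {atom.name} {atom.residue_name}{atom.residue_number})")
        if r <= 0:
            raise ValueError(f"non-positive radius for element {atom.element!r}")
        return r


DEFAULT_RADII = RadiusTable()


@dataclass
class SasaResult:
    per_atom: np.ndarray  # Å², aligned with the input atom list (waters 0)
    total: float
    probe_radius: float
    n_points: int


@dataclass(frozen=True)
class SolvationParams:
    """Five-class atomic solvation parameters σ (cal·mol⁻¹·Å⁻²).

    Burying apolar (carbon) area is favorable: with σ_C > 0, the energy
    Σ σ·(ASA_reference − ASA_assembly) is positive for hydrophobic burial.
    """

    sigma: dict = field(default_factory=lambda: {
        "C": 16.0, "N/O": -6.0, "O-": -24.0, "N+": -50.0, "S": 21.0})
    reference_state: str = "isolated strand"


CHARGED_O = {"OD1", "OD2", "OE1", "OE2", "OXT"}
CHARGED_N = {"NZ", "NH1", "NH2"}
HYDROXYL_O = {"OG", "OG1", "OH"}


def atom_solvation_class(atom: AtomSite) -> str:
    el = atom.element.upper()
    name = atom.name.strip().upper()
    if el == "C":
        return "C"
    if el == "S":
        return "S"
    if el == "O":
        if name in CHARGED_O and atom.residue_name.upper() in {"ASP", "GLU"} or name == "OXT":
            return "O-"
        return "N/O"
    if el == "N":
        if name in CHARGED_N and atom.residue_name.upper() in {"LYS", "ARG"}:
            return "N+"
        return "N/O"
    if el in {"H", "D"}:
        return "N/O"  # negligible weight; hydrogens rarely present
    raise ValueError(f"unclassifiable atom for solvation: {atom.name} "
                     f"({atom.element}) in {atom.residue_name}{atom.residue_number}")


@dataclass
class HBond:
    donor: str
    acceptor: str
    distance: float
    angle: float
    type: str  # "backbone-backbone" | "side-chain"


@dataclass
class InterfaceMetrics:
    """The per-interface report card of a putative steric zipper."""

    buried_per_strand: float
    buried_per_residue: float
    sc: float | None
    n_hbonds: int
    solvation_energy_per_strand: float
    zipper_class: int | None
    dry: bool
    n_strands_used: int


# ---------------------------------------------------------------------------
# SASA


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_list(obj) -> list[AtomSite]:
    if isinstance(obj, (SheetAssembly, ZipperAssembly)):
        return obj.atoms
    return list(obj)


def sasa(atoms: Iterable[AtomSite], radii: RadiusTable = DEFAULT_RADII,
         n_points: int = 960, include_waters: bool = False) -> SasaResult:
    """Shrake–Rupley SASA with a deterministic spherical point set.

    Each atom's accessible sphere (radius r_vdw + probe) is sampled at
    ``n_points`` Fibonacci-lattice points; the accessible fraction is the
    share of points outside every neighbor's accessible sphere.
    """
    if n_points < 64:
        raise ValueError("n_points must be ≥ 64 for a meaningful area")
    atoms = _atom_list(atoms)
    mask = np.array([include_waters or not a.is_water for a in atoms])
    per_atom = np.zeros(len(atoms))
    active = [i for i in range(len(atoms)) if mask[i]]
    if not active:
        return SasaResult(per_atom, 0.0, radii.probe_radius, n_points)
    pos = np.array([atoms[i].position for i in active])
    rad = np.array([radii.radius_for(atoms[i]) + radii.probe_radius for i in active])
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(pos)
    rmax = rad.max()
    for k in range(len(active)):
        neighbors = [j for j in tree.query_ball_point(pos[k], rad[k] + rmax)
                     if j != k and np.linalg.norm(pos[j] - pos[k]) < rad[k] + rad[j]]
        pts = pos[k] + rad[k] * sphere
        if neighbors:
            npos = pos[neighbors]
            nrad = rad[neighbors]
            d2 = ((pts[:, None, :] - npos[None, :, :]) ** 2).sum(-1)
            buried = (d2 < (nrad ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[active[k]] = 4.0 * math.pi * rad[k] ** 2 * frac
    return SasaResult(per_atom, float(per_atom.sum()), radii.probe_radius, n_points)


# ---------------------------------------------------------------------------
# Buried area


def _central_strand_indices(sheet: SheetAssembly) -> list[int]:
    n = sheet.n_strands
    return list(range(1, n - 1)) if n > 2 else list(range(n))


def buried_area(sheet_a: SheetAssembly, sheet_b: SheetAssembly,
                radii: RadiusTable = DEFAULT_RADII, n_points: int = 960
                ) -> tuple[float, float]:
    """Interface burial per strand and per residue (Å²).

    Computed as [SASA(A) + SASA(B) − SASA(A∪B)] restricted to central
    (edge-trimmed) strands and divided by 2 × (central strands per sheet):
    the per-strand, per-sheet-side convention under which an 11-residue
    strand burying 24 Å²/residue buries 264 Å²/strand.
    """
    atoms_a = [a for a in sheet_a.atoms if not a.is_water]
    atoms_b = [a for a in sheet_b.atoms if not a.is_water]
    if not atoms_a or not atoms_b:
        raise ValueError("both sheets must contain atoms")
    pa = np.array([a.position for a in atoms_a])
    pb = np.array([a.position for a in atoms_b])
    dmin = cKDTree(pa).query(pb, k=1)[0].min()
    if dmin < 1.0:
        raise ValueError(f"sheets clash: minimum interatomic distance {dmin:.2f} Å")

    res_a = sasa(atoms_a, radii, n_points)
    res_b = sasa(atoms_b, radii, n_points)
    res_ab = sasa(atoms_a + atoms_b, radii, n_points)
    delta_a = res_a.per_atom - res_ab.per_atom[: len(atoms_a)]
    delta_b = res_b.per_atom - res_ab.per_atom[len(atoms_a):]

    def central_sum(sheet: SheetAssembly, atoms: list[AtomSite],
                    delta: np.ndarray) -> tuple[float, int]:
        keep_ids = set()
        for i in _central_strand_indices(sheet):
            keep_ids.update(id(a) for a in sheet.strands[i] if not a.is_water)
        total = sum(delta[j] for j, a in enumerate(atoms) if id(a) in keep_ids)
        return float(total), len(_central_strand_indices(sheet))

    sum_a, n_ca = central_sum(sheet_a, atoms_a, delta_a)
    sum_b, n_cb = central_sum(sheet_b, atoms_b, delta_b)
    per_strand = max(0.0, (sum_a + sum_b) / (n_ca + n_cb))
    n_res = len({a.residue_number for a in sheet_a.strands[0]})
    return per_strand, per_strand / n_res


# ---------------------------------------------------------------------------
# Shape complementarity


def _surface_points(atoms: list[AtomSite], radii: RadiusTable,
                    n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Van der Waals dot surface: points and outward normals."""
    pos = np.array([a.position for a in atoms])
    rad = np.array([radii.radius_for(a) for a in atoms])
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(pos)
    pts, nrm = [], []
    rmax = rad.max()
    for k in range(len(atoms)):
        cand = pos[k] + rad[k] * sphere
        neighbors = [j for j in tree.query_ball_point(pos[k], rad[k] + rmax)
                     if j != k]
        if neighbors:
            d2 = ((cand[:, None, :] - pos[neighbors][None, :, :]) ** 2).sum(-1)
            keep = ~(d2 < (rad[neighbors] ** 2)[None, :] - 1e-9).any(axis=1)
        else:
            keep = np.ones(len(cand), bool)
        pts.append(cand[keep])
        nrm.append(sphere[keep])
    return np.concatenate(pts), np.concatenate(nrm)


def shape_complementarity(sheet_a: SheetAssembly | Sequence[AtomSite],
                          sheet_b: SheetAssembly | Sequence[AtomSite],
                          weight: float = 0.5, band: float = 1.5,
                          radii: RadiusTable = DEFAULT_RADII,
                          n_points: int = 240) -> float:
    """Lawrence–Colman-style shape complementarity statistic.

    For each surface point x on A in the interface band, with nearest point
    x′ on B's surface, the score is s(x) = −(n̂(x)·n̂(x′))·exp(−w·d(x,x′)²);
    opposing normals of snugly mated surfaces score near +1.  Sc is the
    median of s over the interface points of both surfaces.
    """
    atoms_a = [a for a in _atom_list(sheet_a) if not a.is_water]
    atoms_b = [a for a in _atom_list(sheet_b) if not a.is_water]
    pa, na = _surface_points(atoms_a, radii, n_points)
    pb, nb = _surface_points(atoms_b, radii, n_points)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("no contact surface")
    tree_b = cKDTree(pb)
    tree_a = cKDTree(pa)
    scores = []
    for (p1, n1, tree2, p2, n2) in ((pa, na, tree_b, pb, nb),
                                    (pb, nb, tree_a, pa, na)):
        d, idx = tree2.query(p1, k=1)
        sel = d <= band
        if sel.any():
            dots = -(n1[sel] * n2[idx[sel]]).sum(axis=1)
            scores.append(dots * np.exp(-weight * d[sel] ** 2))
    if not scores:
        raise ValueError("no contact surface")
    return float(np.median(np.concatenate(scores)))


# ---------------------------------------------------------------------------
# Hydrogen bonds


def _covalent_neighbors(atoms: list[AtomSite]) -> dict[int, list[int]]:
    pos = np.array([a.position for a in atoms])
    tree = cKDTree(pos)
    pairs = tree.query_pairs(1.8)
    out: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
    for i, j in pairs:
        ai, aj = atoms[i], atoms[j]
        same_res = (ai.chain_id == aj.chain_id
                    and ai.residue_number == aj.residue_number)
        peptide = (ai.chain_id == aj.chain_id
                   and {ai.name.strip(), aj.name.strip()} == {"C", "N"}
                   and abs(ai.residue_number - aj.residue_number) == 1)
        if same_res or peptide:
            out[i].append(j)
            out[j].append(i)
    return out


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def hydrogen_bonds(group_a: Sequence[AtomSite] | SheetAssembly,
                   group_b: Sequence[AtomSite] | SheetAssembly,
                   d_max: float = 3.5, angle_min: float = 90.0,
                   include_waters: bool = False) -> list[HBond]:
    """Heavy-atom hydrogen-bond enumeration between two disjoint groups.

    A donor N (or hydroxyl O) and acceptor O/N within ``d_max`` form a bond
    when every covalent antecedent–donor–acceptor angle is at least
    ``angle_min`` — the deposited peptide structures carry no hydrogens, so
    the geometric heavy-atom criterion is the default.  Each bond is listed
    once.
    """
    atoms_a = [a for a in _atom_list(group_a) if include_waters or not a.is_water]
    atoms_b = [a for a in _atom_list(group_b) if include_waters or not a.is_water]
    ids_a = {id(a) for a in atoms_a}
    if any(id(b) in ids_a for b in atoms_b):
        raise ValueError("hydrogen-bond groups must be disjoint")

    def donors_and_acceptors(atoms):
        donors, acceptors = [], []
        for i, a in enumerate(atoms):
            el = a.element.upper()
            name = a.name.strip().upper()
            if el == "N" or (el == "O" and name in HYDROXYL_O):
                donors.append(i)
            if el in {"O", "N"}:
                acceptors.append(i)
        return donors, acceptors

    bonds: list[HBond] = []
    seen: set[frozenset[int]] = set()
    for atoms_x, atoms_y in ((atoms_a, atoms_b), (atoms_b, atoms_a)):
        neigh = _covalent_neighbors(atoms_x)
        donors, _ = donors_and_acceptors(atoms_x)
        _, acceptors = donors_and_acceptors(atoms_y)
        if not donors or not acceptors:
            continue
        pos_y = np.array([atoms_y[j].position for j in acceptors])
        tree = cKDTree(pos_y)
        for di in donors:
            d_atom = atoms_x[di]
            for jj in tree.query_ball_point(d_atom.position, d_max):
                a_atom = atoms_y[acceptors[jj]]
                key = frozenset((id(d_atom), id(a_atom)))
                if key in seen:
                    continue
                dist = float(np.linalg.norm(a_atom.position - d_atom.position))
                antecedents = neigh.get(di, [])
                angles = [_angle(atoms_x[n].position, d_atom.position,
                                 a_atom.position) for n in antecedents]
                ang = min(angles) if angles else 180.0
                if ang >= angle_min:
                    seen.add(key)
                    bb = {d_atom.name.strip(), a_atom.name.strip()} <= {"N", "O"}
                    bonds.append(HBond(
                        donor=f"{d_atom.chain_id}/{d_atom.residue_name}"
                              f"{d_atom.residue_number}/{d_atom.name.strip()}",
                        acceptor=f"{a_atom.chain_id}/{a_atom.residue_name}"
                                 f"{a_atom.residue_number}/{a_atom.name.strip()}",
                        distance=dist, angle=ang,
                        type="backbone-backbone" if bb else "side-chain"))
    return bonds


# ---------------------------------------------------------------------------
# Solvation energy


def solvation_energy(assembly: SheetAssembly | ZipperAssembly,
                     params: SolvationParams | None = None,
                     radii: RadiusTable = DEFAULT_RADII,
                     n_points: int = 960,
                     reference: str = "strand") -> float:
    """Transfer (solvation) energy per strand, cal/mol.

    ΔG = Σ_atoms σ(class) · [ASA(reference) − ASA(assembly)], averaged over
    central strands; positive values indicate net apolar burial.  With
    ``reference="strand"`` each strand in isolation is the reference, so
    the value includes the intra-sheet ladder burial; ``reference="sheet"``
    references each strand within its own isolated sheet, so the value
    isolates the solvation gain stored in the inter-sheet (zipper)
    interface — the quantity that separates mated zippers from unmated
    sheet stacks.
    """
    if reference not in {"strand", "sheet"}:
        raise ValueError(f"unknown reference state {reference!r}")
    params = params or SolvationParams()
    sheets = ([assembly] if isinstance(assembly, SheetAssembly)
              else [assembly.sheet_a, assembly.sheet_b])
    all_atoms = [a for s in sheets for a in s.atoms if not a.is_water]
    asa_all = sasa(all_atoms, radii, n_points).per_atom
    index = {id(a): j for j, a in enumerate(all_atoms)}

    energies = []
    for sheet in sheets:
        if reference == "sheet":
            sheet_atoms = [a for a in sheet.atoms if not a.is_water]
            asa_sheet = sasa(sheet_atoms, radii, n_points).per_atom
            ref_lookup = {id(a): asa_sheet[j]
                          for j, a in enumerate(sheet_atoms)}
        for i in _central_strand_indices(sheet):
            strand = [a for a in sheet.strands[i] if not a.is_water]
            if reference == "strand":
                asa_iso = sasa(strand, radii, n_points).per_atom
                ref_lookup = {id(a): asa_iso[j] for j, a in enumerate(strand)}
            dg = 0.0
            for a in strand:
                sigma = params.sigma[atom_solvation_class(a)]
                dg += sigma * (ref_lookup[id(a)] - asa_all[index[id(a)]])
            energies.append(dg)
    return float(np.mean(energies))


# ---------------------------------------------------------------------------
# Zipper classification


def _ranked_strands(sheet: SheetAssembly, axis: np.ndarray) -> list:
    heights = [np.mean([x.position for x in s], axis=0) @ axis
               for s in sheet.strands]
    return [sheet.strands[i] for i in np.argsort(heights)]


def _presented_face_parity(sheet: SheetAssembly, toward: np.ndarray,
                           axis: np.ndarray) -> int | None:
    # antiparallel sheets present alternating faces per strand sub-lattice;
    # vote over the even-ranked sub-lattice along the common fiber axis so
    # that both sheets of a zipper are compared consistently
    votes = {0: 0, 1: 0}
    for strand in _ranked_strands(sheet, axis)[::2]:
        by_res: dict[int, dict[str, AtomSite]] = {}
        for a in strand:
            by_res.setdefault(a.residue_number, {})[a.name.strip()] = a
        for num, res in by_res.items():
            if "CB" in res and "CA" in res:
                v = res["CB"].position - res["CA"].position
                if v @ toward > 0:
                    votes[num % 2] += 1
    if votes[0] == votes[1]:
        return None
    return 0 if votes[0] > votes[1] else 1


def classify_zipper(zipper: ZipperAssembly,
                    radii: RadiusTable = DEFAULT_RADII,
                    dry_threshold: float = DRY_THRESHOLD,
                    n_points: int = 480,
                    precomputed_burial: float | None = None) -> int | None:
    """Assign the steric-zipper class (1–8) or ``None`` for a non-zipper.

    The class is determined by three binary descriptors: strand orientation
    within the sheets (parallel → classes 1–4), whether the two sheets mate
    the same face (face-to-face) or opposite faces, and whether strands at
    the same height along the fiber axis run the same way (up-up) or
    opposite ways (up-down).  Interfaces burying less than ``dry_threshold``
    Å² per residue are not steric zippers and return ``None``.
    """
    from .synthetic import ZIPPER_CLASSES  # table shared with the builder

    a, b = zipper.sheet_a, zipper.sheet_b
    try:
        reg_a = strand_registry(a)
        reg_b = strand_registry(b)
    except ValueError as exc:
        logger.warning("classification failed: %s", exc)
        return None
    if reg_a.orientation != reg_b.orientation or reg_a.orientation == "mixed":
        logger.warning("ambiguous orientations: %s vs %s",
                       reg_a.orientation, reg_b.orientation)
        return None
    parallel = reg_a.orientation == "parallel"

    if precomputed_burial is None:
        _, per_res = buried_area(a, b, radii, n_points)
    else:
        per_res = precomputed_burial
    if per_res < dry_threshold:
        logger.info("burial %.1f Å²/residue below dry threshold %.1f: not a zipper",
                    per_res, dry_threshold)
        return None

    cent_a = np.mean([x.position for x in a.atoms], axis=0)
    cent_b = np.mean([x.position for x in b.atoms], axis=0)
    ref_dir = strand_direction(a.strands[0])
    v = cent_b - cent_a
    try:
        stack = _stacking_axis(a)
    except ValueError:
        stack = a.fiber_axis
    n_hat = v - (v @ ref_dir) * ref_dir - (v @ stack) * stack
    norm = np.linalg.norm(n_hat)
    if norm < 1e-6:
        logger.warning("interface normal undefined")
        return None
    n_hat /= norm

    par_a = _presented_face_parity(a, n_hat, a.fiber_axis)
    par_b = _presented_face_parity(b, -n_hat, a.fiber_axis)
    if par_a is None or par_b is None:
        logger.warning("face parity ambiguous (no or tied Cβ votes)")
        return None
    face_to_face = par_a == par_b

    # rank strands of both sheets along the common fiber axis and compare
    # direction patterns rank-by-rank (robust to half-rise lateral offsets)
    axis = a.fiber_axis
    ra, rb = _ranked_strands(a, axis), _ranked_strands(b, axis)
    vote = sum(float(strand_direction(sa) @ strand_direction(sb))
               for sa, sb in zip(ra, rb))
    up_up = vote > 0

    inverse = {v: k for k, v in ZIPPER_CLASSES.items()}
    return inverse[(parallel, face_to_face, up_up)]


def compute_interface_metrics(zipper: ZipperAssembly,
                              radii: RadiusTable = DEFAULT_RADII,
                              n_points: int = 960,
                              dry_threshold: float = DRY_THRESHOLD,
                              hbond_d_max: float = 3.5,
                              hbond_angle_min: float = 90.0) -> InterfaceMetrics:
    """Assemble the full interface report for a sheet pair."""
    a, b = zipper.sheet_a, zipper.sheet_b
    per_strand, per_res = buried_area(a, b, radii, n_points)
    dry = per_res >= dry_threshold
    try:
        sc = shape_complementarity(a, b, radii=radii)
    except ValueError:
        sc = None
    n_hb = len(hydrogen_bonds(a, b, hbond_d_max, hbond_angle_min))
    # sheet reference isolates the solvation gain of the zipper interface
    solv = solvation_energy(zipper, radii=radii, n_points=n_points,
                            reference="sheet")
    cls = classify_zipper(zipper, radii, dry_threshold, n_points=min(n_points, 480),
                          precomputed_burial=per_res)
    n_used = len(_central_strand_indices(a)) + len(_central_strand_indices(b))
    return InterfaceMetrics(
        buried_per_strand=per_strand, buried_per_residue=per_res, sc=sc,
        n_hbonds=n_hb, solvation_energy_per_strand=solv, zipper_class=cls,
        dry=dry, n_strands_used=n_used)
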