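"""Crystal-geometry descriptors for molecular solids.

Unit-cell volumes, periodic contact distances (hydrogen-bond O...O
lengths), and grid-based probe-occupiable void fractions — the
descriptors used to relate segmental mobility to packing in polymorph
studies. Structures are read from CIF or PDB via gemmi and expanded to
P1 so that all downstream geometry works on explicit sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import VDW_RADII_SETS
from .exceptions import FormatError, InvalidParameterError

__all__ = [
    "Site",
    "UnitCell",
    "Contact",
    "VoidResult",
    "read_structure",
    "cell_volume",
    "contacts",
    "void_fraction",
]


@dataclass(frozen=True)
class Site:
    element: str
    frac: tuple[float, float, float]
    label: str = ""


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell with explicit (P1) atomic sites.

    Lengths in Angstrom, angles in degrees. Fractional coordinates are
    wrapped to [0, 1).
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    sites: tuple[Site, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidParameterError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise InvalidParameterError("cell angles must lie in (0, 180) degrees")
        wrapped = tuple(
            replace(s, frac=tuple(x % 1.0 for x in s.frac)) for s in self.sites
        )
        object.__setattr__(self, "sites", wrapped)

    @property
    def matrix(self) -> np.ndarray:
        """Lower-triangular fractional->Cartesian cell matrix (rows = a, b, c)."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
        sg = math.sin(ga)
        cx = self.c * cb
        cy = self.c * (ca - cb * cg) / sg
        cz2 = self.c**2 - cx**2 - cy**2
        if cz2 <= 0:
            raise InvalidParameterError("cell angles do not define a positive volume")
        return np.array(
            [
                [self.a, 0.0, 0.0],
                [self.b * cg, self.b * sg, 0.0],
                [cx, cy, math.sqrt(cz2)],
            ]
        )

    def cartesian(self) -> np.ndarray:
        """Cartesian coordinates of all sites, shape (n, 3), Angstrom."""
        if not self.sites:
            return np.zeros((0, 3))
        frac = np.array([s.frac for s in self.sites])
        return frac @ self.matrix


@dataclass(frozen=True)
class Contact:
    label_a: str
    label_b: str
    image: tuple[int, int, int]
    distance: float


@dataclass(frozen=True)
class VoidResult:
    probe_radius: float
    grid_spacing: float
    fraction: float  # percent of cell volume
    radii_set: str = "bondi"


def cell_volume(cell: UnitCell) -> float:
    """Unit-cell volume in cubic Angstrom.

    Uses the triclinic closed form
    V = abc * sqrt(1 - cos^2 a - cos^2 b - cos^2 g + 2 cos a cos b cos g).
    """
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if arg <= 0:
        raise InvalidParameterError("cell angles do not define a positive volume")
    return cell.a * cell.b * cell.c * math.sqrt(arg)


def _merge_duplicates(sites: list[Site], cell: UnitCell, tol: float = 0.3) -> list[Site]:
    """Drop sites closer than `tol` Angstrom to an earlier site (periodic)."""
    kept: list[Site] = []
    mat = cell.matrix
    shifts = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    for s in sites:
        dup = False
        for t in kept:
            if t.element != s.element:
                continue
            d = np.array(s.frac) - np.array(t.frac)
            dc = (d + shifts) @ mat
            if np.min(np.linalg.norm(dc, axis=1)) < tol:
                dup = True
                break
        if not dup:
            kept.append(s)
    return kept


def read_structure(path, fmt: str | None = None) -> UnitCell:
    """Read a crystal structure from CIF or PDB into a P1 UnitCell.

    CIF files go through gemmi's small-molecule reader and are expanded
    over all symmetry operators; sites duplicated by special positions
    are merged within 0.3 Angstrom. PDB files are taken as deposited
    (CRYST1 cell + explicit atoms).
    """
    import gemmi

    path = str(path)
    if fmt is None:
        fmt = "pdb" if path.lower().endswith(".pdb") else "cif"
    if fmt == "cif":
        try:
            doc = gemmi.cif.read(path)
            block = doc.sole_block()
            small = gemmi.read_small_structure(path)
        except Exception as exc:
            raise FormatError(f"could not parse CIF {path}: {exc}") from exc
        if block.find_value("_cell_length_a") is None:
            raise FormatError(f"{path}: missing _cell block")
        cellg = small.cell
        if cellg.volume <= 0 or cellg.a <= 0:
            raise FormatError(f"{path}: missing or invalid _cell block")
        cell0 = UnitCell(cellg.a, cellg.b, cellg.c, cellg.alpha, cellg.beta, cellg.gamma)
        sites: list[Site] = [
            Site(site.element.name, (site.fract.x, site.fract.y, site.fract.z), site.label)
            for site in small.sites
        ]
        sg = gemmi.SpaceGroup(small.spacegroup_hm) if small.spacegroup_hm else None
        expanded: list[Site] = []
        if sg is not None:
            ops = sg.operations()
            for s in sites:
                for op in ops:
                    x, y, z = op.apply_to_xyz(list(s.frac))
                    expanded.append(Site(s.element, (x % 1.0, y % 1.0, z % 1.0), s.label))
        else:
            expanded = sites
        cell = UnitCell(
            cell0.a, cell0.b, cell0.c, cell0.alpha, cell0.beta, cell0.gamma,
            tuple(_merge_duplicates(expanded, cell0)),
        )
        return cell
    if fmt == "pdb":
        try:
            st = gemmi.read_structure(path)
        except Exception as exc:
            raise FormatError(f"could not parse PDB {path}: {exc}") from exc
        cellg = st.cell
        if cellg.a <= 0:
            raise FormatError(f"{path}: missing CRYST1 record")
        cell0 = UnitCell(cellg.a, cellg.b, cellg.c, cellg.alpha, cellg.beta, cellg.gamma)
        mat_inv = np.linalg.inv(cell0.matrix)
        sites = []
        for model in st:
            for chain in model:
                for res in chain:
                    for atom in res:
                        frac = np.array([atom.pos.x, atom.pos.y, atom.pos.z]) @ mat_inv
                        sites.append(
                            Site(atom.element.name, tuple(frac % 1.0), atom.name)
                        )
            break  # first model only
        return UnitCell(
            cell0.a, cell0.b, cell0.c, cell0.alpha, cell0.beta, cell0.gamma, tuple(sites)
        )
    raise FormatError(f"unknown structure format: {fmt!r}")


def contacts(
    cell: UnitCell, elem_a: str, elem_b: str, cutoff: float
) -> list[Contact]:
    """All elem_a...elem_b pairs with periodic distance <= cutoff.

    Periodic images over the 3x3x3 neighbourhood are searched; each pair
    is reported once with the integer image shift that realises the
    minimum distance. Self-pairs through a lattice translation are
    included (image != (0,0,0)).
    """
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be positive")
    idx_a = [i for i, s in enumerate(cell.sites) if s.element == elem_a]
    idx_b = [i for i, s in enumerate(cell.sites) if s.element == elem_b]
    out: list[Contact] = []
    if not idx_a or not idx_b:
        return out
    mat = cell.matrix
    shifts = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    cart_shifts = shifts @ mat
    frac = np.array([s.frac for s in cell.sites])
    cart = frac @ mat
    seen: set[tuple[int, int, tuple[int, int, int]]] = set()
    same = elem_a == elem_b
    for ia in idx_a:
        for ib in idx_b:
            if same and ib < ia:
                continue
            d = cart[ib] + cart_shifts - cart[ia]
            dist = np.linalg.norm(d, axis=1)
            mask = (dist <= cutoff) & (dist > 1e-9)
            for k in np.nonzero(mask)[0]:
                img = tuple(int(x) for x in shifts[k])
                if ia == ib and img < tuple(-x for x in img):
                    continue  # count each self-image pair once
                key = (ia, ib, img)
                if key in seen:
                    continue
                seen.add(key)
                la = cell.sites[ia].label or f"{elem_a}{ia}"
                lb = cell.sites[ib].label or f"{elem_b}{ib}"
                out.append(Contact(la, lb, img, float(dist[k])))
    out.sort(key=lambda c: c.distance)
    return out


def void_fraction(
    cell: UnitCell,
    probe_radius: float,
    grid_spacing: float = 0.2,
    radii_set: str = "bondi",
) -> VoidResult:
    """Probe-occupiable void fraction of the unit cell, in percent.

    A uniform grid over fractional space is tested; a point is void if
    its periodic distance to every atom exceeds vdW(atom) + probe_radius.
    """
    if probe_radius < 0:
        raise InvalidParameterError("probe radius must be non-negative")
    if probe_radius > 0 and grid_spacing > probe_radius / 2:
        raise InvalidParameterError(
            f"grid spacing {grid_spacing} too coarse for probe {probe_radius}"
            " (need spacing <= probe_radius / 2)"
        )
    radii = VDW_RADII_SETS[radii_set]
    mat = cell.matrix
    na = max(2, int(math.ceil(cell.a / grid_spacing)))
    nb = max(2, int(math.ceil(cell.b / grid_spacing)))
    nc = max(2, int(math.ceil(cell.c / grid_spacing)))
    fa = (np.arange(na) + 0.5) / na
    fb = (np.arange(nb) + 0.5) / nb
    fc = (np.arange(nc) + 0.5) / nc
    grid_frac = np.stack(np.meshgrid(fa, fb, fc, indexing="ij"), axis=-1).reshape(-1, 3)
    void = np.ones(len(grid_frac), dtype=bool)
    shifts = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
        dtype=float,
    )
    for s in cell.sites:
        try:
            rad = radii[s.element] + probe_radius
        except KeyError:
            raise KeyError(f"no vdW radius for element {s.element!r} in set {radii_set!r}")
        if not void.any():
            break
        d_frac = grid_frac[void] - np.array(s.frac)
        # periodic minimum over 27 images, computed in Cartesian space
        min_d2 = None
        for sh in shifts:
            dc = (d_frac + sh) @ mat
            d2 = np.einsum("ij,ij->i", dc, dc)
            min_d2 = d2 if min_d2 is None else np.minimum(min_d2, d2)
        keep = min_d2 > rad * rad
        idx = np.nonzero(void)[0]
        void[idx[~keep]] = False
    frac_pct = 100.0 * void.sum() / len(grid_frac)
    return VoidResult(probe_radius, grid_spacing, float(frac_pct), radii_set)
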