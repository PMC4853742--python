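"""Amino-acid geometry: vdW surfaces, rigid conformations and excluded areas.

A residue is modelled as the union of its atoms' van der Waals spheres.  The
structure is centred so the backbone (N, CA, C) centroid sits on the channel
axis (z), with z the longitudinal direction of peptide translocation.  All
lengths are in angstroms.

The measurement operations here are the geometric primitives of the
hard-sphere transport model:

* :func:`mean_surface_radius` — the average radius ``r_o`` from the origin to
  the vdW surface, used to place the hydrodynamic bulk boundary.
* :func:`shell_volume` — volume of a proximal shell (points at a given
  perpendicular distance band from the vdW surface), used to normalise ion
  counts into concentrations.
* :func:`plane_exclusion_area` — the free (ion-accessible) area of the y=0
  cross-section once every atom is inflated by a species' effective radius.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import RESIDUE_LENGTH_A
from ._kernels import count_free_cells

__all__ = [
    "STANDARD_RESIDUES",
    "AminoAcidStructure",
    "Conformation",
    "GeometryError",
    "TemplateParseError",
    "UnknownResidueError",
    "apply_conformation",
    "load_residue_template",
    "mean_surface_radius",
    "plane_exclusion_area",
    "shell_volume",
]

STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: Covalent radii (angstrom) used only to infer bonds in templates.
_COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05}
_BOND_SLACK_A = 0.45


class UnknownResidueError(KeyError):
    """Requested residue code has no packaged template."""


class TemplateParseError(ValueError):
    """A template PDB file could not be parsed."""


class GeometryError(ValueError):
    """A geometric precondition is violated (e.g. origin outside surface)."""


def _wrap_angle(a: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    a = float(a) % 360.0
    if a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class Conformation:
    """Rigid-body conformation of a residue in the channel.

    ``phi``/``psi`` are the backbone dihedrals in degrees (the extended
    template corresponds to phi = psi = 180); ``azimuth`` is the rotation
    about the longitudinal z axis.  ``tilt`` is kept at 0 in production:
    the peptide bond is rigid enough to pin the backbone to the channel
    axis.
    """

    phi: float = 180.0
    psi: float = 180.0
    azimuth: float = 0.0
    tilt: float = 0.0

    def __post_init__(self):
        for name in ("phi", "psi", "azimuth", "tilt"):
            object.__setattr__(self, name, _wrap_angle(getattr(self, name)))


@dataclass(frozen=True)
class AminoAcidStructure:
    """One residue as a rigid union of vdW spheres, centred in the channel.

    ``phi_moving`` / ``psi_moving`` list the atom indices that rotate with
    the phi (N-side) and psi (C-side) dihedrals; they are empty when the
    dihedral is locked (proline's ring) or for synthetic shapes.
    """

    residue_code: str
    elements: tuple
    coords: np.ndarray  # (n_atoms, 3) angstrom
    vdw_radii: np.ndarray  # (n_atoms,)
    atom_names: tuple = ()
    backbone_atom_indices: frozenset = frozenset()
    phi_moving: tuple = ()
    psi_moving: tuple = ()
    terminal_z_extent: float = 0.0

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        radii = np.asarray(self.vdw_radii, dtype=float).reshape(-1)
        if coords.shape[0] == 0 and self.residue_code != "SYN":
            raise ValueError("standard residues must have at least one atom")
        if radii.shape != (coords.shape[0],) or np.any(radii <= 0):
            raise ValueError("each atom needs a positive vdW radius")
        if self.residue_code not in STANDARD_RESIDUES and self.residue_code != "SYN":
            raise ValueError(f"unrecognised residue code {self.residue_code!r}")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "vdw_radii", radii)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def inflated_radii(self, inflate_by: float) -> np.ndarray:
        return self.vdw_radii + float(inflate_by)

    @classmethod
    def from_spheres(cls, centers, radii, residue_code="SYN", **kw) -> "AminoAcidStructure":
        """Build a synthetic test shape from bare spheres (element 'X')."""
        centers = np.asarray(centers, dtype=float).reshape(-1, 3)
        radii = np.asarray(radii, dtype=float).reshape(-1)
        z_ext = float(np.max(np.abs(centers[:, 2]) + radii)) if len(radii) else 0.0
        kw.setdefault("terminal_z_extent", z_ext)
        return cls(
            residue_code=residue_code,
            elements=tuple(["X"] * len(radii)),
            coords=centers,
            vdw_radii=radii,
            **kw,
        )


# ---------------------------------------------------------------------------
# template loading


def _vdw_radius_table() -> dict:
    with resources.files("ticseq.data").joinpath("vdw_radii.json").open() as fh:
        return json.load(fh)["radii_A"]


def _parse_pdb_atoms(path: Path):
    """Parse ATOM records; returns (names, elements, coords).

    Occupancy and B-factor columns are ignored.  A malformed record raises
    :class:`TemplateParseError` naming the offending line.
    """
    names, elements, coords = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                names.append(line[12:16].strip())
                coords.append(
                    (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                )
                element = line[76:78].strip() or names[-1][0]
                elements.append(element.capitalize())
            except (ValueError, IndexError) as exc:
                raise TemplateParseError(
                    f"{path.name}, line {lineno}: malformed ATOM record"
                ) from exc
    return names, elements, np.asarray(coords, dtype=float)


def _infer_bonds(elements, coords) -> list:
    """Distance-based covalent bond detection (adequate for single residues)."""
    n = len(elements)
    rcov = np.array([_COVALENT_RADII.get(e, 0.77) for e in elements])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cut = rcov[:, None] + rcov[None, :] + _BOND_SLACK_A
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < cut[i, j]:
                bonds.append((i, j))
    return bonds


def _component(start: int, blocked_edge: tuple, adj: dict) -> set:
    """Atoms reachable from ``start`` without crossing ``blocked_edge``."""
    seen = {start}
    stack = [start]
    while stack:
        a = stack.pop()
        for b in adj[a]:
            if {a, b} == set(blocked_edge) or b in seen:
                continue
            seen.add(b)
            stack.append(b)
    return seen


def _dihedral_partitions(names, bonds):
    """Atom sets moved by phi (about N-CA) and psi (about CA-C) rotations.

    If removing the pivot bond leaves the two pivots connected (proline's
    N-CA, which sits in the ring) the dihedral is locked and the partition
    is empty.
    """
    idx = {n: i for i, n in enumerate(names)}
    adj = {i: set() for i in range(len(names))}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    parts = {}
    for key, pivot_from, pivot_to in (("phi", "CA", "N"), ("psi", "CA", "C")):
        if pivot_from not in idx or pivot_to not in idx:
            parts[key] = ()
            continue
        i_from, i_to = idx[pivot_from], idx[pivot_to]
        comp = _component(i_to, (i_from, i_to), adj)
        if i_from in comp:  # ring closure: dihedral locked
            parts[key] = ()
        else:
            comp.discard(i_to)  # the pivot atom itself stays on the axis
            parts[key] = tuple(sorted(comp))
    return parts["phi"], parts["psi"]


def load_residue_template(code: str) -> AminoAcidStructure:
    """Load the packaged extended-conformation template for a residue.

    Templates are single amino acids isolated from a straight chain
    (phi = psi = 180 degrees), capped with N-terminal hydrogens and a
    C-terminal OH, oriented with the backbone N->C direction along +z and
    the backbone centroid at the origin.  vdW radii come from the packaged
    Bondi radius table.
    """
    code = str(code).upper()
    if code not in STANDARD_RESIDUES:
        raise UnknownResidueError(f"unknown residue code {code!r}")
    path = resources.files("ticseq.data").joinpath(f"templates/{code}.pdb")
    with resources.as_file(path) as p:
        if not p.exists():
            raise UnknownResidueError(f"no packaged template for {code!r}")
        names, elements, coords = _parse_pdb_atoms(p)
    radii_table = _vdw_radius_table()
    try:
        radii = np.array([radii_table[e] for e in elements])
    except KeyError as exc:
        raise TemplateParseError(f"no vdW radius for element {exc}") from exc

    backbone = frozenset(i for i, n in enumerate(names) if n in ("N", "CA", "C"))
    # terminal caps bound the residue's reach along z
    terminal = [i for i, n in enumerate(names) if n in ("N", "C", "O", "OXT", "H", "H2", "H3", "HXT")]
    if not terminal:
        terminal = list(range(len(names)))
    z_ext = float(np.max(np.abs(coords[terminal, 2]) + radii[terminal]))
    phi_moving, psi_moving = _dihedral_partitions(names, _infer_bonds(elements, coords))
    return AminoAcidStructure(
        residue_code=code,
        elements=tuple(elements),
        coords=coords,
        vdw_radii=radii,
        atom_names=tuple(names),
        backbone_atom_indices=backbone,
        phi_moving=phi_moving,
        psi_moving=psi_moving,
        terminal_z_extent=z_ext,
    )


# ---------------------------------------------------------------------------
# rigid transforms


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def _axis_through(names, coords, a: str, b: str):
    idx = {n: i for i, n in enumerate(names)}
    return coords[idx[b]], coords[idx[b]] - coords[idx[a]]


def apply_conformation(s: AminoAcidStructure, c: Conformation) -> AminoAcidStructure:
    """Return a copy of ``s`` posed in conformation ``c``.

    Dihedral rotations are applied relative to the extended template:
    the phi partition rotates about the N-CA axis by (phi - 180) and the psi
    partition about the CA-C axis by (psi - 180); finally the whole residue
    rotates by ``azimuth`` about z.  All transforms are rigid.
    """
    coords = s.coords.copy()
    for angle, moving, pivots in (
        (c.phi, s.phi_moving, ("CA", "N")),
        (c.psi, s.psi_moving, ("CA", "C")),
    ):
        delta = _wrap_angle(angle - 180.0)
        if not moving or delta == 0.0:
            continue
        origin, axis = _axis_through(s.atom_names, coords, *pivots)
        R = _rotation_matrix(axis, delta)
        m = list(moving)
        coords[m] = (coords[m] - origin) @ R.T + origin
    if c.azimuth != 0.0:
        Rz = _rotation_matrix(np.array([0.0, 0.0, 1.0]), c.azimuth)
        coords = coords @ Rz.T
    return replace(s, coords=coords)


# ---------------------------------------------------------------------------
# surface measurements


def _fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def mean_surface_radius(s: AminoAcidStructure, n_directions: int = 20000) -> float:
    """Average distance r_o from the origin to the vdW surface.

    Casts ``n_directions`` quasi-uniform rays from the origin and averages
    the distance to the outermost crossing of the union-of-spheres surface.
    The origin must lie inside the union.
    """
    centers, radii = s.coords, s.vdw_radii
    if s.n_atoms == 0 or np.min(np.linalg.norm(centers, axis=1) - radii) >= 0:
        raise GeometryError("origin lies outside the vdW surface")
    dirs = _fibonacci_directions(int(n_directions))
    # farthest ray/sphere intersection per atom: t = d.c + sqrt((d.c)^2 - |c|^2 + r^2)
    dc = dirs @ centers.T  # (n_dir, n_atoms)
    disc = dc * dc - (np.linalg.norm(centers, axis=1) ** 2)[None, :] + (radii**2)[None, :]
    t = np.where(disc >= 0, dc + np.sqrt(np.maximum(disc, 0.0)), -np.inf)
    t_max = t.max(axis=1)
    if np.any(~np.isfinite(t_max)) or np.any(t_max <= 0):
        raise GeometryError("a ray from the origin misses the vdW surface")
    return float(t_max.mean())


def surface_distance(points: np.ndarray, s: AminoAcidStructure,
                     inflate_by: float = 0.0) -> np.ndarray:
    """Signed distance from points to the (optionally inflated) vdW surface.

    min over atoms of (|p - center| - radius); negative inside the molecule.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.full(points.shape[0], np.inf)
    radii = s.inflated_radii(inflate_by)
    for c, r in zip(s.coords, radii):
        np.minimum(d, np.linalg.norm(points - c, axis=1) - r, out=d)
    return d


def _grid_axis(lo: float, hi: float, anchor: float, step: float) -> np.ndarray:
    """Deterministic cell centers anchor + (k + 0.5) * step covering [lo, hi]."""
    k_lo = int(np.floor((lo - anchor) / step)) - 1
    k_hi = int(np.ceil((hi - anchor) / step)) + 1
    return anchor + (np.arange(k_lo, k_hi) + 0.5) * step


def shell_volume(s: AminoAcidStructure, r_lo: float, r_hi: float,
                 grid_step: float = 0.1) -> float:
    """Volume of the proximal shell r_lo <= d < r_hi outside the molecule.

    Counts grid cells whose centers fall in the band of perpendicular
    distance d from the vdW surface; each cell contributes grid_step^3.
    The grid lattice is anchored at the structure centroid, so the result
    is deterministic.
    """
    if not (np.isfinite(r_lo) and np.isfinite(r_hi)):
        raise ValueError("shell bounds must be finite")
    if r_lo < 0 or r_hi < r_lo or grid_step <= 0:
        raise ValueError("need 0 <= r_lo <= r_hi and grid_step > 0")
    if r_hi == r_lo:
        return 0.0
    anchor = s.coords.mean(axis=0)
    margin = float(s.vdw_radii.max() + r_hi + grid_step)
    axes = [
        _grid_axis(s.coords[:, k].min() - margin, s.coords[:, k].max() + margin,
                   anchor[k], grid_step)
        for k in range(3)
    ]
    xs, ys, zs = axes
    count = 0
    # slab over z to bound memory on large shells
    slab = max(1, int(4e6 // (len(xs) * len(ys))))
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    xy = np.column_stack([X.ravel(), Y.ravel()])
    for z0 in range(0, len(zs), slab):
        zblock = zs[z0:z0 + slab]
        pts = np.concatenate(
            [np.column_stack([xy, np.full(len(xy), z)]) for z in zblock]
        )
        d = surface_distance(pts, s)
        count += int(np.count_nonzero((d >= r_lo) & (d < r_hi)))
    return count * grid_step**3


def plane_exclusion_area(
    s: AminoAcidStructure,
    inflate_by: float,
    disk_radius: float,
    z_margin: float | None = RESIDUE_LENGTH_A / 2.0,
    grid_step: float = 0.05,
) -> float:
    """Free area of the y=0 cross-section outside the inflated vdW surface.

    The accessible window is the disk of ``disk_radius`` about the channel
    axis, clipped to |z| <= terminal_z_extent + z_margin (pass ``z_margin=None``
    to disable the clip).  Each atom sphere of radius (vdW + inflate_by)
    slices the y=0 plane in a circle; the returned value is the window area
    lying outside every such circle, computed by cell counting on a fixed
    lattice.  The clip models the reach of neighbouring residues along the
    chain: beyond half the inter-residue spacing the cross-section belongs
    to the neighbours, not to the residue being measured.
    """
    disk_radius = float(disk_radius)
    inflate_by = float(inflate_by)
    if disk_radius <= 0 or not np.isfinite(disk_radius):
        raise ValueError("disk_radius must be positive and finite")
    if inflate_by < 0 or not np.isfinite(inflate_by):
        raise ValueError("inflate_by must be non-negative and finite")
    if z_margin is None:
        z_window = disk_radius
    else:
        z_window = min(disk_radius, float(s.terminal_z_extent) + float(z_margin))
    if z_window <= 0:
        return 0.0
    free = count_free_cells(
        s.coords, s.inflated_radii(inflate_by), disk_radius, z_window, grid_step
    )
    return free * grid_step**2
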