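"""Polyproline-II ruler models and dye accessible volumes.

The distance calibration rests on rigid Cys-(Pro)n-Cys peptides used as
molecular rulers: the polyproline-II (PPII) helix has a well defined rise of
~3.1 A per residue, so the number of prolines sets the separation of the two
terminal cysteine sulfurs to which the dye is coupled.  The dye itself is not
a point at the sulfur: it explores an *accessible volume* (AV) — every
position its flexible linker can reach without clashing with the peptide.
The distance relevant to self-quenching is the distance between the mean dye
positions of the two AVs (the R_mp convention).

This module builds the ruler coordinates from ideal internal coordinates,
computes AV1-style single-sphere accessible volumes on a grid by geodesic
flood fill, and provides the distance-per-residue regression and the
all-trans-helix probability helper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "DyeParameters",
    "AccessibleVolume",
    "EmptyAccessibleVolumeError",
    "build_polyproline",
    "accessible_volume",
    "mean_position_distance",
    "distance_per_residue_slope",
    "all_trans_probability",
    "helix_rise_per_residue",
    "write_pdb",
]

# Ideal backbone internal coordinates (Engh-Huber-like averages), Angstrom / degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
BOND_CB_SG = 1.808
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5
ANGLE_CA_CB_SG = 114.0

# Canonical PPII dihedrals.  The left-handed extended helix these produce has
# a rise close to 3.1 A per residue, the textbook value for PPII.
PPII_PHI = -75.0
PPII_PSI = 145.0
PPII_OMEGA = 180.0

# van der Waals radii (A) for the elements that occur in the rulers.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


@dataclass(frozen=True)
class Atom:
    """One atom of a structural model."""

    name: str
    res_index: int  # 1-based residue number
    res_name: str
    element: str
    vdw: float
    xyz: np.ndarray

    def id(self) -> str:
        return f"{self.res_index}:{self.res_name}:{self.name}"


@dataclass
class StructureModel:
    """Peptide coordinates plus the two dye attachment atoms.

    ``attachment_atoms`` are the identifiers (``"resindex:RES:NAME"``) of the
    two cysteine sulfurs where the dye linker is coupled.
    """

    atoms: list[Atom]
    n_pro: int
    attachment_atoms: tuple[str, str]

    def __post_init__(self) -> None:
        if self.n_pro < 0:
            raise ValueError("n_pro must be non-negative")
        if len(self.attachment_atoms) != 2:
            raise ValueError("exactly two attachment atoms required")
        coords = self.coordinates()
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")

    def coordinates(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw for a in self.atoms], dtype=float)

    def atom(self, atom_id: str) -> Atom:
        for a in self.atoms:
            if a.id() == atom_id:
                return a
        raise KeyError(f"no atom {atom_id!r} in structure")

    def ca_trace(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms if a.name == "CA"])


@dataclass(frozen=True)
class DyeParameters:
    """Single-sphere (AV1) dye model parameters, all in Angstrom.

    Defaults are FPS-like values for a rhodamine on a thiol-reactive linker;
    they are configurable because the calibration study does not print the
    parameters it used.
    """

    linker_length: float = 15.0
    linker_width: float = 4.5
    dye_radius: float = 3.5
    grid_spacing: float = 0.9

    def __post_init__(self) -> None:
        for name in ("linker_length", "linker_width", "dye_radius", "grid_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.grid_spacing > self.linker_width:
            raise ValueError("grid_spacing must not exceed linker_width")


class EmptyAccessibleVolumeError(RuntimeError):
    """The attachment site is fully buried: no dye position is reachable."""


@dataclass
class AccessibleVolume:
    """Grid cloud of sterically allowed dye positions."""

    grid_points: np.ndarray  # (n, 3) A
    grid_spacing: float
    attachment_xyz: np.ndarray

    @property
    def n_points(self) -> int:
        return int(self.grid_points.shape[0])

    @property
    def mean_position(self) -> np.ndarray:
        if self.n_points == 0:
            raise EmptyAccessibleVolumeError("empty accessible volume has no mean position")
        return self.grid_points.mean(axis=0)

    @property
    def volume(self) -> float:
        """Occupied volume in A^3 (point count times cell volume)."""
        return self.n_points * self.grid_spacing**3


# ---------------------------------------------------------------------------
# Internal-coordinate (NeRF) atom placement
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position atom d given a-b-c, bond c-d, angle b-c-d and dihedral a-b-c-d."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.cos(chi) * math.sin(theta),
        bond * math.sin(chi) * math.sin(theta),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_polyproline(n_pro: int) -> StructureModel:
    """Build a Cys-(Pro)n-Cys ruler with canonical PPII dihedrals.

    Backbone (N, CA, C, O) plus CB for every residue and SG for the terminal
    cysteines, generated from ideal bond lengths/angles with
    (phi, psi, omega) = (-75, +145, 180) degrees.  ``n_pro = 0`` gives the
    smallest ruler, Cys-Cys.
    """
    if n_pro < 0:
        raise ValueError("n_pro must be non-negative")
    n_res = n_pro + 2
    res_names = ["CYS"] + ["PRO"] * n_pro + ["CYS"]

    # Seed the first residue's backbone in a canonical frame.
    backbone: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    theta = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + np.array([-BOND_CA_C * math.cos(theta), BOND_CA_C * math.sin(theta), 0.0])
    backbone.append({"N": n0, "CA": ca0, "C": c0})

    for i in range(1, n_res):
        prev = backbone[-1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, PPII_PSI)
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, PPII_OMEGA)
        c_i = _place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, PPII_PHI)
        backbone.append({"N": n_i, "CA": ca_i, "C": c_i})

    atoms: list[Atom] = []
    for i, res in enumerate(backbone):
        idx = i + 1
        rname = res_names[i]
        n_i, ca_i, c_i = res["N"], res["CA"], res["C"]
        # Carbonyl O: trans to the next N (or to the chain direction at the C-terminus).
        if i + 1 < n_res:
            psi_like = 180.0 + PPII_PSI  # O opposes the next N about the CA-C bond
        else:
            psi_like = 180.0
        o_i = _place_atom(n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O, psi_like)
        # CB branches off CA; dihedral chosen to give near-tetrahedral geometry.
        cb_i = _place_atom(c_i, n_i, ca_i, BOND_CA_CB, ANGLE_N_CA_CB, -120.0)
        atoms.append(Atom("N", idx, rname, "N", VDW_RADII["N"], n_i))
        atoms.append(Atom("CA", idx, rname, "C", VDW_RADII["C"], ca_i))
        atoms.append(Atom("C", idx, rname, "C", VDW_RADII["C"], c_i))
        atoms.append(Atom("O", idx, rname, "O", VDW_RADII["O"], o_i))
        atoms.append(Atom("CB", idx, rname, "C", VDW_RADII["C"], cb_i))
        if rname == "CYS":
            sg_i = _place_atom(n_i, ca_i, cb_i, BOND_CB_SG, ANGLE_CA_CB_SG, 180.0)
            atoms.append(Atom("SG", idx, rname, "S", VDW_RADII["S"], sg_i))

    attach = (f"1:CYS:SG", f"{n_res}:CYS:SG")
    return StructureModel(atoms=atoms, n_pro=n_pro, attachment_atoms=attach)


def helix_rise_per_residue(structure: StructureModel) -> float:
    """Rise per residue: mean CA(i)->CA(i+1) displacement projected on the
    helix axis, the axis being the dominant singular vector of the centred
    CA trace."""
    ca = structure.ca_trace()
    if ca.shape[0] < 2:
        raise ValueError("need at least two CA atoms")
    centred = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    proj = centred @ axis
    return float(np.abs(np.diff(proj)).mean())


# ---------------------------------------------------------------------------
# Accessible-volume engine
# ---------------------------------------------------------------------------

def _chamfer_offsets(max_r: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Primitive integer offsets within a (2r+1)^3 neighbourhood and their
    Euclidean lengths.  Offsets with a common divisor are redundant (their
    path decomposes into shorter ones), so only visible lattice points are
    kept.  A radius-3 neighbourhood approximates the Euclidean geodesic to
    about 1%, which keeps the free-space AV within the sphere-volume check."""
    offs = []
    for dx in range(-max_r, max_r + 1):
        for dy in range(-max_r, max_r + 1):
            for dz in range(-max_r, max_r + 1):
                if dx == dy == dz == 0:
                    continue
                if math.gcd(math.gcd(abs(dx), abs(dy)), abs(dz)) != 1:
                    continue
                offs.append((dx, dy, dz))
    arr = np.array(offs, dtype=int)
    return arr, np.linalg.norm(arr, axis=1)


_OFFSETS, _OFFSET_LENGTHS = _chamfer_offsets(3)


def accessible_volume(structure: StructureModel, attachment: str,
                      dye: DyeParameters | None = None) -> AccessibleVolume:
    """AV1 accessible volume of a dye coupled at ``attachment``.

    A grid covering a cube of side 2*(linker_length + dye_radius) around the
    attachment atom is classified: a cell is *passable* if the linker
    (half-width clearance) fits there, and *allowed* if the whole dye sphere
    fits.  The AV is the set of allowed cells whose geodesic (obstacle-
    avoiding chamfer flood-fill) distance from the attachment atom is at most
    the linker length.  The attachment atom itself is not an obstacle.

    Raises
    ------
    EmptyAccessibleVolumeError
        If the attachment site is fully buried and no cell is reachable.
    """
    if dye is None:
        dye = DyeParameters()
    origin_atom = structure.atom(attachment)
    origin = origin_atom.xyz
    h = dye.grid_spacing
    half = dye.linker_length + dye.dye_radius
    # odd node count so one grid node coincides with the attachment atom
    n_side = 2 * int(math.ceil(half / h)) + 1
    ax = origin[0] + (np.arange(n_side) - (n_side - 1) / 2) * h
    ay = origin[1] + (np.arange(n_side) - (n_side - 1) / 2) * h
    az = origin[2] + (np.arange(n_side) - (n_side - 1) / 2) * h

    # Clearance of each cell centre: distance to the nearest atom surface.
    obstacles = [a for a in structure.atoms if a.id() != attachment]
    gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
    clearance = np.full(gx.shape, np.inf)
    for a in obstacles:
        d = np.sqrt((gx - a.xyz[0]) ** 2 + (gy - a.xyz[1]) ** 2 + (gz - a.xyz[2]) ** 2)
        np.minimum(clearance, d - a.vdw, out=clearance)

    passable = clearance >= dye.linker_width / 2.0
    allowed = clearance >= dye.dye_radius

    # Chamfer flood fill (vectorised Bellman-Ford over the offset stencil).
    dist = np.full(gx.shape, np.inf)
    i0 = np.array([np.argmin(np.abs(ax - origin[0])),
                   np.argmin(np.abs(ay - origin[1])),
                   np.argmin(np.abs(az - origin[2]))])
    start_offset = float(np.linalg.norm(
        np.array([ax[i0[0]], ay[i0[1]], az[i0[2]]]) - origin))
    dist[tuple(i0)] = start_offset
    blocked = ~passable
    dist[blocked] = np.inf
    if blocked[tuple(i0)]:
        # The seed cell itself must stay live, else nothing propagates.
        dist[tuple(i0)] = start_offset
        blocked = blocked.copy()
        blocked[tuple(i0)] = False

    step_costs = _OFFSET_LENGTHS * h
    while True:
        updated = dist
        prev = dist.copy()
        for (dx, dy, dz), cost in zip(_OFFSETS, step_costs):
            shifted = np.full_like(dist, np.inf)
            src = shifted[max(dx, 0) or None: dist.shape[0] + min(dx, 0) or None,
                          max(dy, 0) or None: dist.shape[1] + min(dy, 0) or None,
                          max(dz, 0) or None: dist.shape[2] + min(dz, 0) or None]
            tgt = dist[max(-dx, 0) or None: dist.shape[0] + min(-dx, 0) or None,
                       max(-dy, 0) or None: dist.shape[1] + min(-dy, 0) or None,
                       max(-dz, 0) or None: dist.shape[2] + min(-dz, 0) or None]
            src[...] = tgt + cost
            np.minimum(updated, shifted, out=updated)
        updated[blocked] = np.inf
        if np.allclose(np.nan_to_num(updated, posinf=-1.0),
                       np.nan_to_num(prev, posinf=-1.0)):
            break
        dist = updated

    keep = (dist <= dye.linker_length) & allowed
    pts = np.column_stack([gx[keep], gy[keep], gz[keep]])
    if pts.shape[0] == 0:
        raise EmptyAccessibleVolumeError(
            f"attachment {attachment} is fully buried: accessible volume is empty")
    return AccessibleVolume(grid_points=pts, grid_spacing=h,
                            attachment_xyz=origin.copy())


def mean_position_distance(av_a: AccessibleVolume, av_b: AccessibleVolume) -> float:
    """Euclidean distance between mean dye positions (R_mp)."""
    return float(np.linalg.norm(av_a.mean_position - av_b.mean_position))


def distance_per_residue_slope(series: Sequence[tuple[float, float]]) -> float:
    """OLS slope (A/residue) of inter-dye distance versus proline count."""
    if len(series) < 2:
        raise ValueError("need at least two (n_pro, distance) points")
    n = np.array([p[0] for p in series], dtype=float)
    d = np.array([p[1] for p in series], dtype=float)
    if np.ptp(n) == 0:
        raise ValueError("all n_pro identical: slope undefined")
    slope, _ = np.polyfit(n, d, 1)
    return float(slope)


def all_trans_probability(p_cis: float, n_bonds: int) -> float:
    """Probability that every one of ``n_bonds`` prolyl bonds is trans,
    assuming independent isomerisation with per-bond cis probability
    ``p_cis``.  Whether terminal prolines count toward ``n_bonds`` is the
    caller's convention."""
    if not 0.0 <= p_cis <= 1.0:
        raise ValueError("p_cis must be a probability")
    if n_bonds < 1:
        raise ValueError("n_bonds must be positive")
    return (1.0 - p_cis) ** n_bonds


# ---------------------------------------------------------------------------
# PDB output
# ---------------------------------------------------------------------------

def write_pdb(structure: StructureModel, path) -> None:
    """Write the model as a minimal single-chain PDB file (1-based residues)."""
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        x, y, z = a.xyz
        lines.append(
            f"ATOM  {i:5d} {a.name:<4s}{a.res_name:<4s}A{a.res_index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
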