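"""Two-density coarse-grained detergent corona.

The hydrophobic detergent tails around the transmembrane belt are
modelled as an elliptical hollow torus of height ``a``: a circular tube
of radius a/2 swept along an in-plane ellipse of mean radius ``b`` (semi
axes b*e and b/e, optionally rotated by ``phi``).  The hydrophilic head
groups form a shell of constant thickness ``t`` around that tube.  Each
region is filled with one type of pseudo-atom on a simple cubic lattice
whose spacing is chosen so that one bead per cell reproduces the region's
electron-density contrast against the buffer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "CoronaParams",
    "PseudoAtomSpec",
    "DensitySpec",
    "CoronaModel",
    "DetergentCounts",
    "TAIL_SPEC",
    "HEAD_SPEC",
    "V_MOL_TAIL",
    "V_MOL_HEAD",
    "RHO_WATER",
    "cell_volume",
    "lattice_spacing",
    "corona_membership",
    "membership_codes",
    "build_corona",
    "count_detergents",
    "effective_density",
]

#: electron density of pure water, e-/A^3 (default buffer)
RHO_WATER = 0.334

#: molecular volume of a C12 alkyl tail, A^3 (Tanford: 27.4 + 26.9 n)
V_MOL_TAIL = 350.2
#: molecular volume of a maltoside head, A^3 (DDM partial specific volume minus tail)
V_MOL_HEAD = 359.0


@dataclass(frozen=True)
class PseudoAtomSpec:
    """A coarse-grained scattering centre placed on lattice nodes."""

    label: str
    n_e: float
    v_vdw: float
    role: str  # "head" | "tail"

    def __post_init__(self):
        if self.n_e <= 0 or self.v_vdw <= 0:
            raise ValueError("pseudo-atom needs n_e > 0 and v_vdw > 0")


TAIL_SPEC = PseudoAtomSpec("CH3", 9.0, 32.0, "tail")
HEAD_SPEC = PseudoAtomSpec("NH3", 10.0, 18.2, "head")


@dataclass(frozen=True)
class CoronaParams:
    """Corona torus geometry (lengths in Angstrom, phi in degrees)."""

    a: float          # torus (tube) height; tube radius is a/2
    b: float          # mean radius of the elliptical path
    t: float          # head-shell thickness
    e: float = 1.0    # in-plane ellipticity (semi-axes b*e and b/e)
    phi: float = 0.0  # in-plane rotation of the ellipse axes

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("torus needs a > 0 and b > 0")
        if self.t < 0:
            raise ValueError("head-shell thickness t must be >= 0")
        if self.e <= 0:
            raise ValueError("ellipticity e must be > 0")
        if not (0.0 <= self.phi < 180.0):
            raise ValueError("phi must lie in [0, 180)")

    @property
    def R(self) -> float:
        """Mean outer radius of the hydrophobic torus, b + a/2."""
        return self.b + self.a / 2.0


@dataclass(frozen=True)
class DensitySpec:
    """Region electron densities and the free contrast parameters."""

    rho_heads: float = 0.52   # e-/A^3, hydrophilic head region
    rho_tails: float = 0.28   # e-/A^3, hydrophobic tail region
    rho0: float = RHO_WATER   # buffer
    alpha: float = 1.0        # excluded-volume (contrast-bias) factor
    drho_hyd: float = 0.0     # hydration-layer contrast, e-/A^3

    def __post_init__(self):
        if self.rho0 <= 0:
            raise ValueError("buffer density rho0 must be > 0")
        if not (self.rho_heads > self.rho0 > self.rho_tails):
            raise ValueError(
                "expected opposite-sign contrasts: rho_heads > rho0 > rho_tails")
        if not (0.5 <= self.alpha <= 1.5):
            raise ValueError("alpha outside the supported window [0.5, 1.5]")


@dataclass
class CoronaModel:
    """Generated bead sets with their lattice metadata."""

    tail_beads: np.ndarray  # (Nt, 3)
    head_beads: np.ndarray  # (Nh, 3)
    s_tail: float
    s_head: float
    v_cell_tail: float
    v_cell_head: float
    params: CoronaParams
    densities: DensitySpec
    tail_spec: PseudoAtomSpec = TAIL_SPEC
    head_spec: PseudoAtomSpec = HEAD_SPEC
    warnings: list = field(default_factory=list)

    @property
    def n_beads(self) -> int:
        return len(self.tail_beads) + len(self.head_beads)


def cell_volume(spec: PseudoAtomSpec, rho: float, rho0: float) -> float:
    """Elementary cell volume that makes one bead per cell match contrast rho - rho0."""
    if rho == rho0:
        raise ValueError(f"{spec.label}: rho equals rho0, infinite cell volume")
    num = spec.n_e - rho0 * spec.v_vdw
    den = rho - rho0
    if num * den <= 0:
        raise ValueError(
            f"{spec.label}: contrast sign mismatch (n_e - rho0*V_vdW = {num:.3f}, "
            f"rho - rho0 = {den:.3f}); this pseudo-atom cannot represent the region")
    return num / den


def lattice_spacing(spec: PseudoAtomSpec, rho: float, rho0: float) -> float:
    """Cubic network parameter: cube root of the elementary cell volume."""
    return cell_volume(spec, rho, rho0) ** (1.0 / 3.0)


def _elliptic_u(points: np.ndarray, params: CoronaParams) -> np.ndarray:
    """Elliptical radial coordinate: u = b at the tube centre path."""
    phi = np.deg2rad(params.phi)
    x, y = points[:, 0], points[:, 1]
    xp = x * np.cos(phi) + y * np.sin(phi)
    yp = -x * np.sin(phi) + y * np.cos(phi)
    b, e = params.b, params.e
    return b * np.sqrt((xp / (b * e)) ** 2 + (yp / (b / e)) ** 2)


def membership_codes(points: np.ndarray, params: CoronaParams) -> np.ndarray:
    """Vectorised region test: 0 = tail, 1 = head, 2 = outside."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    u = _elliptic_u(points, params)
    d2 = (u - params.b) ** 2 + points[:, 2] ** 2
    codes = np.full(len(points), 2, dtype=np.int8)
    codes[d2 <= (params.a / 2.0 + params.t) ** 2] = 1
    codes[d2 <= (params.a / 2.0) ** 2] = 0
    return codes


def corona_membership(point, params: CoronaParams) -> str:
    """Region of a single point: 'tail', 'head' or 'outside'."""
    code = membership_codes(np.asarray(point, dtype=float).reshape(1, 3), params)[0]
    return ("tail", "head", "outside")[code]


def _cubic_lattice(spacing: float, half_xy: float, half_z: float) -> np.ndarray:
    """Axis-aligned simple cubic lattice with a node at the origin."""
    n_xy = int(np.floor(half_xy / spacing))
    n_z = int(np.floor(half_z / spacing))
    ax = np.arange(-n_xy, n_xy + 1) * spacing
    az = np.arange(-n_z, n_z + 1) * spacing
    X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def build_corona(structure, params: CoronaParams, dens: DensitySpec,
                 tail_spec: PseudoAtomSpec = TAIL_SPEC,
                 head_spec: PseudoAtomSpec = HEAD_SPEC, *,
                 clash_base: float = 1.8) -> CoronaModel:
    """Generate the tail and head bead lattices around an oriented protein.

    A bead is kept when it lies in its region and no protein heavy-atom
    centre is closer than ``clash_base + spacing/2`` (prevents density
    double-counting at the protein surface).  ``structure`` may be None
    (or empty) for a protein-free corona.
    """
    v_cell_tail = cell_volume(tail_spec, dens.rho_tails, dens.rho0)
    v_cell_head = cell_volume(head_spec, dens.rho_heads, dens.rho0)
    s_tail = v_cell_tail ** (1 / 3)
    s_head = v_cell_head ** (1 / 3)

    u_max = params.b + params.a / 2.0 + params.t
    half_xy = max(params.e, 1.0 / params.e) * u_max + 1.0

    regions = {}
    for spec, spacing, code, half_z in (
            (tail_spec, s_tail, 0, params.a / 2.0),
            (head_spec, s_head, 1, params.a / 2.0 + params.t)):
        nodes = _cubic_lattice(spacing, half_xy, half_z + spacing)
        nodes = nodes[membership_codes(nodes, params) == code]
        regions[code] = nodes

    notes = []
    prot = getattr(structure, "coords", None)
    if prot is not None and len(prot):
        tree = cKDTree(prot)
        for code, spacing in ((0, s_tail), (1, s_head)):
            if len(regions[code]):
                d, _ = tree.query(regions[code], k=1)
                regions[code] = regions[code][d >= clash_base + spacing / 2.0]

    if len(regions[0]) == 0 and len(regions[1]) == 0:
        msg = "corona is empty (fully inside the clash region or too small)"
        warnings.warn(msg)
        notes.append(msg)

    return CoronaModel(regions[0], regions[1], s_tail, s_head,
                       v_cell_tail, v_cell_head, params, dens,
                       tail_spec, head_spec, notes)


class DetergentCounts(NamedTuple):
    heads: float
    tails: float

    def rounded(self) -> tuple[int, int]:
        return int(round(self.heads)), int(round(self.tails))


def count_detergents(model: CoronaModel, v_mol_head: float = V_MOL_HEAD,
                     v_mol_tail: float = V_MOL_TAIL) -> DetergentCounts:
    """Detergent-molecule numbers from bead counts and cell volumes.

    N = (number of beads) * V_cell / V_molecular for each region.
    """
    if v_mol_head <= 0 or v_mol_tail <= 0:
        raise ValueError("molecular volumes must be positive")
    heads = len(model.head_beads) * model.v_cell_head / v_mol_head
    tails = len(model.tail_beads) * model.v_cell_tail / v_mol_tail
    return DetergentCounts(heads, tails)


def effective_density(spec: PseudoAtomSpec, alpha: float, v_cell: float,
                      rho0: float) -> float:
    """Region electron density after the excluded-volume bias alpha.

    rho' = rho0 + (n_e - alpha * rho0 * V_vdW) / V_cell; at alpha = 1 this
    inverts the cell-volume relation and returns the nominal density.
    """
    if v_cell <= 0:
        raise ValueError("v_cell must be positive")
    return rho0 + (spec.n_e - alpha * rho0 * spec.v_vdw) / v_cell
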