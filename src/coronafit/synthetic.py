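"""Download-free test inputs: toy proteins and simulated noisy curves.

The toy "membrane protein" is a lattice-filled cylinder of carbon-like
beads at desk scale; its default dimensions (radius 15 A, height 30 A)
put the best-fit corona parameters in the same range as a real
detergent-solubilised membrane protein while keeping particle counts
small.  ``simulate_experiment`` forward-computes the exact model curve
for known corona parameters and adds independent Gaussian noise with a
recorded seed, standing in for a SEC-SAXS measurement with per-point
error estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corona import CoronaParams, DensitySpec, HEAD_SPEC, TAIL_SPEC, build_corona
from .saxs import ScatteringCurve, add_hydration_shell, debye_curve, particles_from_model
from .structures import Atom, Provenance, Structure

__all__ = ["NoiseModel", "make_toy_protein", "make_tetramer_standin",
           "simulate_experiment"]


@dataclass(frozen=True)
class NoiseModel:
    """Independent Gaussian per-point noise: sigma_i = max(rel * I_i, floor)."""

    relative_sd: float = 0.01
    floor: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")
        if self.floor <= 0:
            raise ValueError("floor must be > 0")


def _bead_structure(coords: np.ndarray, n_e: float, v_vdw: float,
                    source: str) -> Structure:
    atoms = [Atom(i + 1, "BD", "TOY", "A", i + 1, *map(float, xyz),
                  element="X", n_e=n_e, v_vdw=v_vdw)
             for i, xyz in enumerate(coords)]
    return Structure(atoms, Provenance(source=source))


def make_toy_protein(radius: float = 15.0, height: float = 30.0,
                     spacing: float = 3.0, *, n_e: float = 7.0,
                     v_vdw: float = 20.0) -> Structure:
    """Cylinder of carbon-like beads on a cubic lattice (deterministic).

    Beads fill x^2 + y^2 <= radius^2, |z| <= height/2; already oriented
    in the corona frame (axis = z, mid-plane = 0).
    """
    if radius <= 0 or height <= 0 or spacing <= 0:
        raise ValueError("radius, height and spacing must be positive")
    if spacing > min(radius, height):
        raise ValueError("spacing larger than the cylinder; body would be empty")
    n_xy = int(np.floor(radius / spacing))
    ax = np.arange(-n_xy, n_xy + 1) * spacing
    # z planes at +-(k + 1/2) * spacing: symmetric under z -> -z and the
    # occupied slab thickness matches `height` instead of overshooting by
    # one plane
    n_z = int(np.floor(height / (2.0 * spacing) + 0.5))
    az = (np.arange(-n_z, n_z) + 0.5) * spacing
    X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    keep = (pts[:, 0] ** 2 + pts[:, 1] ** 2 <= radius ** 2) \
        & (np.abs(pts[:, 2]) <= height / 2.0)
    return _bead_structure(pts[keep], n_e, v_vdw, "make_toy_protein")


def make_tetramer_standin(half_width: float = 27.0, corner_radius: float = 12.0,
                          tm_height: float = 34.0, total_height: float = 56.0,
                          cap_radius: float = 24.0, spacing: float = 2.5, *,
                          n_e: float = 7.8, v_vdw: float = 16.0) -> Structure:
    """SYNTHETIC stand-in for an aquaporin-like membrane-protein tetramer.

    This is *not* a real structure: it is a desk-scale geometric surrogate
    (a rounded-square prism for the transmembrane region, capped by
    narrower cylindrical extramembrane domains) with overall dimensions
    fixed once from published aquaporin tetramer geometry (~60 A wide,
    ~34 A hydrophobic belt, ~56 A tall).  Bead spacing 2.5 A approximates
    protein heavy-atom packing density.  Intended for exercising corona
    construction and clash removal when the deposited structure is not
    available; conclusions drawn from it are qualitative.
    """
    half_z = total_height / 2.0
    n_xy = int(np.floor((half_width + 1) / spacing))
    n_z = int(np.floor(half_z / spacing))
    ax = np.arange(-n_xy, n_xy + 1) * spacing
    az = np.arange(-n_z, n_z + 1) * spacing
    X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    x, y, z = np.abs(pts[:, 0]), np.abs(pts[:, 1]), np.abs(pts[:, 2])
    inner = half_width - corner_radius
    dx = np.maximum(x - inner, 0.0)
    dy = np.maximum(y - inner, 0.0)
    in_square = (x <= half_width) & (y <= half_width) \
        & (dx ** 2 + dy ** 2 <= corner_radius ** 2)
    tm = in_square & (z <= tm_height / 2.0)
    cap = (pts[:, 0] ** 2 + pts[:, 1] ** 2 <= cap_radius ** 2) \
        & (z > tm_height / 2.0) & (z <= half_z)
    return _bead_structure(pts[tm | cap], n_e, v_vdw, "make_tetramer_standin")


def simulate_experiment(s: Structure, params: CoronaParams, dens: DensitySpec,
                        q: np.ndarray, noise: NoiseModel, *,
                        tail_spec=TAIL_SPEC, head_spec=HEAD_SPEC,
                        hydration_thickness: float = 3.0,
                        clash_base: float = 1.8) -> ScatteringCurve:
    """Noisy synthetic experimental curve from known corona parameters.

    The noiseless truth is build_corona -> Debye sum (with a hydration
    shell when dens.drho_hyd > 0, and alpha = dens.alpha); then
    sigma_i = max(relative_sd * I_i, floor) and I_exp = I + N(0, sigma_i)
    drawn with the stated seed.
    """
    model = build_corona(s, params, dens, tail_spec, head_spec,
                         clash_base=clash_base)
    particles = particles_from_model(s, model)
    if dens.drho_hyd > 0 and hydration_thickness > 0:
        particles = add_hydration_shell(particles, hydration_thickness,
                                        dens.drho_hyd)
    truth = debye_curve(particles, q, alpha=dens.alpha, rho0=dens.rho0,
                        drho_hyd=dens.drho_hyd)
    if not np.any(truth.i):
        raise ValueError("model scattering is identically zero")
    sigma = np.maximum(noise.relative_sd * truth.i, noise.floor)
    rng = np.random.default_rng(noise.seed)
    i_exp = truth.i + rng.normal(0.0, 1.0, size=len(truth)) * sigma
    return ScatteringCurve(q, i_exp, sigma)
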