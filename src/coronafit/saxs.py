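"""Debye-sum SAXS engine with excluded-volume and hydration-layer terms.

Each particle (protein atomic group or corona pseudo-atom) scatters with
an effective amplitude

    f_eff(q) = f_grp(q) - alpha * rho0 * V_vdW * exp(-q^2 V_vdW^(2/3) / (4 pi))

where the Gaussian-sphere term is the solvent displaced by the group and
``alpha`` is a global excluded-volume factor close to 1.  Protein groups
use tabulated atomic form factors with implicit hydrogens folded in;
corona pseudo-atoms are point-like (f_grp = n_e); hydration-shell dummy
waters carry drho_hyd * 30 A^3 of contrast.  The orientationally
averaged intensity is the Debye double sum, evaluated through
species-resolved pair-distance histograms so that amplitude changes
(alpha, drho_hyd scans) do not repeat the O(N^2) distance work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _pairhist
from .corona import CoronaModel, PseudoAtomSpec
from .formfactors import ATOMIC_NUMBER, CROMER_MANN, group_form_factor

__all__ = [
    "ScatteringCurve",
    "FitScore",
    "EngineSettings",
    "Species",
    "ParticleSystem",
    "particles_from_model",
    "effective_amplitude",
    "add_hydration_shell",
    "hydration_shell_positions",
    "DebyeEvaluator",
    "debye_curve",
    "fit_scale_chi",
    "harmonics_order",
    "read_curve",
    "write_curve",
    "EXTERNAL_ENGINE_MAX_L",
    "WATER_BEAD_VOLUME",
]

#: highest spherical-harmonics order accepted by CRYSOL-compatible engines
EXTERNAL_ENGINE_MAX_L = 99

#: volume of a hydration-shell dummy water, A^3
WATER_BEAD_VOLUME = 30.0


# ---------------------------------------------------------------------------
# curves

@dataclass
class ScatteringCurve:
    """(Q, I, sigma) triples; sigma may be absent for calculated curves."""

    q: np.ndarray
    i: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.i.shape:
            raise ValueError("Q and I must be 1-D arrays of equal length")
        if np.any(self.q < 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("Q must be non-negative and strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match the Q grid")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive wherever present")

    def __len__(self) -> int:
        return len(self.q)


def read_curve(path: str | Path, *, q_unit: str = "A") -> ScatteringCurve:
    """Read a 3-column ASCII curve (Q, I, sigma); '#' starts a comment.

    ``q_unit="nm"`` converts nm^-1 input to A^-1.  A 2-column file yields
    a curve without errors.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            continue
        rows.append([float(x) for x in parts[:3]])
    if not rows:
        raise ValueError(f"no data rows in {path}")
    n_col = min(len(r) for r in rows)
    arr = np.array([r[:n_col] for r in rows], dtype=float)
    q = arr[:, 0] / (10.0 if q_unit == "nm" else 1.0)
    sigma = arr[:, 2] if n_col >= 3 else None
    return ScatteringCurve(q, arr[:, 1], sigma)


def write_curve(curve: ScatteringCurve, path: str | Path,
                header: str = "") -> None:
    lines = [f"# {h}" for h in header.splitlines() if h]
    lines.append("# Q (1/A)    I    sigma")
    for k in range(len(curve)):
        s = "" if curve.sigma is None else f" {curve.sigma[k]:.8e}"
        lines.append(f"{curve.q[k]:.6f} {curve.i[k]:.8e}{s}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class FitScore:
    chi: float
    c: float  # scale applied to the calculated curve


@dataclass(frozen=True)
class EngineSettings:
    qmax: float = 0.5     # 1/A
    dmax: float = 120.0   # A, maximum complex diameter (user input)
    l_hint: int | None = None  # spherical-harmonics order for external engines
    r_bin: float = 0.1    # A, pair-distance histogram bin width

    def __post_init__(self):
        if self.qmax <= 0 or self.dmax <= 0 or self.r_bin <= 0:
            raise ValueError("qmax, dmax and r_bin must be positive")
        if self.l_hint is not None and self.l_hint < 5:
            raise ValueError("L must be at least 5")


def harmonics_order(qmax: float, dmax: float,
                    cap: int = EXTERNAL_ENGINE_MAX_L) -> int:
    """Spherical-harmonics order for an external engine: ceil(5 + Qmax*Dmax/2)."""
    if qmax < 0 or dmax <= 0:
        raise ValueError("need qmax >= 0 and dmax > 0")
    return min(cap, math.ceil(5.0 + qmax * dmax / 2.0))


# ---------------------------------------------------------------------------
# particles

@dataclass(frozen=True)
class Species:
    """A scattering species: all particles sharing one amplitude model."""

    label: str
    kind: str          # "atom" | "point" | "water"
    n_e: float = 0.0
    v_vdw: float = 0.0
    element: str = ""
    n_h: int = 0

    def damping(self, q: np.ndarray) -> np.ndarray:
        """Gaussian-sphere form factor of the group volume."""
        q = np.asarray(q, dtype=float)
        return np.exp(-q * q * self.v_vdw ** (2 / 3) / (4.0 * np.pi))

    def amplitude(self, q: np.ndarray, alpha: float = 1.0,
                  rho0: float = 0.334, drho_hyd: float = 0.0) -> np.ndarray:
        """Effective (solvent-subtracted) amplitude in electrons.

        Protein atomic groups: tabulated form factor minus the displaced
        Gaussian solvent sphere, f_grp(q) - alpha rho0 V_vdW g(q).
        Point-like pseudo-atoms stand for a uniform density cell, so
        their *net* contrast is damped: (n_e - alpha rho0 V_vdW) g(q).
        Hydration dummy waters carry drho_hyd * 30 A^3 of contrast.
        """
        q = np.asarray(q, dtype=float)
        if self.kind == "atom":
            return (group_form_factor(self.element, self.n_h, q)
                    - alpha * rho0 * self.v_vdw * self.damping(q))
        if self.kind == "point":
            return (self.n_e - alpha * rho0 * self.v_vdw) * self.damping(q)
        if self.kind == "water":
            return drho_hyd * WATER_BEAD_VOLUME * self.damping(q)
        raise ValueError(f"unknown species kind {self.kind!r}")


@dataclass
class ParticleSystem:
    """Coordinates plus a per-particle species index."""

    coords: np.ndarray          # (N, 3)
    species_index: np.ndarray   # (N,) int32
    species: tuple[Species, ...]
    default_drho_hyd: float = 0.0

    def __post_init__(self):
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        self.species_index = np.ascontiguousarray(self.species_index,
                                                  dtype=np.int32)
        if len(self.coords) != len(self.species_index):
            raise ValueError("coords and species_index length mismatch")

    def __len__(self) -> int:
        return len(self.coords)


def _structure_species(structure) -> tuple[list[Species], np.ndarray]:
    """Group structure atoms into species by (element, n_e, v_vdw)."""
    if not structure.groups_assigned():
        raise ValueError("structure atoms lack n_e / v_vdw; run "
                         "assign_scattering_groups first")
    keys: dict[tuple, int] = {}
    species: list[Species] = []
    idx = np.empty(len(structure), dtype=np.int32)
    for i in range(len(structure)):
        elem = (structure.element[i] or "").upper()
        key = (elem, round(float(structure.n_e[i]), 6),
               round(float(structure.v_vdw[i]), 6))
        if key not in keys:
            if elem in CROMER_MANN:
                n_h = int(round(structure.n_e[i] - ATOMIC_NUMBER[elem]))
                sp = Species(f"{elem}H{n_h}" if n_h else elem, "atom",
                             float(structure.n_e[i]), float(structure.v_vdw[i]),
                             elem, max(n_h, 0))
            else:
                sp = Species(f"bead:{elem or '?'}", "point",
                             float(structure.n_e[i]), float(structure.v_vdw[i]))
            keys[key] = len(species)
            species.append(sp)
        idx[i] = keys[key]
    return species, idx


def particles_from_model(structure=None, corona: CoronaModel | None = None
                         ) -> ParticleSystem:
    """Assemble the scattering particle system for protein and/or corona."""
    species: list[Species] = []
    blocks: list[tuple[np.ndarray, np.ndarray]] = []
    if structure is not None and len(structure):
        sp, idx = _structure_species(structure)
        species.extend(sp)
        blocks.append((structure.coords, idx))
    if corona is not None:
        for beads, spec in ((corona.tail_beads, corona.tail_spec),
                            (corona.head_beads, corona.head_spec)):
            if len(beads) == 0:
                continue
            species.append(Species(spec.label, "point", spec.n_e, spec.v_vdw))
            blocks.append((beads, np.full(len(beads), len(species) - 1,
                                          dtype=np.int32)))
    if not blocks:
        raise ValueError("empty particle system")
    coords = np.vstack([b[0] for b in blocks])
    idx = np.concatenate([b[1] for b in blocks])
    return ParticleSystem(coords, idx, tuple(species))


def effective_amplitude(particle, q, alpha: float = 1.0, rho0: float = 0.334,
                        drho_hyd: float = 0.0) -> np.ndarray:
    """Effective (solvent-subtracted) amplitude of one particle/species.

    Accepts a :class:`Species`, a :class:`~coronafit.corona.PseudoAtomSpec`
    or any object with ``n_e``/``v_vdw`` (and optionally ``element``).
    """
    q = np.asarray(q, dtype=float)
    if isinstance(particle, Species):
        sp = particle
    elif isinstance(particle, PseudoAtomSpec):
        sp = Species(particle.label, "point", particle.n_e, particle.v_vdw)
    else:
        elem = (getattr(particle, "element", "") or "").upper()
        n_e = float(particle.n_e)
        if elem in CROMER_MANN:
            n_h = max(int(round(n_e - ATOMIC_NUMBER[elem])), 0)
            sp = Species(elem, "atom", n_e, float(particle.v_vdw), elem, n_h)
        else:
            sp = Species("point", "point", n_e, float(particle.v_vdw))
    return sp.amplitude(q, alpha=alpha, rho0=rho0, drho_hyd=drho_hyd)


def hydration_shell_positions(coords: np.ndarray, thickness: float = 3.0,
                              grid: float = 3.0) -> np.ndarray:
    """Positions of hydration dummy beads around a particle cloud.

    The particle envelope is found on a voxel grid (half the bead grid):
    voxels holding a particle are marked occupied, interior voids are
    filled, and the Euclidean distance transform of the solvent region
    then measures distance to the envelope surface.  Shell beads are the
    solvent nodes of the ``grid``-spaced sub-lattice within ``thickness``
    of the surface, so internal cavities gain no beads.
    """
    if thickness <= 0 or len(coords) == 0:
        return np.empty((0, 3))
    from scipy import ndimage

    voxel = grid / 2.0
    pad = thickness + 2 * grid
    lo = coords.min(axis=0) - pad
    shape = np.ceil((coords.max(axis=0) + pad - lo) / voxel).astype(int) + 1
    occ = np.zeros(shape, dtype=bool)
    idx = np.floor((coords - lo) / voxel + 0.5).astype(int)
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    # particles are sparser than the voxel grid: close single-voxel pores
    # (closing does not move the outer surface), then fill enclosed voids
    occ = ndimage.binary_closing(occ, structure=np.ones((3, 3, 3), bool))
    occ = ndimage.binary_fill_holes(occ)
    dist = ndimage.distance_transform_edt(~occ, sampling=voxel)
    shell = (dist > 0) & (dist <= thickness)
    shell[::2, :, :] = False  # keep only the coarser bead sub-lattice
    shell[:, ::2, :] = False
    shell[:, :, ::2] = False
    nodes = np.argwhere(shell)
    return nodes * voxel + lo


def add_hydration_shell(system: ParticleSystem, thickness: float = 3.0,
                        drho_hyd: float = 0.0, *, grid: float = 3.0
                        ) -> ParticleSystem:
    """Append dummy-water beads covering the hydration layer.

    Beads (volume 30 A^3) sit on a ``grid``-spaced lattice at
    solvent-exposed positions within ``thickness`` of the particle
    envelope.  With ``drho_hyd = 0`` the beads carry no amplitude and
    the curve is unchanged.
    """
    if thickness < 0:
        raise ValueError("thickness must be >= 0")
    if thickness == 0 or len(system) == 0:
        return system
    shell = hydration_shell_positions(system.coords, thickness, grid)
    if len(shell) == 0:
        return system
    species = system.species + (Species("HOH-shell", "water",
                                        v_vdw=WATER_BEAD_VOLUME),)
    coords = np.vstack([system.coords, shell])
    idx = np.concatenate([system.species_index,
                          np.full(len(shell), len(species) - 1, dtype=np.int32)])
    return ParticleSystem(coords, idx, species, default_drho_hyd=drho_hyd)


# ---------------------------------------------------------------------------
# Debye evaluation

class DebyeEvaluator:
    """Histogram-backed Debye sum with cheap (alpha, drho_hyd) re-evaluation.

    Particle blocks are added one at a time; the self-histogram of a block
    (e.g. the protein, constant across a grid scan) can be supplied
    pre-computed.  ``intensity`` then assembles I(q) from species
    amplitudes in O(n_species^2 * n_q).
    """

    def __init__(self, species: Sequence[Species], q: np.ndarray, *,
                 r_bin: float = 0.1, rho0: float = 0.334,
                 r_max: float | None = None, sinc: np.ndarray | None = None):
        self.species = tuple(species)
        self.q = np.asarray(q, dtype=float)
        self.r_bin = float(r_bin)
        self.rho0 = float(rho0)
        if r_max is None and sinc is None:
            raise ValueError("provide r_max (or a precomputed sinc table)")
        if sinc is not None:
            self.n_bins = sinc.shape[0]
            self._sinc = sinc
        else:
            self.n_bins = int(np.ceil(r_max / self.r_bin)) + 2
            self._sinc = sinc_table(self.q, self.r_bin, self.n_bins)
        n_sp = len(self.species)
        self.hist = np.zeros((n_sp, n_sp, self.n_bins))
        self.counts = np.zeros(n_sp)
        self._blocks: list[tuple[np.ndarray, np.ndarray]] = []
        self._t_sym: np.ndarray | None = None

    def add_block(self, coords: np.ndarray, species_index: np.ndarray,
                  self_hist: np.ndarray | None = None) -> np.ndarray:
        """Add particles; returns the block's self-histogram (reusable)."""
        coords = np.ascontiguousarray(coords, dtype=np.float64)
        species_index = np.ascontiguousarray(species_index, dtype=np.int32)
        n_sp = len(self.species)
        inv_dr = 1.0 / self.r_bin
        if self_hist is None:
            self_hist = _pairhist.pair_hist_self(coords, species_index, n_sp,
                                                 inv_dr, self.n_bins)
        self.hist += self_hist
        for prev_coords, prev_idx in self._blocks:
            self.hist += _pairhist.pair_hist_cross(
                prev_coords, prev_idx, coords, species_index,
                n_sp, inv_dr, self.n_bins)
        self._blocks.append((coords, species_index))
        np.add.at(self.counts, species_index, 1.0)
        self._t_sym = None
        return self_hist

    def add_system(self, system: ParticleSystem) -> None:
        self.add_block(system.coords, system.species_index)

    def _amplitudes(self, alpha: float, drho_hyd: float) -> np.ndarray:
        f = np.empty((len(self.species), len(self.q)))
        for k, sp in enumerate(self.species):
            f[k] = sp.amplitude(self.q, alpha=alpha, rho0=self.rho0,
                                drho_hyd=drho_hyd)
        return f

    def intensity(self, alpha: float = 1.0, drho_hyd: float = 0.0) -> np.ndarray:
        if self._t_sym is None:
            h_sym = self.hist + self.hist.transpose(1, 0, 2)
            self._t_sym = h_sym @ self._sinc  # (n_sp, n_sp, n_q)
        f = self._amplitudes(alpha, drho_hyd)
        i_q = np.einsum("aq,bq,abq->q", f, f, self._t_sym)
        i_q += self.counts @ (f * f)
        return i_q


def sinc_table(q: np.ndarray, r_bin: float, n_bins: int) -> np.ndarray:
    """sin(q r)/(q r) at bin centres r_k = (k + 1/2) r_bin; shape (bins, nq)."""
    r = (np.arange(n_bins) + 0.5) * r_bin
    x = np.outer(r, np.asarray(q, dtype=float))
    return np.sinc(x / np.pi)


def debye_curve(particles: ParticleSystem, q: np.ndarray,
                settings: EngineSettings | None = None, *,
                alpha: float = 1.0, rho0: float = 0.334,
                drho_hyd: float | None = None) -> ScatteringCurve:
    """Debye-sum intensity of a particle system on the given Q grid."""
    if len(particles) == 0:
        raise ValueError("empty particle set")
    q = np.asarray(q, dtype=float)
    r_bin = settings.r_bin if settings is not None else 0.1
    span = particles.coords.max(axis=0) - particles.coords.min(axis=0)
    r_max = float(np.linalg.norm(span)) + r_bin
    ev = DebyeEvaluator(particles.species, q, r_bin=r_bin, rho0=rho0,
                        r_max=r_max)
    ev.add_system(particles)
    if drho_hyd is None:
        drho_hyd = particles.default_drho_hyd
    return ScatteringCurve(q, ev.intensity(alpha=alpha, drho_hyd=drho_hyd))


# ---------------------------------------------------------------------------
# scoring

def fit_scale_chi(exp: ScatteringCurve, calc: ScatteringCurve | np.ndarray
                  ) -> FitScore:
    """Error-weighted agreement factor after optimal scaling.

    c = argmin_c sum ((I_exp - c I_calc) / sigma)^2  (closed form), then
    chi = sqrt( sum ((I_exp - c I_calc) / sigma)^2 / (N - 1) ).
    """
    if exp.sigma is None:
        raise ValueError("experimental curve needs per-point sigma")
    if len(exp) < 2:
        raise ValueError("need at least 2 points")
    if isinstance(calc, ScatteringCurve):
        if len(calc) == len(exp) and np.allclose(calc.q, exp.q):
            i_calc = calc.i
        else:
            if exp.q[0] < calc.q[0] - 1e-12 or exp.q[-1] > calc.q[-1] + 1e-12:
                raise ValueError("experimental Q grid outside calculated range")
            i_calc = np.interp(exp.q, calc.q, calc.i)
    else:
        i_calc = np.asarray(calc, dtype=float)
        if i_calc.shape != exp.q.shape:
            raise ValueError("calculated intensities do not match the Q grid")
    w = 1.0 / exp.sigma ** 2
    denom = float(np.sum(w * i_calc * i_calc))
    if denom == 0:
        raise ValueError("calculated curve is identically zero")
    c = float(np.sum(w * exp.i * i_calc)) / denom
    resid = (exp.i - c * i_calc) / exp.sigma
    chi = math.sqrt(float(np.sum(resid * resid)) / (len(exp) - 1))
    return FitScore(chi=chi, c=c)
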