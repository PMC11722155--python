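"""Generalized Born radii, energy decomposition and surface potentials.

The effective Born radius R_i of atom i is the radius of the isolated Born
sphere that reproduces the atom's self-solvation energy inside the molecular
surface.  It is computed here from the R6 discretized surface integral over
the solvent-excluded surface:

    R_i^-3 = (1/4π) Σ_k A_k ((c_k − x_i)·n̂_k) / |c_k − x_i|^6

with surface patches (point c_k, outward normal n̂_k, area A_k).  For a
sphere of radius R with the atom at its center the sum reduces exactly to
R^-3, so the estimator is sphere-exact up to mesh discretization.

Energies use the standard GB pair function

    f_GB(d, R_i, R_j) = sqrt(d² + R_i R_j exp(−d²/(4 R_i R_j)))

which interpolates between the Born limit f(0) = sqrt(R_i R_j) and the
Coulomb limit f → d.  The total electrostatic free energy splits into the
in-solute Coulomb term, the Born desolvation (self) term, the cross
(pairwise) solvation term, and a hydrophobic term proportional to the
solvent-accessible area through a uniform surface tension γ.  Salt enters
through Debye screening of the solvation terms, exp(−κ f_GB)/ε_out.

Energies are in kJ/mol, potentials in kJ/(mol·e), lengths in Å, charges
in e.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import AlignmentError, ConfigurationError, GeometryError
from .io_structures import MolecularEntity
from .surface import PatchSet, SasResult

logger = logging.getLogger(__name__)

#: Coulomb constant in kJ·Å/(mol·e²).
COULOMB_CONSTANT = 1389.35

_MIN_SEPARATION = 1e-6


@dataclass(frozen=True)
class SolventModel:
    """Continuum solvent parameters.

    eps_in/eps_out are the solute and solvent dielectric constants, kappa the
    inverse Debye length in Å⁻¹ (0 = no salt), gamma the uniform surface
    tension in kJ/(mol·Å²), and test_charge_radius the Born radius assigned
    to the probe charge used when evaluating the potential at a surface
    point.
    """

    eps_in: float = 1.0
    eps_out: float = 78.54
    kappa: float = 0.0
    gamma: float = 0.021
    test_charge_radius: float = 1.4
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self) -> None:
        if not (self.eps_out > self.eps_in >= 1.0):
            raise ConfigurationError("require eps_out > eps_in >= 1")
        if self.kappa < 0 or self.gamma < 0:
            raise ConfigurationError("kappa and gamma must be >= 0")
        if self.test_charge_radius <= 0:
            raise ConfigurationError("test_charge_radius must be > 0")

    def tau(self, f: np.ndarray | float) -> np.ndarray | float:
        """Solvation screening factor 1/ε_in − exp(−κ f)/ε_out."""
        return 1.0 / self.eps_in - np.exp(-self.kappa * np.asarray(f)) / self.eps_out


@dataclass
class GBRadiusSet:
    """Effective Born radii (Å) with per-atom clamp flags."""

    radii: np.ndarray
    clamped: np.ndarray

    def __len__(self) -> int:
        return len(self.radii)


def f_gb(d, r_i, r_j):
    """Canonical GB pair function (Still form).

    Symmetric in (r_i, r_j); equals sqrt(r_i r_j) at contact and approaches
    the separation d asymptotically.
    """
    d = np.asarray(d, dtype=float)
    rr = np.asarray(r_i, dtype=float) * np.asarray(r_j, dtype=float)
    out = np.sqrt(d * d + rr * np.exp(-(d * d) / (4.0 * rr)))
    return float(out) if out.ndim == 0 else out


def compute_gb_radii(
    patches: PatchSet,
    entity: MolecularEntity,
    cutoff: float | None = None,
    clamp_factor: float = 0.5,
    scale: float = 1.0,
) -> GBRadiusSet:
    """Effective Born radii from the discretized R6 surface integral.

    By default the entire closed surface is integrated for every atom; an
    optional ``cutoff`` restricts the integral to patches within that
    distance of the atom.  Non-positive or unphysically small integrals
    (radius below ``clamp_factor`` times the vdW radius) are clamped to the
    floor and flagged.  ``scale`` is a hook for empirical rescaling of the
    radii (1.0 = none).
    """
    pos = entity.positions
    vdw = entity.radii
    n = entity.n_atoms
    pts = patches.points
    nrm = patches.normals
    areas = patches.areas

    inv_r3 = np.empty(n)
    chunk = max(1, int(4e6 // max(1, len(pts))))
    for s in range(0, n, chunk):
        block = pos[s : s + chunk]                       # (B, 3)
        diff = pts[None, :, :] - block[:, None, :]       # (B, K, 3)
        r2 = np.einsum("bkj,bkj->bk", diff, diff)
        if np.any(r2 < _MIN_SEPARATION**2):
            raise GeometryError("surface patch coincides with an atom center")
        dot = np.einsum("bkj,kj->bk", diff, nrm)
        w = areas[None, :] * dot / (r2 * r2 * r2)
        if cutoff is not None:
            w = np.where(r2 <= cutoff * cutoff, w, 0.0)
        inv_r3[s : s + chunk] = w.sum(axis=1) / (4.0 * np.pi)

    floor = clamp_factor * vdw
    radii = np.empty(n)
    positive = inv_r3 > 0
    radii[positive] = inv_r3[positive] ** (-1.0 / 3.0) * scale
    radii[~positive] = floor[~positive]
    clamped = ~positive | (radii < floor)
    radii = np.where(radii < floor, floor, radii)
    if clamped.any():
        logger.warning("clamped %d GB radii to %.2g x vdW radius", int(clamped.sum()), clamp_factor)
    return GBRadiusSet(radii=radii, clamped=clamped)


@dataclass
class EnergyReport:
    """Electrostatic + hydrophobic free energy decomposition (kJ/mol).

    ``per_atom`` assigns self terms wholly to their atom and splits every
    pair term half/half, so it sums to coulomb + gb_self + gb_cross.
    The ``sasa_term`` is γ × total SASA and has no per-atom split here.
    """

    coulomb: float
    gb_self: float
    gb_cross: float
    sasa_term: float
    per_atom: np.ndarray
    model: SolventModel
    label: str = ""

    @property
    def total(self) -> float:
        return self.coulomb + self.gb_self + self.gb_cross + self.sasa_term

    @property
    def solvation(self) -> float:
        return self.gb_self + self.gb_cross + self.sasa_term


def energy_report(
    entity: MolecularEntity,
    radii: GBRadiusSet,
    sas: SasResult,
    model: SolventModel,
) -> EnergyReport:
    """All energy components for one entity.

    coulomb  = (k_e/ε_in) Σ_{i<j} q_i q_j / d_ij
    gb_self  = −(k_e/2) Σ_i τ(R_i) q_i² / R_i
    gb_cross = −k_e Σ_{i<j} q_i q_j τ(f_ij) / f_ij ,  f_ij = f_GB(d_ij, R_i, R_j)
    sasa     = γ × SASA_total
    """
    n = entity.n_atoms
    if len(radii) != n:
        raise AlignmentError("GB radii not aligned with atoms")
    if len(sas.per_atom_area) != n:
        raise AlignmentError("SAS areas not aligned with atoms")
    ke = model.coulomb_constant
    q = entity.charges
    pos = entity.positions
    R = radii.radii

    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    off = ~np.eye(n, dtype=bool)
    if n > 1 and d[off].min() < _MIN_SEPARATION:
        raise GeometryError("two distinct atoms coincide")

    qq = np.outer(q, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        coul_m = np.where(off, ke / model.eps_in * qq / np.where(off, d, 1.0), 0.0)
    f = f_gb(d, R[:, None], R[None, :])
    tau = model.tau(f)
    cross_m = np.where(off, -ke * qq * tau / f, 0.0)

    self_terms = -0.5 * ke * np.asarray(model.tau(R)) * q * q / R

    coulomb = 0.5 * float(coul_m.sum())
    gb_cross = 0.5 * float(cross_m.sum())
    gb_self = float(self_terms.sum())
    sasa_term = model.gamma * sas.total_area
    per_atom = self_terms + 0.5 * coul_m.sum(axis=1) + 0.5 * cross_m.sum(axis=1)
    return EnergyReport(
        coulomb=coulomb,
        gb_self=gb_self,
        gb_cross=gb_cross,
        sasa_term=sasa_term,
        per_atom=per_atom,
        model=model,
        label=entity.label,
    )


def energy_difference(
    cplx: EnergyReport, mol1: EnergyReport, mol2: EnergyReport
) -> EnergyReport:
    """Component-wise binding decomposition: complex − (mol1 + mol2).

    Per-atom differences align by atom identity (mol1 atoms first, matching
    the complex ordering produced by the pipeline).
    """
    if not (cplx.model == mol1.model == mol2.model):
        raise ConfigurationError("energy reports come from different solvent models")
    parts = np.concatenate([mol1.per_atom, mol2.per_atom])
    if parts.shape != cplx.per_atom.shape:
        raise AlignmentError("per-atom arrays of complex and parts do not align")
    return EnergyReport(
        coulomb=cplx.coulomb - mol1.coulomb - mol2.coulomb,
        gb_self=cplx.gb_self - mol1.gb_self - mol2.gb_self,
        gb_cross=cplx.gb_cross - mol1.gb_cross - mol2.gb_cross,
        sasa_term=cplx.sasa_term - mol1.sasa_term - mol2.sasa_term,
        per_atom=cplx.per_atom - parts,
        model=cplx.model,
        label="diff",
    )


def surface_potential(
    patches: PatchSet,
    source_entity: MolecularEntity,
    radii: GBRadiusSet,
    model: SolventModel,
) -> np.ndarray:
    """GB electrostatic potential at each surface patch, kJ/(mol·e).

    The potential is that felt by a probe charge of Born radius
    ``model.test_charge_radius`` placed at the surface point:

        φ(c_k) = k_e Σ_i q_i [ 1/(ε_in d_ik) − τ(f_ik)/f_ik ]

    with f_ik = f_GB(d_ik, R_i, R_t).  The result is also stored on
    ``patches.potential``.
    """
    if len(radii) != source_entity.n_atoms:
        raise AlignmentError("GB radii not aligned with source atoms")
    ke = model.coulomb_constant
    q = source_entity.charges
    pos = source_entity.positions
    R = radii.radii
    rt = model.test_charge_radius

    phi = np.empty(len(patches))
    chunk = max(1, int(4e6 // max(1, source_entity.n_atoms)))
    for s in range(0, len(patches), chunk):
        block = patches.points[s : s + chunk]
        diff = block[:, None, :] - pos[None, :, :]
        d = np.sqrt(np.einsum("kij,kij->ki", diff, diff))
        if d.min() < _MIN_SEPARATION:
            raise GeometryError("surface point coincides with an atom center")
        f = f_gb(d, R[None, :], rt)
        tau = model.tau(f)
        phi[s : s + chunk] = ke * (q[None, :] / (model.eps_in * d) - q[None, :] * tau / f).sum(axis=1)
    patches.potential = phi
    return phi


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def format_energy_value(v: float) -> str:
    return f"{v:.6g}"


def write_nrg(
    report: EnergyReport,
    path: str | Path,
    entity: MolecularEntity | None = None,
    atom_indices: Sequence[int] | None = None,
) -> None:
    """Write a .nrg energy file: component lines, then per-atom lines.

    Per-atom contributions are listed for ``atom_indices`` (typically the
    interface atoms); each line carries the atom identity and its share of
    the electrostatic energy.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# free energy components (kJ/mol) for {report.label}\n")
        fh.write(f"coulomb {format_energy_value(report.coulomb)}\n")
        fh.write(f"gb_self {format_energy_value(report.gb_self)}\n")
        fh.write(f"gb_cross {format_energy_value(report.gb_cross)}\n")
        fh.write(f"sasa_term {format_energy_value(report.sasa_term)}\n")
        fh.write(f"total {format_energy_value(report.total)}\n")
        if entity is not None and atom_indices is not None:
            fh.write("# per-atom electrostatic contributions (kJ/mol)\n")
            for i in atom_indices:
                a = entity.atoms[i]
                fh.write(
                    f"ATOM {a.serial:5d} {a.name:<4s} {a.residue_name:<4s} "
                    f"{a.chain_id:1s} {a.residue_number:4d} "
                    f"{format_energy_value(report.per_atom[i])}\n"
                )


def write_gbr(entity: MolecularEntity, radii: GBRadiusSet, path: str | Path) -> None:
    """Write a .gbr file: serial, atom name and GB radius per line."""
    if len(radii) != entity.n_atoms:
        raise AlignmentError("GB radii not aligned with atoms")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# serial name gb_radius(A)\n")
        for a, r in zip(entity.atoms, radii.radii):
            fh.write(f"{a.serial:5d} {a.name:<4s} {r:8.4f}\n")
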