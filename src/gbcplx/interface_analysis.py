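"""Interface extraction and electrostatic complementarity statistics.

Two notions of contact are used, both governed by the same short cutoff δ
(default 1 Å): atom pairs whose van der Waals surfaces are closer than δ
(d₁₂ < r₁ + r₂ + δ), and surface-point pairs from the two isolated-molecule
surfaces closer than δ in the complex frame.  Note the convention: the
surface of each molecular entity is computed in the absence of the other, so
the potentials paired here are those of the free partners.

Electrostatic complementarity (ec) is the sign-changed Pearson correlation
over all such value pairs; the concordant fraction is the fraction of pairs
whose two values share a sign (an exactly zero product counts as
non-concordant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, StateError
from .io_structures import MolecularEntity
from .surface import PatchSet, SasResult

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 1.0


@dataclass(frozen=True)
class AtomContactPair:
    """A cross-entity atom pair in vdW-surface contact."""

    index1: int
    index2: int
    q1: float
    q2: float
    gap: float  # d12 - r1 - r2, Å


@dataclass(frozen=True)
class SurfacePotentialPair:
    """A cross-entity surface-point pair with the two free-molecule potentials."""

    index1: int
    index2: int
    phi1: float
    phi2: float
    distance: float


@dataclass
class ComplementarityResult:
    """Pearson statistics over paired values.

    ``ec`` is −pearson_r (positive for complementary, i.e. anticorrelated,
    patterns); ``sum_products`` is Σ v1·v2; ``concordant_fraction`` the
    same-sign fraction.  When the correlation is undefined (fewer than three
    pairs, or zero variance on either side) ``defined`` is False and
    pearson_r/ec are NaN while the other statistics are still computed.
    """

    pearson_r: float
    ec: float
    sum_products: float
    n_pairs: int
    concordant_fraction: float
    defined: bool = True


def atom_contact_pairs(
    mol1: MolecularEntity,
    mol2: MolecularEntity,
    delta: float = DEFAULT_CONTACT_CUTOFF,
) -> list[AtomContactPair]:
    """All cross-entity atom pairs with d₁₂ < r₁ + r₂ + δ.

    KD-tree accelerated but set-identical to the brute-force double loop.
    """
    if mol1.n_atoms == 0 or mol2.n_atoms == 0:
        return []
    p1, p2 = mol1.positions, mol2.positions
    r1, r2 = mol1.radii, mol2.radii
    q1, q2 = mol1.charges, mol2.charges
    rmax = float(r1.max() + r2.max()) + delta
    t1, t2 = cKDTree(p1), cKDTree(p2)
    pairs: list[AtomContactPair] = []
    for i, js in enumerate(t1.query_ball_tree(t2, rmax)):
        if not js:
            continue
        js = np.sort(js)
        d = np.linalg.norm(p2[js] - p1[i], axis=1)
        cut = r1[i] + r2[js] + delta
        for j, dij, ok in zip(js, d, d < cut):
            if ok:
                pairs.append(
                    AtomContactPair(
                        index1=i,
                        index2=int(j),
                        q1=float(q1[i]),
                        q2=float(q2[j]),
                        gap=float(dij - r1[i] - r2[j]),
                    )
                )
    return pairs


def surface_contact_pairs(
    patches1: PatchSet,
    patches2: PatchSet,
    delta: float = DEFAULT_CONTACT_CUTOFF,
) -> list[SurfacePotentialPair]:
    """All cross pairs of surface points closer than δ (all pairs, not
    nearest-neighbor only).  Both patch sets must already carry potentials
    from their own isolated entity."""
    if patches1.potential is None or patches2.potential is None:
        raise StateError("patches lack potentials; run surface_potential first")
    if len(patches1) == 0 or len(patches2) == 0:
        return []
    t1 = cKDTree(patches1.points)
    t2 = cKDTree(patches2.points)
    pairs: list[SurfacePotentialPair] = []
    for i, js in enumerate(t1.query_ball_tree(t2, delta)):
        if not js:
            continue
        js = np.sort(js)
        d = np.linalg.norm(patches2.points[js] - patches1.points[i], axis=1)
        for j, dij in zip(js, d):
            if dij < delta:
                pairs.append(
                    SurfacePotentialPair(
                        index1=i,
                        index2=int(j),
                        phi1=float(patches1.potential[i]),
                        phi2=float(patches2.potential[j]),
                        distance=float(dij),
                    )
                )
    return pairs


def _pair_values(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, tuple) and len(pairs) == 2:
        return np.asarray(pairs[0], float), np.asarray(pairs[1], float)
    if len(pairs) and isinstance(pairs[0], AtomContactPair):
        return (
            np.array([p.q1 for p in pairs]),
            np.array([p.q2 for p in pairs]),
        )
    if len(pairs) and isinstance(pairs[0], SurfacePotentialPair):
        return (
            np.array([p.phi1 for p in pairs]),
            np.array([p.phi2 for p in pairs]),
        )
    arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    return arr[:, 0], arr[:, 1]


def complementarity(pairs) -> ComplementarityResult:
    """Pearson r, ec = −r, sum of products and concordant fraction of pairs.

    ``pairs`` may be a list of (v1, v2) tuples, a tuple of two arrays, or a
    list of AtomContactPair / SurfacePotentialPair.
    """
    v1, v2 = _pair_values(pairs)
    n = len(v1)
    if n == 0:
        return ComplementarityResult(np.nan, np.nan, 0.0, 0, 0.0, defined=False)
    if not (np.all(np.isfinite(v1)) and np.all(np.isfinite(v2))):
        raise ValueError("non-finite values in pairs")
    sum_products = float(v1 @ v2)
    concordant = float(np.mean(v1 * v2 > 0))
    if n < 3 or v1.std() == 0 or v2.std() == 0:
        return ComplementarityResult(np.nan, np.nan, sum_products, n, concordant, defined=False)
    r = float(np.corrcoef(v1, v2)[0, 1])
    return ComplementarityResult(r, -r, sum_products, n, concordant, defined=True)


def buried_sasa(sas1: SasResult, sas2: SasResult, sas_cplx: SasResult) -> float:
    """Interface size: SASA(mol1) + SASA(mol2) − SASA(complex), Å²."""
    probes = {sas1.probe_radius, sas2.probe_radius, sas_cplx.probe_radius}
    points = {sas1.n_sphere_points, sas2.n_sphere_points, sas_cplx.n_sphere_points}
    if len(probes) != 1 or len(points) != 1:
        raise ConfigurationError("SAS results use different probe radii or sampling")
    return sas1.total_area + sas2.total_area - sas_cplx.total_area


def interface_atoms(pairs: Sequence[AtomContactPair]) -> tuple[list[int], list[int]]:
    """Sorted unique atom indices of each entity appearing in contact pairs."""
    s1 = sorted({p.index1 for p in pairs})
    s2 = sorted({p.index2 for p in pairs})
    return s1, s2


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    return f"{v:.6g}"


def write_crg_pair(
    pairs: Sequence[AtomContactPair],
    mol1: MolecularEntity,
    mol2: MolecularEntity,
    result: ComplementarityResult,
    path: str | Path,
) -> None:
    """Write the contacting-atom charge pairs with Pearson footer lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# atom1_serial name chain q1(e) atom2_serial name chain q2(e) gap(A)\n")
        for p in pairs:
            a1 = mol1.atoms[p.index1]
            a2 = mol2.atoms[p.index2]
            fh.write(
                f"{a1.serial:5d} {a1.name:<4s} {a1.chain_id:1s} {p.q1:8.4f} "
                f"{a2.serial:5d} {a2.name:<4s} {a2.chain_id:1s} {p.q2:8.4f} "
                f"{p.gap:7.3f}\n"
            )
        r_txt = _fmt(result.pearson_r) if result.defined else "nan"
        fh.write(f"Pearson correlation coefficient {r_txt}\n")
        fh.write(f"Sum of charge-charge products {_fmt(result.sum_products)}\n")


def write_srf_pot_pair(
    pairs: Sequence[SurfacePotentialPair],
    patches1: PatchSet,
    patches2: PatchSet,
    mol1: MolecularEntity,
    mol2: MolecularEntity,
    result: ComplementarityResult,
    path: str | Path,
) -> None:
    """Write contacting surface-point potential pairs with Pearson footer."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "# x1 y1 z1 phi1(kJ/mol/e) owner1 x2 y2 z2 phi2(kJ/mol/e) owner2 distance(A)\n"
        )
        for p in pairs:
            c1 = patches1.points[p.index1]
            c2 = patches2.points[p.index2]
            o1 = mol1.atoms[int(patches1.owner_atom[p.index1])].serial
            o2 = mol2.atoms[int(patches2.owner_atom[p.index2])].serial
            fh.write(
                f"{c1[0]:9.3f} {c1[1]:9.3f} {c1[2]:9.3f} {p.phi1:10.4f} {o1:5d} "
                f"{c2[0]:9.3f} {c2[1]:9.3f} {c2[2]:9.3f} {p.phi2:10.4f} {o2:5d} "
                f"{p.distance:6.3f}\n"
            )
        r_txt = _fmt(result.pearson_r) if result.defined else "nan"
        fh.write(f"Pearson correlation coefficient {r_txt}\n")
        fh.write(f"Sum of potential products {_fmt(result.sum_products)}\n")


def write_srf(
    patches: PatchSet,
    indices: Sequence[int],
    entity: MolecularEntity,
    path: str | Path,
) -> None:
    """Write contacting surface points as PDB records, potential in the
    temperature-factor field (kJ/(mol·e)), clamped to the field width."""
    path = Path(path)
    if patches.potential is None:
        raise StateError("patches lack potentials")
    n_clamped = 0
    with path.open("w") as fh:
        for n, k in enumerate(indices, start=1):
            c = patches.points[k]
            phi = float(patches.potential[k])
            if abs(phi) >= 1000.0:
                n_clamped += 1
            if abs(phi) > 999.9:  # keep the printed value inside the 6-char field
                phi = float(np.sign(phi)) * 999.9
            owner = entity.atoms[int(patches.owner_atom[k])]
            fh.write(
                f"ATOM  {n % 100000:5d}  SP  SRF {owner.chain_id:1s}{n % 10000:4d}    "
                f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}{1.00:6.2f}{phi:6.1f}\n"
            )
        fh.write("END\n")
    if n_clamped:
        logger.warning("%s: %d potentials clamped to fit the B-factor field", path, n_clamped)
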