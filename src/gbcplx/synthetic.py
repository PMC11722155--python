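"""Self-contained synthetic test systems with known analytic properties.

Three generators cover the pipeline's needs without any external structures:
a single charged sphere (whose solvation energy has the closed Born form),
a planar two-slab complex with tunable electrostatic complementarity, and a
far-separated recombination of two entities (the non-interacting limit).

The planar complex places two parallel square lattices of atoms (chains A
and B).  Chain-A charges are drawn i.i.d. Gaussian; chain-B charges are
built as −c·q_A + √(1−c²)·noise with noise of the same scale, so the
expected correlation of directly opposing charge pairs is −c.  With the
default geometry (atom radius 1.7 Å, lattice spacing 3.5 Å, gap 3.9 Å) each
slab's solvent-excluded surface is a single connected component, facing
surfaces sit about 0.5 Å apart (inside the 1 Å contact cutoff), and only
directly opposing atoms form vdW contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_structures import AtomRecord, MolecularEntity, merge_entities


@dataclass(frozen=True)
class ToyComplexSpec:
    """Parameters of the planar two-slab toy complex.

    ``complementarity_level`` c in [−1, 1] sets the expected charge-pair
    correlation across the interface to −c.
    """

    n_atoms_per_side: int = 16
    lattice_spacing: float = 3.5
    gap: float = 3.9
    charge_amplitude: float = 0.5
    complementarity_level: float = 0.0
    seed: int = 0
    atom_radius: float = 1.7

    def __post_init__(self) -> None:
        if self.gap <= 0:
            raise ValueError("gap must be > 0")
        if abs(self.complementarity_level) > 1:
            raise ValueError("complementarity_level must be in [-1, 1]")


def make_sphere(q: float = 1.0, r: float = 2.0) -> MolecularEntity:
    """A single charged sphere at the origin (the analytic Born system)."""
    if r <= 0:
        raise ValueError("radius must be > 0")
    atom = AtomRecord(
        serial=1,
        name="X",
        residue_name="SPH",
        chain_id="A",
        residue_number=1,
        position=(0.0, 0.0, 0.0),
        charge=q,
        vdw_radius=r,
    )
    return MolecularEntity([atom], label="complex")


def _lattice_xy(n: int, spacing: float) -> np.ndarray:
    side = int(round(np.sqrt(n)))
    if side * side != n:
        raise ValueError("n_atoms_per_side must be a perfect square")
    coords = (np.arange(side) - (side - 1) / 2.0) * spacing
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()])


def make_planar_complex(spec: ToyComplexSpec) -> MolecularEntity:
    """Two parallel charged lattices (chains A and B) separated by ``gap``.

    Deterministic given ``spec.seed``; the atom order is chain A then chain
    B, opposing atoms sharing the lattice index.
    """
    rng = np.random.default_rng(spec.seed)
    xy = _lattice_xy(spec.n_atoms_per_side, spec.lattice_spacing)
    n = len(xy)
    c = spec.complementarity_level
    q_a = spec.charge_amplitude * rng.standard_normal(n)
    noise = spec.charge_amplitude * rng.standard_normal(n)
    q_b = -c * q_a + np.sqrt(1.0 - c * c) * noise

    atoms: list[AtomRecord] = []
    serial = 1
    for chain, z, charges in (("A", -spec.gap / 2.0, q_a), ("B", +spec.gap / 2.0, q_b)):
        for k in range(n):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name="C",
                    residue_name="TOY",
                    chain_id=chain,
                    residue_number=k + 1,
                    position=(float(xy[k, 0]), float(xy[k, 1]), float(z)),
                    charge=float(charges[k]),
                    vdw_radius=spec.atom_radius,
                )
            )
            serial += 1
    return MolecularEntity(atoms, label="complex")


def make_separated(
    entity1: MolecularEntity, entity2: MolecularEntity, distance: float
) -> MolecularEntity:
    """Recombine two entities with their centroids ``distance`` apart along x.

    Used for non-interacting-limit tests: at large separation every energy
    difference, contact list and buried area must vanish.
    """
    c1 = entity1.positions.mean(axis=0)
    c2 = entity2.positions.mean(axis=0)
    bound1 = float(np.linalg.norm(entity1.positions - c1, axis=1).max() + entity1.radii.max())
    bound2 = float(np.linalg.norm(entity2.positions - c2, axis=1).max() + entity2.radii.max())
    if distance <= bound1 + bound2:
        raise ValueError(
            f"distance {distance} must exceed the sum of bounding radii {bound1 + bound2:.1f}"
        )
    target = c1 + np.array([distance, 0.0, 0.0])
    shifted = entity2.translated(target - c2)
    return merge_entities(entity1, shifted, label="complex")
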