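"""Shared fixtures: small systems whose surfacing cost is paid once."""

from __future__ import annotations

import numpy as np
import pytest

from gbcplx.io_structures import AtomRecord, MolecularEntity
from gbcplx.gb_core import compute_gb_radii
from gbcplx.surface import compute_sas, extract_patches, triangulate_ses
from gbcplx.synthetic import ToyComplexSpec, make_planar_complex


def make_atom(serial, pos, radius, charge=0.0, chain="A", name="X", resname="SPH"):
    return AtomRecord(
        serial=serial,
        name=name,
        residue_name=resname,
        chain_id=chain,
        residue_number=serial,
        position=tuple(float(v) for v in pos),
        charge=float(charge),
        vdw_radius=float(radius),
    )


def random_entity(n, rng, box=12.0, radius_range=(1.2, 2.0), chain="A"):
    atoms = []
    for i in range(n):
        atoms.append(
            make_atom(
                i + 1,
                rng.uniform(-box / 2, box / 2, 3),
                rng.uniform(*radius_range),
                charge=rng.normal(),
                chain=chain,
            )
        )
    return MolecularEntity(atoms, label="complex")


@pytest.fixture(scope="session")
def sphere_entity():
    from gbcplx.synthetic import make_sphere

    return make_sphere(q=1.0, r=2.0)


@pytest.fixture(scope="session")
def sphere_surface(sphere_entity):
    return triangulate_ses(sphere_entity)


@pytest.fixture(scope="session")
def sphere_patches(sphere_entity, sphere_surface):
    return extract_patches(sphere_surface, sphere_entity)


@pytest.fixture(scope="session")
def sphere_gb(sphere_entity, sphere_patches):
    return compute_gb_radii(sphere_patches, sphere_entity)


@pytest.fixture(scope="session")
def two_sphere_entity():
    return MolecularEntity(
        [make_atom(1, (0, 0, 0), 2.0), make_atom(2, (2.5, 0, 0), 1.7)],
        label="complex",
    )


@pytest.fixture(scope="session")
def two_sphere_patches(two_sphere_entity):
    surf = triangulate_ses(two_sphere_entity)
    return extract_patches(surf, two_sphere_entity)


@pytest.fixture(scope="session")
def toy_spec():
    return ToyComplexSpec(complementarity_level=0.9, seed=7)


@pytest.fixture(scope="session")
def toy_complex(toy_spec):
    return make_planar_complex(toy_spec)


@pytest.fixture(scope="session")
def toy_result(toy_complex):
    from gbcplx.pipeline import RunConfig, analyze_complex

    return analyze_complex(toy_complex, RunConfig(chains1="A", chains2="B"))
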