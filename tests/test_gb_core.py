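"""GB radii, the pair function, energy decomposition and surface potentials."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbcplx.errors import AlignmentError, ConfigurationError, GeometryError
from gbcplx.gb_core import (
    COULOMB_CONSTANT,
    GBRadiusSet,
    SolventModel,
    compute_gb_radii,
    energy_difference,
    energy_report,
    f_gb,
    surface_potential,
)
from gbcplx.io_structures import MolecularEntity
from gbcplx.surface import PatchSet, SasResult, compute_sas, extract_patches, triangulate_ses

from conftest import make_atom

KE = COULOMB_CONSTANT
WATER = SolventModel(gamma=0.0)


def uniform_sas(entity, value=0.0):
    return SasResult(
        per_atom_area=np.full(entity.n_atoms, value),
        probe_radius=1.4,
        n_sphere_points=960,
    )


class TestFGb:
    def test_contact_limit(self):
        assert f_gb(0.0, 2.0, 2.0) == pytest.approx(2.0)
        assert f_gb(0.0, 1.0, 4.0) == pytest.approx(2.0)

    def test_hand_evaluated_value(self):
        assert f_gb(2.0, 1.0, 1.0) == pytest.approx(np.sqrt(4 + np.exp(-1)), rel=1e-12)

    def test_asymptote(self):
        f = f_gb(1000.0, 3.0, 1.2)
        assert 1.0 <= f / 1000.0 <= 1.0 + 1e-9

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        d=st.floats(0, 50),
        ri=st.floats(0.5, 5),
        rj=st.floats(0.5, 5),
    )
    def test_symmetric_and_bounded_below_by_separation_scale(self, d, ri, rj):
        assert f_gb(d, ri, rj) == pytest.approx(f_gb(d, rj, ri), rel=1e-12)
        assert f_gb(d, ri, rj) >= d


class TestGbRadii:
    def test_sphere_radius_within_two_percent(self, sphere_gb):
        assert sphere_gb.radii[0] == pytest.approx(2.0, rel=0.02)
        assert not sphere_gb.clamped[0]

    def test_error_strictly_decreases_over_refinement(self, sphere_entity):
        errs = []
        for h, n in ((0.8, 256), (0.5, 1024), (0.25, 4096)):
            surf = triangulate_ses(sphere_entity, grid_spacing=h, n_surface_samples=n)
            gb = compute_gb_radii(extract_patches(surf, sphere_entity), sphere_entity)
            errs.append(abs(gb.radii[0] - 2.0))
        assert errs[0] > errs[1] > errs[2]

    def test_buried_atom_radius_exceeds_vdw(self):
        # central atom enclosed by an octahedral shell: burial inflates R
        atoms = [make_atom(1, (0, 0, 0), 1.8)]
        for k, d in enumerate(
            [(3.2, 0, 0), (-3.2, 0, 0), (0, 3.2, 0), (0, -3.2, 0), (0, 0, 3.2), (0, 0, -3.2)]
        ):
            atoms.append(make_atom(k + 2, d, 1.8))
        ent = MolecularEntity(atoms)
        surf = triangulate_ses(ent)
        gb = compute_gb_radii(extract_patches(surf, ent), ent)
        assert gb.radii[0] > 1.8

    def test_two_sphere_matches_volume_integral_oracle(
        self, two_sphere_entity, two_sphere_patches
    ):
        gb = compute_gb_radii(two_sphere_patches, two_sphere_entity)
        oracle = brute_force_gb_radii(two_sphere_entity)
        np.testing.assert_allclose(gb.radii, oracle, rtol=0.03)

    def test_coincident_patch_rejected(self, sphere_entity):
        patches = PatchSet(
            points=np.zeros((1, 3)),
            normals=np.array([[0.0, 0.0, 1.0]]),
            areas=np.array([1.0]),
            owner_atom=np.array([0]),
        )
        with pytest.raises(GeometryError):
            compute_gb_radii(patches, sphere_entity)


def brute_force_gb_radii(entity, h=0.25, rp=1.4, tail_radius=10.0):
    """Independent voxel oracle: R_i^-3 = (3/4pi) \\int_solvent dV/|r-x_i|^6.

    The solvent region is every point within rp of the probe-accessible
    region; the integral beyond ``tail_radius`` (all solvent there) is the
    analytic 1/tail_radius^3.
    """
    from scipy.spatial import cKDTree

    pos, rad = entity.positions, entity.radii
    pad = tail_radius + 2.0
    lo, hi = pos.min(0) - pad, pos.max(0) + pad
    axes = [np.arange(lo[d], hi[d] + h, h) for d in range(3)]
    G = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
    f = np.min(np.linalg.norm(G[:, None, :] - pos[None], axis=2) - (rad + rp)[None], axis=1)
    acc = G[f >= 0]
    d, _ = cKDTree(acc).query(G, workers=-1)
    solvent = d <= rp
    out = np.empty(entity.n_atoms)
    for i in range(entity.n_atoms):
        ri = np.linalg.norm(G - pos[i], axis=1)
        mask = solvent & (ri <= tail_radius) & (ri > 1e-9)
        integral = (3.0 / (4.0 * np.pi)) * h**3 * np.sum(1.0 / ri[mask] ** 6)
        out[i] = (integral + 1.0 / tail_radius**3) ** (-1.0 / 3.0)
    return out


class TestEnergy:
    def test_born_self_energy_closed_form(self, sphere_entity, sphere_gb):
        sas = uniform_sas(sphere_entity)
        rep = energy_report(sphere_entity, sphere_gb, sas, WATER)
        exact = -(KE / 2.0) * (1.0 - 1.0 / 78.54) / 2.0
        assert rep.total == pytest.approx(exact, rel=0.02)
        assert rep.coulomb == 0.0
        assert rep.gb_self < 0

    def test_neutral_system_has_zero_electrostatics(self):
        ent = MolecularEntity(
            [make_atom(1, (0, 0, 0), 1.5, 0.0), make_atom(2, (3, 0, 0), 1.5, 0.0)]
        )
        gb = GBRadiusSet(radii=np.array([1.5, 1.5]), clamped=np.zeros(2, bool))
        rep = energy_report(ent, gb, uniform_sas(ent, 10.0), SolventModel(gamma=0.021))
        assert rep.coulomb == rep.gb_self == rep.gb_cross == 0.0
        assert rep.sasa_term == pytest.approx(0.021 * 20.0)
        assert rep.total == pytest.approx(rep.sasa_term)

    def test_screening_limit_far_pair(self):
        d = 1000.0
        ent = MolecularEntity(
            [make_atom(1, (0, 0, 0), 2.0, 1.0), make_atom(2, (d, 0, 0), 2.0, 1.0)]
        )
        gb = GBRadiusSet(radii=np.array([2.0, 2.0]), clamped=np.zeros(2, bool))
        rep = energy_report(ent, gb, uniform_sas(ent), WATER)
        interaction = rep.coulomb + rep.gb_cross
        assert interaction == pytest.approx(KE / (78.54 * d), rel=1e-3)

    def test_quadratic_charge_scaling(self):
        rng = np.random.default_rng(11)
        atoms = [
            make_atom(i + 1, rng.uniform(-4, 4, 3), 1.6, rng.normal()) for i in range(6)
        ]
        ent = MolecularEntity(atoms)
        gb = GBRadiusSet(radii=np.full(6, 1.9), clamped=np.zeros(6, bool))
        rep1 = energy_report(ent, gb, uniform_sas(ent), WATER)
        scaled = MolecularEntity(
            [
                make_atom(a.serial, a.position, a.vdw_radius, 3.0 * a.charge)
                for a in atoms
            ]
        )
        rep3 = energy_report(scaled, gb, uniform_sas(scaled), WATER)
        for attr in ("coulomb", "gb_self", "gb_cross"):
            assert getattr(rep3, attr) == pytest.approx(9.0 * getattr(rep1, attr), rel=1e-12)

    def test_per_atom_decomposition_sums_to_totals(self):
        rng = np.random.default_rng(5)
        atoms = [
            make_atom(i + 1, rng.uniform(-5, 5, 3), 1.5, rng.normal()) for i in range(10)
        ]
        ent = MolecularEntity(atoms)
        gb = GBRadiusSet(radii=rng.uniform(1.5, 3.0, 10), clamped=np.zeros(10, bool))
        rep = energy_report(ent, gb, uniform_sas(ent, 5.0), SolventModel())
        electro = rep.coulomb + rep.gb_self + rep.gb_cross
        assert rep.per_atom.sum() == pytest.approx(electro, rel=1e-6)
        assert rep.total == pytest.approx(electro + rep.sasa_term, rel=1e-9)

    def test_salt_screens_solvation(self):
        ent = MolecularEntity([make_atom(1, (0, 0, 0), 2.0, 1.0)])
        gb = GBRadiusSet(radii=np.array([2.0]), clamped=np.zeros(1, bool))
        fresh = energy_report(ent, gb, uniform_sas(ent), WATER)
        salty = energy_report(
            ent, gb, uniform_sas(ent), SolventModel(kappa=0.1, gamma=0.0)
        )
        assert salty.gb_self < fresh.gb_self  # screening deepens solvation

    def test_coincident_atoms_rejected(self):
        ent = MolecularEntity(
            [make_atom(1, (0, 0, 0), 1.5, 1.0), make_atom(2, (0, 0, 0), 1.5, 1.0)]
        )
        gb = GBRadiusSet(radii=np.full(2, 1.5), clamped=np.zeros(2, bool))
        with pytest.raises(GeometryError):
            energy_report(ent, gb, uniform_sas(ent), WATER)

    def test_misaligned_radii_rejected(self, sphere_entity):
        gb = GBRadiusSet(radii=np.array([2.0, 2.0]), clamped=np.zeros(2, bool))
        with pytest.raises(AlignmentError):
            energy_report(sphere_entity, gb, uniform_sas(sphere_entity), WATER)


class TestEnergyDifference:
    def test_self_difference_is_zero(self):
        # complex report minus two halves carrying its own per-atom shares
        import dataclasses

        ent = MolecularEntity(
            [make_atom(1, (0, 0, 0), 1.6, 0.5), make_atom(2, (4, 0, 0), 1.6, -0.5)]
        )
        gb = GBRadiusSet(np.full(2, 1.8), np.zeros(2, bool))
        rep = energy_report(ent, gb, uniform_sas(ent, 5.0), WATER)
        halves = []
        for sl in (slice(0, 1), slice(1, 2)):
            halves.append(
                dataclasses.replace(
                    rep,
                    coulomb=rep.coulomb / 2,
                    gb_self=rep.gb_self / 2,
                    gb_cross=rep.gb_cross / 2,
                    sasa_term=rep.sasa_term / 2,
                    per_atom=rep.per_atom[sl],
                )
            )
        diff = energy_difference(rep, halves[0], halves[1])
        assert diff.total == 0.0
        assert np.all(diff.per_atom == 0.0)

    def test_model_mismatch_rejected(self, sphere_entity, sphere_gb):
        rep1 = energy_report(sphere_entity, sphere_gb, uniform_sas(sphere_entity), WATER)
        rep2 = energy_report(
            sphere_entity, sphere_gb, uniform_sas(sphere_entity), SolventModel(eps_out=40.0, gamma=0.0)
        )
        with pytest.raises(ConfigurationError):
            energy_difference(rep1, rep2, rep2)

    def test_delta_coulomb_equals_inter_entity_sum(self):
        rng = np.random.default_rng(2)
        a_atoms = [make_atom(i + 1, rng.uniform(-3, 3, 3), 1.5, rng.normal(), "A") for i in range(5)]
        b_atoms = [
            make_atom(i + 6, rng.uniform(-3, 3, 3) + [7, 0, 0], 1.5, rng.normal(), "B")
            for i in range(5)
        ]
        mol1, mol2 = MolecularEntity(a_atoms, "mol1"), MolecularEntity(b_atoms, "mol2")
        cplx = MolecularEntity(a_atoms + b_atoms, "complex")
        radii = {id(e): GBRadiusSet(np.full(e.n_atoms, 1.8), np.zeros(e.n_atoms, bool)) for e in (mol1, mol2, cplx)}
        reps = {
            e.label: energy_report(e, radii[id(e)], uniform_sas(e), WATER)
            for e in (cplx, mol1, mol2)
        }
        diff = energy_difference(reps["complex"], reps["mol1"], reps["mol2"])
        direct = 0.0
        for a in a_atoms:
            for b in b_atoms:
                d = np.linalg.norm(np.subtract(a.position, b.position))
                direct += KE * a.charge * b.charge / d
        assert diff.coulomb == pytest.approx(direct, rel=1e-9)


class TestSurfacePotential:
    def test_zero_charges_zero_potential(self, sphere_gb):
        ent = MolecularEntity([make_atom(1, (0, 0, 0), 2.0, 0.0)])
        patches = PatchSet(
            points=np.array([[3.0, 0, 0], [5.0, 0, 0]]),
            normals=np.tile([[1.0, 0, 0]], (2, 1)),
            areas=np.ones(2),
            owner_atom=np.zeros(2, int),
        )
        phi = surface_potential(patches, ent, GBRadiusSet(np.array([2.0]), np.zeros(1, bool)), WATER)
        assert np.all(phi == 0.0)

    def test_positive_charge_positive_decaying_potential(self):
        ent = MolecularEntity([make_atom(1, (0, 0, 0), 2.0, 1.0)])
        gb = GBRadiusSet(np.array([2.0]), np.zeros(1, bool))
        patches = PatchSet(
            points=np.array([[2.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]]),
            normals=np.tile([[1.0, 0, 0]], (3, 1)),
            areas=np.ones(3),
            owner_atom=np.zeros(3, int),
        )
        phi = surface_potential(patches, ent, gb, WATER)
        assert np.all(phi > 0)
        assert phi[0] > phi[1] > phi[2]

    def test_linearity_in_charges(self, toy_complex):
        from gbcplx.io_structures import partition_entities

        mol1, _ = partition_entities(toy_complex, "A", "B")
        surf = triangulate_ses(mol1)
        patches = extract_patches(surf, mol1)
        gb = compute_gb_radii(patches, mol1)
        phi1 = surface_potential(patches, mol1, gb, WATER).copy()
        doubled = MolecularEntity(
            [make_atom(a.serial, a.position, a.vdw_radius, 2 * a.charge, a.chain_id) for a in mol1.atoms],
            "mol1",
        )
        phi2 = surface_potential(patches, doubled, gb, WATER)
        np.testing.assert_allclose(phi2, 2 * phi1, rtol=1e-12)
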