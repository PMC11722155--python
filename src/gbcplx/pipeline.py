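"""Full-analysis orchestration: three calculations and the output file suite.

A run performs three calculations — one for the complex and one for each
isolated interacting entity (each surfaced in the absence of the other) —
then crosses them: atom contact pairs and their charge correlation, surface
point pairs and their potential correlation (the electrostatic
complementarity), buried SASA, and the component-wise binding free energy
difference.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, MeshFormatError
from .gb_core import (
    EnergyReport,
    GBRadiusSet,
    SolventModel,
    compute_gb_radii,
    energy_difference,
    energy_report,
    format_energy_value,
    surface_potential,
    write_gbr,
    write_nrg,
)
from .interface_analysis import (
    AtomContactPair,
    ComplementarityResult,
    SurfacePotentialPair,
    atom_contact_pairs,
    buried_sasa,
    complementarity,
    interface_atoms,
    surface_contact_pairs,
    write_crg_pair,
    write_srf,
    write_srf_pot_pair,
)
from .io_structures import (
    MolecularEntity,
    merge_entities,
    partition_entities,
    read_pqr,
    write_pqg,
    write_pqr,
)
from .surface import (
    DEFAULT_GRID_SPACING,
    DEFAULT_PROBE_RADIUS,
    DEFAULT_SAS_POINTS,
    PatchSet,
    SasResult,
    TriangulatedSurface,
    compute_sas,
    extract_patches,
    generate_nanoshaper_input,
    parse_msms_surface,
    triangulate_ses,
)

logger = logging.getLogger(__name__)

SURFACERS = ("internal", "msms-files", "nanoshaper-files")


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs besides the structure itself."""

    input_pqr: str = ""
    basename: str = "out"
    chains1: str = "A"
    chains2: str = "B"
    delta: float = 1.0
    probe: float = DEFAULT_PROBE_RADIUS
    grid_spacing: float = DEFAULT_GRID_SPACING
    sas_points: int = DEFAULT_SAS_POINTS
    surface_samples: int = 1024
    solvent: SolventModel = field(default_factory=SolventModel)
    surfacer: str = "internal"
    surface_base: str | None = None
    keep_cavities: bool = True
    lite: bool = False
    rpns: bool = False
    seed: int = 0
    outdir: str = "."

    def __post_init__(self) -> None:
        if not self.basename:
            raise ConfigurationError("basename must be non-empty")
        if self.surfacer not in SURFACERS:
            raise ConfigurationError(f"surfacer must be one of {SURFACERS}")
        if self.surfacer != "internal" and not self.surface_base:
            raise ConfigurationError("external surfacer mode needs a surface basename")
        if set(self.chains1) & set(self.chains2):
            raise ConfigurationError("chain selections overlap")


@dataclass
class EntityResult:
    """Surface, areas, GB radii and energies of one entity."""

    entity: MolecularEntity
    surface: TriangulatedSurface
    patches: PatchSet
    sas: SasResult
    gb_radii: GBRadiusSet
    energy: EnergyReport


@dataclass
class AnalysisResult:
    """Complete result of a three-calculation run."""

    config: RunConfig
    complex: EntityResult
    mol1: EntityResult
    mol2: EntityResult
    diff: EnergyReport
    atom_pairs: list[AtomContactPair]
    charge_comp: ComplementarityResult
    surface_pairs: list[SurfacePotentialPair]
    potential_comp: ComplementarityResult
    buried_sasa: float

    @property
    def ec(self) -> float:
        """Electrostatic complementarity (−Pearson r of potential pairs)."""
        return self.potential_comp.ec

    @property
    def interface_indices(self) -> tuple[list[int], list[int]]:
        return interface_atoms(self.atom_pairs)


def _external_mesh_paths(base: str, label: str) -> tuple[Path, Path]:
    suffix = {"complex": "", "mol1": "_mol_1", "mol2": "_mol_2"}[label]
    return Path(f"{base}{suffix}.vert"), Path(f"{base}{suffix}.face")


def _surface_for(entity: MolecularEntity, config: RunConfig) -> TriangulatedSurface:
    if config.surfacer == "internal":
        return triangulate_ses(
            entity,
            probe_radius=config.probe,
            grid_spacing=config.grid_spacing,
            n_surface_samples=config.surface_samples,
            keep_cavities=config.keep_cavities,
        )
    vert, face = _external_mesh_paths(config.surface_base, entity.label)
    if not vert.exists() or not face.exists():
        raise MeshFormatError(
            f"external mesh files {vert} / {face} not found for entity {entity.label}"
        )
    return parse_msms_surface(vert, face)


def _analyze_entity(entity: MolecularEntity, config: RunConfig) -> EntityResult:
    t0 = time.perf_counter()
    surface = _surface_for(entity, config)
    patches = extract_patches(surface, entity)
    sas = compute_sas(entity, probe_radius=config.probe, n_sphere_points=config.sas_points)
    gb = compute_gb_radii(patches, entity)
    energy = energy_report(entity, gb, sas, config.solvent)
    logger.info(
        "stage %s: %d atoms, %d patches, %.2f s",
        entity.label,
        entity.n_atoms,
        len(patches),
        time.perf_counter() - t0,
    )
    return EntityResult(entity=entity, surface=surface, patches=patches, sas=sas, gb_radii=gb, energy=energy)


def analyze_complex(
    source: MolecularEntity | str | Path, config: RunConfig
) -> AnalysisResult:
    """Run the three calculations and all interface statistics.

    ``source`` is a complex entity or a PQR path; chains are taken from the
    config.  The complex is re-ordered as mol1 atoms followed by mol2 atoms
    so per-atom energy differences align by identity.
    """
    entity = source if isinstance(source, MolecularEntity) else read_pqr(source)
    mol1, mol2 = partition_entities(entity, config.chains1, config.chains2)
    cplx = merge_entities(mol1, mol2, label="complex")

    res_c = _analyze_entity(cplx, config)
    res_1 = _analyze_entity(mol1, config)
    res_2 = _analyze_entity(mol2, config)

    diff = energy_difference(res_c.energy, res_1.energy, res_2.energy)

    surface_potential(res_1.patches, mol1, res_1.gb_radii, config.solvent)
    surface_potential(res_2.patches, mol2, res_2.gb_radii, config.solvent)

    apairs = atom_contact_pairs(mol1, mol2, delta=config.delta)
    ccomp = complementarity(apairs)
    spairs = surface_contact_pairs(res_1.patches, res_2.patches, delta=config.delta)
    pcomp = complementarity(spairs)
    buried = buried_sasa(res_1.sas, res_2.sas, res_c.sas)

    return AnalysisResult(
        config=config,
        complex=res_c,
        mol1=res_1,
        mol2=res_2,
        diff=diff,
        atom_pairs=apairs,
        charge_comp=ccomp,
        surface_pairs=spairs,
        potential_comp=pcomp,
        buried_sasa=buried,
    )


def electrostatic_complementarity(
    source: MolecularEntity | str | Path,
    chains1: str,
    chains2: str,
    config: RunConfig | None = None,
) -> ComplementarityResult:
    """Light path computing only the surface-potential complementarity.

    Surfaces, GB radii and potentials of the two isolated entities are
    computed (no energies, no complex surface); the result carries the
    Pearson r, ec, sum of products and concordant fraction of the
    contacting surface-point pairs.
    """
    config = config or RunConfig()
    config = replace(config, chains1=chains1, chains2=chains2)
    entity = source if isinstance(source, MolecularEntity) else read_pqr(source)
    mol1, mol2 = partition_entities(entity, chains1, chains2)
    results = []
    for mol in (mol1, mol2):
        surface = _surface_for(mol, config)
        patches = extract_patches(surface, mol)
        gb = compute_gb_radii(patches, mol)
        surface_potential(patches, mol, gb, config.solvent)
        results.append(patches)
    spairs = surface_contact_pairs(results[0], results[1], delta=config.delta)
    return complementarity(spairs)


# ---------------------------------------------------------------------------
# Output file suite
# ---------------------------------------------------------------------------

def output_inventory(basename: str) -> list[str]:
    """The 18 file names a full run writes."""
    b = basename
    return [
        f"{b}_int.pqr",
        f"{b}_int_mol_1.pqr",
        f"{b}_int_mol_2.pqr",
        f"{b}.nrg",
        f"{b}_mol_1.nrg",
        f"{b}_mol_2.nrg",
        f"{b}_diff.nrg",
        f"{b}.gbr",
        f"{b}_mol_1.gbr",
        f"{b}_mol_2.gbr",
        f"{b}.pqg",
        f"{b}_mol_1.pqg",
        f"{b}_mol_2.pqg",
        f"{b}_mol_1.srf",
        f"{b}_mol_2.srf",
        f"{b}.crg_pair",
        f"{b}.srf_pot_pair",
        f"{b}.summary",
    ]


def write_summary(result: AnalysisResult, path: str | Path) -> None:
    """Keyed summary of the most relevant quantities of the analysis.

    The correlation and sum-of-products entries are formatted identically to
    the footers of the .crg_pair / .srf_pot_pair files.
    """
    r = result
    fmt = format_energy_value
    lines: list[str] = []
    lines.append(f"n_atoms_complex {r.complex.entity.n_atoms}")
    lines.append(f"n_atoms_mol_1 {r.mol1.entity.n_atoms}")
    lines.append(f"n_atoms_mol_2 {r.mol2.entity.n_atoms}")
    for name, rep in (
        ("complex", r.complex.energy),
        ("mol_1", r.mol1.energy),
        ("mol_2", r.mol2.energy),
        ("diff", r.diff),
    ):
        lines.append(f"coulomb_{name} {fmt(rep.coulomb)}")
        lines.append(f"gb_self_{name} {fmt(rep.gb_self)}")
        lines.append(f"gb_cross_{name} {fmt(rep.gb_cross)}")
        lines.append(f"sasa_term_{name} {fmt(rep.sasa_term)}")
        lines.append(f"total_{name} {fmt(rep.total)}")
    lines.append(f"buried_sasa {fmt(r.buried_sasa)}")
    lines.append(f"sasa_diff {fmt(-r.buried_sasa)}")
    lines.append(f"n_atom_pairs {r.charge_comp.n_pairs}")
    lines.append(
        f"charge_pearson_r {fmt(r.charge_comp.pearson_r) if r.charge_comp.defined else 'nan'}"
    )
    lines.append(f"sum_charge_products {fmt(r.charge_comp.sum_products)}")
    lines.append(f"n_surface_pairs {r.potential_comp.n_pairs}")
    lines.append(
        f"potential_pearson_r {fmt(r.potential_comp.pearson_r) if r.potential_comp.defined else 'nan'}"
    )
    lines.append(f"ec {fmt(r.potential_comp.ec) if r.potential_comp.defined else 'nan'}")
    lines.append(f"sum_potential_products {fmt(r.potential_comp.sum_products)}")
    lines.append(f"concordant_fraction {fmt(r.potential_comp.concordant_fraction)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_outputs(result: AnalysisResult, outdir: str | Path | None = None) -> list[Path]:
    """Write the full output file suite (or only the summary in lite mode).

    Returns the list of files written.  On failure every partially written
    file is removed before the exception propagates.
    """
    cfg = result.config
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    b = outdir / cfg.basename
    written: list[Path] = []

    def _target(name_suffix: str) -> Path:
        p = Path(f"{b}{name_suffix}")
        written.append(p)
        return p

    try:
        if cfg.lite:
            write_summary(result, _target(".summary"))
            return written

        idx1, idx2 = result.interface_indices
        n1 = result.mol1.entity.n_atoms
        cplx_iface = sorted(idx1) + [n1 + j for j in sorted(idx2)]

        write_pqr(result.complex.entity.subset(cplx_iface, "complex"), _target("_int.pqr"))
        write_pqr(result.mol1.entity.subset(idx1, "mol1"), _target("_int_mol_1.pqr"))
        write_pqr(result.mol2.entity.subset(idx2, "mol2"), _target("_int_mol_2.pqr"))

        write_nrg(result.complex.energy, _target(".nrg"), result.complex.entity, cplx_iface)
        write_nrg(result.mol1.energy, _target("_mol_1.nrg"), result.mol1.entity, idx1)
        write_nrg(result.mol2.energy, _target("_mol_2.nrg"), result.mol2.entity, idx2)
        write_nrg(result.diff, _target("_diff.nrg"), result.complex.entity, cplx_iface)

        write_gbr(result.complex.entity, result.complex.gb_radii, _target(".gbr"))
        write_gbr(result.mol1.entity, result.mol1.gb_radii, _target("_mol_1.gbr"))
        write_gbr(result.mol2.entity, result.mol2.gb_radii, _target("_mol_2.gbr"))

        write_pqg(result.complex.entity, result.complex.gb_radii, _target(".pqg"))
        write_pqg(result.mol1.entity, result.mol1.gb_radii, _target("_mol_1.pqg"))
        write_pqg(result.mol2.entity, result.mol2.gb_radii, _target("_mol_2.pqg"))

        sp1 = sorted({p.index1 for p in result.surface_pairs})
        sp2 = sorted({p.index2 for p in result.surface_pairs})
        write_srf(result.mol1.patches, sp1, result.mol1.entity, _target("_mol_1.srf"))
        write_srf(result.mol2.patches, sp2, result.mol2.entity, _target("_mol_2.srf"))

        write_crg_pair(
            result.atom_pairs,
            result.mol1.entity,
            result.mol2.entity,
            result.charge_comp,
            _target(".crg_pair"),
        )
        write_srf_pot_pair(
            result.surface_pairs,
            result.mol1.patches,
            result.mol2.patches,
            result.mol1.entity,
            result.mol2.entity,
            result.potential_comp,
            _target(".srf_pot_pair"),
        )
        write_summary(result, _target(".summary"))
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return written


def prepare_surfacer_inputs(
    entity: MolecularEntity, config: RunConfig
) -> list[Path]:
    """Write .xyzr (and, unless -rpns, a parameter file) for an external
    surfacer run with the configured surface basename."""
    base = config.surface_base or config.basename
    xyzr_path = Path(f"{base}.xyzr")
    prm_path = Path(f"{base}.prm")
    xyzr, prm = generate_nanoshaper_input(
        entity, probe_radius=config.probe, xyzr_name=xyzr_path.name
    )
    xyzr_path.write_text(xyzr)
    written = [xyzr_path]
    if not config.rpns:
        prm_path.write_text(prm)
        written.append(prm_path)
    else:
        logger.info("-rpns: existing parameter file %s left untouched", prm_path)
    return written
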