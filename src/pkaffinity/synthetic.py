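"""Desk-scale synthetic inputs for every pipeline stage.

The generators build what the analysis stages assume about real data —
small parameterized receptor-pocket/peptide complexes with charged contact
pairs, snapshot ensembles as Gaussian positional noise around a reference
with *constructively imposed* hydrogen-bond occupancy schedules, and the
published kinetics/decomposition tables as read-only fixtures.  All
generators are pure functions of their arguments and a mandatory seed.

Occupancy schedules are imposed frame-wise (the scheduled pair's distance
is placed inside or outside the 3.5 A criterion in an exact, seed-shuffled
subset of frames) rather than sampled, so recounting tests are exact
instead of binomially fuzzy; a sampled mode exists for realism tests.

Toy parameter values sit inside common force-field ranges: contact charges
+/-0.5-1.0 e, LJ well depths 0.05-0.2 kcal/mol, radii 1.2-2.0 A.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import InputError
from .structure import (Atom, AngleTerm, BondTerm, ComplexPartition,
                        MolecularSystem, SnapshotEnsemble)

__all__ = [
    "ContactSpec",
    "EnsembleRecipe",
    "PublishedTables",
    "make_toy_complex",
    "make_ensemble",
    "published_tables",
    "make_linear_dataset",
]

# frozen digests guard the read-only reference tables against edits
_FIXTURE_SHA256 = {
    "kinetics_reference.tsv":
        "14fb65f7c2b9c542ca51f1bfc73cbb1d5c3661106b53f4e789fd0807784d3a73",
    "mutant_components.tsv":
        "a40c98eae02c3acb5d32940d74505bf21ff42715ed13912e4c4b4a488b9c2ef8",
    "short_peptide_components.tsv":
        "4d9bd63f753ea222df8f7da4d7f5aa18146382f1e07bcbfd9c43fcebd4c6f08e",
}


@dataclass(frozen=True)
class ContactSpec:
    """One receptor-ligand contact: a donor-like atom on a receptor
    residue paired with an acceptor-like atom on a ligand residue, placed
    ``distance`` angstroms apart and carrying the given partial charges."""

    receptor_residue: int     # 1-based residue index on the receptor
    ligand_residue: int       # 1-based residue index on the ligand
    distance: float           # A, donor-acceptor separation
    receptor_charge: float = 0.5
    ligand_charge: float = -0.5


@dataclass(frozen=True)
class EnsembleRecipe:
    """Recipe for a synthetic snapshot ensemble.

    ``hb_schedule`` maps (donor_index, acceptor_index) pairs to target
    occupancies in percent; the realized occupancy at the stated frame
    count is exact in constructive mode (``sampled=False``).
    """

    n_frames: int
    sigma: float                      # A, isotropic positional noise
    seed: int
    hb_schedule: tuple = ()           # ((pair, occupancy_pct), ...)
    dt_ps: float = 10.0
    cutoff: float = 3.5               # A, the criterion the schedule targets
    sampled: bool = False

    def __post_init__(self):
        if self.n_frames < 1:
            raise InputError("n_frames must be >= 1")
        if self.sigma < 0:
            raise InputError("noise sigma must be >= 0")
        for _, occ in self.hb_schedule:
            if not (0.0 <= occ <= 100.0):
                raise InputError(f"target occupancy {occ} outside [0, 100]")


# --------------------------------------------------------------------------
# toy complexes
# --------------------------------------------------------------------------

_RESIDUE_ATOMS = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))


def _place_residue(origin: np.ndarray, rng) -> np.ndarray:
    """Four-atom pseudo-residue (N, CA, C, O) with mild geometric jitter."""
    base = np.array(
        [[0.0, 0.0, 0.0], [1.45, 0.2, 0.0], [2.4, -0.6, 0.9], [2.4, -1.8, 0.9]]
    )
    return origin + base + rng.normal(0.0, 0.05, size=base.shape)


def make_toy_complex(n_receptor_residues: int, n_ligand_residues: int,
                     contact_spec=(), seed: int = 0
                     ) -> tuple[MolecularSystem, ComplexPartition]:
    """A fully parameterized mini receptor pocket + peptide ligand.

    Receptor residues (chain A) and ligand residues (chain B) are laid out
    on offset strands about 8 A apart; each requested contact adds a
    charged donor atom (``NZ``) on the receptor residue and acceptor atom
    (``OD1``) on the ligand residue at the prescribed separation.
    Deterministic for a fixed seed, including the PDB bytes written from
    the result.
    """
    if n_receptor_residues < 1 or n_ligand_residues < 1:
        raise InputError("need at least one residue on each side")
    contacts = list(contact_spec)
    seen = set()
    for c in contacts:
        if c.distance <= 0:
            raise InputError(f"contact distance must be positive, got {c.distance}")
        if not (1 <= c.receptor_residue <= n_receptor_residues):
            raise InputError(f"contact receptor residue {c.receptor_residue} out of range")
        if not (1 <= c.ligand_residue <= n_ligand_residues):
            raise InputError(f"contact ligand residue {c.ligand_residue} out of range")
        key = (c.receptor_residue, c.ligand_residue)
        if key in seen:
            raise InputError(f"contradictory contact_spec: duplicate contact {key}")
        seen.add(key)

    rng = np.random.default_rng(seed)

    # phase 1: residue geometry (receptor strand at y=0, ligand at y=8)
    residue_xyz: dict[tuple[str, int], np.ndarray] = {}
    for r in range(n_receptor_residues):
        residue_xyz[("A", r + 1)] = _place_residue(
            np.array([3.5 * r, 0.0, 0.0]), rng)
    for r in range(n_ligand_residues):
        residue_xyz[("B", r + 1)] = _place_residue(
            np.array([3.5 * r, 8.0, 0.0]), rng)

    # contact-atom positions from the two CA anchors
    contact_atoms: dict[tuple[str, int], list] = {}
    for c in contacts:
        rca = residue_xyz[("A", c.receptor_residue)][1]
        lca = residue_xyz[("B", c.ligand_residue)][1]
        axis = lca - rca
        axis = axis / np.linalg.norm(axis)
        midpoint = 0.5 * (rca + lca)
        contact_atoms.setdefault(("A", c.receptor_residue), []).append(
            ("NZ", "N", float(c.receptor_charge), 0.1, 1.85, 1.55,
             midpoint - 0.5 * c.distance * axis))
        contact_atoms.setdefault(("B", c.ligand_residue), []).append(
            ("OD1", "O", float(c.ligand_charge), 0.12, 1.7, 1.5,
             midpoint + 0.5 * c.distance * axis))

    # phase 2: assemble atoms grouped by residue (PDB-stable order)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    serial = 0
    keys = ([("A", r + 1) for r in range(n_receptor_residues)]
            + [("B", r + 1) for r in range(n_ligand_residues)])
    for chain, resseq in keys:
        resname = "GLY" if chain == "A" else "ALA"
        xyz = residue_xyz[(chain, resseq)]
        first = len(atoms)
        for (name, element), pos in zip(_RESIDUE_ATOMS, xyz):
            serial += 1
            atoms.append(Atom(
                serial=serial, name=name, residue_name=resname,
                residue_seq=resseq, chain=chain, element=element,
                charge=float(rng.uniform(-0.3, 0.3)),
                lj_epsilon=float(rng.uniform(0.05, 0.2)),
                lj_rmin_half=float(rng.uniform(1.2, 2.0)),
                gb_radius=float(rng.uniform(1.2, 2.0)),
            ))
            coords.append(pos)
        # N-CA, CA-C, C-O bonds at their realized lengths; N-CA-C angle
        for i, j in ((0, 1), (1, 2), (2, 3)):
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            bonds.append(BondTerm(first + i, first + j, k_b=300.0, b0=d))
        v1, v2 = xyz[0] - xyz[1], xyz[2] - xyz[1]
        theta = np.degrees(np.arccos(
            np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
        angles.append(AngleTerm(first, first + 1, first + 2,
                                k_theta=50.0, theta0=float(theta)))
        for name, element, charge, eps, rh, rad, pos in \
                contact_atoms.get((chain, resseq), []):
            serial += 1
            atoms.append(Atom(serial=serial, name=name, residue_name=resname,
                              residue_seq=resseq, chain=chain, element=element,
                              charge=charge, lj_epsilon=eps, lj_rmin_half=rh,
                              gb_radius=rad))
            coords.append(pos)
            bonds.append(BondTerm(first + 1, len(atoms) - 1, k_b=250.0,
                                  b0=float(np.linalg.norm(pos - xyz[1]))))

    system = MolecularSystem(atoms=atoms, coordinates=np.asarray(coords),
                             bonds=bonds, angles=angles)
    ligand = tuple(i for i, a in enumerate(atoms) if a.chain == "B")
    receptor = tuple(i for i, a in enumerate(atoms) if a.chain == "A")
    return system, ComplexPartition(receptor_indices=receptor,
                                    ligand_indices=ligand)


def contact_atom_indices(system: MolecularSystem) -> list[tuple[int, int]]:
    """(donor NZ, acceptor OD1) index pairs of a toy complex, in the
    order the contacts were specified."""
    nz = [i for i, a in enumerate(system.atoms) if a.name == "NZ"]
    od = [i for i, a in enumerate(system.atoms) if a.name == "OD1"]
    return list(zip(nz, od))


# --------------------------------------------------------------------------
# ensembles
# --------------------------------------------------------------------------

def make_ensemble(reference_system: MolecularSystem,
                  recipe: EnsembleRecipe) -> SnapshotEnsemble:
    """Frames = reference + isotropic Gaussian noise, then each scheduled
    pair's distance is set inside/outside the cutoff so the realized
    occupancy equals its target exactly (constructive mode).

    The acceptor atom of each scheduled pair is repositioned along the
    donor->acceptor axis; an atom may appear in at most one schedule
    (and never as both donor and acceptor), otherwise the schedule is
    contradictory and rejected.
    """
    rng = np.random.default_rng(recipe.seed)
    ref = reference_system.coordinates
    n = recipe.n_frames
    frames = ref[None, :, :] + rng.normal(0.0, recipe.sigma,
                                          size=(n, *ref.shape))

    moved: set[int] = set()
    anchors: set[int] = set()
    for (donor, acceptor), _ in recipe.hb_schedule:
        if acceptor in moved or acceptor in anchors:
            raise InputError(
                f"contradictory schedule: atom {acceptor} already constrained")
        if donor in moved:
            raise InputError(
                f"contradictory schedule: atom {donor} is repositioned elsewhere")
        moved.add(acceptor)
        anchors.add(donor)

    for (donor, acceptor), occ in recipe.hb_schedule:
        if recipe.sampled:
            inside = rng.random(n) < occ / 100.0
        else:
            k = int(round(occ / 100.0 * n))
            order = rng.permutation(n)
            inside = np.zeros(n, dtype=bool)
            inside[order[:k]] = True
        axis = ref[acceptor] - ref[donor]
        norm = np.linalg.norm(axis)
        axis = axis / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        # strict margins keep float noise from crossing the criterion
        d_in = rng.uniform(recipe.cutoff - 0.9, recipe.cutoff - 0.2, size=n)
        d_out = rng.uniform(recipe.cutoff + 0.2, recipe.cutoff + 1.1, size=n)
        d = np.where(inside, d_in, d_out)
        frames[:, acceptor, :] = frames[:, donor, :] + d[:, None] * axis
    times = recipe.dt_ps * np.arange(n, dtype=float)
    return SnapshotEnsemble(system=reference_system, frames=frames,
                            time_ps=times)


# --------------------------------------------------------------------------
# published-table fixtures
# --------------------------------------------------------------------------

class PublishedTables(NamedTuple):
    kinetics: pd.DataFrame       # peptide kinetics and experimental shifts
    mutant_components: pd.DataFrame   # arginine-mutant decomposition
    short_components: pd.DataFrame    # shorter-peptide decomposition


def _load_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("pkaffinity.data") / name
    data = ref.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    expected = _FIXTURE_SHA256.get(name)
    if expected is not None and digest != expected:
        raise InputError(f"fixture {name} failed its checksum; do not edit "
                         f"packaged tables in place")
    return pd.read_csv(ref, sep="\t", comment="#")


def published_tables() -> PublishedTables:
    """The packaged read-only reference tables: per-peptide kinetics with
    both experimental shift columns, and the two MM/GBSA component
    decomposition tables (verbatim as published, including one known row
    whose components do not sum to its total — see the methods note)."""
    return PublishedTables(
        kinetics=_load_fixture("kinetics_reference.tsv"),
        mutant_components=_load_fixture("mutant_components.tsv"),
        short_components=_load_fixture("short_peptide_components.tsv"),
    )


def calc_ddg_table(tables: PublishedTables | None = None) -> dict:
    """system -> published calculated ddG(E->ES), mutants + short peptides."""
    if tables is None:
        tables = published_tables()
    merged = pd.concat([tables.mutant_components, tables.short_components])
    merged = merged.drop_duplicates(subset="system")
    return dict(zip(merged["system"], merged["ddg_calc"]))


def exp_ddg_ts_table(tables: PublishedTables | None = None) -> dict:
    """system -> published experimental ddG(E->TS)."""
    if tables is None:
        tables = published_tables()
    return dict(zip(tables.kinetics["system"], tables.kinetics["ddg_ts_exp_kcal"]))


# --------------------------------------------------------------------------
# regression fixtures
# --------------------------------------------------------------------------

def make_linear_dataset(slope: float, intercept: float, sigma: float,
                        n: int, seed: int):
    """(x, y) with y = slope*x + intercept + N(0, sigma); x on [-3, 3]."""
    if n < 3:
        raise InputError("need at least 3 points")
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(-3.0, 3.0, size=n))
    y = slope * x + intercept + rng.normal(0.0, sigma, size=n)
    return x, y
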