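"""Structures, snapshot ensembles, force-field parameter tables and
receptor/ligand partitions — the shared data backbone of the pipeline.

Coordinates are Cartesian angstroms with no periodic box: energies are
evaluated on solute snapshots extracted from solvated trajectories, so
minimum-image logic is deliberately absent.  The interchange format for
ensembles is multi-model PDB; per-atom force-field parameters (partial
charge, Lennard-Jones well depth and half-r_min, intrinsic Born radius)
travel in a flat tab-separated table keyed by (residue_name, atom_name)
rather than in CHARMM PSF/PRM files, which keeps fixtures hand-writable.
"""

from __future__ import annotations

import fnmatch
import io
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .errors import InputError, ParameterLookupError, PDBParseError, SelectionError

__all__ = [
    "Atom",
    "BondTerm",
    "AngleTerm",
    "DihedralTerm",
    "MolecularSystem",
    "ComplexPartition",
    "SnapshotEnsemble",
    "read_pdb",
    "read_ensemble",
    "write_pdb",
    "merge_parameters",
    "partition_by_selection",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Atom:
    """One atom with its identity and per-atom force-field parameters.

    Parameters are NaN until :func:`merge_parameters` assigns them; energy
    kernels refuse to run on unparameterized systems.
    """

    serial: int
    name: str
    residue_name: str
    residue_seq: int
    chain: str = "A"
    element: str = ""
    charge: float = math.nan          # e
    lj_epsilon: float = math.nan      # kcal/mol
    lj_rmin_half: float = math.nan    # angstrom
    gb_radius: float = math.nan       # angstrom

    def __post_init__(self):
        if not self.element:
            self.element = _infer_element(self.name)

    @property
    def label(self) -> str:
        """Human-readable id such as ``Arg19-NH1`` -> ``ARG19-NH1``."""
        return f"{self.residue_name.capitalize()}{self.residue_seq}-{self.name}"

    @property
    def parameterized(self) -> bool:
        return not any(
            math.isnan(v)
            for v in (self.charge, self.lj_epsilon, self.lj_rmin_half, self.gb_radius)
        )


def _infer_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    k_b: float = math.nan     # kcal/mol/A^2
    b0: float = math.nan      # angstrom


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int
    k: int
    k_theta: float = math.nan   # kcal/mol/rad^2
    theta0: float = math.nan    # degrees


@dataclass(frozen=True)
class DihedralTerm:
    i: int
    j: int
    k: int
    l: int
    k_phi: float = math.nan     # kcal/mol
    mult: int = 1
    delta: float = 0.0          # degrees


@dataclass
class MolecularSystem:
    """An ordered atom list with coordinates and bonded-term lists."""

    atoms: list[Atom]
    coordinates: np.ndarray                       # (N, 3) angstrom
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    dihedrals: list[DihedralTerm] = field(default_factory=list)
    scale14: float = 1.0        # 1-4 electrostatic/LJ scaling factor

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.atoms), 3):
            raise InputError(
                f"coordinate array has shape {self.coordinates.shape}, "
                f"expected ({len(self.atoms)}, 3)"
            )
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise InputError("atom serial numbers are not unique")
        n = len(self.atoms)
        for term in (*self.bonds, *self.angles, *self.dihedrals):
            idx = [term.i, term.j, getattr(term, "k", 0), getattr(term, "l", 0)]
            if any(not (0 <= x < n) for x in idx):
                raise InputError(f"bonded term {term} indexes outside 0..{n - 1}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    # -- derived topology ---------------------------------------------------

    def bond_graph(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for b in self.bonds:
            adj[b.i].add(b.j)
            adj[b.j].add(b.i)
        return adj

    def exclusion_pairs(self) -> tuple[set[frozenset[int]], set[frozenset[int]]]:
        """(excluded 1-2/1-3 pairs, 1-4 pairs to be scaled by ``scale14``).

        Derived from the bond graph: graph distance 1 or 2 excludes the pair
        from nonbonded sums; distance 3 scales it.  The sets are symmetric by
        construction (frozenset keys).
        """
        adj = self.bond_graph()
        excluded: set[frozenset[int]] = set()
        one_four: set[frozenset[int]] = set()
        for i in range(self.n_atoms):
            dist = {i: 0}
            frontier = [i]
            for d in (1, 2, 3):
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if v not in dist:
                            dist[v] = d
                            nxt.append(v)
                frontier = nxt
            for j, d in dist.items():
                if j == i:
                    continue
                (excluded if d <= 2 else one_four).add(frozenset((i, j)))
        one_four -= excluded
        return excluded, one_four

    def subset(self, indices, renumber: bool = False) -> "MolecularSystem":
        """Extract the subsystem on ``indices`` (file order preserved).

        Bonded terms are kept only when all their atoms lie inside the
        subset; crossing terms are dropped silently here — callers that
        must not cut bonds (the binding scorer) check for crossings first.
        """
        idx = sorted(int(i) for i in indices)
        remap = {old: new for new, old in enumerate(idx)}
        atoms = [replace(self.atoms[i]) for i in idx]
        if renumber:
            for new, a in enumerate(atoms):
                a.serial = new + 1

        def keep(term_indices):
            return all(t in remap for t in term_indices)

        bonds = [
            replace(b, i=remap[b.i], j=remap[b.j])
            for b in self.bonds if keep((b.i, b.j))
        ]
        angles = [
            replace(t, i=remap[t.i], j=remap[t.j], k=remap[t.k])
            for t in self.angles if keep((t.i, t.j, t.k))
        ]
        dihedrals = [
            replace(t, i=remap[t.i], j=remap[t.j], k=remap[t.k], l=remap[t.l])
            for t in self.dihedrals if keep((t.i, t.j, t.k, t.l))
        ]
        return MolecularSystem(
            atoms=atoms,
            coordinates=self.coordinates[idx],
            bonds=bonds,
            angles=angles,
            dihedrals=dihedrals,
            scale14=self.scale14,
        )


@dataclass(frozen=True)
class ComplexPartition:
    """Receptor/ligand split of the scored atoms (disjoint, covering)."""

    receptor_indices: tuple[int, ...]
    ligand_indices: tuple[int, ...]

    def __post_init__(self):
        rec, lig = set(self.receptor_indices), set(self.ligand_indices)
        if not rec or not lig:
            raise SelectionError("both receptor and ligand must be non-empty")
        if rec & lig:
            raise SelectionError(
                f"receptor and ligand overlap on atoms {sorted(rec & lig)[:5]}"
            )
        object.__setattr__(self, "receptor_indices", tuple(sorted(rec)))
        object.__setattr__(self, "ligand_indices", tuple(sorted(lig)))

    def covers(self, n_atoms: int) -> bool:
        return set(self.receptor_indices) | set(self.ligand_indices) == set(range(n_atoms))


@dataclass
class SnapshotEnsemble:
    """Frames of coordinates for one fixed topology, with frame times."""

    system: MolecularSystem
    frames: np.ndarray          # (F, N, 3)
    time_ps: np.ndarray         # (F,)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.time_ps = np.asarray(self.time_ps, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.system.n_atoms, 3):
            raise InputError(
                f"frames have shape {self.frames.shape}, expected "
                f"(F, {self.system.n_atoms}, 3)"
            )
        if self.time_ps.shape != (self.frames.shape[0],):
            raise InputError("time_ps length must equal the frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.time_ps) > 0):
            raise InputError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


# --------------------------------------------------------------------------
# PDB input/output (Biopython behind the surface)
# --------------------------------------------------------------------------

def _scan_pdb_records(path) -> int:
    """Pre-scan for malformed ATOM/HETATM records; returns the record count.

    Biopython's strict parser raises without a line number, so coordinate
    fields are validated here first to name the offending line.
    """
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                n += 1
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(f"{path}: line {lineno}: truncated record")
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise PDBParseError(
                            f"{path}: line {lineno}: bad coordinate field "
                            f"{line[lo:hi]!r}"
                        ) from None
    return n


def _structure_from(path):
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            return parser.get_structure("system", str(path))
        except PDBConstructionException as exc:
            raise PDBParseError(f"{path}: {exc}") from exc


def _model_to_atoms(model):
    atoms, coords = [], []
    for chain in model:
        for residue in chain:
            for atom in residue:
                atoms.append(
                    Atom(
                        serial=int(atom.serial_number),
                        name=atom.get_name(),
                        residue_name=residue.get_resname().strip(),
                        residue_seq=int(residue.get_id()[1]),
                        chain=chain.get_id().strip() or "A",
                        element=(atom.element or "").strip(),
                    )
                )
                coords.append(atom.get_coord())
    return atoms, np.asarray(coords, dtype=float)


def read_pdb(path) -> MolecularSystem:
    """Read a single-model PDB file into a :class:`MolecularSystem`.

    Atoms keep file order; coordinates are in angstroms; force-field
    parameters stay unset until :func:`merge_parameters`.  For multi-model
    files only the first model is returned (use :func:`read_ensemble`).
    """
    if _scan_pdb_records(path) == 0:
        raise InputError(f"{path}: no ATOM/HETATM records")
    structure = _structure_from(path)
    model = next(structure.get_models())
    atoms, coords = _model_to_atoms(model)
    return MolecularSystem(atoms=atoms, coordinates=coords)


def read_ensemble(path, dt_ps: float = 1.0) -> SnapshotEnsemble:
    """Read a multi-model PDB as a snapshot ensemble.

    Topology comes from the first model; later models contribute only
    coordinates and must have the same atom count.  A single-model file
    yields a one-frame ensemble.  Frame times default to ``dt_ps`` spacing
    when the file carries no time metadata (PDB has none).
    """
    if _scan_pdb_records(path) == 0:
        raise InputError(f"{path}: no ATOM/HETATM records")
    structure = _structure_from(path)
    models = list(structure.get_models())
    atoms, first = _model_to_atoms(models[0])
    frames = [first]
    for m in models[1:]:
        _, coords = _model_to_atoms(m)
        if coords.shape != first.shape:
            raise InputError(
                f"{path}: model {m.get_id() + 1} has {coords.shape[0]} atoms, "
                f"expected {first.shape[0]}"
            )
        frames.append(coords)
    system = MolecularSystem(atoms=atoms, coordinates=first.copy())
    times = dt_ps * np.arange(len(frames), dtype=float)
    return SnapshotEnsemble(system=system, frames=np.stack(frames), time_ps=times)


def _format_atom_line(atom: Atom, xyz) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    return (
        f"ATOM  {atom.serial % 100000:5d} {name[:4]:<4s} "
        f"{atom.residue_name[:3]:<3s} {atom.chain[:1]:1s}"
        f"{atom.residue_seq % 10000:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element[:2]:>2s}\n"
    )


def write_pdb(obj, path) -> None:
    """Write a system (single model) or ensemble (MODEL/ENDMDL blocks).

    Fixed-width output with 3-decimal coordinates; byte-deterministic for
    a given input, which the synthetic generators rely on.
    """
    buf = io.StringIO()
    if isinstance(obj, SnapshotEnsemble):
        for k in range(obj.n_frames):
            buf.write(f"MODEL     {k + 1:4d}\n")
            for atom, xyz in zip(obj.system.atoms, obj.frames[k]):
                buf.write(_format_atom_line(atom, xyz))
            buf.write("ENDMDL\n")
    else:
        for atom, xyz in zip(obj.atoms, obj.coordinates):
            buf.write(_format_atom_line(atom, xyz))
    buf.write("END\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# --------------------------------------------------------------------------
# parameter tables
# --------------------------------------------------------------------------

_ATOM_TABLE_COLUMNS = ("residue_name", "atom_name", "charge",
                       "lj_epsilon", "lj_rmin_half", "gb_radius")


def read_parameter_table(path) -> pd.DataFrame:
    """Read the flat per-atom parameter TSV (documented schema)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _ATOM_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: parameter table lacks columns {missing}")
    return df


def merge_parameters(system: MolecularSystem, parameter_table) -> MolecularSystem:
    """Assign per-atom parameters from a table keyed by (residue, atom name).

    ``parameter_table`` is a path to the TSV schema or an equivalent
    DataFrame.  Every atom must resolve: unmatched atoms raise a
    :class:`ParameterLookupError` listing each offending (residue, atom)
    pair — there are no silent defaults.
    """
    if not isinstance(parameter_table, pd.DataFrame):
        parameter_table = read_parameter_table(parameter_table)
    key = {}
    for row in parameter_table.itertuples(index=False):
        key[(str(row.residue_name), str(row.atom_name))] = row
    atoms = []
    missing = []
    for a in system.atoms:
        row = key.get((a.residue_name, a.name))
        if row is None:
            missing.append((a.residue_name, a.name))
            continue
        eps, rad = float(row.lj_epsilon), float(row.gb_radius)
        if eps < 0 or rad <= 0:
            raise InputError(
                f"invalid parameters for ({a.residue_name}, {a.name}): "
                f"lj_epsilon={eps}, gb_radius={rad}"
            )
        atoms.append(
            replace(
                a,
                charge=float(row.charge),
                lj_epsilon=eps,
                lj_rmin_half=float(row.lj_rmin_half),
                gb_radius=rad,
            )
        )
    if missing:
        raise ParameterLookupError(sorted(set(missing)))
    return MolecularSystem(
        atoms=atoms,
        coordinates=system.coordinates.copy(),
        bonds=list(system.bonds),
        angles=list(system.angles),
        dihedrals=list(system.dihedrals),
        scale14=system.scale14,
    )


# --------------------------------------------------------------------------
# selections
# --------------------------------------------------------------------------

def _select(system: MolecularSystem, spec: str) -> set[int]:
    """Mini selection grammar: clauses joined by ``and``.

    Clauses: ``chain A`` | ``resid 5`` / ``resid 3-7`` / ``resid 1,4-6`` |
    ``resname LIG`` | ``name CA,CB`` (names accept fnmatch wildcards).
    """
    selected = set(range(system.n_atoms))
    for clause in (c.strip() for c in spec.split(" and ")):
        if not clause:
            continue
        try:
            keyword, arg = clause.split(None, 1)
        except ValueError:
            raise SelectionError(f"cannot parse selection clause {clause!r}") from None
        keyword = keyword.lower()
        if keyword == "chain":
            ok = {i for i, a in enumerate(system.atoms) if a.chain == arg.strip()}
        elif keyword == "resid":
            wanted: set[int] = set()
            for part in arg.split(","):
                part = part.strip()
                if "-" in part[1:]:
                    lo, hi = part.rsplit("-", 1)
                    wanted.update(range(int(lo), int(hi) + 1))
                else:
                    wanted.add(int(part))
            ok = {i for i, a in enumerate(system.atoms) if a.residue_seq in wanted}
        elif keyword == "resname":
            names = {n.strip() for n in arg.split(",")}
            ok = {i for i, a in enumerate(system.atoms) if a.residue_name in names}
        elif keyword == "name":
            pats = [p.strip() for p in arg.split(",")]
            ok = {
                i for i, a in enumerate(system.atoms)
                if any(fnmatch.fnmatch(a.name, p) for p in pats)
            }
        else:
            raise SelectionError(f"unknown selection keyword {keyword!r}")
        selected &= ok
    return selected


def partition_by_selection(system: MolecularSystem, ligand_spec: str) -> ComplexPartition:
    """Partition the system into ligand (matching ``ligand_spec``) and
    receptor (the complement).  Deterministic; empty ligand is an error."""
    ligand = _select(system, ligand_spec)
    if not ligand:
        raise SelectionError(f"ligand selection {ligand_spec!r} matches no atoms")
    receptor = set(range(system.n_atoms)) - ligand
    if not receptor:
        raise SelectionError(f"ligand selection {ligand_spec!r} matches every atom")
    return ComplexPartition(
        receptor_indices=tuple(sorted(receptor)),
        ligand_indices=tuple(sorted(ligand)),
    )
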