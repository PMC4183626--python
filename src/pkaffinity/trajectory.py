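"""Ensemble statistics: backbone RMSD, hydrogen-bond occupancy with
conditional distance statistics, and hydrophobic contacts.

The hydrogen-bond criterion is a donor-acceptor *heavy-atom* distance below
3.5 A, with no angle term — weaker than DSSP-style geometric definitions,
but it is the criterion the occupancy tables are defined by.  Two different
denominators are used deliberately: occupancy is a percentage of *all*
frames, while the mean +/- SD distance is computed over the qualifying
frames only.  An interaction is called stable when its occupancy is at
least 50%.  Hydrophobic contacts use the same machinery with a 4.5 A
carbon-carbon cutoff.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import InputError, NumericalError, SelectionError
from .structure import Atom, ComplexPartition, MolecularSystem, SnapshotEnsemble

__all__ = [
    "HBondStat",
    "ContactStat",
    "superpose",
    "rmsd_series",
    "hbond_occupancy",
    "stable_interactions",
    "hydrophobic_contacts",
    "enumerate_candidate_pairs",
    "load_hbond_chemistry",
    "atom_roles",
    "stats_frame",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")
HB_CUTOFF_A = 3.5
CONTACT_CUTOFF_A = 4.5
STABILITY_THRESHOLD_PCT = 50.0


@dataclass(frozen=True)
class HBondStat:
    """Occupancy and conditional distance statistics for one donor-acceptor
    pair.  ``mean_distance``/``sd_distance`` are None when the pair never
    qualifies; ``over_cutoff_mean`` flags the pathological case of a mean
    distance above the cutoff (possible only when statistics are requested
    over all frames rather than qualifying ones — recomputed here they
    cannot occur, and the flag records that)."""

    donor: str
    acceptor: str
    donor_index: int
    acceptor_index: int
    occupancy_pct: float
    mean_distance: float | None
    sd_distance: float | None

    @property
    def over_cutoff_mean(self) -> bool:
        return self.mean_distance is not None and self.mean_distance >= HB_CUTOFF_A


@dataclass(frozen=True)
class ContactStat:
    atom_a: str
    atom_b: str
    index_a: int
    index_b: int
    occupancy_pct: float
    mean_distance: float | None
    sd_distance: float | None


# --------------------------------------------------------------------------
# superposition and RMSD
# --------------------------------------------------------------------------

def superpose(mobile_coords, reference_coords, fit_indices=None):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd_fit)`` where
    ``x' = x @ rotation.T + translation`` maps mobile onto the reference
    frame.  The rotation is proper (det = +1).  Degenerate fits (< 3 atoms,
    or all fit atoms collinear) raise :class:`NumericalError`.
    """
    mob = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    if mob.shape != ref.shape:
        raise InputError("mobile and reference coordinate shapes differ")
    if fit_indices is not None:
        idx = np.asarray(fit_indices, dtype=int)
        mob_fit, ref_fit = mob[idx], ref[idx]
    else:
        mob_fit, ref_fit = mob, ref
    n = mob_fit.shape[0]
    if n < 3:
        raise NumericalError("superposition needs at least 3 fit atoms")
    mob_c = mob_fit - mob_fit.mean(axis=0)
    ref_c = ref_fit - ref_fit.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise NumericalError("fit atoms are collinear; rotation is undefined")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    rmsd_fit = float(rssd) / np.sqrt(n)
    rotation = rot.as_matrix()
    translation = ref_fit.mean(axis=0) - mob_fit.mean(axis=0) @ rotation.T
    return rotation, translation, rmsd_fit


def _selection_indices(system: MolecularSystem, selection) -> np.ndarray:
    if isinstance(selection, str):
        if selection == "backbone":
            idx = [i for i, a in enumerate(system.atoms) if a.name in BACKBONE_NAMES]
        elif selection == "all":
            idx = list(range(system.n_atoms))
        else:
            names = [s.strip() for s in selection.split(",")]
            idx = [i for i, a in enumerate(system.atoms) if a.name in names]
    else:
        idx = [int(i) for i in selection]
    if not idx:
        raise SelectionError(f"selection {selection!r} matches no atoms")
    return np.asarray(idx, dtype=int)


def rmsd_series(ensemble: SnapshotEnsemble, reference_frame: int = 0,
                selection="backbone") -> np.ndarray:
    """Per-frame RMSD (A) after superposition on the same selection.

    ``reference_frame`` defaults to the first frame; pass the first
    post-equilibration frame index to discard the equilibration span.
    """
    idx = _selection_indices(ensemble.system, selection)
    ref = ensemble.frames[int(reference_frame)]
    out = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        _, _, out[f] = superpose(ensemble.frames[f], ref, fit_indices=idx)
    return out


# --------------------------------------------------------------------------
# occupancy machinery
# --------------------------------------------------------------------------

def _pair_distances(ensemble: SnapshotEnsemble, pairs: np.ndarray) -> np.ndarray:
    """(F, P) distance matrix for index pairs across all frames."""
    a = ensemble.frames[:, pairs[:, 0], :]
    b = ensemble.frames[:, pairs[:, 1], :]
    return np.linalg.norm(a - b, axis=-1)


def _occupancy_stats(dists: np.ndarray, cutoff: float):
    """Occupancy over all frames; mean/sd over qualifying frames only
    (population SD, ddof=0)."""
    inside = dists < cutoff
    n_frames = dists.shape[0]
    occ = 100.0 * inside.sum(axis=0) / n_frames
    means, sds = [], []
    for p in range(dists.shape[1]):
        q = dists[inside[:, p], p]
        if q.size:
            means.append(float(q.mean()))
            sds.append(float(q.std(ddof=0)))
        else:
            means.append(None)
            sds.append(None)
    return occ, means, sds


def hbond_occupancy(ensemble: SnapshotEnsemble, candidate_pairs,
                    cutoff: float = HB_CUTOFF_A) -> list[HBondStat]:
    """Occupancy statistics for (donor, acceptor) heavy-atom index pairs.

    occupancy = 100 x (#frames with d < cutoff) / (#frames); the
    conditional mean and SD use qualifying frames only.
    """
    if ensemble.n_frames == 0:
        raise InputError("ensemble has no frames")
    pairs = np.asarray(list(candidate_pairs), dtype=int)
    if pairs.size == 0:
        return []
    dists = _pair_distances(ensemble, pairs)
    occ, means, sds = _occupancy_stats(dists, cutoff)
    atoms = ensemble.system.atoms
    return [
        HBondStat(
            donor=atoms[i].label,
            acceptor=atoms[j].label,
            donor_index=int(i),
            acceptor_index=int(j),
            occupancy_pct=float(o),
            mean_distance=m,
            sd_distance=s,
        )
        for (i, j), o, m, s in zip(pairs, occ, means, sds)
    ]


def stable_interactions(stats, threshold: float = STABILITY_THRESHOLD_PCT):
    """Keep statistics with occupancy >= threshold, ordered by
    (donor, acceptor) labels for deterministic reports."""
    kept = [s for s in stats if s.occupancy_pct >= threshold]
    key = (lambda s: (s.donor, s.acceptor)) if stats and isinstance(stats[0], HBondStat) \
        else (lambda s: (s.atom_a, s.atom_b))
    return sorted(kept, key=key)


def hydrophobic_contacts(ensemble: SnapshotEnsemble, carbon_pairs,
                         cutoff: float = CONTACT_CUTOFF_A,
                         stability_threshold: float = STABILITY_THRESHOLD_PCT,
                         ) -> list[ContactStat]:
    """Stable carbon-carbon contact statistics (same occupancy machinery,
    4.5 A cutoff, stability filter applied)."""
    if ensemble.n_frames == 0:
        raise InputError("ensemble has no frames")
    pairs = np.asarray(list(carbon_pairs), dtype=int)
    if pairs.size == 0:
        return []
    atoms = ensemble.system.atoms
    for i, j in pairs:
        for k in (i, j):
            if atoms[k].element != "C":
                raise InputError(
                    f"hydrophobic contact atom {atoms[k].label} is not carbon"
                )
    dists = _pair_distances(ensemble, pairs)
    occ, means, sds = _occupancy_stats(dists, cutoff)
    stats = [
        ContactStat(
            atom_a=atoms[i].label,
            atom_b=atoms[j].label,
            index_a=int(i),
            index_b=int(j),
            occupancy_pct=float(o),
            mean_distance=m,
            sd_distance=s,
        )
        for (i, j), o, m, s in zip(pairs, occ, means, sds)
    ]
    return stable_interactions(stats, stability_threshold)


# --------------------------------------------------------------------------
# donor/acceptor chemistry and candidate enumeration
# --------------------------------------------------------------------------

def load_hbond_chemistry(path=None) -> pd.DataFrame:
    """Load the editable donor/acceptor role table (packaged default)."""
    if path is None:
        with resources.as_file(
            resources.files("pkaffinity.data") / "hbond_chemistry.tsv"
        ) as p:
            return pd.read_csv(p, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")


def atom_roles(atom: Atom, chemistry: pd.DataFrame) -> set[str]:
    """Roles ('donor'/'acceptor') for a heavy atom; first matching row of
    the chemistry table wins.  Hydrogens never match."""
    if atom.element == "H":
        return set()
    for row in chemistry.itertuples(index=False):
        if fnmatch.fnmatch(atom.residue_name, str(row.residue_name)) and \
                fnmatch.fnmatch(atom.name, str(row.atom_name)):
            role = str(row.role)
            return {"donor", "acceptor"} if role == "both" else {role}
    return set()


def enumerate_candidate_pairs(system: MolecularSystem,
                              partition: ComplexPartition,
                              max_distance: float,
                              ensemble: SnapshotEnsemble | None = None,
                              stride: int = 1,
                              kind: str = "hbond",
                              chemistry: pd.DataFrame | None = None):
    """Receptor-ligand candidate pairs within ``max_distance`` in any
    scanned frame (pre-screen that avoids all-vs-all over every frame).

    For ``kind='hbond'`` the pairs are chemically plausible (donor,
    acceptor) ordered tuples in both directions across the interface; for
    ``kind='contact'`` they are unordered carbon-carbon pairs.  With
    ``stride=1`` the result is a strict superset of every pair that
    qualifies at any cutoff <= max_distance; with stride > 1 a frame
    subsample is scanned and the superset guarantee holds only for pairs
    within max_distance in the scanned frames — pass a margin above the
    analysis cutoff accordingly.
    """
    if kind not in ("hbond", "contact"):
        raise InputError(f"unknown candidate kind {kind!r}")
    frames = (ensemble.frames[::max(1, int(stride))]
              if ensemble is not None else system.coordinates[None, :, :])
    rec = np.asarray(partition.receptor_indices, dtype=int)
    lig = np.asarray(partition.ligand_indices, dtype=int)
    atoms = system.atoms
    if kind == "hbond":
        if chemistry is None:
            chemistry = load_hbond_chemistry()
        roles = {i: atom_roles(atoms[i], chemistry) for i in (*rec, *lig)}
        rec = np.asarray([i for i in rec if roles[i]], dtype=int)
        lig = np.asarray([i for i in lig if roles[i]], dtype=int)
    else:
        rec = np.asarray([i for i in rec if atoms[i].element == "C"], dtype=int)
        lig = np.asarray([i for i in lig if atoms[i].element == "C"], dtype=int)
    if rec.size == 0 or lig.size == 0:
        return []
    # min over scanned frames of receptor-ligand distances
    dmin = np.full((rec.size, lig.size), np.inf)
    for frame in frames:
        d = np.linalg.norm(frame[rec][:, None, :] - frame[lig][None, :, :], axis=-1)
        dmin = np.minimum(dmin, d)
    pairs = []
    for a, b in zip(*np.nonzero(dmin <= max_distance)):
        i, j = int(rec[a]), int(lig[b])
        if kind == "contact":
            pairs.append((min(i, j), max(i, j)))
        else:
            if "donor" in roles[i] and "acceptor" in roles[j]:
                pairs.append((i, j))
            if "donor" in roles[j] and "acceptor" in roles[i] and i != j:
                pairs.append((j, i))
    return sorted(set(pairs))


# --------------------------------------------------------------------------
# tabular output
# --------------------------------------------------------------------------

def stats_frame(stats) -> pd.DataFrame:
    """Flatten HBondStat/ContactStat lists into the report table."""
    rows = []
    for s in stats:
        if isinstance(s, HBondStat):
            a, b = s.donor, s.acceptor
        else:
            a, b = s.atom_a, s.atom_b
        rows.append(
            {
                "donor": a,
                "acceptor": b,
                "occupancy_pct": s.occupancy_pct,
                "mean_distance_A": s.mean_distance,
                "sd_distance_A": s.sd_distance,
            }
        )
    return pd.DataFrame(rows, columns=["donor", "acceptor", "occupancy_pct",
                                       "mean_distance_A", "sd_distance_A"])
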