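"""Hydrogen-bond and salt-bridge detection and occupancy statistics.

A contact is a geometric predicate evaluated per frame; its *occupancy* (or
occurrence) is the percentage of frames in which it holds, reported per MD
replica and for the merged pool.  Because "averaged over the two replicas"
is ambiguous for unequal replica lengths, the table carries both the
pooled-frame percentage (``merged``, the frame-weighted mean) and the plain
mean of the replica percentages (``replica_mean``).

Default geometric criteria (configurable): H-bond donor-acceptor heavy-atom
distance <= 3.5 Å and, when hydrogen positions are available, D-H...A angle
>= 120 deg, both inclusive; salt bridge side-chain N...O minimum distance
<= 4.0 Å, inclusive.  Candidate salt-bridge pairs are restricted to charged
residues with a heavy atom within a selection cutoff (10 Å by default) of
the ligand, and rows occurring in less than a threshold fraction of the
simulation (10% by default) can be filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .system import LIGAND, MolecularSystem, Trajectory

#: residue names treated as carrying a side-chain formal charge.  Histidine
#: is neutral unless explicitly protonated (HIP/HSP naming).
ANION_RESIDUES = {"ASP", "GLU"}
CATION_RESIDUES = {"LYS", "ARG", "HIP", "HSP"}
ANION_SIDECHAIN_O = {"OD1", "OD2", "OE1", "OE2"}
CATION_SIDECHAIN_N = {"NZ", "NH1", "NH2", "NE", "ND1", "NE2"}


@dataclass(frozen=True)
class ContactDefinition:
    """A donor/acceptor (or cation/anion) atom-group contact."""

    kind: str                      # "hbond" | "saltbridge"
    donor_atoms: tuple[int, ...]   # donor atom / cation-group indices
    acceptor_atoms: tuple[int, ...]  # acceptor atom / anion-group indices
    label: str
    hydrogen_atom: int | None = None  # for the D-H...A angle criterion

    def __post_init__(self):
        if set(self.donor_atoms) & set(self.acceptor_atoms):
            raise ValueError("donor and acceptor groups must be disjoint")
        if not self.donor_atoms or not self.acceptor_atoms:
            raise ValueError("empty contact group")


@dataclass(frozen=True)
class HBondCriteria:
    d_max: float = 3.5          # donor-acceptor heavy-atom distance, Å
    angle_min: float = 120.0    # D-H...A angle, degrees
    use_angle: bool = True


@dataclass(frozen=True)
class SaltBridgeCriteria:
    d_max: float = 4.0          # min side-chain N...O distance, Å


@dataclass
class OccupancyTable:
    """Contact occupancies (in %) per replica and merged."""

    contacts: list[ContactDefinition]
    replica_ids: list[int]
    per_replica: np.ndarray      # (n_contacts, n_replicas), %
    merged: np.ndarray           # pooled-frame %, frame-weighted mean
    replica_mean: np.ndarray     # plain mean of replica %
    frames_per_replica: np.ndarray
    n_frames: int

    def to_dataframe(self) -> pd.DataFrame:
        data = {"label": [c.label for c in self.contacts]}
        for j, rep in enumerate(self.replica_ids):
            data[f"replica{rep}_%"] = np.round(self.per_replica[:, j], 4)
        data["merged_%"] = np.round(self.merged, 4)
        data["replica_mean_%"] = np.round(self.replica_mean, 4)
        data["n_frames"] = self.n_frames
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Per-frame detection

def _group_min_distance(frame: np.ndarray, a: tuple[int, ...],
                        b: tuple[int, ...]) -> float:
    pa = frame[list(a)]
    pb = frame[list(b)]
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return float(d.min())


def detect_hbond(
    frame: np.ndarray,
    contact: ContactDefinition,
    criteria: HBondCriteria = HBondCriteria(),
) -> bool:
    """True iff the donor-acceptor distance (and, if enabled, the D-H...A
    angle) satisfies the criteria in this frame.  Boundaries are inclusive."""
    d = _group_min_distance(frame, contact.donor_atoms, contact.acceptor_atoms)
    if d > criteria.d_max:
        return False
    if criteria.use_angle:
        if contact.hydrogen_atom is None:
            raise ValueError(
                f"angle criterion enabled but contact {contact.label!r} "
                f"(donor atoms {contact.donor_atoms}) has no hydrogen"
            )
        h = frame[contact.hydrogen_atom]
        v1 = frame[contact.donor_atoms[0]] - h
        v2 = frame[contact.acceptor_atoms[0]] - h
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle < criteria.angle_min:
            return False
    return True


def _contact_present_series(
    traj: Trajectory, contact: ContactDefinition, d_max: float,
    angle_min: float | None, hydrogen: int | None,
) -> np.ndarray:
    """Boolean per-frame presence of one contact (vectorized over frames)."""
    coords = traj.coords
    pa = coords[:, list(contact.donor_atoms), :]
    pb = coords[:, list(contact.acceptor_atoms), :]
    d = np.linalg.norm(pa[:, :, None, :] - pb[:, None, :, :], axis=-1)
    present = d.min(axis=(1, 2)) <= d_max
    if angle_min is not None:
        if hydrogen is None:
            raise ValueError(
                f"angle criterion enabled but contact {contact.label!r} "
                f"(donor atoms {contact.donor_atoms}) has no hydrogen"
            )
        h = coords[:, hydrogen, :]
        v1 = coords[:, contact.donor_atoms[0], :] - h
        v2 = coords[:, contact.acceptor_atoms[0], :] - h
        cosang = np.sum(v1 * v2, axis=-1) / (
            np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        present &= ang >= angle_min
    return present


def _occupancy_table(
    traj: Trajectory,
    contacts: list[ContactDefinition],
    d_max: float,
    angle_min: float | None = None,
) -> OccupancyTable:
    replicas = traj.replicas()
    n_c = len(contacts)
    per_rep = np.zeros((n_c, len(replicas)))
    merged = np.zeros(n_c)
    for i, c in enumerate(contacts):
        present = _contact_present_series(
            traj, c, d_max, angle_min, c.hydrogen_atom
        )
        merged[i] = 100.0 * present.mean()
        for j, rep in enumerate(replicas):
            sel = traj.replica_ids == rep
            per_rep[i, j] = 100.0 * present[sel].mean()
    frames_per_rep = np.array(
        [int((traj.replica_ids == r).sum()) for r in replicas]
    )
    return OccupancyTable(
        contacts=list(contacts),
        replica_ids=replicas,
        per_replica=per_rep,
        merged=merged,
        replica_mean=per_rep.mean(axis=1),
        frames_per_replica=frames_per_rep,
        n_frames=traj.n_frames,
    )


def hbond_occupancy(
    traj: Trajectory,
    contacts: list[ContactDefinition],
    criteria: HBondCriteria = HBondCriteria(),
) -> OccupancyTable:
    """Occupancy (in %) of each H-bond, per replica and merged.

    No occurrence filter is applied: rows with 0% are retained.
    """
    if not contacts:
        raise ValueError("no contacts given")
    angle = criteria.angle_min if criteria.use_angle else None
    return _occupancy_table(traj, contacts, criteria.d_max, angle)


# ---------------------------------------------------------------------------
# Salt bridges

def _charged_groups(system: MolecularSystem):
    """(residue_key, kind, heavy-atom indices, charged-group indices)."""
    res_index = system.atom_residue_indices()
    table = system.residue_table()
    heavy = np.array([str(e).upper() != "H" for e in system.elements])
    groups = []
    for k, (chain, rid, rname) in enumerate(table):
        atoms = np.flatnonzero(res_index == k)
        is_ligand = (system.molecule_labels[atoms] == LIGAND).all()
        if is_ligand:
            # the ligand's protonated amine: heavy N atoms carrying the
            # formal positive charge (partial charge >= +0.5 e)
            grp = [
                int(i) for i in atoms
                if heavy[i] and str(system.elements[i]).upper() == "N"
                and system.charges[i] >= 0.5
            ]
            if grp:
                groups.append(((chain, rid, rname), "cation", atoms, grp))
            continue
        if rname in ANION_RESIDUES:
            grp = [int(i) for i in atoms if system.names[i] in ANION_SIDECHAIN_O]
            if grp:
                groups.append(((chain, rid, rname), "anion", atoms, grp))
        elif rname in CATION_RESIDUES:
            grp = [int(i) for i in atoms if system.names[i] in CATION_SIDECHAIN_N]
            if grp:
                groups.append(((chain, rid, rname), "cation", atoms, grp))
    return groups, heavy


def ligand_proximal_residue_pairs(
    system: MolecularSystem,
    frame: np.ndarray,
    cutoff: float = 10.0,
) -> list[ContactDefinition]:
    """Candidate salt-bridge pairs among charged residues near the ligand.

    A residue qualifies when any of its heavy atoms lies within ``cutoff``
    of any ligand heavy atom in the supplied frame; all (cation, anion)
    combinations of qualifying groups (including the ligand's protonated
    amine) are returned.  An empty list is not an error.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    frame = np.asarray(frame, float)
    groups, heavy = _charged_groups(system)
    lig_heavy = [
        int(i) for i in system.ligand_indices() if heavy[i]
    ]
    if not lig_heavy:
        return []
    lig_pos = frame[lig_heavy]

    near = []
    for key, kind, atoms, grp in groups:
        res_heavy = [int(i) for i in atoms if heavy[i]]
        d = np.linalg.norm(
            frame[res_heavy][:, None, :] - lig_pos[None, :, :], axis=-1
        )
        if d.min() <= cutoff:
            near.append((key, kind, grp))

    def _tag(key):
        chain, rid, rname = key
        return f"{rname}{rid}"

    pairs = []
    for key_c, kind_c, grp_c in near:
        if kind_c != "cation":
            continue
        for key_a, kind_a, grp_a in near:
            if kind_a != "anion" or key_a == key_c:
                continue
            pairs.append(
                ContactDefinition(
                    kind="saltbridge",
                    donor_atoms=tuple(grp_c),
                    acceptor_atoms=tuple(grp_a),
                    label=f"{_tag(key_c)}-{_tag(key_a)}",
                )
            )
    return pairs


def salt_bridge_occupancy(
    traj: Trajectory,
    pairs: list[ContactDefinition],
    criteria: SaltBridgeCriteria = SaltBridgeCriteria(),
    min_occupancy_pct: float = 10.0,
) -> OccupancyTable:
    """Salt-bridge occupancies with a minimum-occurrence filter.

    A bridge is present in a frame when the minimum distance between any
    side-chain N of the cation group and any side-chain O of the anion
    group is <= ``criteria.d_max`` (inclusive).  Rows whose merged
    (pooled-frame) occupancy falls below ``min_occupancy_pct`` are removed.
    """
    if not 0.0 <= min_occupancy_pct <= 100.0:
        raise ValueError("min_occupancy_pct must lie in [0, 100]")
    table = _occupancy_table(traj, pairs, criteria.d_max, angle_min=None)
    keep = np.flatnonzero(table.merged >= min_occupancy_pct)
    return OccupancyTable(
        contacts=[table.contacts[i] for i in keep],
        replica_ids=table.replica_ids,
        per_replica=table.per_replica[keep],
        merged=table.merged[keep],
        replica_mean=table.replica_mean[keep],
        frames_per_replica=table.frames_per_replica,
        n_frames=table.n_frames,
    )
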