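"""Fast random-reference RMSD clustering and representative selection.

The scheme has two phases.  Phase 1 picks a random still-unbinned frame as a
reference and bins every unbinned frame whose (Kabsch-fitted) RMSD to it is
strictly below the cutoff; this repeats until no frames remain, so the
number of references is data-driven.  Phase 2 reassigns every frame of the
pool to its nearest reference, with no cutoff.  On a pool concatenated from
several receptor forms ("sections"), the per-section membership counts
identify, for each form, the reference structure that represents it best —
the frame used as that form's representative conformation.

Randomness is confined to the Phase-1 draw order and is fully determined by
the seed; ties (equal RMSD, equal counts) resolve to the lowest reference
index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import rmsd_to_reference
from .system import SelectionMask, Trajectory


@dataclass(frozen=True)
class ClusterAssignment:
    reference_frames: np.ndarray  # frame indices, in draw order
    membership: np.ndarray        # per frame: index into reference_frames
    cutoff: float                 # Å, Phase-1 binning radius
    seed: int


@dataclass(frozen=True)
class SectionRepresentation:
    sections: list[str]
    counts: np.ndarray            # (n_references, n_sections)
    most_represented: dict        # section -> reference index


def fast_reference_clustering(
    traj: Trajectory,
    mask: SelectionMask,
    cutoff: float,
    seed: int,
) -> ClusterAssignment:
    """Two-phase random-reference clustering of a trajectory.

    Phase 1 draws references uniformly from the unbinned frames and bins
    frames with RMSD < cutoff; Phase 2 assigns every frame to its nearest
    reference regardless of distance.  Deterministic given ``seed``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if len(mask) == 0:
        raise ValueError("empty selection mask")
    n = traj.n_frames
    if n == 0:
        raise ValueError("empty trajectory")

    rng = np.random.default_rng(seed)
    unbinned = np.ones(n, dtype=bool)
    references: list[int] = []
    while unbinned.any():
        pool = np.flatnonzero(unbinned)
        ref = int(pool[rng.integers(len(pool))])
        references.append(ref)
        d = rmsd_to_reference(
            traj.coords[pool], traj.coords[ref], fit_mask=mask,
            measure_mask=mask,
        )
        unbinned[pool[d < cutoff]] = False
        unbinned[ref] = False  # guard: the reference always leaves the pool

    refs = np.asarray(references, dtype=int)
    dists = np.stack(
        [
            rmsd_to_reference(traj.coords, traj.coords[r], fit_mask=mask,
                              measure_mask=mask)
            for r in refs
        ],
        axis=0,
    )  # (n_refs, n_frames)
    membership = np.argmin(dists, axis=0)  # first minimum = lowest ref index
    return ClusterAssignment(refs, membership, float(cutoff), int(seed))


def reassign(traj: Trajectory, mask: SelectionMask,
             assignment: ClusterAssignment) -> np.ndarray:
    """Nearest-reference membership recomputed from scratch (Phase 2 only)."""
    dists = np.stack(
        [
            rmsd_to_reference(traj.coords, traj.coords[r], fit_mask=mask,
                              measure_mask=mask)
            for r in assignment.reference_frames
        ],
        axis=0,
    )
    return np.argmin(dists, axis=0)


def section_representation(
    assignment: ClusterAssignment, traj: Trajectory
) -> SectionRepresentation:
    """Membership counts of each reference within each trajectory section."""
    if len(assignment.membership) != traj.n_frames:
        raise ValueError("assignment/trajectory length mismatch")
    sections = traj.sections()
    n_refs = len(assignment.reference_frames)
    counts = np.zeros((n_refs, len(sections)), dtype=int)
    for s_idx, s in enumerate(sections):
        members = assignment.membership[traj.section_frames(s)]
        counts[:, s_idx] = np.bincount(members, minlength=n_refs)
    most = {
        s: int(np.argmax(counts[:, k])) for k, s in enumerate(sections)
    }
    return SectionRepresentation(sections, counts, most)


def select_representative(
    assignment: ClusterAssignment,
    representation: SectionRepresentation,
    target_section: str,
) -> int:
    """Frame index of the reference most represented in ``target_section``."""
    if target_section not in representation.most_represented:
        raise KeyError(f"unknown section {target_section!r}")
    k = representation.sections.index(target_section)
    if representation.counts[:, k].sum() == 0:
        raise ValueError(f"section {target_section!r} is empty")
    ref_idx = representation.most_represented[target_section]
    return int(assignment.reference_frames[ref_idx])
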