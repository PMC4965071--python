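"""Core containers: atoms, molecular systems, trajectories and atom selections.

A :class:`MolecularSystem` stores one receptor-ligand complex as parallel
numpy arrays (struct-of-arrays), with per-atom nonbonded parameters
(partial charge, 12-6 Lennard-Jones well depth and r_min/2, Poisson-Boltzmann
radius).  Parameters default to NaN, the "unset" sentinel, until a parameter
table is applied.  A :class:`Trajectory` is an ordered stack of coordinate
frames for that system, with per-frame replica and section labels so that
several MD replicas of several receptor forms can be concatenated into one
analysis pool.

Units: coordinates and radii in Å, charges in elementary charges, energies
downstream in kcal/mol, frame spacing in ps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

RECEPTOR = "receptor"
LIGAND = "ligand"

#: backbone atom names used for fitting masks
BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, coordinates and nonbonded parameters."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    coordinates: tuple[float, float, float]
    partial_charge: float = np.nan
    lj_epsilon: float = np.nan
    lj_rmin_half: float = np.nan
    pb_radius: float = np.nan
    molecule_label: str = RECEPTOR


class MolecularSystem:
    """A receptor-ligand complex as parallel per-atom arrays.

    Atom order is the canonical order: every frame of an associated
    :class:`Trajectory` must list its coordinates in this order.
    """

    def __init__(
        self,
        serials: Sequence[int],
        names: Sequence[str],
        elements: Sequence[str],
        res_names: Sequence[str],
        res_ids: Sequence[int],
        chain_ids: Sequence[str],
        coords: np.ndarray,
        charges: np.ndarray | None = None,
        lj_epsilon: np.ndarray | None = None,
        lj_rmin_half: np.ndarray | None = None,
        pb_radius: np.ndarray | None = None,
        molecule_labels: Sequence[str] | None = None,
    ):
        n = len(names)
        if n == 0:
            raise ValueError("no atoms")
        self.serials = np.asarray(serials, dtype=int)
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.res_names = np.asarray(res_names, dtype=object)
        self.res_ids = np.asarray(res_ids, dtype=int)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

        def _param(x):
            return np.full(n, np.nan) if x is None else np.asarray(x, dtype=float)

        self.charges = _param(charges)
        self.lj_epsilon = _param(lj_epsilon)
        self.lj_rmin_half = _param(lj_rmin_half)
        self.pb_radius = _param(pb_radius)
        if molecule_labels is None:
            molecule_labels = [RECEPTOR] * n
        self.molecule_labels = np.asarray(molecule_labels, dtype=object)
        for arr in (self.serials, self.elements, self.res_names, self.res_ids,
                    self.chain_ids, self.charges, self.lj_epsilon,
                    self.lj_rmin_half, self.pb_radius, self.molecule_labels):
            if len(arr) != n:
                raise ValueError("per-atom arrays have inconsistent lengths")

    # -- construction -------------------------------------------------

    @classmethod
    def from_atoms(cls, atoms: Iterable[AtomRecord]) -> "MolecularSystem":
        atoms = list(atoms)
        if not atoms:
            raise ValueError("no atoms")
        return cls(
            serials=[a.serial for a in atoms],
            names=[a.name for a in atoms],
            elements=[a.element for a in atoms],
            res_names=[a.residue_name for a in atoms],
            res_ids=[a.residue_index for a in atoms],
            chain_ids=[a.chain_id for a in atoms],
            coords=np.array([a.coordinates for a in atoms], dtype=float),
            charges=[a.partial_charge for a in atoms],
            lj_epsilon=[a.lj_epsilon for a in atoms],
            lj_rmin_half=[a.lj_rmin_half for a in atoms],
            pb_radius=[a.pb_radius for a in atoms],
            molecule_labels=[a.molecule_label for a in atoms],
        )

    # -- basic queries -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serials[i]), name=self.names[i],
            element=self.elements[i], residue_name=self.res_names[i],
            residue_index=int(self.res_ids[i]), chain_id=self.chain_ids[i],
            coordinates=tuple(self.coords[i]),
            partial_charge=float(self.charges[i]),
            lj_epsilon=float(self.lj_epsilon[i]),
            lj_rmin_half=float(self.lj_rmin_half[i]),
            pb_radius=float(self.pb_radius[i]),
            molecule_label=self.molecule_labels[i],
        )

    def residue_table(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, residue_index, residue_name) triples."""
        seen: dict[tuple[str, int, str], None] = {}
        for c, r, n in zip(self.chain_ids, self.res_ids, self.res_names):
            seen.setdefault((c, int(r), n))
        return list(seen)

    def atom_residue_indices(self) -> np.ndarray:
        """Per-atom index into :meth:`residue_table`."""
        table = {key: k for k, key in enumerate(self.residue_table())}
        return np.array(
            [table[(c, int(r), n)]
             for c, r, n in zip(self.chain_ids, self.res_ids, self.res_names)],
            dtype=int,
        )

    def net_charge(self) -> float:
        return float(np.nansum(self.charges))

    def has_unset_parameters(self) -> bool:
        return bool(
            np.isnan(self.charges).any()
            or np.isnan(self.lj_epsilon).any()
            or np.isnan(self.lj_rmin_half).any()
            or np.isnan(self.pb_radius).any()
        )

    # -- selections ----------------------------------------------------

    def subset(self, indices: np.ndarray) -> "MolecularSystem":
        idx = np.asarray(indices, dtype=int)
        return MolecularSystem(
            self.serials[idx], self.names[idx], self.elements[idx],
            self.res_names[idx], self.res_ids[idx], self.chain_ids[idx],
            self.coords[idx], self.charges[idx], self.lj_epsilon[idx],
            self.lj_rmin_half[idx], self.pb_radius[idx],
            self.molecule_labels[idx],
        )

    def with_coords(self, coords: np.ndarray) -> "MolecularSystem":
        out = self.subset(np.arange(self.n_atoms))
        out.coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        return out

    def ligand_indices(self) -> np.ndarray:
        return np.flatnonzero(self.molecule_labels == LIGAND)

    def receptor_indices(self) -> np.ndarray:
        return np.flatnonzero(self.molecule_labels == RECEPTOR)


@dataclass(frozen=True)
class SelectionMask:
    """Sorted, unique 0-based atom indices into a MolecularSystem."""

    atom_indices: np.ndarray

    def __post_init__(self):
        idx = np.unique(np.asarray(self.atom_indices, dtype=int))
        object.__setattr__(self, "atom_indices", idx)

    def validate(self, system: MolecularSystem) -> None:
        if len(self.atom_indices) and (
            self.atom_indices[0] < 0 or self.atom_indices[-1] >= system.n_atoms
        ):
            raise IndexError("selection index out of range")

    def __len__(self) -> int:
        return len(self.atom_indices)


def backbone_mask(system: MolecularSystem) -> SelectionMask:
    """Protein backbone (N, CA, C, O) atoms of the receptor."""
    sel = np.flatnonzero(
        np.isin(system.names, BACKBONE_NAMES)
        & (system.molecule_labels == RECEPTOR)
    )
    return SelectionMask(sel)


def calpha_mask(system: MolecularSystem) -> SelectionMask:
    sel = np.flatnonzero(
        (system.names == "CA") & (system.molecule_labels == RECEPTOR)
    )
    return SelectionMask(sel)


def ligand_mask(system: MolecularSystem) -> SelectionMask:
    return SelectionMask(system.ligand_indices())


def all_atom_mask(system: MolecularSystem) -> SelectionMask:
    return SelectionMask(np.arange(system.n_atoms))


class Trajectory:
    """Ordered coordinate frames with replica and section bookkeeping.

    ``section_ids`` labels which system/form a frame belongs to in a
    concatenated pool; section blocks must be contiguous.  Within a replica,
    frame i is at time ``i * frame_spacing`` ps.
    """

    def __init__(
        self,
        coords: np.ndarray,
        frame_spacing: float,
        replica_ids: Sequence[int] | None = None,
        section_ids: Sequence[str] | None = None,
    ):
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if frame_spacing <= 0:
            raise ValueError("frame_spacing must be > 0")
        self.frame_spacing = float(frame_spacing)
        n = self.coords.shape[0]
        if replica_ids is None:
            replica_ids = np.zeros(n, dtype=int)
        if section_ids is None:
            section_ids = np.array(["all"] * n, dtype=object)
        self.replica_ids = np.asarray(replica_ids, dtype=int)
        self.section_ids = np.asarray(section_ids, dtype=object)
        if len(self.replica_ids) != n or len(self.section_ids) != n:
            raise ValueError("per-frame labels must match frame count")
        self._check_contiguous_sections()

    def _check_contiguous_sections(self) -> None:
        seen: set[str] = set()
        prev = None
        for s in self.section_ids:
            if s != prev:
                if s in seen:
                    raise ValueError(f"section {s!r} is not contiguous")
                seen.add(s)
                prev = s

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def sections(self) -> list[str]:
        """Section labels in order of first appearance."""
        out: list[str] = []
        for s in self.section_ids:
            if not out or out[-1] != s:
                out.append(s)
        return out

    def section_frames(self, section: str) -> np.ndarray:
        return np.flatnonzero(self.section_ids == section)

    def replicas(self) -> list[int]:
        out: list[int] = []
        for r in self.replica_ids:
            if int(r) not in out:
                out.append(int(r))
        return out
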