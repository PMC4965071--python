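"""Structure, trajectory and parameter-table I/O.

Structures are exchanged as PDB v3.3 fixed-width text; trajectories as the
multi-model dialect of the same format (``MODEL``/``ENDMDL`` blocks, one
frame per model, identical atom order in every model), so that fixtures stay
diffable.  Parsing and formatting of the fixed-width records is delegated to
:mod:`biotite`; this module adds the bookkeeping the analysis layer relies
on (receptor/ligand labelling, sentinel nonbonded parameters, per-model
atom-count validation, replica concatenation with equilibration discard).

Nonbonded parameters travel separately as a tab-separated table with header
``residue_name atom_name charge_e epsilon_kcal rmin_half_A pb_radius_A``
(a desk-scale stand-in for a force-field assignment).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .system import LIGAND, RECEPTOR, MolecularSystem, Trajectory

_SPACING_REMARK = "REMARK 250 FRAME_SPACING_PS"


class PDBParseError(ValueError):
    pass


def _first_malformed_line(path: str) -> tuple[int, str] | None:
    """Locate the first ATOM/HETATM record whose fixed-width numeric
    fields do not parse; returns (1-based line number, line)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            try:
                int(line[6:11])
                int(line[22:26])
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except (ValueError, IndexError):
                return lineno, line.rstrip("\n")
    return None


def _infer_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_pdb(
    path: str,
    ligand_resnames: tuple[str, ...] | None = None,
    ligand_chains: tuple[str, ...] | None = None,
) -> MolecularSystem:
    """Read a single-model PDB file into a :class:`MolecularSystem`.

    HETATM records are labelled "ligand" by default; ``ligand_resnames`` or
    ``ligand_chains`` override that rule.  Nonbonded parameters are left at
    the NaN "unset" sentinel until a parameter table is applied.
    """
    with open(path) as fh:
        if not any(l.startswith(("ATOM  ", "HETATM")) for l in fh):
            raise PDBParseError(f"no atoms in {path}")
    try:
        pdb_file = pdbio.PDBFile.read(path)
        array = pdb_file.get_structure(model=1, extra_fields=["atom_id"])
    except Exception as exc:
        bad = _first_malformed_line(path)
        if bad is not None:
            raise PDBParseError(
                f"malformed PDB record at line {bad[0]}: {bad[1]!r}"
            ) from exc
        raise PDBParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if array.array_length() == 0:
        raise PDBParseError(f"no atoms in {path}")

    serials = np.asarray(array.atom_id, dtype=int)
    uniq, counts = np.unique(serials, return_counts=True)
    if (counts > 1).any():
        warnings.warn(
            f"duplicate atom serial(s) {uniq[counts > 1].tolist()} in {path}; "
            "keeping all records"
        )

    labels = np.where(array.hetero, LIGAND, RECEPTOR).astype(object)
    if ligand_resnames is not None or ligand_chains is not None:
        labels = np.full(array.array_length(), RECEPTOR, dtype=object)
        if ligand_resnames is not None:
            labels[np.isin(array.res_name, ligand_resnames)] = LIGAND
        if ligand_chains is not None:
            labels[np.isin(array.chain_id, ligand_chains)] = LIGAND

    elements = [
        el if el else _infer_element(nm)
        for el, nm in zip(array.element, array.atom_name)
    ]
    return MolecularSystem(
        serials=serials,
        names=list(array.atom_name),
        elements=elements,
        res_names=list(array.res_name),
        res_ids=np.asarray(array.res_id, dtype=int),
        chain_ids=list(array.chain_id),
        coords=np.asarray(array.coord, dtype=float),
        molecule_labels=labels,
    )


def _to_atom_array(system: MolecularSystem, coords: np.ndarray) -> struc.AtomArray:
    n = system.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=float).reshape(n, 3)
    arr.chain_id = np.asarray([str(c)[:1] or "A" for c in system.chain_ids])
    arr.res_id = system.res_ids.copy()
    arr.res_name = np.asarray([str(r) for r in system.res_names])
    arr.atom_name = np.asarray([str(a) for a in system.names])
    arr.element = np.asarray(
        [e if e and e != "X" else _infer_element(nm)
         for e, nm in zip(system.elements, system.names)]
    )
    arr.hetero = system.molecule_labels == LIGAND
    arr.set_annotation("atom_id", system.serials.copy())
    return arr


def _check_writable_coords(coords: np.ndarray) -> None:
    coords = np.asarray(coords)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if (coords >= 10000.0).any() or (coords <= -1000.0).any():
        raise ValueError(
            "coordinate magnitude overflows the fixed-width PDB field "
            "(must lie in (-1000, 10000) Å)"
        )


def write_pdb(system: MolecularSystem, path: str) -> None:
    """Write a system as PDB v3.3; coordinates are printed to 3 decimals."""
    _check_writable_coords(system.coords)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(_to_atom_array(system, system.coords))
    pdb_file.write(path)


def read_multimodel_trajectory(
    path: str,
    system: MolecularSystem,
    frame_spacing: float | None = None,
) -> Trajectory:
    """Read a MODEL/ENDMDL-delimited PDB as a trajectory for ``system``.

    Every model must contain exactly ``system.n_atoms`` records, in the
    system's atom order.  The frame spacing comes from the caller if given,
    else from a ``REMARK 250 FRAME_SPACING_PS`` header, else defaults to
    1 ps.
    """
    # cheap pre-scan: per-model record counts, so a mismatch names its model
    counts: list[int] = []
    remark_spacing = None
    with open(path) as fh:
        in_model = False
        for line in fh:
            if line.startswith(_SPACING_REMARK):
                remark_spacing = float(line[len(_SPACING_REMARK):])
            elif line.startswith("MODEL"):
                in_model = True
                counts.append(0)
            elif line.startswith("ENDMDL"):
                in_model = False
            elif line.startswith(("ATOM  ", "HETATM")):
                if not counts:
                    counts.append(0)  # un-delimited single model
                    in_model = True
                if in_model:
                    counts[-1] += 1
    for k, c in enumerate(counts, start=1):
        if c != system.n_atoms:
            raise ValueError(
                f"model {k} has {c} atoms, expected {system.n_atoms}"
            )
    if not counts:
        raise PDBParseError(f"no atoms in {path}")

    pdb_file = pdbio.PDBFile.read(path)
    stack = pdb_file.get_structure()
    coords = np.asarray(stack.coord, dtype=float)
    if frame_spacing is None:
        frame_spacing = remark_spacing if remark_spacing is not None else 1.0
    return Trajectory(coords, frame_spacing=frame_spacing)


def write_multimodel_trajectory(
    traj: Trajectory, system: MolecularSystem, path: str
) -> None:
    """Write a trajectory as a multi-model PDB with a frame-spacing remark."""
    if traj.n_atoms != system.n_atoms:
        raise ValueError("trajectory/system atom count mismatch")
    _check_writable_coords(traj.coords)
    pdb_file = pdbio.PDBFile()
    stack = struc.stack(
        [_to_atom_array(system, traj.coords[i]) for i in range(traj.n_frames)]
    )
    pdb_file.set_structure(stack)
    pdb_file.lines.insert(0, f"{_SPACING_REMARK} {traj.frame_spacing:.6g}")
    pdb_file.write(path)


# ---------------------------------------------------------------------------
# Parameter tables

_TABLE_COLUMNS = [
    "residue_name", "atom_name", "charge_e",
    "epsilon_kcal", "rmin_half_A", "pb_radius_A",
]


@dataclass(frozen=True)
class AtomParameters:
    charge_e: float
    epsilon_kcal: float
    rmin_half_A: float
    pb_radius_A: float


ParameterTable = dict  # (residue_name, atom_name) -> AtomParameters


def read_parameter_table(path: str) -> ParameterTable:
    """Read a per-atom nonbonded parameter table (TSV, '#' comments)."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=0)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"parameter table missing columns: {missing}")
    table: ParameterTable = {}
    for row in df.itertuples(index=False):
        key = (str(row.residue_name), str(row.atom_name))
        if key in table:
            raise ValueError(f"duplicate parameter-table key {key}")
        table[key] = AtomParameters(
            float(row.charge_e), float(row.epsilon_kcal),
            float(row.rmin_half_A), float(row.pb_radius_A),
        )
    return table


def write_parameter_table(system: MolecularSystem, path: str) -> None:
    """Write the per-atom parameter table of a parameterized system.

    One row per distinct (residue_name, atom_name); raises if two atoms
    sharing a key carry different parameters.
    """
    if system.has_unset_parameters():
        raise ValueError("system has unset parameters")
    rows: dict[tuple[str, str], tuple] = {}
    for i in range(system.n_atoms):
        key = (str(system.res_names[i]), str(system.names[i]))
        vals = (float(system.charges[i]), float(system.lj_epsilon[i]),
                float(system.lj_rmin_half[i]), float(system.pb_radius[i]))
        if key in rows and rows[key] != vals:
            raise ValueError(f"conflicting parameters for {key}")
        rows[key] = vals
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for (rname, aname), vals in sorted(rows.items()):
            fh.write(f"{rname}\t{aname}\t" + "\t".join(
                f"{v:.6g}" for v in vals) + "\n")


def apply_parameters(
    system: MolecularSystem,
    table: ParameterTable,
    drop_unparameterized_hydrogens: bool = False,
) -> MolecularSystem:
    """Overwrite the system's sentinel parameters from a table.

    Every atom must have a ``(residue_name, atom_name)`` entry; missing keys
    raise, listing all of them.  With ``drop_unparameterized_hydrogens``,
    hydrogens without an entry are removed with a warning instead (for
    heavy-atom-only energy models).
    """
    keys = list(zip(system.res_names, system.names))
    missing = sorted({k for k in keys if (k[0], k[1]) not in table})
    if missing and drop_unparameterized_hydrogens:
        is_h = np.array(
            [str(e).upper() == "H" for e in system.elements], dtype=bool
        )
        missing_mask = np.array([k not in table for k in keys], dtype=bool)
        droppable = missing_mask & is_h
        if droppable.any():
            warnings.warn(
                f"dropping {int(droppable.sum())} unparameterized hydrogen(s)"
            )
            system = system.subset(np.flatnonzero(~droppable))
            keys = list(zip(system.res_names, system.names))
            missing = sorted({k for k in keys if k not in table})
    if missing:
        raise KeyError(f"no parameter-table entry for atoms: {missing}")

    out = system.subset(np.arange(system.n_atoms))
    for i, key in enumerate(keys):
        p = table[(key[0], key[1])]
        out.charges[i] = p.charge_e
        out.lj_epsilon[i] = p.epsilon_kcal
        out.lj_rmin_half[i] = p.rmin_half_A
        out.pb_radius[i] = p.pb_radius_A
    return out


# ---------------------------------------------------------------------------
# Replica concatenation

def concatenate_replicas(
    trajectories: list[Trajectory],
    section_labels: list[str],
    discard_ps: float,
) -> Trajectory:
    """Concatenate per-replica trajectories into one labelled analysis pool.

    Frames with time < ``discard_ps`` (equilibration) are removed from the
    head of each replica; frame i of a replica is at ``i * frame_spacing``.
    The resulting frame count is ``sum(n_i - discard_ps/frame_spacing)``.
    Replicas sharing a section label are numbered 1, 2, ... within it.
    """
    if len(trajectories) != len(section_labels):
        raise ValueError("one section label per trajectory is required")
    if not trajectories:
        raise ValueError("no trajectories to concatenate")
    n_atoms = trajectories[0].n_atoms
    spacing = trajectories[0].frame_spacing
    for t in trajectories:
        if t.n_atoms != n_atoms:
            raise ValueError("trajectories have differing atom counts")
        if not math.isclose(t.frame_spacing, spacing):
            raise ValueError("trajectories have differing frame spacing")
    n_discard = math.ceil(discard_ps / spacing) if discard_ps > 0 else 0

    blocks, rep_ids, sec_ids = [], [], []
    per_section_counter: dict[str, int] = {}
    for t, label in zip(trajectories, section_labels):
        if n_discard >= t.n_frames:
            raise ValueError(
                f"discard of {discard_ps} ps removes all {t.n_frames} frames "
                f"of a replica in section {label!r}"
            )
        kept = t.coords[n_discard:]
        rep = per_section_counter.get(label, 0) + 1
        per_section_counter[label] = rep
        blocks.append(kept)
        rep_ids.append(np.full(len(kept), rep, dtype=int))
        sec_ids.append(np.full(len(kept), label, dtype=object))
    return Trajectory(
        np.concatenate(blocks, axis=0),
        frame_spacing=spacing,
        replica_ids=np.concatenate(rep_ids),
        section_ids=np.concatenate(sec_ids),
    )
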