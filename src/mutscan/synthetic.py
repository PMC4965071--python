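"""Synthetic receptor-ligand complexes and trajectories with planted truth.

The generator emulates the statistical structure that the analysis layers
assume, at desk scale and with exactly known ground truth:

* a receptor built as an ideal α-helical backbone trace (N, CA, C, O per
  residue) with a side-chain pseudo-atom chain, carrying round-number
  formal charges (+1 e on a lysine-like NZ, -1 e on an aspartate-like OD1)
  so electrostatic oracles are hand-checkable;
* a rigid multi-atom cationic ligand (a protonated-amine mimic, +1 e on N1)
  seated against the helix side chains, mimicking an inhibitor in a pocket;
* two MD replicas of 5000 frames sampled every 10 ps by default, matching
  the study design of 50 ns runs recorded every 10 ps;
* multi-basin conformational structure imposed by conformer templates with
  mixing weights (or a two-state Markov chain for autocorrelated tests);
* zero-mean Gaussian positional noise with planted per-residue RMS
  amplitudes (the ligand moves rigidly);
* binary contacts whose donor-acceptor distance is set, frame by frame, to
  a bound or unbound value by a Bernoulli draw at the planted occupancy.

Contacts are imposed geometrically rather than dynamically simulated, so
every planted quantity (occupancy, amplitude, basin label) is exactly
recoverable.  Per-replica random streams use seeds ``seed + replica_id``
with 1-based replica ids; all outputs are bit-reproducible given the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import concatenate_replicas
from .system import LIGAND, RECEPTOR, MolecularSystem, Trajectory

# helix geometry: 100 deg turn and 1.5 Å rise per residue, Cα radius 2.3 Å
_TURN_DEG = 100.0
_RISE = 1.5
_CA_RADIUS = 2.3


@dataclass(frozen=True)
class ContactPlan:
    """A planted binary contact.

    ``donor`` / ``acceptor`` name atoms as (residue_index, atom_name) with
    1-based receptor residue indices, or ("LIG", atom_name) for the ligand.
    The donor atom is moved along the current donor-acceptor axis to sit at
    ``bound_distance`` or ``unbound_distance`` from the acceptor.
    """

    donor: tuple
    acceptor: tuple
    target_occupancy: float
    bound_distance: float = 2.9
    unbound_distance: float = 6.0


@dataclass(frozen=True)
class BasinSpec:
    """A conformer template: a rigid shift of a residue segment."""

    weight: float
    segment: tuple[int, int] = (1, 0)      # 1-based inclusive; empty = base
    displacement: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class SyntheticSpec:
    """Study-condition parameters of the synthetic complex generator."""

    n_residues: int = 12
    ligand_atom_count: int = 5
    ligand_charge: float = 1.0
    fluctuation_amplitudes: np.ndarray | float = 0.5   # Å RMS per residue
    ligand_amplitude: float = 0.3                      # Å rigid-body RMS
    contact_plan: list[ContactPlan] = field(default_factory=list)
    basins: list[BasinSpec] = field(default_factory=lambda: [BasinSpec(1.0)])
    basin_mode: str = "iid"          # "iid" | "markov" (two basins)
    markov_switch_rate: float = 0.05  # per-frame switching probability
    charge_plan: list[int] | None = None  # per-residue formal charge
    replica_count: int = 2
    frames_per_replica: int = 5000
    frame_spacing: float = 10.0      # ps
    seed: int = 0

    def amplitudes(self) -> np.ndarray:
        a = self.fluctuation_amplitudes
        if np.isscalar(a):
            a = np.full(self.n_residues, float(a))
        a = np.asarray(a, dtype=float)
        if len(a) != self.n_residues:
            raise ValueError("one fluctuation amplitude per residue required")
        if (a < 0).any():
            raise ValueError("amplitudes must be >= 0")
        return a

    def validate(self) -> None:
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        if self.charge_plan is not None and len(self.charge_plan) != self.n_residues:
            raise ValueError("charge_plan length must equal n_residues")
        w = np.array([b.weight for b in self.basins], dtype=float)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("basin mixing weights must sum to 1")
        for c in self.contact_plan:
            if not 0.0 <= c.target_occupancy <= 1.0:
                raise ValueError("contact occupancy must lie in [0, 1]")
        if self.basin_mode not in ("iid", "markov"):
            raise ValueError("basin_mode must be 'iid' or 'markov'")
        if self.basin_mode == "markov" and len(self.basins) != 2:
            raise ValueError("markov basin mode requires exactly 2 basins")
        self.amplitudes()


@dataclass
class PlantedTruth:
    """Ground truth of one simulated trajectory (pre-discard frame order)."""

    contact_occupancies: np.ndarray      # planned target per contact
    contact_states: np.ndarray           # (n_contacts, n_frames) bool
    basin_labels: np.ndarray             # (n_frames,) int
    residue_amplitudes: np.ndarray       # Å, receptor residues
    ligand_amplitude: float
    receptor_net_charge: float
    ligand_net_charge: float
    contact_atoms: list[tuple[int, int]]  # resolved (donor, acceptor) indices


# ---------------------------------------------------------------------------
# System construction

def _helix_point(t: float) -> np.ndarray:
    ang = np.radians(_TURN_DEG) * t
    return np.array([_CA_RADIUS * np.cos(ang), _CA_RADIUS * np.sin(ang),
                     _RISE * t])


def _outward(t: float) -> np.ndarray:
    ang = np.radians(_TURN_DEG) * t
    return np.array([np.cos(ang), np.sin(ang), 0.0])


def _residue_kind(charge: int) -> str:
    return {0: "ALA", 1: "LYS", -1: "ASP"}[int(charge)]


def pocket_residues(spec: SyntheticSpec) -> tuple[int, int]:
    """1-based indices of the two residues whose side chains line the pocket."""
    mid = spec.n_residues // 2
    return mid, min(mid + 3, spec.n_residues)


def make_toy_complex(spec: SyntheticSpec) -> MolecularSystem:
    """Build a parameterized helical receptor with a ligand in its pocket.

    The ligand sits against the side chain of the first pocket residue, with
    a minimum receptor-ligand heavy-atom separation of about 3 Å.  All atoms
    carry charges, 12-6 LJ parameters and PB radii from the embedded toy
    table (LJ: epsilon 0.1 kcal/mol, r_min/2 1.9 Å everywhere; radii 1.7 Å
    for C, 1.5 Å for N/O).
    """
    spec.validate()
    charges_plan = spec.charge_plan or [0] * spec.n_residues

    serials, names, elements, res_names, res_ids, chain_ids = [], [], [], [], [], []
    coords, q, eps, rmin, rad, labels = [], [], [], [], [], []

    def add(name, element, rname, rid, xyz, charge, label):
        serials.append(len(serials) + 1)
        names.append(name)
        elements.append(element)
        res_names.append(rname)
        res_ids.append(rid)
        chain_ids.append("A" if label == RECEPTOR else "L")
        coords.append(np.asarray(xyz, float))
        q.append(float(charge))
        eps.append(0.1)
        rmin.append(1.9)
        rad.append(1.7 if element == "C" else 1.5)
        labels.append(label)

    for i in range(spec.n_residues):
        rid = i + 1
        rname = _residue_kind(charges_plan[i])
        ca = _helix_point(i)
        out = _outward(i)
        add("N", "N", rname, rid, _helix_point(i - 0.35), 0.0, RECEPTOR)
        add("CA", "C", rname, rid, ca, 0.0, RECEPTOR)
        add("C", "C", rname, rid, _helix_point(i + 0.35), 0.0, RECEPTOR)
        add("O", "O", rname, rid, _helix_point(i + 0.35) + out * 1.23, 0.0,
            RECEPTOR)
        add("CB", "C", rname, rid, ca + out * 1.5, 0.0, RECEPTOR)
        # every residue carries a side-chain tip pseudo-atom at the same
        # position, so charge-plan variants share identical geometry and a
        # "mutation" is a pure charge (and name) change
        tip = ca + out * 3.0
        if charges_plan[i] == -1:
            add("OD1", "O", rname, rid, tip, -1.0, RECEPTOR)
        elif charges_plan[i] == 1:
            add("NZ", "N", rname, rid, tip, 1.0, RECEPTOR)
        else:
            add("CG", "C", rname, rid, tip, 0.0, RECEPTOR)

    # rigid ligand: charged N1 at the centre, carbons on a ring around it,
    # seated against the side-chain tip of the first pocket residue
    p1, _ = pocket_residues(spec)
    anchor = _helix_point(p1 - 1) + _outward(p1 - 1) * 3.0  # side-chain tip
    center = anchor + _outward(p1 - 1) * 4.4
    rid = spec.n_residues + 1
    add("N1", "N", "LIG", rid, center, spec.ligand_charge, LIGAND)
    axis = _outward(p1 - 1)
    e1 = np.array([-axis[1], axis[0], 0.0])
    e2 = np.cross(axis, e1)
    for k in range(spec.ligand_atom_count - 1):
        ang = 2.0 * np.pi * k / max(spec.ligand_atom_count - 1, 1)
        pos = center + 1.4 * (np.cos(ang) * (-axis) + np.sin(ang) * e2) \
            + 0.3 * np.sin(3 * ang) * e1
        add(f"C{k + 1}", "C", "LIG", rid, pos, 0.0, LIGAND)

    return MolecularSystem(
        serials, names, elements, res_names, res_ids, chain_ids,
        np.array(coords), q, eps, rmin, rad, labels,
    )


def resolve_contact_atoms(
    system: MolecularSystem, plan: ContactPlan
) -> tuple[int, int]:
    """Resolve a contact plan's (residue, atom-name) pairs to atom indices."""

    def _find(spec_pair):
        res, name = spec_pair
        if res == "LIG":
            sel = (system.molecule_labels == LIGAND) & (system.names == name)
        else:
            sel = (
                (system.molecule_labels == RECEPTOR)
                & (system.res_ids == int(res))
                & (system.names == name)
            )
        idx = np.flatnonzero(sel)
        if len(idx) != 1:
            raise ValueError(f"contact atom {spec_pair} resolves to {len(idx)} atoms")
        return int(idx[0])

    return _find(plan.donor), _find(plan.acceptor)


# ---------------------------------------------------------------------------
# Trajectory simulation

def _basin_templates(system: MolecularSystem, spec: SyntheticSpec) -> np.ndarray:
    base = system.coords
    templates = []
    for b in spec.basins:
        t = base.copy()
        lo, hi = b.segment
        if hi >= lo:
            sel = (
                (system.molecule_labels == RECEPTOR)
                & (system.res_ids >= lo) & (system.res_ids <= hi)
            )
            t[sel] += np.asarray(b.displacement, float)
        templates.append(t)
    return np.stack(templates)


def simulate_trajectory(
    system: MolecularSystem,
    spec: SyntheticSpec,
    section: str = "all",
) -> tuple[Trajectory, PlantedTruth]:
    """Simulate ``replica_count`` independent replicas of planted frames.

    Per frame: draw a basin template (mixing weights, or the two-state
    Markov chain), add per-residue Gaussian noise (ligand rigid), then pin
    each planned contact to its bound or unbound distance by a Bernoulli
    draw at the target occupancy.  Returns the concatenated trajectory (no
    equilibration discard) and the exact planted truth, frame-aligned.
    """
    spec.validate()
    if spec.frames_per_replica <= 0:
        raise ValueError("frames_per_replica must be > 0")
    amplitudes = spec.amplitudes()
    templates = _basin_templates(system, spec)
    weights = np.array([b.weight for b in spec.basins])
    res_index = system.atom_residue_indices()
    n_rec_res = len(
        [r for r in system.residue_table() if r[0] == "A"]
    )
    is_ligand = system.molecule_labels == LIGAND
    contact_atoms = [resolve_contact_atoms(system, c) for c in spec.contact_plan]

    # per-atom Gaussian sigma: RMS displacement a  =>  sigma = a / sqrt(3)
    sigma = np.zeros(system.n_atoms)
    for i in range(system.n_atoms):
        if is_ligand[i]:
            continue
        sigma[i] = amplitudes[res_index[i]] / np.sqrt(3.0) \
            if res_index[i] < n_rec_res else 0.0
    lig_sigma = spec.ligand_amplitude / np.sqrt(3.0)

    replica_trajs = []
    all_states = []
    all_basins = []
    for rep in range(1, spec.replica_count + 1):
        rng = np.random.default_rng(spec.seed + rep)
        nf = spec.frames_per_replica
        if spec.basin_mode == "markov" and len(spec.basins) == 2:
            labels = np.zeros(nf, dtype=int)
            state = 0
            for f in range(nf):
                labels[f] = state
                if rng.random() < spec.markov_switch_rate:
                    state = 1 - state
        else:
            labels = rng.choice(len(spec.basins), size=nf, p=weights)
        frames = templates[labels].copy()

        noise = rng.standard_normal((nf, system.n_atoms, 3)) * sigma[None, :, None]
        frames += noise
        lig_shift = rng.standard_normal((nf, 3)) * lig_sigma
        frames[:, is_ligand, :] += lig_shift[:, None, :]

        states = np.zeros((len(contact_atoms), nf), dtype=bool)
        for ci, (plan, (d_idx, a_idx)) in enumerate(
            zip(spec.contact_plan, contact_atoms)
        ):
            bound = rng.random(nf) < plan.target_occupancy
            states[ci] = bound
            vec = frames[:, d_idx, :] - frames[:, a_idx, :]
            norm = np.linalg.norm(vec, axis=1, keepdims=True)
            unit = vec / np.where(norm > 0, norm, 1.0)
            dist = np.where(bound, plan.bound_distance, plan.unbound_distance)
            frames[:, d_idx, :] = frames[:, a_idx, :] + unit * dist[:, None]
        replica_trajs.append(
            Trajectory(frames, frame_spacing=spec.frame_spacing)
        )
        all_states.append(states)
        all_basins.append(labels)

    traj = concatenate_replicas(
        replica_trajs, [section] * spec.replica_count, discard_ps=0.0
    )
    truth = PlantedTruth(
        contact_occupancies=np.array(
            [c.target_occupancy for c in spec.contact_plan]
        ),
        contact_states=np.concatenate(all_states, axis=1)
        if contact_atoms else np.zeros((0, traj.n_frames), dtype=bool),
        basin_labels=np.concatenate(all_basins),
        residue_amplitudes=amplitudes,
        ligand_amplitude=spec.ligand_amplitude,
        receptor_net_charge=float(
            system.charges[~is_ligand].sum()
        ),
        ligand_net_charge=float(system.charges[is_ligand].sum()),
        contact_atoms=contact_atoms,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Variant suites for resistance-style comparisons

def variant_charge_plans(n_residues: int) -> dict[str, list[int]]:
    """Charge plans for a sensitive / wild-type / resistant receptor trio.

    The wild type carries one aspartate-like charge lining the pocket (the
    analogue of the Asp whose D->V substitution abolishes a favourable
    contribution); the sensitive variant adds a second pocket acidic
    residue (stronger electrostatic complementarity with the cationic
    ligand); the resistant variant neutralizes the pocket aspartate.
    Planted binding-strength ordering: sensitive < wild-type < resistant
    (more negative = stronger).
    """
    spec = SyntheticSpec(n_residues=n_residues)
    p1, p2 = pocket_residues(spec)
    wt = [0] * n_residues
    wt[p1 - 1] = -1
    sensitive = list(wt)
    sensitive[p2 - 1] = -1
    resistant = [0] * n_residues
    return {"sensitive": sensitive, "wildtype": wt, "resistant": resistant}


def make_variant_suite(
    seed: int,
    n_residues: int = 9,
    frames_per_replica: int = 25,
    replica_count: int = 2,
) -> dict[str, tuple[MolecularSystem, Trajectory, PlantedTruth]]:
    """Build the three planted variants with matched geometry and noise."""
    out = {}
    for k, (label, plan) in enumerate(variant_charge_plans(n_residues).items()):
        spec = SyntheticSpec(
            n_residues=n_residues,
            charge_plan=plan,
            fluctuation_amplitudes=0.3,
            ligand_amplitude=0.2,
            replica_count=replica_count,
            frames_per_replica=frames_per_replica,
            seed=seed + 1000 * k,
        )
        system = make_toy_complex(spec)
        traj, truth = simulate_trajectory(system, spec, section=label)
        out[label] = (system, traj, truth)
    return out
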