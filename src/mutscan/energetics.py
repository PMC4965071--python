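"""MM/PBSA binding energetics with per-residue decomposition.

The binding free energy of a receptor-ligand complex is estimated with the
single-trajectory end-state scheme:

    dG_bind ~= dE_MM + dG_sol - T dS
    dE_MM   =  dE_int + dE_elect + dE_vdw

with the bound and unbound conformations taken from the same complex
trajectory, so the internal (bonded) term dE_int cancels and is reported as
an exact zero; the entropy term -T dS is neglected and carried as a null
field, so the reported value is a relative binding energy.  dE_elect and
dE_vdw are the receptor-ligand Coulomb and 12-6 Lennard-Jones interaction
energies with no cutoff.  dG_sol splits into a polar part from a
finite-difference solution of the linearized Poisson-Boltzmann equation
(complex minus receptor minus ligand, all on the identical grid) and a
nonpolar part proportional to the buried solvent-accessible surface area
(Shrake-Rupley).

Per-residue contributions follow the atomwise bound-minus-free convention:
each atom's energy in the bound state minus the free state is summed over
the atoms of a residue, with pairwise interaction terms split half-and-half
between the two atoms' residues, so residue contributions add up exactly to
the total.

All energies are in kcal/mol, lengths in Å, charges in elementary charges;
the Coulomb constant is k = 332.0636 kcal*Å/(mol*e^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import cg
from scipy.stats import pearsonr

from .system import MolecularSystem, Trajectory

COULOMB_K = 332.0636  # kcal*Å/(mol*e^2)
_GAS_KCAL = 0.0019872041  # kcal/(mol*K)
_AVOGADRO_PER_A3 = 6.02214076e-4  # (mol/L) -> charges per Å^3 is I * this * 1e-3
# I [mol/L] * N_A [1/mol] * 1e-27 [L/Å^3] = I * 6.02214076e-4 per Å^3


# ---------------------------------------------------------------------------
# Molecular-mechanics pair terms

def coulomb_pair_matrix(
    coords_a: np.ndarray, charges_a: np.ndarray,
    coords_b: np.ndarray, charges_b: np.ndarray,
) -> np.ndarray:
    """Pairwise Coulomb energies k q_i q_j / r_ij (kcal/mol), no cutoff."""
    diff = np.asarray(coords_a)[:, None, :] - np.asarray(coords_b)[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    if (r < 1e-9).any():
        raise ValueError("zero distance between charge groups")
    return COULOMB_K * np.outer(charges_a, charges_b) / r


def coulomb_interaction(
    coords_a, charges_a, coords_b, charges_b
) -> float:
    """Total intergroup Coulomb energy (kcal/mol); groups must be disjoint."""
    return float(coulomb_pair_matrix(coords_a, charges_a,
                                     coords_b, charges_b).sum())


def lj_pair_matrix(
    coords_a, eps_a, rmin_half_a, coords_b, eps_b, rmin_half_b
) -> np.ndarray:
    """Pairwise 12-6 energies eps_ij[(rmin_ij/r)^12 - 2 (rmin_ij/r)^6].

    Combination rules: eps_ij = sqrt(eps_i eps_j) and
    rmin_ij = rmin_half_i + rmin_half_j (the r_min/2 convention of the
    parameter table).
    """
    diff = np.asarray(coords_a)[:, None, :] - np.asarray(coords_b)[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    if (r < 1e-9).any():
        raise ValueError("zero distance between atom groups")
    eps = np.sqrt(np.outer(eps_a, eps_b))
    rmin = np.add.outer(np.asarray(rmin_half_a, float),
                        np.asarray(rmin_half_b, float))
    x6 = (rmin / r) ** 6
    return eps * (x6 ** 2 - 2.0 * x6)


def lj_interaction(coords_a, eps_a, rmin_half_a,
                   coords_b, eps_b, rmin_half_b) -> float:
    return float(lj_pair_matrix(coords_a, eps_a, rmin_half_a,
                                coords_b, eps_b, rmin_half_b).sum())


# ---------------------------------------------------------------------------
# Finite-difference linearized Poisson-Boltzmann solver

@dataclass(frozen=True)
class PBGridSpec:
    """Grid and physical parameters of the PB solve.

    Defaults: solute dielectric 2, solvent 80, 0.15 M monovalent salt at
    310 K, 0.5 Å spacing, 10 Å padding, Dirichlet boundary values from the
    Debye-Hückel screened-Coulomb approximation.
    """

    spacing: float = 0.5          # Å
    padding: float = 10.0         # Å beyond the solute extent
    solute_dielectric: float = 2.0
    solvent_dielectric: float = 80.0
    ionic_strength: float = 0.15  # mol/L
    temperature: float = 310.0    # K
    boundary: str = "debye-huckel"
    cg_rtol: float = 1e-8
    cg_maxiter: int = 20000

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.solute_dielectric <= 0 or self.solvent_dielectric <= 0:
            raise ValueError("dielectrics must be > 0")

    def kappa_bar_sq(self) -> float:
        """Screening coefficient kbar^2 = eps_s * kappa^2 in Å^-2."""
        if self.ionic_strength <= 0:
            return 0.0
        n = self.ionic_strength * _AVOGADRO_PER_A3  # charges / Å^3
        rt = _GAS_KCAL * self.temperature
        return 8.0 * np.pi * COULOMB_K * n / rt


@dataclass(frozen=True)
class PBBox:
    """Axis-aligned grid geometry shared by a set of PB solves."""

    origin: np.ndarray            # lower corner, Å
    shape: tuple[int, int, int]   # node counts
    spacing: float

    @classmethod
    def enclosing(cls, coords: np.ndarray, grid: PBGridSpec) -> "PBBox":
        coords = np.asarray(coords, float)
        lo = coords.min(axis=0) - grid.padding
        hi = coords.max(axis=0) + grid.padding
        shape = tuple(
            int(np.ceil((hi[d] - lo[d]) / grid.spacing)) + 1 for d in range(3)
        )
        return cls(origin=lo, shape=shape, spacing=grid.spacing)

    def node_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.shape[axis])


def _spread_charges(coords, charges, box: PBBox) -> np.ndarray:
    """Trilinear (cloud-in-cell) charge assignment to grid nodes."""
    rho = np.zeros(box.shape)
    t = (np.asarray(coords, float) - box.origin) / box.spacing
    i0 = np.floor(t).astype(int)
    f = t - i0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                np.add.at(
                    rho,
                    (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz),
                    w * charges,
                )
    return rho


def _interp_at(phi: np.ndarray, coords, box: PBBox) -> np.ndarray:
    """Trilinear interpolation of a node field at atom positions."""
    t = (np.asarray(coords, float) - box.origin) / box.spacing
    i0 = np.floor(t).astype(int)
    f = t - i0
    out = np.zeros(len(t))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                out += w * phi[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    return out


def _inside_solute(points_shape, offsets, coords, radii, box: PBBox):
    """Boolean mask of grid-aligned points lying inside any atom sphere.

    ``offsets`` shifts the node lattice (in units of spacing) to address
    face midpoints.
    """
    mask = np.zeros(points_shape, dtype=bool)
    h = box.spacing
    for xyz, r in zip(coords, radii):
        t = (xyz - box.origin) / h - offsets
        lo = np.maximum(np.ceil(t - r / h).astype(int), 0)
        hi = np.minimum(np.floor(t + r / h).astype(int),
                        np.array(points_shape) - 1)
        if (lo > hi).any():
            continue
        xs = (np.arange(lo[0], hi[0] + 1) + offsets[0]) * h + box.origin[0]
        ys = (np.arange(lo[1], hi[1] + 1) + offsets[1]) * h + box.origin[1]
        zs = (np.arange(lo[2], hi[2] + 1) + offsets[2]) * h + box.origin[2]
        d2 = (
            (xs - xyz[0])[:, None, None] ** 2
            + (ys - xyz[1])[None, :, None] ** 2
            + (zs - xyz[2])[None, None, :] ** 2
        )
        sub = mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        sub |= d2 <= r * r
        mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = sub
    return mask


def _edge_inside_fraction(shape, axis, coords, radii, box: PBBox):
    """Per-edge fraction of the grid edge (along ``axis``) lying inside the
    solute, from the exact segment-sphere intersection per atom, combined
    with a max over atoms.  Used for the 1-D harmonic (series) dielectric
    homogenization across the solute boundary."""
    h = box.spacing
    frac = np.zeros(shape)
    for xyz, r in zip(coords, radii):
        t = (xyz - box.origin) / h
        lo = np.maximum(np.floor(t - r / h - 1).astype(int), 0)
        hi = np.minimum(np.ceil(t + r / h + 1).astype(int),
                        np.array(shape) - 1)
        if (lo > hi).any():
            continue
        axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
        grids = np.meshgrid(*axes, indexing="ij")
        pos = [grids[d] * h + box.origin[d] for d in range(3)]
        perp2 = np.zeros(grids[0].shape)
        for d in range(3):
            if d != axis:
                perp2 += (pos[d] - xyz[d]) ** 2
        s2 = r * r - perp2
        s = np.sqrt(np.maximum(s2, 0.0))
        x0 = pos[axis]
        a = np.maximum(x0, xyz[axis] - s)
        b = np.minimum(x0 + h, xyz[axis] + s)
        f = np.clip((b - a) / h, 0.0, 1.0) * (s2 > 0)
        sl = tuple(slice(lo[d], hi[d] + 1) for d in range(3))
        frac[sl] = np.maximum(frac[sl], f)
    return frac


def _boundary_potential(coords, charges, box: PBBox, eps: float,
                        kappa: float) -> dict[str, np.ndarray]:
    """Screened-Coulomb Dirichlet values on the six box faces -> full grid."""
    nx, ny, nz = box.shape
    phi = np.zeros(box.shape)
    xs = box.node_coords(0)
    ys = box.node_coords(1)
    zs = box.node_coords(2)
    grid_x, grid_y, grid_z = np.meshgrid(xs, ys, zs, indexing="ij")
    # only boundary values are consumed; computing faces keeps memory modest
    faces = np.zeros(box.shape, dtype=bool)
    faces[0, :, :] = faces[-1, :, :] = True
    faces[:, 0, :] = faces[:, -1, :] = True
    faces[:, :, 0] = faces[:, :, -1] = True
    pts = np.stack(
        [grid_x[faces], grid_y[faces], grid_z[faces]], axis=1
    )
    vals = np.zeros(len(pts))
    for xyz, q in zip(coords, charges):
        r = np.linalg.norm(pts - xyz, axis=1)
        r = np.maximum(r, 1e-6)
        vals += COULOMB_K * q * np.exp(-kappa * r) / (eps * r)
    phi[faces] = vals
    return phi


def _solve_grid(
    coords, charges, radii, box: PBBox, grid: PBGridSpec, homogeneous: bool
) -> np.ndarray:
    """Solve the FD (linearized) PB equation; returns the potential grid.

    ``homogeneous`` solves the uniform solute-dielectric reference problem
    (same grid and charge spreading) whose potential is subtracted to cancel
    the grid self-energy.
    """
    h = box.spacing
    nx, ny, nz = box.shape
    eps_in = grid.solute_dielectric
    eps_out = grid.solvent_dielectric

    rho = _spread_charges(coords, charges, box)

    if homogeneous:
        eps_x = np.full((nx - 1, ny, nz), eps_in)
        eps_y = np.full((nx, ny - 1, nz), eps_in)
        eps_z = np.full((nx, ny, nz - 1), eps_in)
        kbar2 = np.zeros(box.shape)
        kappa = 0.0
        bc_eps = eps_in
    else:
        # series (harmonic) dielectric on each edge from its exact
        # inside-solute fraction: smooth, monotone grid convergence
        def _series_eps(frac):
            return 1.0 / (frac / eps_in + (1.0 - frac) / eps_out)

        eps_x = _series_eps(
            _edge_inside_fraction((nx - 1, ny, nz), 0, coords, radii, box))
        eps_y = _series_eps(
            _edge_inside_fraction((nx, ny - 1, nz), 1, coords, radii, box))
        eps_z = _series_eps(
            _edge_inside_fraction((nx, ny, nz - 1), 2, coords, radii, box))
        node_inside = _inside_solute(box.shape, np.zeros(3), coords, radii, box)
        kbar2 = np.where(node_inside, 0.0, grid.kappa_bar_sq())
        kappa = np.sqrt(grid.kappa_bar_sq() / eps_out) \
            if grid.ionic_strength > 0 else 0.0
        bc_eps = eps_out

    phi_b = _boundary_potential(coords, charges, box, bc_eps, kappa)

    # interior unknowns
    interior = np.zeros(box.shape, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    n_unk = int(interior.sum())
    unk_index = -np.ones(box.shape, dtype=np.int64)
    unk_index[interior] = np.arange(n_unk)

    ii, jj, kk = np.nonzero(interior)
    rows, cols, vals = [], [], []
    diag = np.zeros(n_unk)
    rhs = -4.0 * np.pi * COULOMB_K * rho[interior] / h
    diag -= kbar2[interior] * h * h

    neighbor_specs = [
        ((-1, 0, 0), eps_x[ii - 1, jj, kk]),
        ((+1, 0, 0), eps_x[ii, jj, kk]),
        ((0, -1, 0), eps_y[ii, jj - 1, kk]),
        ((0, +1, 0), eps_y[ii, jj, kk]),
        ((0, 0, -1), eps_z[ii, jj, kk - 1]),
        ((0, 0, +1), eps_z[ii, jj, kk]),
    ]
    me = unk_index[ii, jj, kk]
    for (di, dj, dk), eface in neighbor_specs:
        ni, nj, nk = ii + di, jj + dj, kk + dk
        nidx = unk_index[ni, nj, nk]
        diag -= eface
        inner = nidx >= 0
        rows.append(me[inner])
        cols.append(nidx[inner])
        vals.append(eface[inner])
        # Dirichlet neighbours move to the RHS
        rhs[~inner] -= eface[~inner] * phi_b[ni[~inner], nj[~inner], nk[~inner]]

    rows.append(me)
    cols.append(me)
    vals.append(diag)
    a = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_unk, n_unk),
    )
    # solve the SPD system (-A) phi = (-rhs) with Jacobi preconditioning
    m_inv = sparse.diags(1.0 / (-a.diagonal()))
    x0 = phi_b[interior]  # screened-Coulomb guess speeds convergence
    phi_vec, info = cg(-a, -rhs, x0=x0, rtol=grid.cg_rtol,
                       maxiter=grid.cg_maxiter, M=m_inv)
    if info != 0:
        residual = np.linalg.norm(-a @ phi_vec + rhs)
        raise RuntimeError(
            f"PB solver did not converge (info={info}, residual={residual:.3g})"
        )
    phi = phi_b.copy()
    phi[interior] = phi_vec
    return phi


def solve_pb(
    coords: np.ndarray,
    charges: np.ndarray,
    radii: np.ndarray,
    grid: PBGridSpec,
    box: PBBox | None = None,
) -> tuple[float, np.ndarray]:
    """Electrostatic (reaction-field) solvation energy of a charge set.

    Solves the linearized PB equation on the grid twice — with the
    solute/solvent dielectric map, and with the uniform solute dielectric —
    and returns ``(energy, per_atom)`` with
    ``per_atom[i] = 1/2 q_i (phi_solvated - phi_uniform)(x_i)``; the grid
    self-energy cancels in the difference.  The result converges to the
    Born value on the single-ion case as spacing -> 0.
    """
    coords = np.asarray(coords, float)
    charges = np.asarray(charges, float)
    radii = np.asarray(radii, float)
    if np.isnan(charges).any() or np.isnan(radii).any():
        raise ValueError("unset charges or PB radii")
    if (radii <= 0).any():
        raise ValueError("PB radii must be > 0")
    if box is None:
        box = PBBox.enclosing(coords, grid)
    hi = box.origin + box.spacing * (np.array(box.shape) - 1)
    if ((coords - radii[:, None] < box.origin + box.spacing).any()
            or (coords + radii[:, None] > hi - box.spacing).any()):
        raise ValueError("grid too small to enclose the solute")
    phi_het = _solve_grid(coords, charges, radii, box, grid, homogeneous=False)
    phi_hom = _solve_grid(coords, charges, radii, box, grid, homogeneous=True)
    dphi = _interp_at(phi_het, coords, box) - _interp_at(phi_hom, coords, box)
    per_atom = 0.5 * charges * dphi
    return float(per_atom.sum()), per_atom


def born_ion_energy(charge: float, radius: float, grid: PBGridSpec) -> float:
    """Closed-form Born solvation energy of a single charged sphere
    transferred from the solute to the solvent dielectric (zero salt)."""
    return (
        -0.5 * COULOMB_K * charge ** 2 / radius
        * (1.0 / grid.solute_dielectric - 1.0 / grid.solvent_dielectric)
    )


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta),
         np.cos(phi)], axis=1
    )


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area (Å²).

    Returns ``(total, per_atom)``; per-atom areas sum to the total.
    """
    if n_points < 50:
        raise ValueError("n_points must be >= 50")
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float) + probe_radius
    n = len(coords)
    pts = _sphere_points(n_points)
    per_atom = np.zeros(n)
    if n > 1:
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(n):
        test = coords[i] + radii[i] * pts
        accessible = np.ones(n_points, dtype=bool)
        if n > 1:
            for j in np.flatnonzero(d[i] < radii[i] + radii):
                if j == i:
                    continue
                accessible &= (
                    np.sum((test - coords[j]) ** 2, axis=1) > radii[j] ** 2
                )
        per_atom[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return float(per_atom.sum()), per_atom


# ---------------------------------------------------------------------------
# Binding-energy reports

@dataclass(frozen=True)
class NonpolarParams:
    """G_np = gamma * SASA + b; the offset cancels in delta-delta maps."""

    gamma: float = 0.00542  # kcal/(mol*Å²)
    b: float = 0.0


@dataclass
class EnergyBreakdown:
    """Component energies of one binding-energy estimate (kcal/mol).

    ``g_bind`` is the exact sum of the components; ``entropy_term`` is kept
    as an explicitly null field because -T dS is neglected.
    """

    e_vdw: float
    e_elect: float
    g_polar: float
    g_nonpolar: float
    e_int: float = 0.0
    entropy_term: float | None = None
    e_vdw_std: float = 0.0
    e_elect_std: float = 0.0
    g_polar_std: float = 0.0
    g_nonpolar_std: float = 0.0
    g_bind_std: float = 0.0
    per_frame: pd.DataFrame | None = None

    @property
    def g_sol(self) -> float:
        return self.g_polar + self.g_nonpolar

    @property
    def g_bind(self) -> float:
        return self.e_vdw + self.e_elect + self.g_polar + self.g_nonpolar \
            + self.e_int

    @classmethod
    def from_components(cls, e_vdw: float, e_elect: float,
                        g_sol: float) -> "EnergyBreakdown":
        """Assemble a report from the three printed component means (the
        combined solvation term is carried as the polar slot)."""
        return cls(e_vdw=float(e_vdw), e_elect=float(e_elect),
                   g_polar=float(g_sol), g_nonpolar=0.0)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "dG_vdw": self.e_vdw,
                "dG_elect": self.e_elect,
                "dG_polar": self.g_polar,
                "dG_nonpolar": self.g_nonpolar,
                "dG_sol": self.g_sol,
                "dE_int": self.e_int,
                "dG_bind": self.g_bind,
            }
        )


def _check_parameterized(system: MolecularSystem) -> None:
    if system.has_unset_parameters():
        raise ValueError(
            "system has unset nonbonded parameters; apply a parameter table"
        )


def binding_energy_frame(
    frame: np.ndarray,
    system: MolecularSystem,
    grid: PBGridSpec = PBGridSpec(),
    nonpolar: NonpolarParams = NonpolarParams(),
    include_pb: bool = True,
    sasa_points: int = 240,
    detail: bool = False,
):
    """Single-frame MM/PBSA breakdown (single-trajectory scheme).

    The polar term is PB(complex) - PB(receptor) - PB(ligand) on the
    identical grid; the nonpolar term is gamma * buried SASA (+ b).  With
    ``detail=True`` also returns per-atom component arrays for residue
    decomposition.
    """
    _check_parameterized(system)
    rec = system.receptor_indices()
    lig = system.ligand_indices()
    if len(rec) == 0 or len(lig) == 0:
        raise ValueError("complex must carry both receptor and ligand labels")
    frame = np.asarray(frame, float)

    cmat = coulomb_pair_matrix(frame[rec], system.charges[rec],
                               frame[lig], system.charges[lig])
    vmat = lj_pair_matrix(
        frame[rec], system.lj_epsilon[rec], system.lj_rmin_half[rec],
        frame[lig], system.lj_epsilon[lig], system.lj_rmin_half[lig],
    )
    e_elect = float(cmat.sum())
    e_vdw = float(vmat.sum())

    n = system.n_atoms
    per_atom = {
        "elect": np.zeros(n), "vdw": np.zeros(n),
        "polar": np.zeros(n), "nonpolar": np.zeros(n),
    }
    # pairwise terms attributed half to each partner atom's residue
    per_atom["elect"][rec] = 0.5 * cmat.sum(axis=1)
    per_atom["elect"][lig] = 0.5 * cmat.sum(axis=0)
    per_atom["vdw"][rec] = 0.5 * vmat.sum(axis=1)
    per_atom["vdw"][lig] = 0.5 * vmat.sum(axis=0)

    if include_pb:
        box = PBBox.enclosing(frame, grid)
        _, pa_c = solve_pb(frame, system.charges, system.pb_radius, grid, box)
        _, pa_r = solve_pb(frame[rec], system.charges[rec],
                           system.pb_radius[rec], grid, box)
        _, pa_l = solve_pb(frame[lig], system.charges[lig],
                           system.pb_radius[lig], grid, box)
        per_atom["polar"] = pa_c.copy()
        per_atom["polar"][rec] -= pa_r
        per_atom["polar"][lig] -= pa_l
        g_polar = float(per_atom["polar"].sum())
    else:
        g_polar = 0.0

    _, sa_c = sasa(frame, system.pb_radius, n_points=sasa_points)
    _, sa_r = sasa(frame[rec], system.pb_radius[rec], n_points=sasa_points)
    _, sa_l = sasa(frame[lig], system.pb_radius[lig], n_points=sasa_points)
    dsasa = sa_c.copy()
    dsasa[rec] -= sa_r
    dsasa[lig] -= sa_l
    per_atom["nonpolar"] = nonpolar.gamma * dsasa
    g_nonpolar = float(per_atom["nonpolar"].sum()) + nonpolar.b

    breakdown = EnergyBreakdown(
        e_vdw=e_vdw, e_elect=e_elect, g_polar=g_polar, g_nonpolar=g_nonpolar
    )
    if detail:
        return breakdown, per_atom
    return breakdown


def binding_energy_trajectory(
    traj: Trajectory,
    system: MolecularSystem,
    grid: PBGridSpec = PBGridSpec(),
    nonpolar: NonpolarParams = NonpolarParams(),
    stride: int = 1,
    include_pb: bool = True,
    sasa_points: int = 240,
) -> EnergyBreakdown:
    """Frame-averaged MM/PBSA breakdown over a (strided) trajectory.

    Component means sum exactly to the mean total; the per-frame table
    (with replica labels) rides along for per-replica reporting.
    """
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    idx = np.arange(0, traj.n_frames, max(int(stride), 1))
    rows = []
    for f in idx:
        b = binding_energy_frame(traj.coords[f], system, grid, nonpolar,
                                 include_pb, sasa_points)
        rows.append(
            {
                "frame": int(f),
                "replica": int(traj.replica_ids[f]),
                "section": traj.section_ids[f],
                "e_vdw": b.e_vdw, "e_elect": b.e_elect,
                "g_polar": b.g_polar, "g_nonpolar": b.g_nonpolar,
                "g_bind": b.g_bind,
            }
        )
    df = pd.DataFrame(rows)
    return EnergyBreakdown(
        e_vdw=float(df.e_vdw.mean()),
        e_elect=float(df.e_elect.mean()),
        g_polar=float(df.g_polar.mean()),
        g_nonpolar=float(df.g_nonpolar.mean()),
        e_vdw_std=float(df.e_vdw.std(ddof=0)),
        e_elect_std=float(df.e_elect.std(ddof=0)),
        g_polar_std=float(df.g_polar.std(ddof=0)),
        g_nonpolar_std=float(df.g_nonpolar.std(ddof=0)),
        g_bind_std=float(df.g_bind.std(ddof=0)),
        per_frame=df,
    )


def replica_breakdowns(report: EnergyBreakdown) -> dict[int, EnergyBreakdown]:
    """Per-replica component means recovered from the per-frame table."""
    if report.per_frame is None:
        raise ValueError("report carries no per-frame table")
    out = {}
    for rep, sub in report.per_frame.groupby("replica"):
        out[int(rep)] = EnergyBreakdown(
            e_vdw=float(sub.e_vdw.mean()),
            e_elect=float(sub.e_elect.mean()),
            g_polar=float(sub.g_polar.mean()),
            g_nonpolar=float(sub.g_nonpolar.mean()),
        )
    return out


# ---------------------------------------------------------------------------
# Per-residue decomposition and delta-delta maps

@dataclass
class ResidueDecomposition:
    """Per-residue contributions to the binding energy (kcal/mol)."""

    residues: list[tuple[str, int, str]]
    total: np.ndarray
    components: dict[str, np.ndarray] = field(default_factory=dict)
    std: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chain": [r[0] for r in self.residues],
                "residue_index": [r[1] for r in self.residues],
                "residue_name": [r[2] for r in self.residues],
                "contribution": self.total,
            }
        )
        for k, v in self.components.items():
            df[k] = v
        if self.std is not None:
            df["std"] = self.std
        return df


def per_residue_decomposition(
    traj: Trajectory,
    system: MolecularSystem,
    grid: PBGridSpec = PBGridSpec(),
    nonpolar: NonpolarParams = NonpolarParams(),
    stride: int = 1,
    include_pb: bool = True,
    sasa_points: int = 240,
) -> ResidueDecomposition:
    """Atomwise bound-minus-free contributions summed within residues.

    The residue totals sum to the trajectory-mean binding energy exactly
    (up to floating-point roundoff), because both are accumulated from the
    same per-atom component arrays.  The constant nonpolar offset b is not
    attributed to residues.
    """
    res_index = system.atom_residue_indices()
    table = system.residue_table()
    n_res = len(table)
    idx = np.arange(0, traj.n_frames, max(int(stride), 1))
    comp_names = ("elect", "vdw", "polar", "nonpolar")
    sums = {k: np.zeros(n_res) for k in comp_names}
    totals_per_frame = np.zeros((len(idx), n_res))
    empty = np.bincount(res_index, minlength=n_res) == 0
    if empty.any():
        warnings.warn("residue(s) with no atoms excluded from decomposition")
    for fi, f in enumerate(idx):
        _, per_atom = binding_energy_frame(
            traj.coords[f], system, grid, nonpolar, include_pb,
            sasa_points, detail=True,
        )
        frame_total = np.zeros(n_res)
        for k in comp_names:
            res_sum = np.bincount(res_index, weights=per_atom[k],
                                  minlength=n_res)
            sums[k] += res_sum
            frame_total += res_sum
        totals_per_frame[fi] = frame_total
    nfr = len(idx)
    components = {k: v / nfr for k, v in sums.items()}
    total = sum(components.values())
    return ResidueDecomposition(
        residues=table,
        total=total,
        components=components,
        std=totals_per_frame.std(axis=0, ddof=0),
    )


@dataclass
class DeltaDeltaMap:
    """Per-residue mutant-minus-wild-type contribution differences."""

    residues: list[tuple[str, int, str]]
    ddg: np.ndarray
    flagged: np.ndarray  # |ddG| beyond the report threshold

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [r[0] for r in self.residues],
                "residue_index": [r[1] for r in self.residues],
                "residue_name": [r[2] for r in self.residues],
                "ddG": self.ddg,
                "flagged": self.flagged,
            }
        )


def delta_delta_map(
    mutant: ResidueDecomposition,
    wildtype: ResidueDecomposition,
    correspondence: dict | None = None,
    flag_threshold: float = 1.0,
) -> DeltaDeltaMap:
    """ddG(x) = mutant contribution - wild-type contribution per residue.

    Residues are matched by (chain, residue_index) identity unless an
    explicit correspondence (mutant key -> wild-type key) is given;
    unmatched residues are excluded with a warning.  Residues with |ddG|
    beyond ``flag_threshold`` (1 kcal/mol by default) are flagged.
    """
    wt_pos = {(r[0], r[1]): i for i, r in enumerate(wildtype.residues)}
    residues, ddg = [], []
    dropped = []
    for i, r in enumerate(mutant.residues):
        key = (r[0], r[1])
        if correspondence is not None:
            key = correspondence.get(key, None)
        j = wt_pos.get(key) if key is not None else None
        if j is None:
            dropped.append(r)
            continue
        residues.append(r)
        ddg.append(mutant.total[i] - wildtype.total[j])
    if dropped:
        warnings.warn(f"unmapped residue(s) excluded from ddG map: {dropped}")
    ddg_arr = np.asarray(ddg)
    return DeltaDeltaMap(residues, ddg_arr,
                         np.abs(ddg_arr) > flag_threshold)


def component_total_correlation(
    reports: list[EnergyBreakdown], component: str
) -> float:
    """Pearson correlation of a component with the total across reports."""
    if len(reports) < 3:
        raise ValueError("need at least 3 reports")
    comp_map = {
        "e_vdw": lambda b: b.e_vdw,
        "e_elect": lambda b: b.e_elect,
        "g_polar": lambda b: b.g_polar,
        "g_nonpolar": lambda b: b.g_nonpolar,
        "g_sol": lambda b: b.g_sol,
    }
    if component not in comp_map:
        raise KeyError(f"unknown component {component!r}")
    x = np.array([comp_map[component](b) for b in reports])
    y = np.array([b.g_bind for b in reports])
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in component or total")
    return float(pearsonr(x, y).statistic)
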