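"""Superposition and trajectory statistics: RMSD, RMSF, positional PCA.

All fits are mass-unweighted least squares (Kabsch) over a fit mask; a
``weights`` hook allows mass weighting.  RMSF is measured about the
trajectory-average structure (computed self-consistently by fit/average
iteration), matching the convention of reporting fluctuations averaged over
the whole production run rather than about the first frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import MolecularSystem, SelectionMask, Trajectory

_DEGENERATE_TOL = 1e-8


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body map ``x -> x @ rotation + translation`` (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


@dataclass(frozen=True)
class FluctuationProfile:
    """Per-residue RMSF (Å), keyed by (chain_id, residue_index, residue_name)."""

    residues: list[tuple[str, int, str]]
    values: np.ndarray
    atom_scope: str


def _masked(coords: np.ndarray, mask: SelectionMask | None) -> np.ndarray:
    if mask is None:
        return coords
    return coords[..., mask.atom_indices, :]


def _kabsch_rotation(mobile_c: np.ndarray, ref_c: np.ndarray,
                     weights: np.ndarray | None = None) -> np.ndarray:
    """Rotation R minimizing ||mobile_c @ R - ref_c|| for centered inputs."""
    if weights is not None:
        mobile_c = mobile_c * weights[:, None]
    h = mobile_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    if s[1] <= _DEGENERATE_TOL * max(s[0], 1.0):
        raise ValueError("degenerate fit: masked atoms are (near-)collinear")
    if np.linalg.det(u @ vt) < 0:
        u[:, -1] *= -1.0
    return u @ vt


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_mask: SelectionMask | None = None,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns the proper rotation and translation minimizing the squared
    deviation over the fit mask, and the post-fit RMSD over that mask.
    Requires at least three non-collinear masked atoms.
    """
    mob = _masked(np.asarray(mobile, float), fit_mask)
    ref = _masked(np.asarray(reference, float), fit_mask)
    if mob.shape != ref.shape:
        raise ValueError("mobile/reference shape mismatch")
    if mob.shape[0] < 3:
        raise ValueError("degenerate fit: need at least 3 masked atoms")
    if weights is None:
        cm_m = mob.mean(axis=0)
        cm_r = ref.mean(axis=0)
    else:
        w = weights / weights.sum()
        cm_m = w @ mob
        cm_r = w @ ref
    rot = _kabsch_rotation(mob - cm_m, ref - cm_r, weights)
    trans = cm_r - cm_m @ rot
    fitted = mob @ rot + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def fit_frames(
    frames: np.ndarray,
    reference: np.ndarray,
    fit_mask: SelectionMask | None = None,
) -> np.ndarray:
    """Fit every frame of a (F, N, 3) stack onto ``reference`` (batched)."""
    frames = np.asarray(frames, float)
    ref = _masked(np.asarray(reference, float), fit_mask)
    mob = _masked(frames, fit_mask)
    if mob.shape[1] < 3:
        raise ValueError("degenerate fit: need at least 3 masked atoms")
    cm_m = mob.mean(axis=1)
    cm_r = ref.mean(axis=0)
    h = np.einsum("fmi,mj->fij", mob - cm_m[:, None, :], ref - cm_r)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(u @ vt)
    u[det < 0, :, -1] *= -1.0
    rot = u @ vt
    out = np.einsum("fni,fij->fnj", frames - cm_m[:, None, :], rot) + cm_r
    return out


def rmsd_to_reference(
    frames: np.ndarray,
    reference: np.ndarray,
    fit_mask: SelectionMask | None = None,
    measure_mask: SelectionMask | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) after a Kabsch fit of each frame on ``fit_mask``."""
    fitted = fit_frames(frames, reference, fit_mask)
    dev = _masked(fitted, measure_mask) - _masked(np.asarray(reference, float),
                                                 measure_mask)
    return np.sqrt(np.mean(np.sum(dev ** 2, axis=-1), axis=-1))


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    fit_mask: SelectionMask | None = None,
    measure_mask: SelectionMask | None = None,
) -> np.ndarray:
    """RMSD of every frame against a reference structure.

    Each frame is first rigid-fitted on ``fit_mask``; the deviation is then
    measured over ``measure_mask`` (defaults to the fit mask).
    """
    if measure_mask is not None and len(measure_mask) == 0:
        raise ValueError("empty measure mask")
    if measure_mask is None:
        measure_mask = fit_mask
    return rmsd_to_reference(traj.coords, reference, fit_mask, measure_mask)


def exclude_terminal_residues(
    mask: SelectionMask,
    system: MolecularSystem,
    n_cterm: int,
) -> SelectionMask:
    """Drop the atoms of the last ``n_cterm`` residues of each receptor chain.

    Flexible C-terminal tails otherwise dominate RMSD; ligand atoms are never
    removed.  Raises if a chain has fewer than ``n_cterm + 1`` residues.
    """
    if n_cterm < 0:
        raise ValueError("n_cterm must be >= 0")
    if n_cterm == 0:
        return mask
    receptor = system.molecule_labels == "receptor"
    drop = np.zeros(system.n_atoms, dtype=bool)
    for chain in dict.fromkeys(system.chain_ids[receptor]):
        in_chain = receptor & (system.chain_ids == chain)
        res_ids = list(dict.fromkeys(system.res_ids[in_chain]))
        if n_cterm >= len(res_ids):
            raise ValueError(
                f"n_cterm={n_cterm} >= chain {chain!r} length {len(res_ids)}"
            )
        tail = set(res_ids[-n_cterm:])
        drop |= in_chain & np.isin(system.res_ids, list(tail))
    keep = [i for i in mask.atom_indices if not drop[i]]
    return SelectionMask(np.asarray(keep, dtype=int))


def _average_structure(
    frames: np.ndarray, fit_mask: SelectionMask | None, n_iter: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Self-consistent (fitted frames, average structure)."""
    ref = frames[0]
    fitted = frames
    for _ in range(n_iter):
        fitted = fit_frames(frames, ref, fit_mask)
        ref = fitted.mean(axis=0)
    return fitted, ref


def rmsf_per_residue(
    traj: Trajectory,
    system: MolecularSystem,
    mask: SelectionMask,
    atom_scope: str = "backbone",
) -> FluctuationProfile:
    """Per-residue RMSF about the trajectory-average structure.

    Frames are fitted on ``mask`` to the self-consistent average structure;
    each masked atom's RMS deviation from its average position is computed
    and averaged within its residue.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fitted, ref = _average_structure(traj.coords, mask)
    idx = mask.atom_indices
    dev = fitted[:, idx, :] - ref[idx]
    atom_rmsf = np.sqrt(np.mean(np.sum(dev ** 2, axis=-1), axis=0))

    res_index = system.atom_residue_indices()[idx]
    table = system.residue_table()
    residues: list[tuple[str, int, str]] = []
    values: list[float] = []
    for r in dict.fromkeys(res_index):
        residues.append(table[r])
        values.append(float(atom_rmsf[res_index == r].mean()))
    return FluctuationProfile(residues, np.asarray(values), atom_scope)


def pca_covariance(
    traj: Trajectory,
    mask: SelectionMask,
    n_modes: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the 3N x 3N positional covariance over a mask.

    Frames are fitted to the average structure first (same convention as
    :func:`rmsf_per_residue`).  Returns eigenvalues in Å², descending, and
    the matching eigenvectors as columns; the eigenvalue sum equals the
    total positional variance.
    """
    fitted, ref = _average_structure(traj.coords, mask)
    idx = mask.atom_indices
    x = (fitted[:, idx, :] - ref[idx]).reshape(traj.n_frames, -1)
    dim = x.shape[1]
    if n_modes is None:
        n_modes = dim
    if n_modes > dim:
        raise ValueError(f"requested {n_modes} modes > 3N = {dim}")
    cov = (x.T @ x) / x.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return evals[:n_modes], evecs[:, :n_modes]
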