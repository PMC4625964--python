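"""Superposition-based trajectory dynamics: RMSD, RMSF, cross-correlation, PCA.

All operations fit frames by least-squares rigid superposition (Kabsch,
mass-unweighted, reflections excluded).  RMSF, the dynamic
cross-correlation matrix (DCCM) and the coordinate-covariance PCA use a
single fit-to-mean iteration: frames are first fitted to the first frame,
the mean structure is computed, and frames are refitted to that mean.

The DCCM entry for atoms i, j is

    c_ij = <dr_i . dr_j> / sqrt(<dr_i^2> <dr_j^2>)

with dr the displacement from the time-mean position; +1 indicates fully
correlated, -1 fully anti-correlated motion.  PCA diagonalizes the
3N x 3N covariance of the fitted selection coordinates; the cumulative
fraction of the leading eigenvalues measures how concerted the motion is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model_io import Trajectory

__all__ = [
    "SuperpositionResult",
    "DCCMatrix",
    "PCASpectrum",
    "RMSFProfile",
    "kabsch_superpose",
    "apply_superposition",
    "rmsd_series",
    "rmsf_profile",
    "dccm",
    "covariance_pca",
]

#: backbone atom names used for protein RMSD fits
BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper (det +1)
    translation: np.ndarray  # applied after rotation, A
    rmsd: float  # A, over the fit selection


@dataclass
class DCCMatrix:
    values: np.ndarray  # N x N, symmetric, unit diagonal, in [-1, 1]
    atom_labels: list[str]


@dataclass
class PCASpectrum:
    eigenvalues: np.ndarray  # descending, A^2
    cumulative_fraction: np.ndarray  # partial sums / total, ends at 1
    k: int  # number of leading modes the caller asked about

    @property
    def first_k_fraction(self) -> float:
        return float(self.cumulative_fraction[self.k - 1])


@dataclass
class RMSFProfile:
    residue_indices: np.ndarray
    values: np.ndarray  # A, per selected atom (grouped by residue)


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation R and translation t minimizing the
    mass-unweighted RMSD over the selection; the fitted coordinates are
    ``mobile @ R.T + t``.  Degenerate (collinear or < 3 atom) selections
    are a hard error.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(mobile.shape[0]) if selection is None else np.asarray(selection)
    if sel.size < 3:
        raise ValueError("superposition needs at least 3 atoms")
    P = mobile[sel]
    Q = reference[sel]
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check: rank of the centered point cloud
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection: superposition undefined")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def apply_superposition(coords: np.ndarray, fit: SuperpositionResult) -> np.ndarray:
    return coords @ fit.rotation.T + fit.translation


def _fit_frames(
    frames: np.ndarray, reference: np.ndarray, fit_selection: np.ndarray | None
) -> np.ndarray:
    out = np.empty_like(frames)
    for f, frame in enumerate(frames):
        sup = kabsch_superpose(frame, reference, fit_selection)
        out[f] = apply_superposition(frame, sup)
    return out


def _fit_to_mean(frames: np.ndarray, selection: np.ndarray | None) -> np.ndarray:
    """One fit-to-mean iteration: fit to frame 1, compute mean, refit to mean."""
    fitted = _fit_frames(frames, frames[0], selection)
    mean = fitted.mean(axis=0)
    return _fit_frames(fitted, mean, selection)


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    fit_selection: np.ndarray | None = None,
    measure_selection: np.ndarray | None = None,
) -> dict:
    """Per-frame RMSD (A) after fitting each frame to ``reference``.

    Frames are fitted on ``fit_selection`` and measured on
    ``measure_selection`` (both default to all atoms).  Returns the series
    plus its mean and fluctuation range, the quantities used to judge
    simulation equilibrium.
    """
    measure = (
        np.arange(traj.n_atoms) if measure_selection is None
        else np.asarray(measure_selection)
    )
    if measure.size == 0:
        raise ValueError("empty measure selection")
    series = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.coordinates):
        sup = kabsch_superpose(frame, reference, fit_selection)
        fitted = apply_superposition(frame, sup)
        series[f] = np.sqrt(
            np.mean(np.sum((fitted[measure] - reference[measure]) ** 2, axis=1))
        )
    return {
        "times": traj.times.copy(),
        "rmsd": series,
        "mean": float(series.mean()),
        "range": float(series.max() - series.min()),
    }


def rmsf_profile(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    fit_selection: np.ndarray | None = None,
) -> RMSFProfile:
    """Per-atom RMSF about the time-mean position, after fit-to-mean.

    Frames are superposed on ``fit_selection`` (default: all atoms; in
    practice a stable core, so genuine fluctuations of mobile regions
    are not absorbed by the fit), then
    RMSF_i = sqrt(<|r_i - <r_i>|^2>) over frames for the atoms in
    ``selection``.  Needs >= 2 frames.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF undefined for a single-frame trajectory")
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    fitted = _fit_to_mean(traj.coordinates, fit_selection)
    sub = fitted[:, sel, :]
    mean = sub.mean(axis=0)
    msf = np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0)
    if traj.topology is not None:
        res = traj.topology.residue_indices[sel]
    else:
        res = sel.copy()
    return RMSFProfile(residue_indices=res, values=np.sqrt(msf))


def dccm(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    fit_selection: np.ndarray | None = None,
) -> DCCMatrix:
    """Dynamic cross-correlation matrix over the selected atoms.

    Frames are superposed on ``fit_selection`` (default: all atoms)
    before displacements are measured.  Zero-variance atoms get
    off-diagonal 0 / diagonal 1 with a warning instead of propagating
    NaN.
    """
    if traj.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    sub = _fit_to_mean(traj.coordinates, fit_selection)[:, sel, :]
    disp = sub - sub.mean(axis=0)  # frames x N x 3
    # <dr_i . dr_j> via einsum over frames and xyz
    cov = np.einsum("fik,fjk->ij", disp, disp) / disp.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance atoms in DCCM; rows zeroed",
            stacklevel=2,
        )
        var[zero] = 1.0
    norm = np.sqrt(np.outer(var, var))
    c = cov / norm
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    c = 0.5 * (c + c.T)
    if traj.topology is not None:
        labels = [
            f"{traj.topology.atoms[i].residue_name}{traj.topology.atoms[i].residue_index}"
            for i in sel
        ]
    else:
        labels = [str(i) for i in sel]
    return DCCMatrix(values=c, atom_labels=labels)


def covariance_pca(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    k: int = 6,
    fit_selection: np.ndarray | None = None,
) -> PCASpectrum:
    """Eigen-spectrum of the 3N x 3N coordinate covariance after fitting.

    Returns the full descending spectrum and the cumulative fraction of
    the first ``k`` eigenvalues in the total (the "concerted motion"
    fraction).
    """
    if traj.n_frames < 2:
        raise ValueError("covariance PCA needs at least 2 frames")
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    if k > 3 * sel.size:
        raise ValueError(f"k={k} exceeds 3N={3 * sel.size}")
    sub = _fit_to_mean(traj.coordinates, fit_selection)[:, sel, :]
    X = sub.reshape(sub.shape[0], -1)
    X = X - X.mean(axis=0)
    cov = (X.T @ X) / X.shape[0]
    evals = np.linalg.eigvalsh(cov)[::-1]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total <= 0:
        cumfrac = np.zeros(evals.size)
        cumfrac[-1] = 1.0 if evals.size else 0.0
    else:
        cumfrac = np.cumsum(evals) / total
    return PCASpectrum(eigenvalues=evals, cumulative_fraction=cumfrac, k=k)
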