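"""End-point binding free energies: MM-GBSA and SIE combiners and pipelines.

Two end-point estimators are assembled from per-snapshot components of a
single complex trajectory (internal terms cancel, so only intermolecular
interaction terms appear):

MM-GBSA:

    dG_bind = dE_ele + dE_vdw + dG_pol + dG_nonpol - T dS

with the gas-phase molecular-mechanics terms at dielectric 1, the polar
term from generalized Born, the non-polar term from dG_nonpol =
gamma * dSASA + beta (gamma = 0.0072 kcal/mol/A^2, beta = 0), and the
entropy penalty from normal-mode analysis, stored as the signed
quantity -T dS (positive for a binding penalty).

SIE (solvated interaction energy):

    dG_bind(rho, D_in, alpha, gamma, C)
        = alpha * [E_c(D_in) + dG^R + E_vdW + gamma*dMSA(rho)] + C

an empirical affine combination with fitted coefficients
alpha = 0.1048, D_in = 2.25, rho = 1.1, gamma = 0.0129 kcal/(mol*A^2),
C = -2.89 kcal/mol.  The reaction-field change dG^R is computed here
with the generalized-Born machinery at interior dielectric D_in.

Also provided: per-residue decomposition of the interaction energy and
harmonic (normal-mode) vibrational entropies for toy systems whose
analysis energy is intra-selection Coulomb + Lennard-Jones + harmonic
bonds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.distance import cdist

from . import implicit_solvent as gb
from . import mm_energy as mm
from .model_io import FrameSelection, Topology, Trajectory, select_frames

__all__ = [
    "EnergyComponents",
    "SIEComponents",
    "SIEParameters",
    "NonpolarParams",
    "ResidueDecomposition",
    "mmgbsa_combine",
    "sie_score",
    "nonpolar_energy",
    "mmgbsa_pipeline",
    "sie_pipeline",
    "residue_decomposition",
    "normal_mode_entropy",
    "nmode_binding_entropy",
    "toy_energy_gradient",
]

# physical constants (CODATA 2018)
AVOGADRO = 6.02214076e23
BOLTZMANN_KCALMOL = 1.987204258640832e-3  # kcal/mol/K (gas constant R)
PLANCK = 6.62607015e-34  # J s
_AMU = 1.66053906660e-27  # kg
#: (kcal/mol/A^2/amu) -> (rad/s)^2
_EIGVAL_TO_OMEGA2 = 4184.0 / AVOGADRO / _AMU * 1e20


@dataclass
class EnergyComponents:
    """MM-GBSA components (kcal/mol); ``minus_T_dS`` is the signed -T dS."""

    ele: float
    vdw: float
    gpol: float
    gnonpol: float
    minus_T_dS: float | None = None


@dataclass
class SIEComponents:
    """SIE components (kcal/mol); ``msa_term`` already carries gamma*dMSA."""

    coulomb_Din: float
    vdw: float
    reaction_field: float
    msa_term: float


@dataclass(frozen=True)
class SIEParameters:
    """The five fitted SIE coefficients (defaults are the published set)."""

    alpha: float = 0.1048
    interior_dielectric: float = 2.25
    rho: float = 1.1
    gamma_msa: float = 0.0129  # kcal mol^-1 A^-2
    constant_C: float = -2.89  # kcal/mol


@dataclass(frozen=True)
class NonpolarParams:
    """dG_nonpol = gamma * SASA + beta."""

    gamma: float = 0.0072  # kcal mol^-1 A^-2
    beta: float = 0.0  # kcal/mol


@dataclass
class ResidueDecomposition:
    """Frame-averaged per-residue interaction terms (kcal/mol)."""

    residues: list[int]
    ele: np.ndarray
    vdw: np.ndarray
    gb: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.ele + self.vdw + self.gb


# ---------------------------------------------------------------------------
# Combiners
# ---------------------------------------------------------------------------

def mmgbsa_combine(components: EnergyComponents) -> float:
    """dG_bind = dE_ele + dE_vdw + dG_pol + dG_nonpol + (-T dS).

    If the entropy term is absent the enthalpy-only value is returned
    with a warning.
    """
    g = (
        components.ele
        + components.vdw
        + components.gpol
        + components.gnonpol
    )
    if components.minus_T_dS is None:
        warnings.warn("entropy term missing; returning enthalpy only", stacklevel=2)
        return float(g)
    return float(g + components.minus_T_dS)


def sie_score(
    components: SIEComponents, params: SIEParameters = SIEParameters()
) -> float:
    """alpha * (E_c + dG^R + E_vdW + gamma*dMSA) + C."""
    return float(
        params.alpha
        * (
            components.coulomb_Din
            + components.reaction_field
            + components.vdw
            + components.msa_term
        )
        + params.constant_C
    )


def nonpolar_energy(
    sasa_value: float, params: NonpolarParams = NonpolarParams()
) -> float:
    """gamma * area + beta (area may be a binding difference)."""
    return float(params.gamma * sasa_value + params.beta)


# ---------------------------------------------------------------------------
# Snapshot pipelines
# ---------------------------------------------------------------------------

def _frames_of(traj: Trajectory, frame_sel: FrameSelection | None) -> Trajectory:
    return traj if frame_sel is None else select_frames(traj, frame_sel)


def mmgbsa_pipeline(
    traj: Trajectory,
    topology: Topology,
    frame_sel: FrameSelection | None = None,
    gb_params: gb.GBModelParams | None = None,
    np_params: NonpolarParams = NonpolarParams(),
    surface_params: gb.SurfaceParams | None = None,
    minus_T_dS: float | None = None,
) -> dict:
    """Per-frame MM-GBSA components, means with snapshot dispersion, dG.

    Gas-phase terms at dielectric 1; dG_pol from the generalized-Born
    binding difference; dG_nonpol from gamma*dSASA + beta with probe
    1.4 A.  The entropy penalty, if supplied, is attached as -T dS.
    """
    if gb_params is None:
        gb_params = gb.GBModelParams()
    if surface_params is None:
        surface_params = gb.SurfaceParams()
    sub = _frames_of(traj, frame_sel)
    rec, lig = topology.receptor_selection, topology.ligand_selection
    both = np.concatenate([rec, lig])
    n = sub.n_frames
    ele = np.empty(n)
    vdw = np.empty(n)
    gpol = np.empty(n)
    gnp = np.empty(n)
    for f, frame in enumerate(sub.coordinates):
        ele[f] = mm.coulomb_energy(frame, topology, rec, lig, dielectric=1.0)
        vdw[f] = mm.lj_energy(frame, topology, rec, lig)
        gpol[f] = gb.delta_gpol_binding(frame, topology, gb_params)
        a_c, _ = gb.sasa(frame, topology, both, surface_params)
        a_r, _ = gb.sasa(frame, topology, rec, surface_params)
        a_l, _ = gb.sasa(frame, topology, lig, surface_params)
        gnp[f] = nonpolar_energy(a_c - a_r - a_l, np_params)
    means = EnergyComponents(
        ele=float(ele.mean()),
        vdw=float(vdw.mean()),
        gpol=float(gpol.mean()),
        gnonpol=float(gnp.mean()),
        minus_T_dS=minus_T_dS,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dg = mmgbsa_combine(means)
    return {
        "per_frame": {"ele": ele, "vdw": vdw, "gpol": gpol, "gnonpol": gnp},
        "means": means,
        "std": {
            "ele": mm.sample_std(ele),
            "vdw": mm.sample_std(vdw),
            "gpol": mm.sample_std(gpol),
            "gnonpol": mm.sample_std(gnp),
        },
        "n_frames": n,
        "delta_g": dg,
        "entropy_included": minus_T_dS is not None,
    }


def sie_pipeline(
    traj: Trajectory,
    topology: Topology,
    frame_sel: FrameSelection | None = None,
    sie_params: SIEParameters = SIEParameters(),
    surface_params: gb.SurfaceParams | None = None,
) -> dict:
    """Per-frame SIE components and the mean SIE binding score.

    E_c and dG^R are evaluated at the SIE interior dielectric; the
    surface term uses radii scaled by rho with probe 0.
    """
    if surface_params is None:
        surface_params = gb.SurfaceParams(
            probe_radius=0.0, radius_scale=sie_params.rho
        )
    gb_params = gb.GBModelParams(
        interior_dielectric=sie_params.interior_dielectric
    )
    sub = _frames_of(traj, frame_sel)
    rec, lig = topology.receptor_selection, topology.ligand_selection
    n = sub.n_frames
    ec = np.empty(n)
    vdw = np.empty(n)
    rf = np.empty(n)
    msa = np.empty(n)
    scores = np.empty(n)
    for f, frame in enumerate(sub.coordinates):
        ec[f] = mm.coulomb_energy(
            frame, topology, rec, lig, dielectric=sie_params.interior_dielectric
        )
        vdw[f] = mm.lj_energy(frame, topology, rec, lig)
        rf[f] = gb.delta_gpol_binding(frame, topology, gb_params)
        msa[f] = sie_params.gamma_msa * gb.delta_msa(frame, topology, surface_params)
        scores[f] = sie_score(
            SIEComponents(ec[f], vdw[f], rf[f], msa[f]), sie_params
        )
    means = SIEComponents(
        coulomb_Din=float(ec.mean()),
        vdw=float(vdw.mean()),
        reaction_field=float(rf.mean()),
        msa_term=float(msa.mean()),
    )
    return {
        "per_frame": {
            "coulomb_Din": ec,
            "vdw": vdw,
            "reaction_field": rf,
            "msa_term": msa,
            "score": scores,
        },
        "means": means,
        "std": {
            "coulomb_Din": mm.sample_std(ec),
            "vdw": mm.sample_std(vdw),
            "reaction_field": mm.sample_std(rf),
            "msa_term": mm.sample_std(msa),
            "score": mm.sample_std(scores),
        },
        "n_frames": n,
        "delta_g": sie_score(means, sie_params),
    }


# ---------------------------------------------------------------------------
# Residue decomposition
# ---------------------------------------------------------------------------

def residue_decomposition(
    traj: Trajectory,
    topology: Topology,
    frame_sel: FrameSelection | None = None,
    gb_params: gb.GBModelParams | None = None,
) -> ResidueDecomposition:
    """Per-receptor-residue interaction terms with the ligand.

    Each residue carries the full pairwise Coulomb + LJ energy of its
    atoms with all ligand atoms, plus half of the complex-state GB
    cross-terms between its atoms and the ligand (the 50/50 per-residue
    attribution convention; the other half belongs to the ligand side).
    The ele+vdw parts sum over residues to the total interaction energy.
    """
    if gb_params is None:
        gb_params = gb.GBModelParams()
    sub = _frames_of(traj, frame_sel)
    rec, lig = topology.receptor_selection, topology.ligand_selection
    both = np.concatenate([rec, lig])
    res_ids = topology.residue_indices
    residues = sorted(set(int(r) for r in res_ids[rec]))
    pos = {r: i for i, r in enumerate(residues)}
    q = topology.charges
    sig_all = topology.lj_sigmas
    eps_all = topology.lj_epsilons
    acc = np.zeros((3, len(residues)))
    pref = -0.5 * mm.COULOMB_CONSTANT * (
        1.0 / gb_params.interior_dielectric - 1.0 / gb_params.exterior_dielectric
    )
    for frame in sub.coordinates:
        r = cdist(frame[rec], frame[lig])
        ele_pairs = mm.COULOMB_CONSTANT * np.outer(q[rec], q[lig]) / r
        sig = 0.5 * (sig_all[rec][:, None] + sig_all[lig][None, :])
        eps = np.sqrt(eps_all[rec][:, None] * eps_all[lig][None, :])
        sr6 = (sig / r) ** 6
        vdw_pairs = 4.0 * eps * (sr6 ** 2 - sr6)
        # complex-state GB cross terms between receptor and ligand atoms
        R = gb.effective_born_radii(frame, topology, gb_params, both)
        Rr, Rl = R[: rec.size], R[rec.size:]
        r2 = r ** 2
        RiRj = np.outer(Rr, Rl)
        fgb = np.sqrt(r2 + RiRj * np.exp(-r2 / (4.0 * RiRj)))
        # E = -k/2 sum_ij over the full double sum; cross(A,B) counts each
        # unordered pair twice, so the A<->B cross energy is 2*pref*sum
        gb_pairs = 2.0 * pref * np.outer(q[rec], q[lig]) / fgb
        for a_local, a_global in enumerate(rec):
            j = pos[int(res_ids[a_global])]
            acc[0, j] += ele_pairs[a_local].sum()
            acc[1, j] += vdw_pairs[a_local].sum()
            acc[2, j] += 0.5 * gb_pairs[a_local].sum()
    acc /= sub.n_frames
    return ResidueDecomposition(
        residues=residues, ele=acc[0], vdw=acc[1], gb=acc[2]
    )


# ---------------------------------------------------------------------------
# Toy-system analysis energy (for normal modes)
# ---------------------------------------------------------------------------

def toy_energy_gradient(
    x: np.ndarray, topology: Topology, selection: np.ndarray
) -> tuple[float, np.ndarray]:
    """Energy and gradient of the intra-selection analysis potential.

    Non-bonded intra-selection Coulomb (dielectric 1) + 12-6 LJ over all
    atom pairs except 1-2 bonded ones, plus harmonic bonds
    E = 1/2 k (r - r0)^2 from the topology.  ``x`` has shape (n_sel, 3).
    """
    sel = np.asarray(selection, dtype=int)
    local = {int(g): i for i, g in enumerate(sel)}
    x = np.asarray(x, dtype=float).reshape(sel.size, 3)
    n = sel.size
    energy = 0.0
    grad = np.zeros_like(x)
    bonded_pairs = set()
    for i, j, k, r0 in topology.bonds:
        if i in local and j in local:
            bonded_pairs.add(frozenset((i, j)))
            a, b = local[i], local[j]
            d = x[a] - x[b]
            r = float(np.linalg.norm(d))
            energy += 0.5 * k * (r - r0) ** 2
            if r > 0:
                f = k * (r - r0) * d / r
                grad[a] += f
                grad[b] -= f
    q = topology.charges[sel]
    sig = topology.lj_sigmas[sel]
    eps = topology.lj_epsilons[sel]
    for a in range(n):
        for b in range(a + 1, n):
            if frozenset((int(sel[a]), int(sel[b]))) in bonded_pairs:
                continue
            d = x[a] - x[b]
            r = float(np.linalg.norm(d))
            if r < 1e-10:
                raise ValueError(f"overlapping atoms {sel[a]} and {sel[b]}")
            e_ele = mm.COULOMB_CONSTANT * q[a] * q[b] / r
            s = 0.5 * (sig[a] + sig[b])
            e_ab = np.sqrt(eps[a] * eps[b])
            sr6 = (s / r) ** 6
            e_lj = 4.0 * e_ab * (sr6 ** 2 - sr6)
            energy += e_ele + e_lj
            de_dr = -e_ele / r + 4.0 * e_ab * (-12.0 * sr6 ** 2 + 6.0 * sr6) / r
            f = de_dr * d / r
            grad[a] += f
            grad[b] -= f
    return energy, grad


def _minimize_structure(
    x0: np.ndarray,
    topology: Topology,
    selection: np.ndarray,
    gtol: float = 1e-8,
) -> np.ndarray:
    """Drive the selection to a local minimum (quasi-Newton, tight gtol)."""
    sel = np.asarray(selection, dtype=int)

    def fun(flat):
        e, g = toy_energy_gradient(flat.reshape(-1, 3), topology, sel)
        return e, g.ravel()

    res = _scipy_minimize(
        fun,
        np.asarray(x0, float).reshape(-1),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 5000, "ftol": 1e-16, "gtol": 1e-12},
    )
    x = res.x.reshape(-1, 3)
    _, g = toy_energy_gradient(x, topology, sel)
    if np.linalg.norm(g) > gtol * max(1.0, np.sqrt(sel.size)):
        # Newton polish with a numerical Hessian
        for _ in range(20):
            H = _numerical_hessian(x, topology, sel)
            _, g = toy_energy_gradient(x, topology, sel)
            step, *_ = np.linalg.lstsq(H, -g.ravel(), rcond=None)
            x = x + step.reshape(-1, 3)
            _, g = toy_energy_gradient(x, topology, sel)
            if np.linalg.norm(g) <= gtol:
                break
    return x


def _numerical_hessian(
    x: np.ndarray,
    topology: Topology,
    selection: np.ndarray,
    step: float = 1e-4,
) -> np.ndarray:
    """Central-difference Hessian of the analysis energy (3n x 3n)."""
    sel = np.asarray(selection, dtype=int)
    flat = np.asarray(x, float).reshape(-1).copy()
    m = flat.size
    H = np.empty((m, m))
    for p in range(m):
        fp = flat.copy()
        fp[p] += step
        _, gp = toy_energy_gradient(fp.reshape(-1, 3), topology, sel)
        fm = flat.copy()
        fm[p] -= step
        _, gm = toy_energy_gradient(fm.reshape(-1, 3), topology, sel)
        H[p] = (gp.ravel() - gm.ravel()) / (2.0 * step)
    return H


def _rigid_body_projector(x: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Projector removing mass-weighted translation/rotation modes."""
    n = x.shape[0]
    sqm = np.sqrt(masses)
    vecs = []
    for axis in range(3):
        v = np.zeros((n, 3))
        v[:, axis] = sqm
        vecs.append(v.ravel())
    com = (masses[:, None] * x).sum(axis=0) / masses.sum()
    rel = x - com
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        v = np.cross(rel, e[None, :]) * sqm[:, None]
        vecs.append(v.ravel())
    V = np.array(vecs).T  # 3n x 6
    # orthonormal basis of the rigid subspace via SVD: robust to the
    # null rotation of linear molecules
    U, s, _ = np.linalg.svd(V, full_matrices=False)
    Q = U[:, s > 1e-8 * s.max()]
    return np.eye(3 * n) - Q @ Q.T


def _vibrational_frequencies(
    x: np.ndarray,
    topology: Topology,
    selection: np.ndarray,
    hessian_step: float = 1e-4,
) -> np.ndarray:
    """Harmonic vibrational frequencies (Hz) at a minimized geometry."""
    sel = np.asarray(selection, dtype=int)
    H = _numerical_hessian(x, topology, sel, hessian_step)
    asym = np.abs(H - H.T).max()
    scale = np.abs(H).max()
    if scale > 0 and asym > 1e-6 * scale:
        raise ValueError(f"Hessian asymmetry {asym:.2e} exceeds tolerance")
    H = 0.5 * (H + H.T)
    masses = topology.masses[sel]
    inv_sqm = 1.0 / np.sqrt(np.repeat(masses, 3))
    Hmw = H * np.outer(inv_sqm, inv_sqm)
    P = _rigid_body_projector(x, masses)
    n_rigid = 3 * sel.size - int(round(np.trace(P)))
    Hproj = P @ Hmw @ P
    evals = np.linalg.eigvalsh(Hproj)
    # drop the (projected-out) rigid-body null space
    order = np.argsort(np.abs(evals))
    vib = np.sort(evals[order[n_rigid:]])
    tol = 1e-6 * max(1.0, np.abs(evals).max())
    n_imag = int((vib < -tol).sum())
    if n_imag:
        raise ValueError(
            f"{n_imag} imaginary frequencies beyond the rigid-body modes: "
            "structure is not at a minimum"
        )
    vib = np.clip(vib, 0.0, None)
    omega = np.sqrt(vib * _EIGVAL_TO_OMEGA2)  # rad/s
    return omega / (2.0 * np.pi)


def _ho_vibrational_entropy(freqs_hz: np.ndarray, temperature: float) -> float:
    """Harmonic-oscillator vibrational entropy (kcal/mol/K)."""
    if temperature <= 0:
        return 0.0
    kT = BOLTZMANN_KCALMOL * temperature  # kcal/mol
    kT_J = kT * 4184.0 / AVOGADRO
    x = PLANCK * np.asarray(freqs_hz) / kT_J
    x = x[(x > 0) & (x < 500.0)]  # modes with hv >> kT contribute nothing
    s = BOLTZMANN_KCALMOL * np.sum(x / np.expm1(x) - np.log1p(-np.exp(-x)))
    return float(s)


def normal_mode_entropy(
    structure: np.ndarray,
    topology: Topology,
    selection,
    temperature: float = 300.0,
    minimize: bool = True,
    hessian_step: float = 1e-4,
) -> dict:
    """Harmonic vibrational entropy of one state from normal modes.

    The structure is driven to a local minimum of the analysis energy
    (unless ``minimize=False``), the mass-weighted Hessian is built by
    central differences, six rigid-body modes are projected out, and the
    harmonic-oscillator entropy is evaluated at ``temperature``.

    Returns frequencies (Hz), the entropy S_vib (kcal/mol/K) and the
    state's -T*S (kcal/mol).
    """
    sel = np.asarray(selection, dtype=int)
    x = np.asarray(structure, float)[sel]
    if minimize:
        x = _minimize_structure(x, topology, sel)
    freqs = _vibrational_frequencies(x, topology, sel, hessian_step)
    s = _ho_vibrational_entropy(freqs, temperature)
    return {
        "frequencies_hz": freqs,
        "entropy": s,
        "minus_TS": -temperature * s,
        "coordinates": x,
    }


def nmode_binding_entropy(
    frame: np.ndarray,
    topology: Topology,
    temperature: float = 300.0,
    minimize: bool = True,
) -> float:
    """-T dS of binding = -T [S(complex) - S(receptor) - S(ligand)]."""
    rec, lig = topology.receptor_selection, topology.ligand_selection
    both = np.concatenate([rec, lig])
    s_c = normal_mode_entropy(frame, topology, both, temperature, minimize)
    s_r = normal_mode_entropy(frame, topology, rec, temperature, minimize)
    s_l = normal_mode_entropy(frame, topology, lig, temperature, minimize)
    return -temperature * (s_c["entropy"] - s_r["entropy"] - s_l["entropy"])
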