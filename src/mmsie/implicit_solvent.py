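"""Generalized-Born polar solvation and solvent-accessible surface area.

The polar solvation free energy uses the pairwise-descreening generalized
Born model with the tanh rescaling of Onufriev, Bashford and Case (OBC).
Effective Born radii come from the Hawkins-Cramer-Truhlar pairwise
descreening integral I_i, rescaled through

    R_i^-1 = rho_i_tilde^-1 - tanh(a*psi - b*psi^2 + g*psi^3) / rho_i

with psi = I_i * rho_i_tilde and rho_i_tilde = rho_i - offset.  The
default shape constants (a, b, g) = (0.8, 0, 2.909125) are the OBC-I
(igb=2) set; the OBC-II (igb=5) set (1.0, 0.8, 4.85) is selectable by
name.  The polar energy is the usual GB cross-term sum with the
still-Born interpolation f_GB = sqrt(r^2 + R_i R_j exp(-r^2/(4 R_i R_j))).

The binding reaction-field term dG_pol(complex) - dG_pol(receptor) -
dG_pol(ligand) recomputes radii for each state from the same frame (the
single-trajectory end-point convention).  With the interior dielectric
set to the solute value used by the SIE scoring function (D_in = 2.25),
the same machinery serves as the reaction-field surrogate for the SIE
dG^R term.

Surface areas use Shrake-Rupley sphere sampling with a deterministic
golden-spiral point set (no RNG), so results are bit-reproducible.  The
SIE "molecular surface area" change is approximated by the accessible
area with all atomic radii scaled by rho (default 1.1) and probe 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .mm_energy import COULOMB_CONSTANT
from .model_io import Topology

__all__ = [
    "GBModelParams",
    "SurfaceParams",
    "OBC_VARIANTS",
    "effective_born_radii",
    "gb_polar_energy",
    "delta_gpol_binding",
    "sasa",
    "delta_msa",
    "golden_spiral_points",
]

#: published tanh shape-constant sets, by variant name
OBC_VARIANTS = {
    "obc1": (0.8, 0.0, 2.909125),  # igb=2
    "obc2": (1.0, 0.8, 4.85),      # igb=5
}


@dataclass(frozen=True)
class GBModelParams:
    """Generalized-Born model parameters.

    ``interior_dielectric`` is the solute dielectric (1.0 for the MM-GBSA
    polar term; 2.25 when the GB machinery stands in for the SIE
    reaction field); ``exterior_dielectric`` is the solvent (78.5).
    """

    interior_dielectric: float = 1.0
    exterior_dielectric: float = 78.5
    obc_alpha: float = OBC_VARIANTS["obc1"][0]
    obc_beta: float = OBC_VARIANTS["obc1"][1]
    obc_gamma: float = OBC_VARIANTS["obc1"][2]
    radius_offset: float = 0.09  # A

    def __post_init__(self):
        if self.interior_dielectric <= 0 or self.exterior_dielectric <= 0:
            raise ValueError("dielectrics must be positive")
        if self.exterior_dielectric <= self.interior_dielectric:
            raise ValueError("exterior dielectric must exceed interior")

    @classmethod
    def variant(cls, name: str, **kwargs) -> "GBModelParams":
        a, b, g = OBC_VARIANTS[name.lower()]
        return cls(obc_alpha=a, obc_beta=b, obc_gamma=g, **kwargs)


@dataclass(frozen=True)
class SurfaceParams:
    """Shrake-Rupley surface parameters.

    ``radius_scale`` is the rho multiplier applied to atomic radii for
    the molecular-surface-area approximation (1.1 in the SIE scoring
    function); plain SASA uses radius_scale=1 and probe 1.4 A.
    """

    probe_radius: float = 1.4  # A
    n_sphere_points: int = 960
    radius_scale: float = 1.0

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < 12:
            raise ValueError("n_sphere_points must be >= 12")


# ---------------------------------------------------------------------------
# Effective Born radii (HCT descreening + OBC tanh rescaling)
# ---------------------------------------------------------------------------

def _descreening_integral(
    coords: np.ndarray, reduced: np.ndarray, scaled: np.ndarray
) -> np.ndarray:
    """HCT pairwise descreening integral I_i (A^-1) for every atom.

    ``reduced`` are the offset-reduced intrinsic radii rho_i - offset;
    ``scaled`` the descreening-scaled reduced radii S_j (rho_j - offset).
    """
    n = coords.shape[0]
    r = cdist(coords, coords)
    I = np.zeros(n)
    for i in range(n):
        rho_i = reduced[i]
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        rij = r[i, mask]
        sj = scaled[mask]
        # atom j fully engulfed by atom i contributes nothing
        active = rij + sj > rho_i
        rij, sj = rij[active], sj[active]
        if rij.size == 0:
            continue
        U = rij + sj
        L = np.maximum(rho_i, np.abs(rij - sj))
        term = (
            1.0 / L
            - 1.0 / U
            + 0.25 * (rij - sj ** 2 / rij) * (1.0 / U ** 2 - 1.0 / L ** 2)
            + 0.5 * np.log(L / U) / rij
        )
        # atom i's center lies inside sphere j: add the interior correction
        inside = sj > rij + rho_i
        term[inside] += 2.0 * (1.0 / rho_i - 1.0 / L[inside])
        I[i] += 0.5 * np.sum(term)
    return I


def effective_born_radii(
    frame: np.ndarray,
    topology: Topology,
    params: GBModelParams = GBModelParams(),
    selection=None,
) -> np.ndarray:
    """Per-atom effective Born radii (A) for the selected sub-system.

    An isolated atom recovers its offset-reduced intrinsic radius (the
    tanh correction vanishes at zero descreening integral).
    """
    sel = (
        np.arange(topology.n_atoms) if selection is None
        else np.asarray(selection, dtype=int)
    )
    rho = topology.gb_radii[sel]
    screen = topology.gb_screens[sel]
    reduced = rho - params.radius_offset
    if (reduced <= 0).any():
        bad = int(sel[np.argmin(reduced)])
        raise ValueError(
            f"atom {bad}: intrinsic radius must exceed the offset "
            f"{params.radius_offset} A"
        )
    I = _descreening_integral(np.asarray(frame, float)[sel], reduced, screen * reduced)
    psi = I * reduced
    tanh_arg = (
        params.obc_alpha * psi
        - params.obc_beta * psi ** 2
        + params.obc_gamma * psi ** 3
    )
    inv_R = 1.0 / reduced - np.tanh(tanh_arg) / rho
    return 1.0 / inv_R


# ---------------------------------------------------------------------------
# GB polar energy
# ---------------------------------------------------------------------------

def gb_polar_energy(
    frame: np.ndarray,
    topology: Topology,
    selection=None,
    params: GBModelParams = GBModelParams(),
    born_radii: np.ndarray | None = None,
) -> float:
    """GB polar solvation free energy (kcal/mol) of a selection.

    -k_e/2 (1/e_in - 1/e_out) * sum_ij q_i q_j / f_GB(r_ij, R_i, R_j),
    self-terms included (the i=j term is the Born ion energy).
    """
    sel = (
        np.arange(topology.n_atoms) if selection is None
        else np.asarray(selection, dtype=int)
    )
    if sel.size == 0:
        return 0.0
    x = np.asarray(frame, float)[sel]
    q = topology.charges[sel]
    R = (
        effective_born_radii(frame, topology, params, sel)
        if born_radii is None
        else np.asarray(born_radii, float)
    )
    r2 = cdist(x, x) ** 2
    RiRj = np.outer(R, R)
    f = np.sqrt(r2 + RiRj * np.exp(-r2 / (4.0 * RiRj)))
    pref = -0.5 * COULOMB_CONSTANT * (
        1.0 / params.interior_dielectric - 1.0 / params.exterior_dielectric
    )
    return float(pref * np.sum(np.outer(q, q) / f))


def delta_gpol_binding(
    frame: np.ndarray,
    topology: Topology,
    params: GBModelParams = GBModelParams(),
) -> float:
    """Binding change in GB polar solvation from one frame.

    G_pol(complex) - G_pol(receptor) - G_pol(ligand), with effective radii
    recomputed for each state from the same coordinates.
    """
    rec, lig = topology.receptor_selection, topology.ligand_selection
    both = np.concatenate([rec, lig])
    g_c = gb_polar_energy(frame, topology, both, params)
    g_r = gb_polar_energy(frame, topology, rec, params)
    g_l = gb_polar_energy(frame, topology, lig, params)
    return g_c - g_r - g_l


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA with deterministic golden-spiral points
# ---------------------------------------------------------------------------

def golden_spiral_points(n: int) -> np.ndarray:
    """n near-uniform unit-sphere points via the golden-angle spiral."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    rho = np.sqrt(1.0 - z ** 2)
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _canonical_frame(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Coordinates in a molecule-fixed canonical frame.

    Sphere sampling is only rigid-motion invariant if the point set is
    attached to the molecule, so coordinates are centred on the
    weighted centroid and rotated into weighted principal axes, with
    signs fixed by the third moment (falling back to identity for a
    fully symmetric axis, where the ambiguity is a symmetry of the atom
    set and cannot change burial).
    """
    w = weights / weights.sum()
    c = (w[:, None] * x).sum(axis=0)
    y = x - c
    if y.shape[0] == 1:
        return y
    cov = (y * w[:, None]).T @ y
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1]  # descending variance
    for k in range(3):
        m3 = float(np.sum(w * (y @ axes[:, k]) ** 3))
        if abs(m3) > 1e-12:
            axes[:, k] *= np.sign(m3)
    if np.linalg.det(axes) < 0:
        axes[:, 2] *= -1.0
    return y @ axes


def sasa(
    frame: np.ndarray,
    topology: Topology,
    selection=None,
    params: SurfaceParams = SurfaceParams(),
    radii: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Solvent-accessible surface area: total and per-atom (A^2).

    Atom radii are ``gb_radius * radius_scale``; each atom's sphere of
    radius r_i + probe is sampled at ``n_sphere_points`` deterministic
    points, and points buried inside any neighbour sphere are discarded.
    Sampling happens in a molecule-fixed canonical frame, so the result
    is deterministic and rigid-motion invariant.
    """
    sel = (
        np.arange(topology.n_atoms) if selection is None
        else np.asarray(selection, dtype=int)
    )
    x = np.asarray(frame, float)[sel]
    if radii is None:
        radii = topology.gb_radii[sel] * params.radius_scale
    ext = radii + params.probe_radius
    x = _canonical_frame(x, ext)
    pts = golden_spiral_points(params.n_sphere_points)
    n = sel.size
    per_atom = np.zeros(n)
    d = cdist(x, x)
    for i in range(n):
        sphere = x[i] + ext[i] * pts
        # only neighbours whose extended spheres can reach atom i's surface
        nb = np.where((d[i] < ext[i] + ext) & (np.arange(n) != i))[0]
        if nb.size:
            dist2 = cdist(sphere, x[nb], "sqeuclidean")
            buried = (dist2 < (ext[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = 4.0 * np.pi * ext[i] ** 2 * frac
    return float(per_atom.sum()), per_atom


def delta_msa(
    frame: np.ndarray,
    topology: Topology,
    params: SurfaceParams | None = None,
) -> float:
    """Binding-induced change in the scaled-radius surface area (A^2).

    area(complex) - area(receptor) - area(ligand) with radii multiplied
    by ``radius_scale`` and probe 0; <= 0 for partners in contact.
    """
    if params is None:
        params = SurfaceParams(probe_radius=0.0, radius_scale=1.1)
    rec, lig = topology.receptor_selection, topology.ligand_selection
    both = np.concatenate([rec, lig])
    a_c, _ = sasa(frame, topology, both, params)
    a_r, _ = sasa(frame, topology, rec, params)
    a_l, _ = sasa(frame, topology, lig, params)
    return a_c - a_r - a_l
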