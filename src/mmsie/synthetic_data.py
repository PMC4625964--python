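"""Synthetic toy complexes, correlated trajectories, and component fixtures.

Everything here is deterministic for a fixed seed so the full pipeline
is testable without any external dataset:

* :func:`make_toy_complex` builds a small two-chain receptor-ligand
  system with hand-computable pairwise energies and, optionally, a
  designed hydrogen-bond triple at a requested distance/angle;
* :func:`sample_correlated_trajectory` draws zero-mean Gaussian
  displacements around a reference frame with a designed block
  correlation structure (ground truth for cross-correlation and PCA
  recovery — the displacement distribution, not dynamics realism, is
  what those analyses measure);
* :func:`make_component_fixtures` writes the published per-complex
  MM-GBSA and SIE component tables for the four MDMX inhibitors (PMI,
  pDI, WK23, WW8) as delimited text, the inputs to the combiner checks.

Documented reference configuration: a 1-atom receptor (q = +1) and a
1-atom ligand (q = -1) at 3.320637 A gives a Coulomb energy of exactly
-100.0 kcal/mol at dielectric 1 (k_e = 332.0637 kcal mol^-1 A e^-2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model_io import (
    Atom,
    Topology,
    Trajectory,
    write_pdb_models,
    write_topology_sidecar,
)
from .endpoint_energies import EnergyComponents, SIEComponents

__all__ = [
    "HBondDesign",
    "ToyComplexSpec",
    "CorrelatedMotionSpec",
    "make_toy_complex",
    "sample_correlated_trajectory",
    "make_component_fixtures",
    "load_mmgbsa_components",
    "load_sie_components",
    "MMGBSA_COMPONENT_TABLE",
    "SIE_COMPONENT_TABLE",
    "HBOND_TABLE",
]

# ---------------------------------------------------------------------------
# Published per-complex component tables (kcal/mol; dispersion after mean).
# Rows: four inhibitor-MDMX complexes.  dG_exp are the experimental
# reference affinities.  Missing dispersions are None.
# ---------------------------------------------------------------------------

MMGBSA_COMPONENT_TABLE = {
    "PMI": {
        "dE_ele": (-136.2, 7.6), "dE_vdw": (-64.8, 2.1),
        "dG_nonpol": (-9.5, 0.1), "dG_pol": (158.3, 8.7),
        "-TdS": (38.9, 1.2), "dG_bind": (-13.3, None), "dG_exp": (-10.1, None),
    },
    "pDI": {
        "dE_ele": (-141.9, 8.4), "dE_vdw": (-55.1, 2.1),
        "dG_nonpol": (-8.5, 0.3), "dG_pol": (161.9, 10.2),
        "-TdS": (32.9, 1.6), "dG_bind": (-10.7, None), "dG_exp": (-8.5, None),
    },
    "WK23": {
        "dE_ele": (-32.9, 6.4), "dE_vdw": (-36.0, 1.9),
        "dG_nonpol": (-5.1, 0.1), "dG_pol": (46.7, 6.8),
        "-TdS": (18.9, 1.1), "dG_bind": (-8.4, None), "dG_exp": (-6.1, None),
    },
    "WW8": {
        "dE_ele": (-53.1, 6.8), "dE_vdw": (-37.1, 1.4),
        "dG_nonpol": (-5.5, 0.2), "dG_pol": (67.1, 7.2),
        "-TdS": (19.7, 1.5), "dG_bind": (-8.9, None), "dG_exp": (-6.8, None),
    },
}

SIE_COMPONENT_TABLE = {
    "PMI": {
        "dE_vdW": (-61.11, 2.08), "dE_c": (-64.99, 7.48),
        "gamma_dMSA": (-11.67, 0.58), "dG_R": (63.13, 6.73),
        "C": (-2.89, 0.0), "dG_bind": (-10.71, 0.47),
    },
    "pDI": {
        "dE_vdW": (-58.54, 2.41), "dE_c": (-66.67, 9.82),
        "gamma_dMSA": (-10.84, 0.61), "dG_R": (68.98, 7.53),
        "C": (-2.89, 0.0), "dG_bind": (-9.92, 1.97),
    },
    "WK23": {
        "dE_vdW": (-36.57, 1.11), "dE_c": (-15.84, 2.87),
        "gamma_dMSA": (-6.29, 0.12), "dG_R": (20.52, 3.05),
        "C": (-2.89, 0.0), "dG_bind": (-6.89, 0.30),
    },
    "WW8": {
        "dE_vdW": (-37.82, 1.44), "dE_c": (-21.58, 3.68),
        "gamma_dMSA": (-6.91, 0.42), "dG_R": (26.23, 3.45),
        "C": (-2.89, 0.0), "dG_bind": (-7.09, 3.54),
    },
}

#: key hydrogen bond per complex: donor, acceptor, distance A, angle deg, occ %
HBOND_TABLE = {
    "PMI": ("Trp7'-NE1-HE1", "Met53-O", 2.83, 149.25, 92.31),
    "pDI": ("Trp7'-NE1-HE1", "Met53-O", 2.91, 138.53, 90.02),
    "WK23": ("WK23-N11-H4", "Met53-O", 2.83, 157.25, 97.04),
    "WW8": ("WW8-N8-H3", "Met53-O", 2.92, 146.35, 79.24),
}


@dataclass(frozen=True)
class HBondDesign:
    """Target geometry for one designed donor-H...acceptor triple."""

    distance: float = 2.83  # donor heavy ... acceptor, A
    angle: float = 149.25  # at the hydrogen, deg
    dh_length: float = 1.0  # donor-H bond length, A


@dataclass(frozen=True)
class ToyComplexSpec:
    """Parameters of a deterministic two-chain toy complex."""

    n_receptor_residues: int = 3
    atoms_per_residue: int = 2
    ligand_atoms: int = 2
    separation: float = 3.320637  # A, receptor edge to first ligand atom
    charge_pattern: tuple[tuple[float, ...], tuple[float, ...]] = (
        (0.4, -0.4, 0.2, -0.2), (-0.3, 0.3, -0.1)
    )
    lj_pattern: tuple[tuple[float, float], ...] = ((3.2, 0.1), (3.0, 0.15))
    designed_hbond: HBondDesign | None = None
    seed: int = 0


@dataclass(frozen=True)
class CorrelatedMotionSpec:
    """Designed displacement statistics for a Gaussian trajectory.

    ``block_partition`` assigns each selected atom to a block;
    ``target_block_correlations`` is the between-block correlation
    matrix (unit diagonal); ``per_atom_variance`` is the per-axis
    displacement variance in A^2 (a scalar, or one value per atom —
    low-variance atoms make good anchors for superposition fits).
    """

    block_partition: tuple[int, ...]
    target_block_correlations: tuple[tuple[float, ...], ...]
    per_atom_variance: float | tuple[float, ...] = 0.25
    n_frames: int = 5000
    frame_spacing: float = 10.0  # ps
    seed: int = 0


def _hbond_triple_coords(design: HBondDesign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Donor heavy, H, acceptor positions realizing the designed geometry.

    Donor at origin, H along +x; the acceptor closes the triangle with
    the requested donor-acceptor distance and angle at H.
    """
    d, theta = design.distance, np.radians(design.angle)
    b = design.dh_length
    # |HA| from the law of cosines in triangle D-H-A
    disc = b * b * np.cos(theta) ** 2 - b * b + d * d
    rho = b * np.cos(theta) + np.sqrt(disc) if disc >= 0 else np.nan
    if not np.isfinite(rho) or rho <= 0:
        raise ValueError(
            f"infeasible hydrogen-bond geometry: d={design.distance} A, "
            f"angle={design.angle} deg"
        )
    donor = np.zeros(3)
    hyd = np.array([b, 0.0, 0.0])
    acc = hyd + rho * np.array([-np.cos(theta), np.sin(theta), 0.0])
    return donor, hyd, acc


def make_toy_complex(
    spec: ToyComplexSpec = ToyComplexSpec(),
    outdir: str | Path | None = None,
) -> tuple[Topology, np.ndarray]:
    """Build a toy receptor-ligand complex; optionally write PDB + sidecar.

    Receptor residues sit on a 3.8-A x-grid with small deterministic
    in-residue offsets; the first ligand atom sits ``separation`` A along
    +x from the receptor's rightmost atom (so the 1-atom/1-atom case has
    an exactly known pair distance).  If ``designed_hbond`` is set, a
    donor(N)+H pair is appended to the receptor and an acceptor(O) to the
    ligand, placed 8 A off the main cluster at the designed geometry.

    Output files for the same spec are byte-identical across runs.
    """
    rq, lq = spec.charge_pattern
    (rsig, reps), (lsig, leps) = spec.lj_pattern
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int, float, float]] = []

    k = 0
    for r in range(spec.n_receptor_residues):
        for a in range(spec.atoms_per_residue):
            coords.append(np.array([
                3.8 * r + 1.3 * (a % 2),
                1.3 * (a // 2),
                0.6 * ((a + r) % 2),
            ]))
            atoms.append(Atom(
                serial=k, name=f"C{a + 1}", element="C", residue_index=r + 1,
                residue_name="TOY", chain_id="A",
                charge=rq[k % len(rq)], lj_sigma=rsig, lj_epsilon=reps,
                gb_radius=1.7, gb_screen=0.72, mass=12.011,
            ))
            k += 1
    x_edge = max(c[0] for c in coords)
    n_rec_core = k
    for a in range(spec.ligand_atoms):
        coords.append(np.array([
            x_edge + spec.separation + 1.4 * (a // 2),
            1.4 * (a % 2),
            0.0,
        ]))
        atoms.append(Atom(
            serial=k, name=f"L{a + 1}", element="C", residue_index=1,
            residue_name="LIG", chain_id="B",
            charge=lq[a % len(lq)], lj_sigma=lsig, lj_epsilon=leps,
            gb_radius=1.6, gb_screen=0.72, mass=14.0,
        ))
        k += 1
    n_lig_core = spec.ligand_atoms

    receptor_idx = list(range(n_rec_core))
    ligand_idx = list(range(n_rec_core, n_rec_core + n_lig_core))

    if spec.designed_hbond is not None:
        donor_xyz, h_xyz, acc_xyz = _hbond_triple_coords(spec.designed_hbond)
        offset = np.array([0.0, 8.0, 0.0])  # keep the triple geometry clean
        d_idx, h_idx, a_idx = k, k + 1, k + 2
        coords.extend([donor_xyz + offset, h_xyz + offset, acc_xyz + offset])
        atoms.append(Atom(
            serial=d_idx, name="N1", element="N",
            residue_index=spec.n_receptor_residues + 1, residue_name="DON",
            chain_id="A", charge=-0.4, lj_sigma=3.3, lj_epsilon=0.17,
            gb_radius=1.55, gb_screen=0.79, mass=14.007, is_donor_heavy=True,
        ))
        atoms.append(Atom(
            serial=h_idx, name="H1", element="H",
            residue_index=spec.n_receptor_residues + 1, residue_name="DON",
            chain_id="A", charge=0.3, lj_sigma=1.0, lj_epsilon=0.016,
            gb_radius=1.2, gb_screen=0.85, mass=1.008,
        ))
        atoms.append(Atom(
            serial=a_idx, name="O1", element="O", residue_index=2,
            residue_name="LIG", chain_id="B", charge=-0.5, lj_sigma=3.0,
            lj_epsilon=0.21, gb_radius=1.5, gb_screen=0.85, mass=15.999,
            is_acceptor=True,
        ))
        bonds.append((d_idx, h_idx, 450.0, spec.designed_hbond.dh_length))
        receptor_idx.extend([d_idx, h_idx])
        ligand_idx.append(a_idx)
        k += 3

    topo = Topology(
        atoms=atoms,
        receptor_selection=np.array(receptor_idx, dtype=int),
        ligand_selection=np.array(ligand_idx, dtype=int),
        bonds=bonds,
    )
    frame = np.array(coords)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        traj = Trajectory(frame[None, :, :], np.array([0.0]), topo)
        write_pdb_models(outdir / "toy_complex.pdb", traj)
        write_topology_sidecar(outdir / "toy_complex.topology.yaml", topo)
    return topo, frame


def sample_correlated_trajectory(
    reference: np.ndarray,
    spec: CorrelatedMotionSpec,
    topology: Topology | None = None,
) -> Trajectory:
    """Gaussian displacement trajectory with designed block correlations.

    Each axis is an independent draw from N(0, S) with
    S = sqrt(v) C sqrt(v), where C has unit diagonal and entry
    ``target_block_correlations[b_i][b_j]`` between atoms of blocks
    b_i != b_j (and also within a block where the design says so).
    The design matrix must be positive semidefinite.
    """
    reference = np.asarray(reference, dtype=float)
    n = reference.shape[0]
    part = np.asarray(spec.block_partition, dtype=int)
    if part.shape != (n,):
        raise ValueError("block_partition must assign every atom to a block")
    B = np.asarray(spec.target_block_correlations, dtype=float)
    C = B[np.ix_(part, part)]
    np.fill_diagonal(C, 1.0)
    evals = np.linalg.eigvalsh(C)
    if evals.min() < -1e-10:
        raise ValueError(
            f"designed correlation matrix is not positive semidefinite "
            f"(smallest eigenvalue {evals.min():.3e})"
        )
    v = np.broadcast_to(
        np.asarray(spec.per_atom_variance, dtype=float), (n,)
    )
    sd = np.sqrt(v)
    S = C * np.outer(sd, sd)
    # eigendecomposition square root tolerates exact semidefiniteness
    w, V = np.linalg.eigh(S)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, 3, n))
    disp = np.einsum("ij,fkj->fki", L, z)  # frames x 3 x n
    frames = reference[None, :, :] + disp.transpose(0, 2, 1)
    times = spec.frame_spacing * np.arange(spec.n_frames, dtype=float)
    # strictly increasing times must start somewhere; keep t=0 for frame 0
    return Trajectory(coordinates=frames, times=times, topology=topology)


# ---------------------------------------------------------------------------
# Component fixtures (delimited text)
# ---------------------------------------------------------------------------

def _table_frame(table: dict) -> pd.DataFrame:
    rows = {}
    for cplx, comp in table.items():
        row = {}
        for key, (mean, std) in comp.items():
            row[key] = mean
            row[key + "_std"] = std if std is not None else np.nan
        rows[cplx] = row
    df = pd.DataFrame(rows).T
    df.index.name = "complex"
    return df


def make_component_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the published MM-GBSA / SIE component tables and the key
    hydrogen-bond table as CSV; stable content across runs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    t1 = outdir / "mmgbsa_components.csv"
    _table_frame(MMGBSA_COMPONENT_TABLE).to_csv(t1, float_format="%.4f")
    paths["mmgbsa"] = t1
    t2 = outdir / "sie_components.csv"
    _table_frame(SIE_COMPONENT_TABLE).to_csv(t2, float_format="%.4f")
    paths["sie"] = t2
    t3 = outdir / "hbond_key.csv"
    with open(t3, "w") as fh:
        fh.write("complex,donor,acceptor,distance_A,angle_deg,occupancy_pct\n")
        for cplx, (don, acc, d, a, occ) in HBOND_TABLE.items():
            fh.write(f"{cplx},{don},{acc},{d},{a},{occ}\n")
    paths["hbond"] = t3
    return paths


def load_mmgbsa_components(name: str | None = None):
    """Published MM-GBSA components as :class:`EnergyComponents`.

    The source table's "WW9" column-header typo is already normalized
    to WW8.  Returns one set for ``name`` or a dict over all complexes.
    """
    def one(c):
        t = MMGBSA_COMPONENT_TABLE[c]
        return EnergyComponents(
            ele=t["dE_ele"][0], vdw=t["dE_vdw"][0], gpol=t["dG_pol"][0],
            gnonpol=t["dG_nonpol"][0], minus_T_dS=t["-TdS"][0],
        )
    if name is not None:
        return one(name)
    return {c: one(c) for c in MMGBSA_COMPONENT_TABLE}


def load_sie_components(name: str | None = None):
    """Published SIE components as :class:`SIEComponents`."""
    def one(c):
        t = SIE_COMPONENT_TABLE[c]
        return SIEComponents(
            coulomb_Din=t["dE_c"][0], vdw=t["dE_vdW"][0],
            reaction_field=t["dG_R"][0], msa_term=t["gamma_dMSA"][0],
        )
    if name is not None:
        return one(name)
    return {c: one(c) for c in SIE_COMPONENT_TABLE}
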