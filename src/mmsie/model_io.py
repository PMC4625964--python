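"""Data model for molecular systems and trajectories, plus file I/O.

The in-memory model is deliberately small: an :class:`Atom` carries the
static per-atom force-field quantities (partial charge, Lennard-Jones
``sigma``/``epsilon``, intrinsic Born radius and descreening scale, mass,
donor/acceptor flags), a :class:`Topology` is an ordered atom list with
receptor/ligand selections, and a :class:`Trajectory` is a
``(n_frames, n_atoms, 3)`` coordinate array in Angstrom with per-frame
times in picoseconds.

Units are fixed throughout the package: Angstrom, picosecond, kcal/mol,
elementary charge, amu.  Atom indices are 0-based internally; 1-based
serials appear only in files.

Supported formats:

* multi-model PDB (read/write, via MDAnalysis),
* a versioned YAML topology sidecar (schema ``mmsie-topology/1``) carrying
  the per-atom parameters PDB cannot hold,
* plain whitespace-delimited text trajectories (``n_frames * n_atoms``
  rows of x y z) for synthetic data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "FrameSelection",
    "read_pdb_models",
    "write_pdb_models",
    "read_topology_sidecar",
    "write_topology_sidecar",
    "read_plain_trajectory",
    "write_plain_trajectory",
    "select_frames",
]

SIDECAR_SCHEMA = "mmsie-topology/1"

#: required per-atom fields in the sidecar, in file order
_ATOM_FIELDS = (
    "serial",
    "name",
    "element",
    "residue_index",
    "residue_name",
    "chain_id",
    "charge",
    "lj_sigma",
    "lj_epsilon",
    "gb_radius",
    "gb_screen",
    "mass",
    "is_donor_heavy",
    "is_acceptor",
)


@dataclass
class Atom:
    """One atom with the static parameters the analysis needs.

    ``lj_sigma``/``lj_epsilon`` are the 12-6 Lennard-Jones parameters in
    Angstrom and kcal/mol; ``gb_radius`` is the intrinsic Born radius in
    Angstrom and ``gb_screen`` the dimensionless descreening scale used by
    the pairwise generalized-Born integrals.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    charge: float = 0.0
    lj_sigma: float = 1.0
    lj_epsilon: float = 0.0
    gb_radius: float = 1.5
    gb_screen: float = 0.8
    is_donor_heavy: bool = False
    is_acceptor: bool = False
    mass: float = 12.0

    def __post_init__(self) -> None:
        if self.lj_sigma <= 0:
            raise ValueError(f"atom {self.serial}: lj_sigma must be > 0")
        if self.lj_epsilon < 0:
            raise ValueError(f"atom {self.serial}: lj_epsilon must be >= 0")
        if self.gb_radius <= 0:
            raise ValueError(f"atom {self.serial}: gb_radius must be > 0")
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be > 0")


@dataclass
class Topology:
    """Ordered atom list plus receptor/ligand selections (0-based indices).

    ``bonds`` holds ``(i, j, k, r0)`` harmonic bond terms (kcal/mol/A^2, A)
    used by toy-system normal-mode analysis and by hydrogen-bond donor
    lookup; it may be empty for purely non-bonded analyses.
    """

    atoms: list[Atom]
    receptor_selection: np.ndarray
    ligand_selection: np.ndarray
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.receptor_selection = np.asarray(self.receptor_selection, dtype=int)
        self.ligand_selection = np.asarray(self.ligand_selection, dtype=int)
        overlap = np.intersect1d(self.receptor_selection, self.ligand_selection)
        if overlap.size:
            raise ValueError(
                f"receptor and ligand selections overlap at atoms {overlap.tolist()}"
            )
        n = len(self.atoms)
        for sel, label in (
            (self.receptor_selection, "receptor"),
            (self.ligand_selection, "ligand"),
        ):
            if sel.size and (sel.min() < 0 or sel.max() >= n):
                raise ValueError(f"{label} selection index out of range (n_atoms={n})")
        # residue_index non-decreasing within each chain
        by_chain: dict[str, int] = {}
        for a in self.atoms:
            prev = by_chain.get(a.chain_id)
            if prev is not None and a.residue_index < prev:
                raise ValueError(
                    f"residue_index decreases within chain {a.chain_id!r} "
                    f"at atom serial {a.serial}"
                )
            by_chain[a.chain_id] = a.residue_index

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    # -- vectorized parameter views -------------------------------------
    def _array(self, attr: str, dtype=float) -> np.ndarray:
        return np.array([getattr(a, attr) for a in self.atoms], dtype=dtype)

    @property
    def charges(self) -> np.ndarray:
        return self._array("charge")

    @property
    def lj_sigmas(self) -> np.ndarray:
        return self._array("lj_sigma")

    @property
    def lj_epsilons(self) -> np.ndarray:
        return self._array("lj_epsilon")

    @property
    def gb_radii(self) -> np.ndarray:
        return self._array("gb_radius")

    @property
    def gb_screens(self) -> np.ndarray:
        return self._array("gb_screen")

    @property
    def masses(self) -> np.ndarray:
        return self._array("mass")

    @property
    def residue_indices(self) -> np.ndarray:
        return self._array("residue_index", dtype=int)

    def selection_charge(self, selection: np.ndarray) -> float:
        """Total charge of a selection (finite by construction)."""
        q = float(self.charges[np.asarray(selection, dtype=int)].sum())
        if not np.isfinite(q):
            raise ValueError("selection charge is not finite")
        return q

    def bonded_hydrogens(self, heavy_index: int) -> list[int]:
        """Indices of hydrogens bonded to ``heavy_index`` per the bond list."""
        out = []
        for i, j, _k, _r0 in self.bonds:
            for a, b in ((i, j), (j, i)):
                if a == heavy_index and self.atoms[b].element.upper() == "H":
                    out.append(b)
        return out


@dataclass
class Trajectory:
    """Coordinate frames (A) with strictly increasing times (ps)."""

    coordinates: np.ndarray
    times: np.ndarray
    topology: Topology | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.coordinates.shape[0],):
            raise ValueError("times must have one entry per frame")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.topology is not None and self.topology.n_atoms != self.n_atoms:
            raise ValueError(
                f"topology has {self.topology.n_atoms} atoms but frames "
                f"have {self.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class FrameSelection:
    """Half-open time window (start_time, end_time] sampled at
    ``start_time + k*stride``, k >= 1 (all in ps).

    "N snapshots from the last T ns at an interval of s" is expressed
    exactly: the boundary frame at ``start_time`` belongs to the earlier
    part of the trajectory and is excluded, so the window [40 ns, 60 ns]
    at 100 ps yields 200 frames (400 ps yields 50)."""

    start_time: float
    end_time: float
    stride: float

    def __post_init__(self) -> None:
        if self.stride <= 0:
            raise ValueError("stride must be positive")
        if self.end_time < self.start_time:
            raise ValueError("end_time must be >= start_time")


# ---------------------------------------------------------------------------
# PDB read / write
# ---------------------------------------------------------------------------

def _scan_model_atom_counts(path: Path) -> list[int]:
    """Count ATOM/HETATM records per MODEL block (one block if no MODEL)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                current += 1
    if not saw_model:
        counts = [current]
    elif in_model:  # unterminated final MODEL
        counts.append(current)
    return counts


def read_pdb_models(path: str | Path) -> Trajectory:
    """Read a (multi-)model PDB into a Trajectory.

    Frames are ordered by MODEL number; HETATM records are retained; atom
    ordering is identical across models.  Atoms get a skeleton topology
    (names, elements, residues, chains) with default force-field
    parameters — real parameters come from the sidecar.

    Raises ``ValueError`` naming the model if atom counts differ across
    models.  A missing element column is inferred from the atom name with
    a warning.
    """
    path = Path(path)
    counts = _scan_model_atom_counts(path)
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts, start=1) if c != counts[0])
        raise ValueError(
            f"inconsistent atom counts across models: model {bad} has "
            f"{counts[bad - 1]} atoms, model 1 has {counts[0]}"
        )

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="PDB")
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory])
        elements = []
        for a in u.atoms:
            try:
                el = a.element.strip()
            except Exception:
                el = ""
            if not el:
                el = "".join(c for c in a.name if c.isalpha())[:1]
                warnings.warn(
                    f"element missing for atom {a.ix}; inferred {el!r} from name",
                    stacklevel=2,
                )
            elements.append(el)
        atoms = [
            Atom(
                serial=i,
                name=str(a.name),
                element=elements[i],
                residue_index=int(a.resid),
                residue_name=str(a.resname),
                chain_id=str(getattr(a, "chainID", "") or a.segid or "A"),
            )
            for i, a in enumerate(u.atoms)
        ]
    topo = Topology(atoms=atoms, receptor_selection=np.arange(len(atoms)),
                    ligand_selection=np.array([], dtype=int))
    times = np.arange(coords.shape[0], dtype=float)
    return Trajectory(coordinates=coords, times=times, topology=topo)


def write_pdb_models(
    path: str | Path,
    traj: Trajectory,
    topology: Topology | None = None,
) -> None:
    """Write a Trajectory as a multi-model PDB (one MODEL per frame)."""
    topo = topology or traj.topology
    if topo is None:
        raise ValueError("a topology is required to write PDB")
    path = Path(path)
    with open(path, "w") as fh:
        for m, frame in enumerate(traj.coordinates, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (atom, xyz) in enumerate(zip(topo.atoms, frame), start=1):
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                fh.write(
                    f"ATOM  {i:5d} {name[:4]:<4s} {atom.residue_name[:3]:>3s} "
                    f"{atom.chain_id[:1]:1s}{atom.residue_index:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          "
                    f"{atom.element[:2]:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Topology sidecar (YAML, versioned)
# ---------------------------------------------------------------------------

def write_topology_sidecar(path: str | Path, topology: Topology) -> None:
    doc = {
        "format": SIDECAR_SCHEMA,
        "atoms": [
            {f: getattr(a, f) for f in _ATOM_FIELDS} for a in topology.atoms
        ],
        "receptor_selection": topology.receptor_selection.tolist(),
        "ligand_selection": topology.ligand_selection.tolist(),
        "bonds": [list(b) for b in topology.bonds],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_topology_sidecar(
    path: str | Path, expected_n_atoms: int | None = None
) -> Topology:
    """Read the YAML topology sidecar; validates schema and invariants.

    Missing per-atom fields and atom-count mismatches with a companion
    structure are hard errors naming the atom and field.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("format") != SIDECAR_SCHEMA:
        raise ValueError(
            f"unrecognized sidecar format {doc.get('format') if isinstance(doc, dict) else doc!r}; "
            f"expected {SIDECAR_SCHEMA!r}"
        )
    atoms = []
    for k, rec in enumerate(doc.get("atoms", [])):
        for fname in _ATOM_FIELDS:
            if fname not in rec:
                raise ValueError(f"atom {k}: {fname}")
        atoms.append(Atom(**{f: rec[f] for f in _ATOM_FIELDS}))
    if expected_n_atoms is not None and len(atoms) != expected_n_atoms:
        raise ValueError(
            f"sidecar lists {len(atoms)} atoms but companion structure has "
            f"{expected_n_atoms}"
        )
    topo = Topology(
        atoms=atoms,
        receptor_selection=np.asarray(doc.get("receptor_selection", []), dtype=int),
        ligand_selection=np.asarray(doc.get("ligand_selection", []), dtype=int),
        bonds=[tuple(b) for b in doc.get("bonds", [])],
    )
    return topo


# ---------------------------------------------------------------------------
# Plain-text trajectories
# ---------------------------------------------------------------------------

def write_plain_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Whitespace-delimited frames*atoms rows of x y z, times in a header."""
    with open(path, "w") as fh:
        fh.write(f"# mmsie-trajectory/1 n_frames={traj.n_frames} "
                 f"n_atoms={traj.n_atoms}\n")
        fh.write("# times_ps " + " ".join(f"{t:.6f}" for t in traj.times) + "\n")
        for frame in traj.coordinates:
            np.savetxt(fh, frame, fmt="%.8f")


def read_plain_trajectory(
    path: str | Path, topology: Topology | None = None
) -> Trajectory:
    times = None
    n_frames = n_atoms = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# mmsie-trajectory/1"):
            parts = dict(p.split("=") for p in first.split()[2:])
            n_frames, n_atoms = int(parts["n_frames"]), int(parts["n_atoms"])
            second = fh.readline()
            times = np.array([float(x) for x in second.split()[2:]])
            data = np.loadtxt(fh)
        else:
            data = np.loadtxt(path)
    if n_atoms is None:
        if topology is None:
            raise ValueError(
                "headerless plain trajectory needs a topology to infer shape"
            )
        n_atoms = topology.n_atoms
        n_frames = data.shape[0] // n_atoms
    coords = data.reshape(n_frames, n_atoms, 3)
    if times is None:
        times = np.arange(n_frames, dtype=float)
    return Trajectory(coordinates=coords, times=times, topology=topology)


# ---------------------------------------------------------------------------
# Frame selection
# ---------------------------------------------------------------------------

def select_frames(traj: Trajectory, sel: FrameSelection) -> Trajectory:
    """Pick frames whose timestamps fall on ``start + k*stride`` (k >= 1)
    within the half-open window, matched to the grid within half the
    native frame spacing.

    The two snapshot protocols used for end-point scoring — 200 frames at a
    100-ps interval over the last 20 ns, and 50 frames at 400 ps — are exact
    instances of this grid.  Raises on an empty selection (e.g. a stride
    larger than the window).
    """
    times = traj.times
    if times.size > 1:
        native = np.min(np.diff(times))
    else:
        native = sel.stride
    tol = 0.5 * native
    n_grid = int(np.floor((sel.end_time - sel.start_time) / sel.stride + 1e-9))
    grid = sel.start_time + sel.stride * np.arange(1, n_grid + 1)
    idx = []
    for g in grid:
        j = int(np.argmin(np.abs(times - g)))
        if abs(times[j] - g) < tol:
            idx.append(j)
    idx = sorted(set(idx))
    if not idx:
        raise ValueError(
            f"frame selection [{sel.start_time}, {sel.end_time}] ps @ "
            f"{sel.stride} ps matches no frames"
        )
    return Trajectory(
        coordinates=traj.coordinates[idx],
        times=times[idx],
        topology=traj.topology,
    )
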