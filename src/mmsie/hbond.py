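"""Geometric hydrogen-bond detection and occupancy over a trajectory.

A donor-H...acceptor triple qualifies in a frame iff the heavy-atom
donor-acceptor distance is strictly less than ``max_heavy_distance``
(default 3.5 A) and the angle at the hydrogen subtended by the donor
heavy atom and the acceptor is strictly greater than ``min_angle``
(default 120 deg).  Occupancy is the percentage of frames in which a
triple qualifies; mean distance and angle are taken over qualifying
frames only.

Donor heavy atoms and acceptors come from topology flags (set in the
sidecar); a donor's hydrogens come from the topology bond list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model_io import Topology, Trajectory

__all__ = ["HBondCriteria", "HBondRecord", "detect_hbonds", "hbond_occupancy"]


@dataclass(frozen=True)
class HBondCriteria:
    max_heavy_distance: float = 3.5  # A, donor heavy ... acceptor
    min_angle: float = 120.0  # deg, at the hydrogen

    def __post_init__(self):
        if self.max_heavy_distance <= 0:
            raise ValueError("max_heavy_distance must be positive")
        if not 0 < self.min_angle <= 180:
            raise ValueError("min_angle must be in (0, 180]")


@dataclass
class HBondRecord:
    donor: str
    hydrogen: str
    acceptor: str
    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    mean_distance: float  # A, over qualifying frames
    mean_angle: float  # deg, over qualifying frames
    occupancy: float  # % of frames


def _label(topology: Topology, i: int) -> str:
    a = topology.atoms[i]
    return f"{a.residue_name}{a.residue_index}-{a.name}"


def _triples(
    topology: Topology, donors_from: np.ndarray, acceptors_from: np.ndarray
):
    """Candidate (donor heavy, H, acceptor) index triples."""
    out = []
    for d in np.asarray(donors_from, dtype=int):
        if not topology.atoms[d].is_donor_heavy:
            continue
        hyds = topology.bonded_hydrogens(int(d))
        if not hyds:
            warnings.warn(
                f"donor {_label(topology, int(d))} has no bonded hydrogen; skipped",
                stacklevel=3,
            )
            continue
        for h in hyds:
            for acc in np.asarray(acceptors_from, dtype=int):
                if topology.atoms[int(acc)].is_acceptor and acc != d:
                    out.append((int(d), int(h), int(acc)))
    return out


def _geometry(frame: np.ndarray, d: int, h: int, a: int) -> tuple[float, float]:
    """Heavy-heavy distance (A) and angle at H (deg)."""
    dist = float(np.linalg.norm(frame[d] - frame[a]))
    v1 = frame[d] - frame[h]
    v2 = frame[a] - frame[h]
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return dist, angle


def detect_hbonds(
    frame: np.ndarray,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
    donors_from=None,
    acceptors_from=None,
) -> list[tuple[int, int, int, float, float]]:
    """Qualifying (donor, H, acceptor, distance, angle) in one frame.

    Both thresholds are strict inequalities; a distance of exactly the
    cutoff or an angle of exactly the minimum does not qualify.
    """
    if donors_from is None:
        donors_from = np.arange(topology.n_atoms)
    if acceptors_from is None:
        acceptors_from = np.arange(topology.n_atoms)
    hits = []
    for d, h, a in _triples(topology, donors_from, acceptors_from):
        dist, angle = _geometry(np.asarray(frame, float), d, h, a)
        if dist < criteria.max_heavy_distance and angle > criteria.min_angle:
            hits.append((d, h, a, dist, angle))
    return hits


def hbond_occupancy(
    traj: Trajectory,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
    donors_from=None,
    acceptors_from=None,
) -> list[HBondRecord]:
    """Occupancy statistics per unique triple, sorted by occupancy.

    occupancy = 100 * (qualifying frames) / (total frames); geometry
    means are over qualifying frames only.
    """
    if traj.n_frames < 1:
        raise ValueError("need at least one frame")
    if donors_from is None:
        donors_from = np.arange(topology.n_atoms)
    if acceptors_from is None:
        acceptors_from = np.arange(topology.n_atoms)
    triples = _triples(topology, donors_from, acceptors_from)
    counts = {t: 0 for t in triples}
    dsum = {t: 0.0 for t in triples}
    asum = {t: 0.0 for t in triples}
    for frame in traj.coordinates:
        for t in triples:
            d, h, a = t
            dist, angle = _geometry(frame, d, h, a)
            if dist < criteria.max_heavy_distance and angle > criteria.min_angle:
                counts[t] += 1
                dsum[t] += dist
                asum[t] += angle
    records = []
    for t in triples:
        if counts[t] == 0:
            continue
        d, h, a = t
        records.append(
            HBondRecord(
                donor=_label(topology, d),
                hydrogen=_label(topology, h),
                acceptor=_label(topology, a),
                donor_index=d,
                hydrogen_index=h,
                acceptor_index=a,
                mean_distance=dsum[t] / counts[t],
                mean_angle=asum[t] / counts[t],
                occupancy=100.0 * counts[t] / traj.n_frames,
            )
        )
    records.sort(key=lambda r: r.occupancy, reverse=True)
    return records
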