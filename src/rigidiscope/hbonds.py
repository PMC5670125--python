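"""Geometric hydrogen-bond detection and persistence tabulation.

A donor–hydrogen–acceptor triplet is counted in a frame when the donor–
acceptor heavy-atom distance is at most ``max_distance`` (default 3.5 Å) and
the D–H···A angle at the hydrogen is at least ``min_angle`` (default 135°) —
a common MD-analysis convention; both cutoffs are configurable. Equivalent
hydrogens on one donor (e.g. the three of an ammonium NZ) are collapsed to a
single record per donor-heavy/acceptor pair, and a frame is counted once per
pair.

Persistence is the percentage of frames in which a pair is detected, reported
to 1 decimal; bonds within one chain are flagged intra-monomer. The default
reporting threshold is 15% presence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .structio import Frame, Topology, TopologyWarning, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "detect_hbonds_frame",
    "hbond_persistence",
    "filter_persistent",
]

DEFAULT_PERSISTENCE_THRESHOLD = 15.0  # %

AtomKey = tuple[str, int, str]  # (chain_id, res_index, atom_name)


@dataclass(frozen=True)
class HBondCriteria:
    max_distance: float = 3.5   # donor–acceptor heavy-atom distance, Å
    min_angle: float = 135.0    # D–H···A angle at the hydrogen, degrees

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")
        if not 0 < self.min_angle <= 180:
            raise ValueError("min_angle must be in (0, 180]")


@dataclass
class HBondRecord:
    donor: AtomKey
    hydrogen: str
    acceptor: AtomKey
    presence_pct: float
    intra_monomer: bool

    def __post_init__(self) -> None:
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor must differ")
        if not 0.0 <= self.presence_pct <= 100.0:
            raise ValueError("presence_pct must be in [0, 100]")


def detect_hbonds_frame(
    frame: Frame,
    topo: Topology,
    criteria: HBondCriteria = HBondCriteria(),
) -> set[tuple[AtomKey, str, AtomKey]]:
    """All (donor, hydrogen-name, acceptor) triplets satisfying the criteria.

    One triplet per donor-heavy/acceptor pair: with several qualifying
    hydrogens, the best-angle one is reported. Deterministic.
    """
    h_idx = np.flatnonzero(topo.is_polar_hydrogen)
    acc_idx = np.flatnonzero(topo.is_acceptor)
    if h_idx.size == 0:
        warnings.warn(
            "no polar hydrogens in frame: no H-bonds detectable",
            TopologyWarning,
            stacklevel=2,
        )
        return set()
    if acc_idx.size == 0:
        return set()
    xyz = frame.coords
    best: dict[tuple[AtomKey, AtomKey], tuple[float, str]] = {}
    acc_xyz = xyz[acc_idx]
    cos_min = np.cos(np.deg2rad(criteria.min_angle))
    for h in h_idx:
        d = topo.h_to_donor[int(h)]
        dvec = acc_xyz - xyz[d]
        dist = np.linalg.norm(dvec, axis=1)
        ok = (dist <= criteria.max_distance) & (acc_idx != d)
        if not ok.any():
            continue
        hd = xyz[d] - xyz[h]
        hd /= np.linalg.norm(hd)
        ha = acc_xyz[ok] - xyz[h]
        ha /= np.linalg.norm(ha, axis=1)[:, None]
        cos_dha = ha @ hd
        # angle >= min_angle  <=>  cos(angle) <= cos(min_angle)
        for a_local, c in zip(np.flatnonzero(ok), cos_dha):
            if c <= cos_min:
                a = int(acc_idx[a_local])
                key = (frame.atoms[d].key, frame.atoms[a].key)
                angle_score = -float(c)  # larger = straighter bond
                prev = best.get(key)
                if prev is None or angle_score > prev[0]:
                    best[key] = (angle_score, frame.atoms[int(h)].name)
    return {(don, hname, acc) for (don, acc), (_, hname) in best.items()}


def hbond_persistence(
    traj: Trajectory,
    topo: Topology | None = None,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBondRecord]:
    """Presence percentage of every donor/acceptor pair seen in >= 1 frame.

    presence_pct = 100 × (frames detected) / (total frames), to 1 decimal;
    records sorted by presence descending (ties by atom keys).
    """
    if topo is None:
        topo = traj.topology
    counts: dict[tuple[AtomKey, AtomKey], int] = {}
    hydro: dict[tuple[AtomKey, AtomKey], str] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", TopologyWarning)
        for frame in traj.frames:
            for don, hname, acc in detect_hbonds_frame(frame, topo, criteria):
                key = (don, acc)
                counts[key] = counts.get(key, 0) + 1
                hydro.setdefault(key, hname)
    n = len(traj)
    records = [
        HBondRecord(
            donor=don,
            hydrogen=hydro[(don, acc)],
            acceptor=acc,
            presence_pct=round(100.0 * c / n, 1),
            intra_monomer=(don[0] == acc[0]),
        )
        for (don, acc), c in counts.items()
    ]
    records.sort(key=lambda r: (-r.presence_pct, r.donor, r.acceptor))
    return records


def filter_persistent(
    records: Iterable[HBondRecord],
    threshold_pct: float = DEFAULT_PERSISTENCE_THRESHOLD,
) -> list[HBondRecord]:
    """Records with presence_pct >= threshold, order preserved."""
    if not 0.0 <= threshold_pct <= 100.0:
        raise ValueError("threshold must be in [0, 100]")
    return [r for r in records if r.presence_pct >= threshold_pct]
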