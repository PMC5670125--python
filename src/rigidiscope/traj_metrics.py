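"""Superposition, RMSD series, per-residue RMSF and mutant−WT differences.

RMSD and RMSF are computed on an atom selection (Cα by default, matching the
distance-fluctuation analysis) after least-squares rigid superposition
(Kabsch). The RMSF reference is the iteratively refined mean structure: each
frame is superposed onto the current mean, the mean is recomputed, and the
procedure repeats until the mean moves by less than a tolerance — a
deterministic, convergent stand-in for "equilibrium positions". No mass
weighting is applied (on a Cα-only selection the weights would be uniform
anyway).

For comparing a variant against the wild-type the per-residue RMSF of
corresponding residues in the different monomers is first averaged
(:func:`average_over_chains`), then subtracted position-by-position
(:func:`delta_rmsf`); negative differences indicate rigidification of the
variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import Frame, Trajectory

__all__ = [
    "RMSFProfile",
    "DeltaProfile",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "average_over_chains",
    "delta_rmsf",
]

MEAN_STRUCTURE_TOL = 1e-6   # Å, convergence of the iterated mean structure
MEAN_STRUCTURE_MAX_ITER = 100


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation (Å).

    ``labels`` are (chain_id, res_index) pairs; after cross-monomer averaging
    the chain component is the concatenation of the averaged chains and each
    residue position appears once.
    """

    labels: list[tuple[str, int]]
    values: np.ndarray
    averaged: bool = False
    n_chains_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values length mismatch")
        if np.any(self.values < 0):
            raise ValueError("RMSF values must be >= 0")


@dataclass
class DeltaProfile:
    """Difference RMSF (variant − wild-type) per residue position."""

    positions: list[int]
    deltas: np.ndarray
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, dtype=float)
        if len(self.positions) != len(self.deltas):
            raise ValueError("positions and deltas length mismatch")


def _check_not_collinear(xyz: np.ndarray) -> None:
    if xyz.shape[0] < 3:
        raise ValueError("superposition needs >= 3 atoms in the subset")
    centered = xyz - xyz.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise ValueError("superposition subset is collinear")


def _fit_rotation(mobile_sub: np.ndarray, ref_sub: np.ndarray):
    """Optimal proper rotation and centroids for subset superposition."""
    mc = mobile_sub.mean(axis=0)
    rc = ref_sub.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_sub - rc, mobile_sub - mc)
    return rot, mc, rc


def kabsch_superpose(
    mobile: Frame,
    ref: Frame,
    subset: str | Sequence[int] | None = "CA",
) -> tuple[Frame, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``ref``.

    The optimal proper rotation (det = +1) and translation are found on the
    atom ``subset`` (Kabsch algorithm via SVD); the whole mobile frame is
    transformed and the minimized RMSD over the subset is returned.
    """
    idx_m = mobile.select(subset)
    idx_r = ref.select(subset)
    if len(idx_m) != len(idx_r):
        raise ValueError(
            f"subset maps {len(idx_m)} mobile atoms onto {len(idx_r)} "
            f"reference atoms"
        )
    mob_sub = mobile.coords[idx_m]
    ref_sub = ref.coords[idx_r]
    _check_not_collinear(ref_sub)
    _check_not_collinear(mob_sub)
    rot, mc, rc = _fit_rotation(mob_sub, ref_sub)
    moved = rot.apply(mobile.coords - mc) + rc
    rmsd = float(np.sqrt(np.mean(np.sum((moved[idx_m] - ref_sub) ** 2, axis=1))))
    return mobile.with_coords(moved), rmsd


def _superposed_subset_coords(
    traj: Trajectory, ref_sub: np.ndarray, idx: np.ndarray
) -> np.ndarray:
    """(F, n, 3) subset coordinates, each frame superposed onto ref_sub."""
    out = np.empty((len(traj), len(idx), 3))
    for f, xyz in enumerate(traj.coords):
        sub = xyz[idx]
        rot, mc, rc = _fit_rotation(sub, ref_sub)
        out[f] = rot.apply(sub - mc) + rc
    return out


def rmsd_series(
    traj: Trajectory,
    ref: Frame,
    subset: str | Sequence[int] | None = "CA",
) -> np.ndarray:
    """Per-frame minimized RMSD (Å) of the trajectory against a reference.

    Each frame is independently superposed onto ``ref`` on the subset.
    """
    idx_t = traj.frames[0].select(subset)
    idx_r = ref.select(subset)
    if len(idx_t) != len(idx_r) or len(idx_t) == 0:
        raise ValueError("reference incompatible with trajectory on subset")
    keys_t = [traj.frames[0].atoms[i].key for i in idx_t]
    keys_r = [ref.atoms[i].key for i in idx_r]
    if keys_t != keys_r:
        raise ValueError("reference atoms do not match trajectory atoms")
    ref_sub = ref.coords[idx_r]
    _check_not_collinear(ref_sub)
    moved = _superposed_subset_coords(traj, ref_sub, idx_t)
    return np.sqrt(np.mean(np.sum((moved - ref_sub) ** 2, axis=2), axis=1))


def mean_structure(
    traj: Trajectory,
    subset: str | Sequence[int] | None = "CA",
    tol: float = MEAN_STRUCTURE_TOL,
    max_iter: int = MEAN_STRUCTURE_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively refined mean subset structure and the aligned coordinates.

    Returns ``(mean, aligned)`` where ``aligned`` has shape (F, n, 3) and each
    frame is superposed onto the converged mean.
    """
    idx = traj.frames[0].select(subset)
    if len(idx) == 0:
        raise ValueError("empty atom subset")
    mean = traj.coords[0][idx]
    _check_not_collinear(mean)
    aligned = _superposed_subset_coords(traj, mean, idx)
    for _ in range(max_iter):
        new_mean = aligned.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        aligned = _superposed_subset_coords(traj, mean, idx)
        if shift < tol:
            break
    return mean, aligned


def rmsf_per_residue(
    traj: Trajectory,
    subset: str | Sequence[int] | None = "CA",
) -> RMSFProfile:
    """Per-residue RMSF about the iterated mean structure.

    RMSF_i = sqrt(⟨‖r_i − ⟨r_i⟩‖²⟩) over frames, after superposing every
    frame onto the converged mean structure on the whole selection.
    """
    if len(traj) < 2:
        raise ValueError("RMSF needs >= 2 frames")
    idx = traj.frames[0].select(subset)
    mean, aligned = mean_structure(traj, subset)
    msf = np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0)
    labels = [
        (traj.frames[0].atoms[i].chain_id, traj.frames[0].atoms[i].res_index)
        for i in idx
    ]
    return RMSFProfile(labels=labels, values=np.sqrt(msf))


def average_over_chains(
    profile: RMSFProfile,
    chain_map: Mapping[str, Sequence[str]] | Sequence[str] | None = None,
) -> RMSFProfile:
    """Average RMSF values of corresponding residues across monomers.

    ``chain_map`` lists the chains to average (default: every chain in the
    profile). The chains must carry identical residue index sets; the result
    has one value per residue position, labelled with the concatenated chain
    ids, and the ``averaged`` flag set.
    """
    if isinstance(chain_map, Mapping):
        chains: list[str] = [c for group in chain_map.values() for c in group]
    elif chain_map is None:
        chains = sorted({c for c, _ in profile.labels})
    else:
        chains = list(chain_map)
    per_chain: dict[str, dict[int, float]] = {c: {} for c in chains}
    for (c, r), v in zip(profile.labels, profile.values):
        if c in per_chain:
            per_chain[c][r] = float(v)
    ref_set = set(per_chain[chains[0]])
    mismatched = []
    for c in chains[1:]:
        diff = ref_set.symmetric_difference(per_chain[c])
        if diff:
            mismatched.extend((c, r) for r in sorted(diff))
    if mismatched:
        raise ValueError(
            f"chains carry different residue sets; offending positions: "
            f"{mismatched[:10]}"
        )
    positions = sorted(ref_set)
    label_chain = "".join(chains)
    values = np.array(
        [np.mean([per_chain[c][r] for c in chains]) for r in positions]
    )
    return RMSFProfile(
        labels=[(label_chain, r) for r in positions],
        values=values,
        averaged=True,
        n_chains_averaged=len(chains),
    )


def delta_rmsf(mutant: RMSFProfile, wildtype: RMSFProfile) -> DeltaProfile:
    """Difference RMSF profile (mutant − wild-type) on common positions.

    Negative values indicate rigidification of the mutant. The summary
    reports the fraction of strictly negative positions (ties count as
    non-negative) and a histogram of the differences.
    """
    if not (mutant.averaged and wildtype.averaged):
        raise ValueError("both profiles must be chain-averaged first")
    mut = {r: v for (_, r), v in zip(mutant.labels, mutant.values)}
    wt = {r: v for (_, r), v in zip(wildtype.labels, wildtype.values)}
    common = sorted(set(mut) & set(wt))
    if not common:
        raise ValueError("profiles share no residue positions")
    deltas = np.array([mut[r] - wt[r] for r in common])
    counts, edges = np.histogram(deltas, bins=20)
    summary = {
        "fraction_negative": float(np.mean(deltas < 0)),
        "mean_delta": float(np.mean(deltas)),
        "median_delta": float(np.median(deltas)),
        "histogram_counts": counts.tolist(),
        "histogram_edges": edges.tolist(),
        "n_positions": len(common),
    }
    return DeltaProfile(positions=common, deltas=deltas, summary=summary)
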