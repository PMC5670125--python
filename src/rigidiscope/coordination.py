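"""Distance-fluctuation (DF) coordination analysis.

The DF parameter of a residue pair (i, j) is the time variance of their
Cα–Cα distance:

    DF_ij = ⟨(d_ij − ⟨d_ij⟩)²⟩

with ⟨·⟩ a plain time average over frames (population variance, 1/F). The
statistic is invariant under per-frame rigid motions — distances do not
change under rotation or translation — so it is computed on raw coordinates
without any superposition, and unlike a coordinate covariance matrix it does
not depend on a choice of reference structure. Low DF means the pair moves in
a coordinated (mutually rigid) fashion; a block pattern in the matrix maps
out rigid substructures such as the monomers of a tetramer. Units are Å².

A two-pass mean-then-variance accumulation is used so that a perfectly rigid
trajectory comes out numerically zero (≲1e-12 Å²) rather than at the
cancellation noise of a sum-of-squares shortcut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structio import Trajectory

__all__ = ["DFMatrix", "df_matrix", "df_block_summary", "df_difference"]


@dataclass
class DFMatrix:
    """Symmetric residue-by-residue matrix of Cα-distance variances (Å²)."""

    labels: list[tuple[str, int]]
    values: np.ndarray
    n_frames: int
    selection: str = "CA"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("DF matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("DF matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("DF values must be >= 0")

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle values (each pair once)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


def df_matrix(traj: Trajectory, scope: str = "tetramer") -> DFMatrix:
    """Distance-fluctuation matrix over all Cα pairs.

    ``scope`` is ``"tetramer"`` (all chains; any oligomer, despite the name)
    or a single chain id, matching the per-monomer calculation.
    """
    if len(traj) < 2:
        raise ValueError("DF needs >= 2 frames")
    frame0 = traj.frames[0]
    idx = frame0.select("CA")
    if scope not in ("tetramer", "all"):
        chain_idx = [i for i in idx if frame0.atoms[i].chain_id == scope]
        if not chain_idx:
            raise ValueError(f"chain {scope!r} not present")
        idx = np.asarray(chain_idx, dtype=int)
    if len(idx) < 2:
        raise ValueError("need >= 2 Calpha atoms")
    labels = [(frame0.atoms[i].chain_id, frame0.atoms[i].res_index) for i in idx]

    coords = traj.coords[:, idx, :]
    n_frames = coords.shape[0]
    # Pass 1: mean pairwise distance; pass 2: variance about it.
    mean_d = np.zeros(len(idx) * (len(idx) - 1) // 2)
    for xyz in coords:
        mean_d += pdist(xyz)
    mean_d /= n_frames
    var_d = np.zeros_like(mean_d)
    for xyz in coords:
        dev = pdist(xyz) - mean_d
        var_d += dev * dev
    var_d /= n_frames

    return DFMatrix(
        labels=labels,
        values=squareform(var_d),
        n_frames=n_frames,
        selection="CA",
        metadata={"scope": scope, "units": "A^2", "variance": "population"},
    )


def _block_indices(
    dfm: DFMatrix, blocks: Sequence[Sequence[tuple[str, int]]]
) -> list[np.ndarray]:
    pos = {lab: i for i, lab in enumerate(dfm.labels)}
    seen: set[tuple[str, int]] = set()
    out = []
    for members in blocks:
        ids = []
        for m in members:
            m = tuple(m)
            if m not in pos:
                raise ValueError(f"block member {m} not among matrix labels")
            if m in seen:
                raise ValueError(f"label {m} appears in more than one block")
            seen.add(m)
            ids.append(pos[m])
        out.append(np.asarray(ids, dtype=int))
    if len(seen) != len(dfm.labels):
        missing = [lab for lab in dfm.labels if lab not in seen]
        raise ValueError(f"blocks do not cover all labels; missing {missing[:5]}")
    return out


def df_block_summary(
    dfm: DFMatrix, blocks: Sequence[Sequence[tuple[str, int]]]
) -> dict:
    """Mean/median DF within each block and between each block pair.

    ``blocks`` must partition the matrix labels. Also reports overall
    within-block and between-block means (off-diagonal pairs only).
    """
    block_idx = _block_indices(dfm, blocks)
    v = dfm.values
    within = {}
    within_all: list[np.ndarray] = []
    for b, ids in enumerate(block_idx):
        if len(ids) > 1:
            sub = v[np.ix_(ids, ids)]
            iu = np.triu_indices(len(ids), k=1)
            vals = sub[iu]
            within[b] = {"mean": float(vals.mean()), "median": float(np.median(vals))}
            within_all.append(vals)
        else:
            within[b] = {"mean": float("nan"), "median": float("nan")}
    between = {}
    between_all: list[np.ndarray] = []
    for a, b in combinations(range(len(block_idx)), 2):
        vals = v[np.ix_(block_idx[a], block_idx[b])].ravel()
        between[(a, b)] = {"mean": float(vals.mean()), "median": float(np.median(vals))}
        between_all.append(vals)
    w = np.concatenate(within_all) if within_all else np.array([])
    b_ = np.concatenate(between_all) if between_all else np.array([])
    return {
        "within": within,
        "between": between,
        "within_mean": float(w.mean()) if w.size else float("nan"),
        "between_mean": float(b_.mean()) if b_.size else float("nan"),
    }


def df_difference(dfm_a: DFMatrix, dfm_b: DFMatrix) -> tuple[np.ndarray, dict]:
    """Element-wise DF difference (a − b) and a coordination summary.

    A negative entry means the pair fluctuates less in ``a`` (more
    coordinated); the fraction of negative off-diagonal pairs summarises
    overall rigidification of variant ``a`` relative to ``b``.
    """
    if dfm_a.labels != dfm_b.labels:
        raise ValueError("DF matrices carry different labels")
    delta = dfm_a.values - dfm_b.values
    iu = np.triu_indices(len(dfm_a.labels), k=1)
    off = delta[iu]
    summary = {
        "fraction_negative": float(np.mean(off < 0)),
        "mean_delta": float(off.mean()),
        "median_delta": float(np.median(off)),
        "n_pairs": int(off.size),
    }
    return delta, summary
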