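"""Synthetic inputs with known ground truth.

Every generator emulates the statistical structure the downstream estimators
assume, at desk scale:

* harmonic (Gaussian) fluctuations of a Cα trace around a reference
  structure, with block-wise coordinated motion and a variant-specific
  amplitude scale — the rigidified-mutant scenario;
* an intermittent donor–hydrogen–acceptor geometry with a set per-frame
  presence probability — the H-bond persistence scenario;
* two-state sigmoidal melting / thermal-inactivation curves;
* hyperbolic Michaelis–Menten rate data with multiplicative noise.

Displacements are frame-independent (no autocorrelation): the estimators
under test are pure time/ensemble averages, for which temporal correlation
only changes the effective sample size, not the expectation. All generators
are seeded and record their ground truth in the output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import AtomRecord, CurveTable, Frame, Trajectory

__all__ = [
    "BlockSpec",
    "SigmoidSpec",
    "KineticsSpec",
    "make_reference_structure",
    "simulate_block_trajectory",
    "simulate_hbond_series",
    "simulate_melting_curve",
    "simulate_kinetics",
]

CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

# Ideal alpha-helix Calpha-trace geometry.
HELIX_RADIUS = 2.3      # Å
HELIX_RISE = 1.5        # Å per residue
HELIX_TWIST = 100.0     # degrees per residue

# Default monomer mass used to convert enzyme mg to nmol; approximate mature
# E. coli type II asparaginase monomer.
DEFAULT_MONOMER_MASS_DA = 34590.0


@dataclass
class BlockSpec:
    """Block-wise coordinated harmonic motion around a reference.

    ``blocks`` partitions the residues — identified as (chain_id, res_index)
    pairs — into groups that share a common random displacement of standard
    deviation ``sigma_block`` (per Cartesian coordinate, Å); each residue
    additionally gets an independent displacement of sd ``sigma_local``.
    ``scale`` multiplies both amplitudes and is the rigidification knob: a
    mutant generated at scale 0.8 has ground-truth RMSF 0.8× the wild-type
    and ground-truth distance fluctuations 0.64×.
    """

    blocks: Sequence[Sequence[tuple[str, int]]]
    sigma_block: float = 0.5
    sigma_local: float = 0.3
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_block < 0 or self.sigma_local < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        flat = [tuple(r) for b in self.blocks for r in b]
        if len(set(flat)) != len(flat):
            raise ValueError("blocks overlap: a residue appears twice")


@dataclass
class SigmoidSpec:
    """Two-state logistic curve: melting (rising) or inactivation (falling).

    ``midpoint`` is the transition temperature (°C); ``k`` the logistic scale
    (°C) — the maximum slope of the percentage curve is 25/k %/°C.
    ``direction`` is ``"unfolding"`` (signal rises with T) or ``"activity"``
    (residual activity falls with T).
    """

    midpoint: float
    k: float
    direction: str = "unfolding"
    baseline: float = 0.0
    amplitude: float = 1.0
    noise_sd: float = 0.0
    t_grid: np.ndarray = field(
        default_factory=lambda: np.arange(25.0, 95.0 + 1e-9, 0.5)
    )

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("logistic scale k must be > 0")
        if self.direction not in ("unfolding", "activity"):
            raise ValueError("direction must be 'unfolding' or 'activity'")
        t = np.asarray(self.t_grid, dtype=float)
        if t[0] > self.midpoint - 3 * self.k or t[-1] < self.midpoint + 3 * self.k:
            raise ValueError("temperature grid must span midpoint ± 3k")
        self.t_grid = t


@dataclass
class KineticsSpec:
    """Michaelis–Menten rate data v(S) = kcat·E0·S/(Km+S) with CV noise.

    ``e0_mg`` is the enzyme amount in mg; the molar amount (nmol) is derived
    from ``monomer_mass_da``. Rates come out in µmol·min⁻¹ (kcat in s⁻¹ is
    converted: 1 nmol enzyme × 1 s⁻¹ = 0.06 µmol·min⁻¹).
    """

    km: float = 0.89          # mM
    kcat: float = 59.77       # s^-1
    e0_mg: float = 0.001
    monomer_mass_da: float = DEFAULT_MONOMER_MASS_DA
    s_grid: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.05, 0.1, 0.2, 0.45, 0.89, 1.8, 3.5, 7.0, 14.0, 28.0]
        )
    )
    cv: float = 0.0

    def __post_init__(self) -> None:
        if self.km <= 0 or self.kcat <= 0 or self.e0_mg <= 0:
            raise ValueError("Km, kcat and E0 must be > 0")
        s = np.asarray(self.s_grid, dtype=float)
        if s.min() >= self.km or s.max() <= self.km:
            raise ValueError("substrate grid must span below and above Km")
        self.s_grid = s

    @property
    def e0_nmol(self) -> float:
        return self.e0_mg / self.monomer_mass_da * 1e6

    @property
    def vmax(self) -> float:
        """µmol·min⁻¹ at the given enzyme amount."""
        return self.kcat * self.e0_nmol * 60.0 / 1000.0


# ---------------------------------------------------------------------------
# Structures and trajectories
# ---------------------------------------------------------------------------

def make_reference_structure(n_chains: int, n_res: int, seed: int) -> Frame:
    """A deterministic Cα-trace reference: one ideal helix per chain.

    Chains are placed on a ring around the origin, each given a random (but
    seed-reproducible) orientation, emulating the arrangement of monomers in
    an oligomer. One CA atom per residue; residues are alanines.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if n_res < 3:
        raise ValueError("n_res must be >= 3")
    rng = np.random.default_rng(seed)
    t = np.arange(n_res)
    helix = np.column_stack(
        [
            HELIX_RADIUS * np.cos(np.deg2rad(HELIX_TWIST) * t),
            HELIX_RADIUS * np.sin(np.deg2rad(HELIX_TWIST) * t),
            HELIX_RISE * t,
        ]
    )
    helix -= helix.mean(axis=0)
    ring_radius = max(12.0, 2.0 * HELIX_RISE * n_res / np.pi)
    atoms: list[AtomRecord] = []
    serial = 1
    for c in range(n_chains):
        phi = 2 * np.pi * c / n_chains
        center = ring_radius * np.array([np.cos(phi), np.sin(phi), 0.0])
        if n_chains == 1:
            center = np.zeros(3)
        rot = Rotation.random(rng=rng)
        xyz = helix @ rot.as_matrix().T + center
        for i in range(n_res):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name="CA",
                    element="C",
                    res_name="ALA",
                    res_index=i + 1,
                    chain_id=CHAIN_IDS[c],
                    coords=tuple(xyz[i]),
                )
            )
            serial += 1
    return Frame(atoms)


def uniform_blocks(ref: Frame, n_blocks: int) -> list[list[tuple[str, int]]]:
    """Partition the residues of ``ref`` into ``n_blocks`` contiguous groups."""
    residues: list[tuple[str, int]] = []
    seen = set()
    for a in ref.atoms:
        key = (a.chain_id, a.res_index)
        if key not in seen:
            seen.add(key)
            residues.append(key)
    splits = np.array_split(np.arange(len(residues)), n_blocks)
    return [[residues[i] for i in idx] for idx in splits]


def simulate_block_trajectory(
    ref: Frame,
    spec: BlockSpec,
    n_frames: int,
    seed: int,
    rigid_motion: bool = False,
) -> Trajectory:
    """Harmonic block-coordinated fluctuations around a reference frame.

    Frame t is ``R_t · (x_i + scale·(a_b(t) + e_i(t))) + T_t`` with
    ``a_b`` an isotropic Gaussian displacement shared within block b
    (sd ``sigma_block`` per coordinate), ``e_i`` independent per residue
    (sd ``sigma_local``), and (R_t, T_t) a random rigid motion iff
    ``rigid_motion``. The generating spec is recorded in the trajectory
    metadata as ground truth.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    residues = [(a.chain_id, a.res_index) for a in ref.atoms]
    block_of: dict[tuple[str, int], int] = {}
    for b, members in enumerate(spec.blocks):
        for r in members:
            block_of[tuple(r)] = b
    missing = [r for r in set(residues) if r not in block_of]
    extra = [r for r in block_of if r not in set(residues)]
    if missing or extra:
        raise ValueError(
            f"blocks must partition the reference residues exactly "
            f"(missing {sorted(missing)[:5]}, extra {sorted(extra)[:5]})"
        )
    atom_block = np.array([block_of[r] for r in residues])
    n_blocks = len(spec.blocks)
    n_atoms = len(ref)
    x0 = ref.coords
    # separate streams: toggling rigid_motion must leave the internal
    # displacements untouched (rigid-motion invariance of DF/RMSF is tested
    # against the same fluctuation realisation)
    disp_ss, rigid_ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(disp_ss)
    rng_rigid = np.random.default_rng(rigid_ss)

    frames = []
    for _ in range(n_frames):
        a_b = rng.normal(0.0, spec.sigma_block, size=(n_blocks, 3))
        e_i = rng.normal(0.0, spec.sigma_local, size=(n_atoms, 3))
        xyz = x0 + spec.scale * (a_b[atom_block] + e_i)
        if rigid_motion:
            rot = Rotation.random(rng=rng_rigid)
            trans = rng_rigid.normal(0.0, 10.0, size=3)
            xyz = xyz @ rot.as_matrix().T + trans
        frames.append(ref.with_coords(xyz))

    # Ground-truth per-residue RMSF: sqrt(3) * scale * sqrt(sb^2 + sl^2).
    rmsf_truth = math.sqrt(3.0) * spec.scale * math.hypot(
        spec.sigma_block, spec.sigma_local
    )
    return Trajectory(
        frames,
        metadata={
            "generator": "simulate_block_trajectory",
            "seed": seed,
            "sigma_block": spec.sigma_block,
            "sigma_local": spec.sigma_local,
            "scale": spec.scale,
            "n_blocks": n_blocks,
            "rigid_motion": rigid_motion,
            "truth_rmsf": rmsf_truth,
        },
    )


# ---------------------------------------------------------------------------
# H-bond series
# ---------------------------------------------------------------------------

def _hbond_toy_frame(present: bool, acceptor_chain: str) -> Frame:
    """N–H···O toy system; geometry satisfies 3.5 Å/135° criteria iff present."""
    n_xyz = np.zeros(3)
    h_xyz = np.array([1.01, 0.0, 0.0])
    if present:
        # Place O so that N–O = 2.9 Å and the N–H···O angle at H is 170°.
        theta = np.deg2rad(180.0 - 170.0)
        direction = np.array([np.cos(theta), np.sin(theta), 0.0])
        # Solve |h + t*direction| = 2.9 for t > 0.
        b = 2.0 * float(h_xyz @ direction)
        c = float(h_xyz @ h_xyz) - 2.9**2
        t = (-b + math.sqrt(b * b - 4 * c)) / 2.0
        o_xyz = h_xyz + t * direction
    else:
        o_xyz = np.array([5.5, 0.0, 0.0])
    atoms = [
        AtomRecord(1, "N", "N", "ALA", 1, "A", tuple(n_xyz)),
        AtomRecord(2, "H", "H", "ALA", 1, "A", tuple(h_xyz)),
        AtomRecord(3, "CA", "C", "ALA", 1, "A", (-0.8, -1.2, 0.0)),
        AtomRecord(4, "CA", "C", "ALA", 2, acceptor_chain, (float(o_xyz[0]) + 1.5, float(o_xyz[1]), 1.2)),
        AtomRecord(5, "O", "O", "ALA", 2, acceptor_chain, tuple(o_xyz)),
    ]
    return Frame(atoms)


def simulate_hbond_series(
    p_present: float,
    n_frames: int,
    seed: int,
    acceptor_chain: str = "A",
) -> Trajectory:
    """Trajectory of a donor(N)–H–acceptor(O) toy system.

    Each frame independently satisfies the default detection criteria
    (N···O 2.9 Å, N–H···O 170°) with probability ``p_present``; otherwise the
    acceptor sits 5.5 Å away. Set ``acceptor_chain`` to a different chain to
    emulate an inter-monomer bond.
    """
    if not 0.0 <= p_present <= 1.0:
        raise ValueError("p_present must be in [0, 1]")
    rng = np.random.default_rng(seed)
    present = rng.random(n_frames) < p_present
    frames = [_hbond_toy_frame(bool(p), acceptor_chain) for p in present]
    return Trajectory(
        frames,
        metadata={
            "generator": "simulate_hbond_series",
            "seed": seed,
            "p_present": p_present,
            "n_present": int(present.sum()),
        },
    )


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------

def simulate_melting_curve(spec: SigmoidSpec, seed: int) -> CurveTable:
    """Two-state logistic curve plus Gaussian noise.

    ``unfolding``: y = baseline + amplitude / (1 + exp((midpoint − T)/k)),
    rising to the unfolded plateau. ``activity``: the mirrored, falling curve
    (residual activity in % when baseline=0, amplitude=100).
    """
    t = spec.t_grid
    if spec.direction == "unfolding":
        logistic = 1.0 / (1.0 + np.exp((spec.midpoint - t) / spec.k))
    else:
        logistic = 1.0 / (1.0 + np.exp((t - spec.midpoint) / spec.k))
    y = spec.baseline + spec.amplitude * logistic
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=t.shape)
    kind = "melting" if spec.direction == "unfolding" else "activity"
    return CurveTable(
        x=t,
        y=y,
        kind=kind,
        metadata={
            "generator": "simulate_melting_curve",
            "seed": seed,
            "midpoint": spec.midpoint,
            "k": spec.k,
            "direction": spec.direction,
            "baseline": spec.baseline,
            "amplitude": spec.amplitude,
            "noise_sd": spec.noise_sd,
            "max_slope_truth": 25.0 / spec.k,
        },
    )


def simulate_kinetics(spec: KineticsSpec, seed: int) -> CurveTable:
    """Hyperbolic Michaelis–Menten rates with multiplicative noise.

    v(S) = Vmax·S/(Km+S)·(1 + N(0, cv)), Vmax = kcat·E0 in µmol·min⁻¹.
    """
    s = spec.s_grid
    v = spec.vmax * s / (spec.km + s)
    if spec.cv > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + rng.normal(0.0, spec.cv, size=s.shape))
    return CurveTable(
        x=s,
        y=v,
        kind="kinetics",
        metadata={
            "generator": "simulate_kinetics",
            "seed": seed,
            "km": spec.km,
            "kcat": spec.kcat,
            "e0_mg": spec.e0_mg,
            "e0_nmol": spec.e0_nmol,
            "monomer_mass_da": spec.monomer_mass_da,
            "vmax_truth": spec.vmax,
            "cv": spec.cv,
        },
    )
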