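"""Structure and curve I/O plus per-atom topology inference.

The pipeline's canonical ensemble format is the multi-model PDB file: one
MODEL/ENDMDL block per conformation, identical atom ordering throughout.
Coordinates are in Å, residue numbering is 1-based within each chain, and
chains follow the PDB single-character convention (monomers A/B/C/D of a
homotetramer map directly onto chain ids).

Tabular inputs (melting curves, thermal-inactivation curves, rate-vs-substrate
kinetics) are two-column CSV files with a header; they are loaded into
:class:`CurveTable` objects sorted by the x variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "Topology",
    "CurveTable",
    "PDBFormatError",
    "CurveFormatError",
    "TopologyWarning",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "infer_topology",
    "read_curve_csv",
]

# Standard 20 amino acids (3-letter codes).
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Side-chain heavy atoms that can donate an H-bond (given an attached H) or
# accept one, per standard residue chemistry. Backbone N (donor, except PRO)
# and backbone O/OXT (acceptors) are handled separately.
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
}
SIDECHAIN_ACCEPTORS = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}

# Maximum N/O–H covalent bond length used to assign hydrogens to their
# donor-heavy partner (Å); generous versus the ~1.0 Å equilibrium value.
COVALENT_H_CUTOFF = 1.25


class PDBFormatError(ValueError):
    """Structured error for malformed or inconsistent multi-model PDB input."""


class CurveFormatError(ValueError):
    """Structured error for malformed curve CSV input."""


class TopologyWarning(UserWarning):
    """Non-fatal topology inference issue (unknown residue, missing H)."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one conformation.

    Coordinates are in Å. ``res_index`` is the 1-based residue number within
    its chain; ``chain_id`` is a single character.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_index: int
    chain_id: str
    coords: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial} ({self.name}): empty element")
        if self.res_index < 1:
            raise ValueError(
                f"atom {self.serial} ({self.name}): res_index must be >= 1, "
                f"got {self.res_index}"
            )
        if not all(np.isfinite(self.coords)):
            raise ValueError(
                f"atom {self.serial} ({self.name}): non-finite coordinates"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        """(chain_id, res_index, name) — unique within a frame."""
        return (self.chain_id, self.res_index, self.name)


class Frame:
    """An ordered collection of atoms: one conformation of the system."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        atoms = list(atoms)
        keys = [a.key for a in atoms]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, int, str]] = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate atom {k} within frame")
                seen.add(k)
        self.atoms: list[AtomRecord] = atoms
        self._coords: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Å (cached)."""
        if self._coords is None:
            self._coords = np.array([a.coords for a in self.atoms], dtype=float)
        return self._coords

    def atom_keys(self) -> list[tuple[str, int, str]]:
        return [a.key for a in self.atoms]

    def with_coords(self, coords: np.ndarray) -> "Frame":
        """A new frame with the same atoms at new positions."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match atom count "
                f"{len(self.atoms)}"
            )
        atoms = [
            AtomRecord(a.serial, a.name, a.element, a.res_name, a.res_index,
                       a.chain_id, tuple(xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return Frame(atoms)

    def select(self, selection: str | Sequence[int] | None) -> np.ndarray:
        """Indices of a named atom selection.

        ``None`` or ``"all"`` selects everything; ``"CA"``/``"calpha"``
        selects Cα atoms (carbon atoms named CA in amino-acid-like residues);
        ``"backbone"`` selects N, CA, C, O. An explicit index sequence passes
        through unchanged.
        """
        if selection is None or (isinstance(selection, str) and selection.lower() == "all"):
            return np.arange(len(self.atoms))
        if isinstance(selection, str):
            sel = selection.lower()
            if sel in ("ca", "calpha"):
                return np.array(
                    [i for i, a in enumerate(self.atoms)
                     if a.name == "CA" and a.element.upper() == "C"],
                    dtype=int,
                )
            if sel == "backbone":
                bb = {"N", "CA", "C", "O"}
                return np.array(
                    [i for i, a in enumerate(self.atoms) if a.name in bb],
                    dtype=int,
                )
            raise ValueError(f"unknown selection {selection!r}")
        return np.asarray(selection, dtype=int)


@dataclass
class Topology:
    """Per-atom flags every analysis consumes.

    ``h_to_donor`` maps each polar-hydrogen atom index to the index of its
    covalently bonded donor heavy atom.
    """

    is_calpha: np.ndarray
    is_backbone: np.ndarray
    is_donor_heavy: np.ndarray
    is_polar_hydrogen: np.ndarray
    is_acceptor: np.ndarray
    h_to_donor: dict[int, int]
    chains: list[str]
    residues_per_chain: dict[str, int]


class Trajectory:
    """Ordered conformations of one molecular system sharing a topology."""

    def __init__(
        self,
        frames: Sequence[Frame],
        topology: Topology | None = None,
        frame_interval: float | None = None,
        metadata: dict | None = None,
    ):
        frames = list(frames)
        if len(frames) < 1:
            raise ValueError("a trajectory needs at least one frame")
        ref_keys = frames[0].atom_keys()
        for i, fr in enumerate(frames[1:], start=2):
            if fr.atom_keys() != ref_keys:
                raise ValueError(
                    f"frame {i} atom ordering/count differs from frame 1"
                )
        self.frames: list[Frame] = frames
        self._topology = topology
        self.frame_interval = frame_interval
        self.metadata: dict = dict(metadata or {})
        self._coords: np.ndarray | None = None

    @property
    def topology(self) -> Topology:
        """Per-atom topology, inferred from the first frame on first use."""
        if self._topology is None:
            self._topology = infer_topology(self.frames[0])
        return self._topology

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0])

    @property
    def coords(self) -> np.ndarray:
        """(F, N, 3) coordinate array in Å (cached)."""
        if self._coords is None:
            self._coords = np.stack([f.coords for f in self.frames])
        return self._coords


# ---------------------------------------------------------------------------
# Multi-model PDB I/O
# ---------------------------------------------------------------------------

def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    Each MODEL/ENDMDL block becomes one frame; a file without MODEL records
    yields a 1-frame trajectory. All models must contain the same atoms in
    the same order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise PDBFormatError(f"{path}: {exc}") from exc
    frames: list[Frame] = []
    model_ids: list[int] = []
    for model in structure:
        atoms: list[AtomRecord] = []
        for chain in model:
            for residue in chain:
                _, res_index, _ = residue.id
                for atom in residue:
                    element = (atom.element or "").strip() or atom.name[0]
                    atoms.append(
                        AtomRecord(
                            serial=int(atom.serial_number or len(atoms) + 1),
                            name=atom.name,
                            element=element,
                            res_name=residue.resname.strip(),
                            res_index=int(res_index),
                            chain_id=chain.id if chain.id.strip() else "A",
                            coords=tuple(float(c) for c in atom.coord),
                        )
                    )
        frames.append(Frame(atoms))
        model_ids.append(model.id)
    if not frames:
        raise PDBFormatError(f"{path}: no models / atoms found")
    ref_keys = frames[0].atom_keys()
    for fr, mid in zip(frames[1:], model_ids[1:]):
        if fr.atom_keys() != ref_keys:
            label = mid + 1 if isinstance(mid, int) else mid
            raise PDBFormatError(
                f"{path}: MODEL {label} atom count/order differs from the "
                f"first model ({len(fr)} vs {len(ref_keys)} atoms)"
            )
    return Trajectory(frames)


def _pdb_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: single-letter elements start at column 14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file.

    Coordinates are emitted at the PDB fixed-width precision (3 decimals),
    so a read/write round trip reproduces them to 0.001 Å and a second
    write is byte-identical on the coordinate fields.
    """
    path = Path(path)
    multi = len(traj) > 1
    lines: list[str] = []
    for imodel, frame in enumerate(traj.frames, start=1):
        if multi:
            lines.append(f"MODEL     {imodel:4d}")
        for a in frame.atoms:
            x, y, z = a.coords
            lines.append(
                f"ATOM  {a.serial % 100000:5d} {_pdb_atom_name(a.name, a.element)}"
                f" {a.res_name:>3s} {a.chain_id}{a.res_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element.upper():>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Topology inference
# ---------------------------------------------------------------------------

def infer_topology(frame: Frame) -> Topology:
    """Infer Cα/backbone/donor/acceptor flags from standard PDB atom names.

    Donors are N/O heavy atoms that carry at least one hydrogen present in
    the frame (backbone amide N, plus side-chain N/O per standard residue
    chemistry); acceptors are N/O heavy atoms with lone pairs (backbone
    carbonyl O, side-chain O/N per residue chemistry). Hydrogens are assigned
    to their donor-heavy partner by proximity (nearest N/O within
    ``COVALENT_H_CUTOFF``). Atoms of unknown residue codes are excluded from
    donor/acceptor flags with a warning, but remain usable for RMSD/RMSF.
    """
    n = len(frame)
    is_calpha = np.zeros(n, dtype=bool)
    is_backbone = np.zeros(n, dtype=bool)
    is_donor = np.zeros(n, dtype=bool)
    is_polar_h = np.zeros(n, dtype=bool)
    is_acceptor = np.zeros(n, dtype=bool)
    coords = frame.coords

    unknown_res: set[str] = set()
    hydrogen_idx: list[int] = []
    for i, a in enumerate(frame.atoms):
        elem = a.element.upper()
        if a.name == "CA" and elem == "C":
            is_calpha[i] = True
        if a.name in ("N", "CA", "C", "O", "OXT") and elem in ("C", "N", "O"):
            is_backbone[i] = True
        if elem == "H":
            hydrogen_idx.append(i)
            continue
        if a.res_name not in AMINO_ACIDS:
            unknown_res.add(a.res_name)
            continue
        if a.name in ("O", "OXT"):
            is_acceptor[i] = True
        if a.name in SIDECHAIN_ACCEPTORS.get(a.res_name, ()):
            is_acceptor[i] = True

    if unknown_res:
        warnings.warn(
            f"unknown residue code(s) {sorted(unknown_res)}: atoms excluded "
            f"from donor/acceptor flags",
            TopologyWarning,
            stacklevel=2,
        )

    # Candidate donor-heavy sites: backbone N (except proline) and the
    # side-chain table above. They become donors only if an H is attached.
    donor_candidates: set[int] = set()
    for i, a in enumerate(frame.atoms):
        if a.res_name not in AMINO_ACIDS or a.element.upper() == "H":
            continue
        if a.name == "N" and a.res_name != "PRO":
            donor_candidates.add(i)
        elif a.name in SIDECHAIN_DONORS.get(a.res_name, ()):
            donor_candidates.add(i)

    h_to_donor: dict[int, int] = {}
    if hydrogen_idx and donor_candidates:
        cand = sorted(donor_candidates)
        cand_xyz = coords[cand]
        for h in hydrogen_idx:
            d2 = np.sum((cand_xyz - coords[h]) ** 2, axis=1)
            j = int(np.argmin(d2))
            if d2[j] <= COVALENT_H_CUTOFF**2:
                partner = cand[j]
                h_to_donor[h] = partner
                is_polar_h[h] = True
                is_donor[partner] = True
    if not hydrogen_idx:
        warnings.warn(
            "frame contains no hydrogens: no donors can be flagged",
            TopologyWarning,
            stacklevel=2,
        )

    chains: list[str] = []
    residues_per_chain: dict[str, int] = {}
    for a in frame.atoms:
        if a.chain_id not in residues_per_chain:
            chains.append(a.chain_id)
            residues_per_chain[a.chain_id] = 0
    for cid in chains:
        residues_per_chain[cid] = len(
            {a.res_index for a in frame.atoms if a.chain_id == cid}
        )

    return Topology(
        is_calpha=is_calpha,
        is_backbone=is_backbone,
        is_donor_heavy=is_donor,
        is_polar_hydrogen=is_polar_h,
        is_acceptor=is_acceptor,
        h_to_donor=h_to_donor,
        chains=chains,
        residues_per_chain=residues_per_chain,
    )


# ---------------------------------------------------------------------------
# Curve tables
# ---------------------------------------------------------------------------

CURVE_KINDS = ("melting", "activity", "kinetics")


@dataclass
class CurveTable:
    """A two-column numeric curve: temperature/substrate vs signal/rate."""

    x: np.ndarray
    y: np.ndarray
    kind: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"kind must be one of {CURVE_KINDS}, got {self.kind!r}")
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-d vectors of equal length")
        if len(self.x) < 4:
            raise ValueError(f"curve needs >= 4 points, got {len(self.x)}")
        if self.kind in ("melting", "activity") and not np.all(np.diff(self.x) > 0):
            raise ValueError(f"{self.kind} curve x must be strictly increasing")

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y})


def read_curve_csv(path: str | Path, kind: str) -> CurveTable:
    """Read a 2-column CSV (with header) into a sorted :class:`CurveTable`.

    Rows are sorted by x; duplicate x values (replicate wells) are averaged.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise CurveFormatError(f"{path}: expected 2 columns, found {df.shape[1]}")
    df = df.iloc[:, :2]
    df.columns = ["x", "y"]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        row = int(np.argwhere(bad.any(axis=1).to_numpy())[0][0]) + 2  # +header
        raise CurveFormatError(f"{path}: non-numeric cell at row {row}")
    if numeric.isna().any().any():
        row = int(np.argwhere(numeric.isna().any(axis=1).to_numpy())[0][0]) + 2
        raise CurveFormatError(f"{path}: missing value at row {row}")
    grouped = numeric.groupby("x", sort=True)["y"].mean()
    x = grouped.index.to_numpy(dtype=float)
    y = grouped.to_numpy(dtype=float)
    if len(x) < 4:
        raise CurveFormatError(f"{path}: need >= 4 distinct points, got {len(x)}")
    return CurveTable(x=x, y=y, kind=kind, metadata={"source": str(path)})


def write_curve_csv(curve: CurveTable, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)
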