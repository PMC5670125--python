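"""Average protein masses and intact-mass cleavage-site matching.

Intact-protein ESI-MS deconvolution yields average (isotope-abundance-
weighted) molecular masses. Limited proteolysis of the asparaginase
N-terminal flexible loop produces N-terminally truncated species, so an
observed deconvoluted mass is interpreted by matching it against the average
masses of all N-terminal truncation products of the construct sequence:
``cleavage_after = s − 1`` means the fragment spans residues s..end.

Only N-terminal truncations are modelled (the degradation under study is
exclusively N-terminal). The default matching tolerance is 5 Da; a relative
tolerance (e.g. the 0.02% typical of linear ion-trap intact-mass work) is
also supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "CleavageCandidate",
    "average_mass",
    "nterm_truncation_masses",
    "match_observed_mass",
    "read_fasta_sequence",
]

# Average residue (amino-acid minus water) masses in Da, standard IUPAC 1997
# atomic weights (as tabulated by ExPASy).
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0513, "A": 71.0779, "S": 87.0773, "P": 97.1152, "V": 99.1311,
    "T": 101.1039, "C": 103.1429, "L": 113.1576, "I": 113.1576,
    "N": 114.1026, "D": 115.0874, "Q": 128.1292, "K": 128.1723,
    "E": 129.1155, "M": 131.1961, "H": 137.1393, "F": 147.1739,
    "R": 156.1857, "Y": 163.1733, "W": 186.2099,
}
WATER_MASS = 18.0153  # Da, one water per peptide chain

DEFAULT_TOLERANCE_DA = 5.0


@dataclass
class CleavageCandidate:
    """One N-terminal cleavage consistent with an observed intact mass."""

    cleavage_after: int   # 1-based; fragment = residues cleavage_after+1 .. end
    calc_mass: float      # Da, average
    delta: float          # observed − calculated, Da


def average_mass(seq: str) -> float:
    """Average molecular mass (Da) of a one-letter protein sequence.

    Sum of average residue masses plus one water. Full precision internally;
    report at 1 decimal.
    """
    if not seq:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for pos, aa in enumerate(seq.upper(), start=1):
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(
                f"non-standard amino acid {aa!r} at position {pos}"
            ) from None
    return total


def nterm_truncation_masses(
    seq: str, start_range: Iterable[int] | tuple[int, int]
) -> list[tuple[int, float]]:
    """Average masses of N-terminal truncation products.

    ``start_range`` is an inclusive (lo, hi) pair or an iterable of 1-based
    start positions; each product spans residues start..end.
    """
    if isinstance(start_range, tuple) and len(start_range) == 2 and all(
        isinstance(v, int) for v in start_range
    ):
        starts = list(range(start_range[0], start_range[1] + 1))
    else:
        starts = sorted(set(int(s) for s in start_range))
    if not starts:
        raise ValueError("empty start range")
    if starts[0] < 1 or starts[-1] > len(seq):
        raise ValueError(
            f"start range {starts[0]}..{starts[-1]} outside sequence "
            f"1..{len(seq)}"
        )
    return [(s, average_mass(seq[s - 1:])) for s in starts]


def match_observed_mass(
    seq: str,
    observed: float,
    tolerance: float = DEFAULT_TOLERANCE_DA,
    relative: bool = False,
) -> list[CleavageCandidate]:
    """N-terminal truncation products matching an observed average mass.

    Candidates within ``tolerance`` Da (or ``tolerance`` as a fraction of the
    observed mass when ``relative``) are returned sorted by |delta|; an empty
    list means no cleavage site is consistent with the observation.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    tol_da = observed * tolerance if relative else tolerance
    out = []
    for start, calc in nterm_truncation_masses(seq, (1, len(seq))):
        delta = observed - calc
        if abs(delta) <= tol_da:
            out.append(
                CleavageCandidate(
                    cleavage_after=start - 1, calc_mass=calc, delta=delta
                )
            )
    out.sort(key=lambda c: abs(c.delta))
    return out


def read_fasta_sequence(path: str | Path) -> str:
    """First sequence of a FASTA file, as an upper-case one-letter string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return str(records[0].seq).upper()
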