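"""Protein Blocks assignment by nearest-prototype angular matching.

The Protein Blocks structural alphabet encodes local backbone
conformation with 16 prototypes, letters a-p, each defined by 8 dihedral
angles over a 5-residue window: (psi(i-2), phi(i-1), psi(i-1), phi(i),
psi(i), phi(i+1), psi(i+1), phi(i+2)).  Letters m and d correspond
roughly to central alpha-helix and central beta-strand; a-c cap the
N-terminus of strands, e-f their C-terminus, g-j are coil-like, k-l cap
helix N-termini and n-p helix C-termini.

A position is assigned the letter whose prototype minimizes the
root-mean-square angular deviation (RMSDA) of its window, with wrap-
around on (-180, 180].  Positions without a full window — the two
residues at each end of every continuous segment, and any window
touching an undefined angle — receive the upper-case Z label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from pbentropy.dihedrals import DihedralRecord, compute_phi_psi, segments, wrap_degrees
from pbentropy.structure_io import Chain, Ensemble

__all__ = [
    "PB_LETTERS",
    "UNASSIGNED",
    "PBPrototypeTable",
    "PBSequence",
    "rmsda",
    "dihedral_window",
    "nearest_block",
    "assign_pb_sequence",
    "assign_ensemble",
    "pb_fasta_name",
    "write_pb_fasta",
    "read_pb_fasta",
]

PB_LETTERS = "abcdefghijklmnop"
UNASSIGNED = "Z"

# Canonical 16x8 prototype dihedrals (degrees), column order
# psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i), phi(i+1), psi(i+1), phi(i+2).
_PROTOTYPE_ANGLES: dict[str, tuple[float, ...]] = {
    "a": (41.14, 75.53, 13.92, -99.80, 131.88, -96.27, 122.08, -99.68),
    "b": (108.24, -90.12, 119.54, -92.21, -18.06, -128.93, 147.04, -99.90),
    "c": (-11.61, -105.66, 94.81, -106.09, 133.56, -106.93, 135.97, -100.63),
    "d": (141.98, -112.79, 132.20, -114.79, 140.11, -111.05, 139.54, -103.16),
    "e": (133.25, -112.37, 137.64, -108.13, 133.00, -87.30, 120.54, 77.40),
    "f": (116.40, -105.53, 129.32, -96.68, 140.72, -74.19, -26.65, -94.51),
    "g": (0.40, -81.83, 4.91, -100.59, 85.50, -71.65, 130.78, 84.98),
    "h": (119.14, -102.58, 130.83, -67.91, 121.55, 76.25, -2.95, -90.88),
    "i": (130.68, -56.92, 119.26, 77.85, 10.42, -99.43, 141.40, -98.01),
    "j": (114.32, -121.47, 118.14, 82.88, -150.05, -83.81, 23.35, -85.82),
    "k": (117.16, -95.41, 140.40, -59.35, -29.23, -72.39, -25.08, -76.16),
    "l": (139.20, -55.96, -32.70, -68.51, -26.09, -74.44, -22.60, -71.74),
    "m": (-39.62, -64.73, -39.52, -65.54, -38.88, -66.89, -37.76, -70.19),
    "n": (-35.34, -65.03, -38.12, -66.34, -29.51, -89.10, -2.91, 77.90),
    "o": (-45.29, -67.44, -27.72, -87.27, 5.13, 77.49, 30.71, -93.23),
    "p": (-27.09, -86.14, 0.30, 59.85, 21.51, -96.30, 132.67, -92.91),
}


def rmsda(v, w) -> float | np.ndarray:
    """Root-mean-square angular deviation with wrap into (-180, 180].

    Broadcasts over leading axes; the last axis holds the 8 angles.
    """
    d = wrap_degrees(np.asarray(v, dtype=float) - np.asarray(w, dtype=float))
    out = np.sqrt(np.mean(np.square(d), axis=-1))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PBPrototypeTable:
    """The 16 reference dihedral vectors, letters a-p."""

    letters: str
    vectors: np.ndarray  # (16, 8) degrees

    @classmethod
    def default(cls) -> "PBPrototypeTable":
        global _DEFAULT_TABLE
        if _DEFAULT_TABLE is None:
            table = cls(
                letters=PB_LETTERS,
                vectors=np.array([_PROTOTYPE_ANGLES[l] for l in PB_LETTERS]),
            )
            table.validate()
            _DEFAULT_TABLE = table
        return _DEFAULT_TABLE

    def validate(self) -> None:
        """Sanity gate: shape, angle range, and the self-assignment identity."""
        if len(self.letters) != 16 or self.vectors.shape != (16, 8):
            raise ValueError("prototype table must have 16 letters x 8 angles")
        if not np.all((self.vectors > -180.0) & (self.vectors <= 180.0)):
            raise ValueError("prototype angles must lie in (-180, 180]")
        recovered = [self.letters[int(np.argmin(rmsda(self.vectors, v)))] for v in self.vectors]
        if recovered != list(self.letters):
            raise ValueError("prototype table fails the self-assignment identity")

    def vector(self, letter: str) -> np.ndarray:
        return self.vectors[self.letters.index(letter)]


_DEFAULT_TABLE: PBPrototypeTable | None = None


@dataclass
class PBSequence:
    """PB string for one model of one chain (letters a-p plus Z)."""

    model_index: int
    chain_id: str
    letters: str


def dihedral_window(records: list[DihedralRecord], i: int) -> np.ndarray | None:
    """8-vector (psi(i-2) ... phi(i+2)) for position *i*, or None.

    *records* must cover a single continuous segment.  Returns None
    (unassignable) for the two positions at each end and whenever any
    component is undefined.
    """
    n = len(records)
    if i < 2 or i > n - 3:
        return None
    r = records[i - 2 : i + 3]
    window = np.array(
        [r[0].psi, r[1].phi, r[1].psi, r[2].phi, r[2].psi, r[3].phi, r[3].psi, r[4].phi]
    )
    if np.any(np.isnan(window)):
        return None
    return window


def nearest_block(window: np.ndarray, table: PBPrototypeTable | None = None) -> str:
    """Letter of the prototype with minimal RMSDA to *window*.

    Ties resolve to the alphabetically first letter (argmin returns the
    first minimum and the table is stored in alphabetical order).
    """
    table = table or PBPrototypeTable.default()
    return table.letters[int(np.argmin(rmsda(table.vectors, window)))]


def _assign_segment(records: list[DihedralRecord], table: PBPrototypeTable) -> list[str]:
    n = len(records)
    letters = [UNASSIGNED] * n
    windows, positions = [], []
    for i in range(n):
        w = dihedral_window(records, i)
        if w is not None:
            windows.append(w)
            positions.append(i)
    if windows:
        dist = rmsda(np.asarray(windows)[:, None, :], table.vectors[None, :, :])
        for pos, j in zip(positions, np.argmin(dist, axis=1)):
            letters[pos] = table.letters[int(j)]
    return letters


def assign_pb_sequence(
    chain: Chain,
    table: PBPrototypeTable | None = None,
    model_index: int = 0,
) -> PBSequence:
    """Assign a PB letter (or Z) to every residue of one chain model.

    Z padding applies per continuous segment: windows never span a chain
    break, so each segment contributes two leading and two trailing Z,
    and segments shorter than 5 residues are entirely Z.  Incomplete
    residues propagate Z to every window that touches them, so heavily
    incomplete chains degenerate to stretches of Z.
    """
    table = table or PBPrototypeTable.default()
    all_records = compute_phi_psi(chain)
    letters = [UNASSIGNED] * len(chain.residues)
    for start, end in segments(chain):
        seg = _assign_segment(all_records[start:end], table)
        letters[start:end] = seg
    return PBSequence(model_index=model_index, chain_id=chain.chain_id, letters="".join(letters))


def assign_ensemble(
    ensemble: Ensemble, table: PBPrototypeTable | None = None
) -> dict[str, list[PBSequence]]:
    """PB sequences for every model, keyed by chain id."""
    table = table or PBPrototypeTable.default()
    out: dict[str, list[PBSequence]] = {cid: [] for cid in ensemble.chain_ids()}
    for mi, model in enumerate(ensemble.models):
        for chain in model:
            out[chain.chain_id].append(assign_pb_sequence(chain, table, model_index=mi))
    return out


def pb_fasta_name(entry_id: str, chain_id: str | None = None) -> str:
    """File naming contract: {entry}.PB.fasta, or {entry}-chain{C}.PB.fasta
    when the entry has several chains."""
    if chain_id is None:
        return f"{entry_id}.PB.fasta"
    return f"{entry_id}-chain{chain_id}.PB.fasta"


def write_pb_fasta(
    entry_id: str,
    sequences_by_chain: dict[str, list[PBSequence]],
    out_dir: str | Path,
) -> list[Path]:
    """Write one PB FASTA per chain (suffix -chain{C} only if multi-chain)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    multi = len(sequences_by_chain) > 1
    paths = []
    for chain_id, seqs in sequences_by_chain.items():
        path = out_dir / pb_fasta_name(entry_id, chain_id if multi else None)
        records = [
            SeqRecord(
                Seq(s.letters),
                id=entry_id,
                description=f"| model {s.model_index + 1} | chain {s.chain_id}",
            )
            for s in seqs
        ]
        SeqIO.write(records, str(path), "fasta")
        paths.append(path)
    return paths


_HEADER_RE = re.compile(r"\|\s*model\s+(\d+)\s*\|\s*chain\s+(\S+)")


def read_pb_fasta(path: str | Path) -> list[PBSequence]:
    """Read a PB FASTA written by :func:`write_pb_fasta`."""
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        m = _HEADER_RE.search(rec.description)
        model_index = int(m.group(1)) - 1 if m else i
        chain_id = m.group(2) if m else "A"
        out.append(PBSequence(model_index=model_index, chain_id=chain_id, letters=str(rec.seq)))
    return out
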