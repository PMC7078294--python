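"""Backbone phi/psi torsion angles with explicit undefined values.

phi(i) is the torsion C(i-1)-N(i)-CA(i)-C(i); psi(i) is
N(i)-CA(i)-C(i)-N(i+1), both in degrees on (-180, 180] with the IUPAC
sign convention (cis = 0).  An angle is UNDEFINED (NaN) at segment
termini, across chain breaks, and wherever a defining atom is missing —
missing data never raises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pbentropy.errors import GeometryError
from pbentropy.structure_io import Chain

__all__ = [
    "UNDEFINED",
    "DihedralRecord",
    "torsion",
    "wrap_degrees",
    "segments",
    "compute_phi_psi",
    "phi_psi_table",
    "write_phi_psi",
]

#: Sentinel for an angle that cannot be computed.
UNDEFINED = math.nan


def is_defined(angle: float) -> bool:
    return not math.isnan(angle)


def wrap_degrees(x):
    """Wrap angle(s) into (-180, 180]."""
    w = np.asarray(x, dtype=float)
    w = (w + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return float(w) if np.isscalar(x) or np.ndim(x) == 0 else w


@dataclass
class DihedralRecord:
    position_index: int
    phi: float = UNDEFINED
    psi: float = UNDEFINED


def torsion(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of p1-p2-p3-p4 in degrees, (-180, 180].

    The angle between the plane (p1, p2, p3) and the plane (p2, p3, p4)
    about the p2-p3 axis; cis arrangements give 0.  Raises
    :class:`GeometryError` for coincident consecutive points or a
    collinear triple.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-9 or np.linalg.norm(b0) < 1e-9 or np.linalg.norm(b2) < 1e-9:
        raise GeometryError("coincident consecutive points")
    b1 = b1 / nb1
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        raise GeometryError("collinear triple; torsion undefined")
    x = v @ w
    y = np.cross(b1, v) @ w
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def segments(chain: Chain) -> list[tuple[int, int]]:
    """Continuous [start, end) index ranges of a chain, split at breaks."""
    n = len(chain.residues)
    if n == 0:
        return []
    bounds = sorted(b for b in chain.breaks if 0 <= b < n - 1)
    out = []
    start = 0
    for b in bounds:
        out.append((start, b + 1))
        start = b + 1
    out.append((start, n))
    return out


def _safe_torsion(*points) -> float:
    if any(p is None for p in points):
        return UNDEFINED
    try:
        return torsion(*(p.coordinates for p in points))
    except GeometryError:
        return UNDEFINED


def compute_phi_psi(chain: Chain) -> list[DihedralRecord]:
    """Per-residue phi/psi for one chain, honouring breaks and gaps.

    The first residue of every continuous segment has UNDEFINED phi and
    the last UNDEFINED psi; angles whose defining atoms are missing are
    UNDEFINED.
    """
    records = [DihedralRecord(i) for i in range(len(chain.residues))]
    for start, end in segments(chain):
        for i in range(start, end):
            res = chain.residues[i]
            n_i, ca_i, c_i = (res.get_atom(a) for a in ("N", "CA", "C"))
            if i > start:
                prev_c = chain.residues[i - 1].get_atom("C")
                records[i].phi = _safe_torsion(prev_c, n_i, ca_i, c_i)
            if i < end - 1:
                next_n = chain.residues[i + 1].get_atom("N")
                records[i].psi = _safe_torsion(n_i, ca_i, c_i, next_n)
    return records


def phi_psi_table(chain: Chain) -> pd.DataFrame:
    """Tabular phi/psi export (NaN for undefined angles)."""
    records = compute_phi_psi(chain)
    return pd.DataFrame(
        {
            "chain_id": chain.chain_id,
            "residue_index": [r.position_index for r in records],
            "author_number": [res.position_key[0] for res in chain.residues],
            "phi": [r.phi for r in records],
            "psi": [r.psi for r in records],
        }
    )


def write_phi_psi(chain: Chain, path: str | Path) -> None:
    """Tab-separated phi/psi table; undefined angles written as NA."""
    phi_psi_table(chain).to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.3f")
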