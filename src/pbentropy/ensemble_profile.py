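"""Per-position PB statistics across an ensemble and the Neq index.

For every residue position the letters observed across models form a
frequency distribution f over the 16 Protein Blocks (Z observations are
"not assigned" and excluded, not a 17th state).  The Neq index

    Neq = exp(-sum_x f_x ln f_x)

is the exponential of the Shannon entropy (natural log): the equivalent
number of PBs the position samples.  Neq = 1 iff a single PB is ever
observed (rigid); Neq = 16 iff all 16 are equiprobable.  Positions never
assigned in any model have undefined Neq and are excluded from the
ensemble mean.

Class labels along the rigidity-flexibility-disorder continuum are a
thresholding of Neq; the cut-offs are configuration the caller must
supply (the shipped config template documents defaults).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from pbentropy.errors import ConsistencyError
from pbentropy.pb_assignment import PB_LETTERS, PBSequence, UNASSIGNED

__all__ = [
    "PBCountMatrix",
    "NeqProfile",
    "count_pbs",
    "frequencies",
    "neq",
    "classify",
    "profile_ensemble",
    "bootstrap_mean_neq",
    "profile_filename",
    "write_count",
    "read_count",
    "write_neq",
    "read_neq",
    "write_classes",
]

_LETTER_INDEX = {letter: i for i, letter in enumerate(PB_LETTERS)}


@dataclass
class PBCountMatrix:
    """positions x 16 integer counts aggregated over models."""

    positions: list[tuple[int, int]]  # (sequential 1-based index, author number)
    counts: np.ndarray  # (n_positions, 16) ints, columns a..p
    n_models: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.positions), 16):
            raise ConsistencyError("counts must be n_positions x 16")
        if np.any(self.counts < 0):
            raise ConsistencyError("counts must be non-negative")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def n_assigned(self) -> np.ndarray:
        """Per-position number of non-Z observations."""
        return self.counts.sum(axis=1)

    def frequency_matrix(self) -> np.ndarray:
        """(n_positions, 16) frequencies; rows with no observation are 0."""
        tot = self.n_assigned.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.counts / tot[:, None]
        f[tot == 0] = 0.0
        return f


@dataclass
class NeqProfile:
    positions: list[tuple[int, int]]
    per_position_neq: np.ndarray  # NaN where never assigned
    mean_neq: float
    labels: list[str] = field(default_factory=list)


def count_pbs(
    sequences: Sequence[PBSequence],
    author_numbers: Sequence[int] | None = None,
) -> PBCountMatrix:
    """Count PB letters per position over models; Z is never counted."""
    if not sequences:
        raise ConsistencyError("no sequences to count")
    length = len(sequences[0].letters)
    chain = sequences[0].chain_id
    for s in sequences:
        if len(s.letters) != length:
            raise ConsistencyError(
                f"model {s.model_index}: sequence length {len(s.letters)} != {length}"
            )
        if s.chain_id != chain:
            raise ConsistencyError(f"mixed chains {chain!r} and {s.chain_id!r}")
    counts = np.zeros((length, 16), dtype=int)
    for s in sequences:
        for i, letter in enumerate(s.letters):
            if letter != UNASSIGNED:
                j = _LETTER_INDEX.get(letter)
                if j is None:
                    raise ConsistencyError(f"unknown PB letter {letter!r} at position {i}")
                counts[i, j] += 1
    if author_numbers is None:
        author_numbers = range(1, length + 1)
    positions = [(i + 1, int(a)) for i, a in enumerate(author_numbers)]
    return PBCountMatrix(positions=positions, counts=counts, n_models=len(sequences))


def frequencies(matrix: PBCountMatrix, i: int) -> np.ndarray | None:
    """16-vector of PB frequencies at position *i* (0-based row index).

    None signals an undefined position (no model assigned here).
    """
    total = int(matrix.counts[i].sum())
    if total == 0:
        return None
    return matrix.counts[i] / total


def neq(f) -> float:
    """Neq = exp(-sum f ln f) with the explicit 0 ln 0 = 0 convention.

    *f* must be a probability distribution (sums to 1 within 1e-9,
    components in [0, 1]).  Ranges over [1, 16] for 16 states, with the
    endpoints attained exactly at degenerate and uniform distributions.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
        raise ValueError("frequencies must lie in [0, 1]")
    if abs(float(f.sum()) - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {f.sum():.12g}, not 1")
    f = np.clip(f, 0.0, 1.0)
    nz = f[f > 0.0]
    return float(np.exp(-np.sum(nz * np.log(nz))))


def classify(value: float, t_rigid: float, t_disorder: float) -> str:
    """Continuum label for one Neq value.

    rigid: Neq < t_rigid; disordered: Neq >= t_disorder; flexible in
    between; unassigned for undefined Neq.
    """
    if not 1.0 <= t_rigid < t_disorder <= 16.0:
        raise ValueError("thresholds must satisfy 1 <= t_rigid < t_disorder <= 16")
    if math.isnan(value):
        return "unassigned"
    if value < t_rigid:
        return "rigid"
    if value >= t_disorder:
        return "disordered"
    return "flexible"


def profile_ensemble(
    sequences: Sequence[PBSequence],
    t_rigid: float,
    t_disorder: float,
    author_numbers: Sequence[int] | None = None,
) -> NeqProfile:
    """Count -> frequency -> Neq for every position, plus the ensemble mean.

    Positions with no assigned observation get NaN and the label
    "unassigned"; the mean is taken over defined positions only.
    """
    matrix = count_pbs(sequences, author_numbers)
    values = np.full(matrix.n_positions, np.nan)
    for i in range(matrix.n_positions):
        f = frequencies(matrix, i)
        if f is not None:
            values[i] = neq(f)
    defined = values[~np.isnan(values)]
    mean = float(defined.mean()) if defined.size else math.nan
    labels = [classify(v, t_rigid, t_disorder) for v in values]
    return NeqProfile(
        positions=matrix.positions, per_position_neq=values, mean_neq=mean, labels=labels
    )


def _mean_neq_from_codes(codes: np.ndarray, positions: np.ndarray) -> float:
    """Mean Neq over *positions* from a (n_models, length) letter-code
    matrix (codes 0..15; 16 = Z)."""
    vals = []
    for p in positions:
        col = codes[:, p]
        col = col[col < 16]
        if col.size == 0:
            continue
        c = np.bincount(col, minlength=16).astype(float)
        f = c / c.sum()
        nz = f[f > 0]
        vals.append(math.exp(-float(np.sum(nz * np.log(nz)))))
    return float(np.mean(vals)) if vals else math.nan


def bootstrap_mean_neq(
    sequences: Sequence[PBSequence],
    positions: Sequence[int],
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Bootstrap (over models) of the mean Neq over *positions* (0-based).

    Returns ``(estimate, bias_corrected, standard_error)``.  The plug-in
    exp-entropy estimator is biased downward by O((k-1)/2n) for k
    occupied states and n models — the same order as its sampling error
    near uniform distributions — so inference should use the
    bias-corrected value ``2*estimate - mean(bootstrap replicates)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alphabet = PB_LETTERS + UNASSIGNED
    lut = {letter: i for i, letter in enumerate(alphabet)}
    codes = np.array([[lut[c] for c in s.letters] for s in sequences], dtype=np.int64)
    positions = np.asarray(list(positions), dtype=int)
    estimate = _mean_neq_from_codes(codes, positions)
    n = codes.shape[0]
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        reps[b] = _mean_neq_from_codes(codes[idx], positions)
    corrected = 2.0 * estimate - float(reps.mean())
    return estimate, corrected, float(reps.std(ddof=1))


# ---------------------------------------------------------------------------
# file formats


def profile_filename(entry_id: str, kind: str, chain_id: str | None = None) -> str:
    """Dataset naming contract for PB products.

    kind: "fasta" -> .PB.fasta, "count" -> .PB.count, "neq" -> .PB.Neq;
    multi-chain entries add the -chain{C} suffix before the extension.
    """
    ext = {"fasta": ".PB.fasta", "count": ".PB.count", "neq": ".PB.Neq"}[kind]
    stem = entry_id if chain_id is None else f"{entry_id}-chain{chain_id}"
    return stem + ext


def write_count(matrix: PBCountMatrix, path: str | Path) -> None:
    """Whitespace-delimited count table: position, a..p, n_assigned."""
    df = pd.DataFrame(matrix.counts, columns=list(PB_LETTERS))
    df.insert(0, "position", [p[0] for p in matrix.positions])
    df["n_assigned"] = matrix.n_assigned
    df.to_csv(path, sep=" ", index=False)


def read_count(path: str | Path, n_models: int | None = None) -> PBCountMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    expected = ["position", *PB_LETTERS, "n_assigned"]
    if list(df.columns) != expected:
        raise ConsistencyError(f"{path}: unexpected count-file header {list(df.columns)}")
    counts = df[list(PB_LETTERS)].to_numpy(dtype=int)
    if n_models is None:
        n_models = int(df["n_assigned"].max())
    positions = [(int(p), int(p)) for p in df["position"]]
    return PBCountMatrix(positions=positions, counts=counts, n_models=n_models)


def write_neq(profile: NeqProfile, path: str | Path) -> None:
    """Whitespace-delimited Neq table: position, Neq at 4 decimals, NA if
    never assigned."""
    with open(path, "w") as fh:
        fh.write("position Neq\n")
        for (seq_idx, _), v in zip(profile.positions, profile.per_position_neq):
            text = "NA" if math.isnan(v) else f"{v:.4f}"
            fh.write(f"{seq_idx} {text}\n")


def read_neq(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    if list(df.columns) != ["position", "Neq"]:
        raise ConsistencyError(f"{path}: unexpected Neq-file header {list(df.columns)}")
    return df


def write_classes(profile: NeqProfile, path: str | Path) -> None:
    """Per-position class table: position, author number, Neq, label."""
    with open(path, "w") as fh:
        fh.write("position author_number Neq class\n")
        for (seq_idx, author), v, lab in zip(
            profile.positions, profile.per_position_neq, profile.labels
        ):
            text = "NA" if math.isnan(v) else f"{v:.4f}"
            fh.write(f"{seq_idx} {author} {text} {lab}\n")
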