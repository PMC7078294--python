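"""Reading, cleaning, and writing multi-model PDB ensembles.

Conformational ensembles (NMR bundles, SAXS-restrained pools, MD
snapshots) are distributed as multi-model PDB files.  Deposited files are
frequently messy: alternate locations, incomplete residues, models whose
residue content disagrees with the rest of the bundle.  This module
normalizes them into a small, explicit data model so that the geometry
code downstream never sees malformed input, and records every
modification in a :class:`CleaningReport`.

Parsing and serialization are delegated to :mod:`gemmi`; a light
fixed-column validator runs first because gemmi silently coerces
malformed numeric fields.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import gemmi
import numpy as np
import pandas as pd

from pbentropy.errors import (
    EmptyEnsembleError,
    PdbParseError,
    UnrecoverableEnsembleError,
)

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "Ensemble",
    "CleaningAction",
    "CleaningReport",
    "read_multimodel_pdb",
    "clean_ensemble",
    "write_pdb",
    "CHAIN_BREAK_CN_CUTOFF",
]

#: Maximum peptide-bond C(i)-N(i+1) distance in A before a chain break is
#: declared (a formed peptide bond is ~1.33 A; 2.5 A leaves slack for
#: poorly refined models while rejecting genuine gaps).
CHAIN_BREAK_CN_CUTOFF = 2.5

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})
BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass
class AtomRecord:
    """One atom of one residue of one model."""

    name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    coordinates: np.ndarray
    occupancy: float = 1.0
    alt_loc: str = ""
    element: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,) or not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """A residue identified by its author (number, insertion-code) key."""

    identity: str
    position_key: tuple[int, str]
    atoms: list[AtomRecord] = field(default_factory=list)

    def get_atom(self, name: str) -> AtomRecord | None:
        hits = [a for a in self.atoms if a.name == name]
        return hits[0] if len(hits) == 1 else None

    @property
    def backbone_complete(self) -> bool:
        """True iff N, CA and C each occur exactly once."""
        counts = Counter(a.name for a in self.atoms)
        return all(counts[n] == 1 for n in BACKBONE_ATOMS)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    #: indices i such that continuity fails between residues i and i+1
    breaks: set[int] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.residues)

    def position_keys(self) -> tuple[tuple[int, str], ...]:
        return tuple(r.position_key for r in self.residues)


@dataclass
class Ensemble:
    """Ordered models, each a list of chains."""

    entry_id: str
    models: list[list[Chain]]
    source_path: str = ""

    @property
    def n_models(self) -> int:
        return len(self.models)

    def chain_ids(self, model_index: int = 0) -> list[str]:
        return [c.chain_id for c in self.models[model_index]]

    def get_chain(self, model_index: int, chain_id: str) -> Chain:
        for c in self.models[model_index]:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def signature(self, ndigits: int = 3) -> tuple:
        """Nested tuple of atom names, position keys and rounded coordinates.

        Used to compare ensembles up to coordinate precision (PDB files
        store 3 decimals).
        """
        return tuple(
            tuple(
                (
                    ch.chain_id,
                    tuple(
                        (
                            r.position_key,
                            tuple(
                                (a.name, tuple(round(float(x), ndigits) for x in a.coordinates))
                                for a in r.atoms
                            ),
                        )
                        for r in ch.residues
                    ),
                )
                for ch in model
            )
            for model in self.models
        )


@dataclass
class CleaningAction:
    model_index: int | None
    chain_id: str | None
    kind: str
    detail: str


@dataclass
class CleaningReport:
    """Every modification made by :func:`clean_ensemble`."""

    actions: list[CleaningAction] = field(default_factory=list)
    models_in: int = 0
    models_dropped: int = 0

    def add(self, model_index: int | None, chain_id: str | None, kind: str, detail: str) -> None:
        self.actions.append(CleaningAction(model_index, chain_id, kind, detail))

    def count(self, kind: str) -> int:
        return sum(1 for a in self.actions if a.kind == kind)

    @property
    def modifications(self) -> list[CleaningAction]:
        """Actions that changed the ensemble (break annotations excluded)."""
        return [a for a in self.actions if a.kind != "chain_break"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.model_index, a.chain_id, a.kind, a.detail) for a in self.actions],
            columns=["model", "chain", "kind", "detail"],
        )

    def __str__(self) -> str:
        lines = [
            f"cleaning report: {len(self.actions)} action(s), "
            f"{self.models_dropped}/{self.models_in} model(s) dropped"
        ]
        for a in self.actions:
            where = f"model {a.model_index}" if a.model_index is not None else "ensemble"
            if a.chain_id:
                where += f" chain {a.chain_id}"
            lines.append(f"  [{a.kind}] {where}: {a.detail}")
        return "\n".join(lines)

    def write(self, log_path: str | Path, table_path: str | Path | None = None) -> None:
        Path(log_path).write_text(str(self) + "\n")
        if table_path is not None:
            self.to_frame().to_csv(table_path, sep="\t", index=False)


def _validate_pdb_lines(path: Path) -> None:
    """Reject coordinate lines whose fixed columns do not parse.

    gemmi tolerates (and zeroes) malformed numeric fields, so the
    "parse error naming the line" contract is enforced here.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PdbParseError(f"{path}: line {lineno}: truncated coordinate record")
            try:
                int(line[22:26])
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
                if line[54:60].strip():
                    float(line[54:60])
            except ValueError as exc:
                raise PdbParseError(
                    f"{path}: line {lineno}: unparseable coordinate record ({exc})"
                ) from None


def _convert_residue(res: gemmi.Residue, chain_id: str) -> Residue | None:
    """Map a gemmi residue into the package model; None = dropped."""
    name = res.name
    if name in WATER_NAMES:
        return None
    het = res.het_flag == "H"
    if het and name != "MSE":
        return None  # ligands, ions, modified residues other than MSE
    if name == "MSE":
        identity = "MET"  # selenomethionine analysed as methionine
    elif name in STANDARD_AA:
        identity = name
    else:
        identity = "UNK"
    icode = res.seqid.icode.strip()
    out = Residue(identity=identity, position_key=(res.seqid.num, icode))
    for atom in res:
        altloc = atom.altloc if atom.altloc not in ("\x00",) else ""
        out.atoms.append(
            AtomRecord(
                name=atom.name,
                residue_number=res.seqid.num,
                insertion_code=icode,
                chain_id=chain_id,
                coordinates=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                occupancy=min(max(atom.occ, 0.0), 1.0),
                alt_loc=altloc,
                element=atom.element.name,
            )
        )
    return out if out.atoms else None


def read_multimodel_pdb(path: str | Path, entry_id: str | None = None) -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    One model per MODEL/ENDMDL block (a file without MODEL records yields
    one model).  Waters and HETATM records are dropped, except MSE which
    is kept as MET.  Non-standard ATOM residue names are kept with
    identity ``UNK`` so tagged disordered constructs remain parseable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_lines(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PdbParseError(f"{path}: {exc}") from exc
    if entry_id is None:
        entry_id = path.name.split(".")[0]

    models: list[list[Chain]] = []
    for g_model in st:
        chains: list[Chain] = []
        for g_chain in g_model:
            ch = Chain(chain_id=g_chain.name or "A")
            for g_res in g_chain:
                res = _convert_residue(g_res, ch.chain_id)
                if res is not None:
                    ch.residues.append(res)
            if ch.residues:
                chains.append(ch)
        if chains:
            models.append(chains)
    if not models:
        raise EmptyEnsembleError(f"{path}: no models with protein atoms")
    return Ensemble(entry_id=entry_id, models=models, source_path=str(path))


def _resolve_altlocs(res: Residue, model_index: int, report: CleaningReport) -> Residue:
    by_name: dict[str, list[AtomRecord]] = {}
    for a in res.atoms:
        by_name.setdefault(a.name, []).append(a)
    kept: list[AtomRecord] = []
    for name, group in by_name.items():
        if len(group) == 1:
            atom = group[0]
            if atom.alt_loc:
                atom = AtomRecord(
                    atom.name, atom.residue_number, atom.insertion_code, atom.chain_id,
                    atom.coordinates, atom.occupancy, "", atom.element,
                )
            kept.append(atom)
            continue
        # highest occupancy wins; ties broken by alphabetically first alt_loc
        best = sorted(group, key=lambda a: (-a.occupancy, a.alt_loc))[0]
        report.add(
            model_index,
            best.chain_id,
            "altloc_resolved",
            f"residue {res.position_key} atom {name}: kept alt '{best.alt_loc}' "
            f"(occ {best.occupancy:g}) of {len(group)} locations",
        )
        kept.append(
            AtomRecord(
                best.name, best.residue_number, best.insertion_code, best.chain_id,
                best.coordinates, best.occupancy, "", best.element,
            )
        )
    return Residue(res.identity, res.position_key, kept)


def _detect_breaks(chain: Chain) -> set[int]:
    breaks: set[int] = set()
    for i in range(len(chain.residues) - 1):
        r1, r2 = chain.residues[i], chain.residues[i + 1]
        c = r1.get_atom("C")
        n = r2.get_atom("N")
        if c is not None and n is not None:
            if float(np.linalg.norm(c.coordinates - n.coordinates)) > CHAIN_BREAK_CN_CUTOFF:
                breaks.add(i)
                continue
        num1, ic1 = r1.position_key
        num2, ic2 = r2.position_key
        if num2 - num1 > 1 and not ic1 and not ic2:
            breaks.add(i)
        elif c is None or n is None:
            # bond unmeasurable and numbering gives no continuity guarantee
            if num2 - num1 != 1 and not (num2 == num1 and ic2):
                breaks.add(i)
    return breaks


def _sort_key(res: Residue) -> tuple[int, str]:
    return res.position_key


def clean_ensemble(
    ensemble: Ensemble,
    on_inconsistent: Literal["drop", "error"] = "drop",
) -> tuple[Ensemble, CleaningReport]:
    """Normalize an ensemble; every modification is logged.

    Steps: resolve alternate locations (highest occupancy, alphabetical
    tie-break), re-sort residues by (number, insertion code), annotate
    chain breaks, and drop (or reject, per *on_inconsistent*) models
    whose residue key sequence or chain set disagrees with the majority
    of models.
    """
    report = CleaningReport(models_in=ensemble.n_models)
    cleaned_models: list[list[Chain]] = []
    for mi, model in enumerate(ensemble.models):
        chains: list[Chain] = []
        for ch in model:
            residues = [_resolve_altlocs(r, mi, report) for r in ch.residues]
            ordered = sorted(residues, key=_sort_key)
            if [r.position_key for r in ordered] != [r.position_key for r in residues]:
                report.add(mi, ch.chain_id, "residues_resorted", "residues re-sorted by position key")
            new_chain = Chain(ch.chain_id, ordered)
            new_chain.breaks = _detect_breaks(new_chain)
            for b in sorted(new_chain.breaks):
                report.add(
                    mi, ch.chain_id, "chain_break",
                    f"continuity fails between residues {ordered[b].position_key} "
                    f"and {ordered[b + 1].position_key}",
                )
            chains.append(new_chain)
        cleaned_models.append(chains)

    # majority vote over (chain ids, per-chain residue keys)
    def model_signature(model: list[Chain]) -> tuple:
        return tuple((c.chain_id, c.position_keys()) for c in model)

    signatures = [model_signature(m) for m in cleaned_models]
    counts = Counter(signatures)
    majority_sig, majority_n = counts.most_common(1)[0]
    if majority_n == 1 and len(cleaned_models) > 1:
        raise UnrecoverableEnsembleError(
            f"{ensemble.entry_id}: all {len(cleaned_models)} models are mutually "
            "inconsistent; no majority residue sequence exists"
        )
    kept: list[list[Chain]] = []
    for mi, (model, sig) in enumerate(zip(cleaned_models, signatures)):
        if sig != majority_sig:
            if on_inconsistent == "error":
                raise UnrecoverableEnsembleError(
                    f"{ensemble.entry_id}: model {mi} disagrees with the majority "
                    "residue sequence"
                )
            report.add(
                mi, None, "model_dropped",
                "residue key sequence disagrees with the majority of models",
            )
            report.models_dropped += 1
            continue
        kept.append(model)
    return (
        Ensemble(entry_id=ensemble.entry_id, models=kept, source_path=ensemble.source_path),
        report,
    )


def write_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write standard PDB text with MODEL/ENDMDL framing and TER records.

    Round-trips through :func:`read_multimodel_pdb` on atom names,
    position keys and coordinates (3-decimal precision).
    """
    if not ensemble.models:
        raise ValueError("cannot write an empty ensemble")
    st = gemmi.Structure()
    st.name = ensemble.entry_id
    for mi, model in enumerate(ensemble.models, start=1):
        g_model = gemmi.Model(mi)
        for ch in model:
            g_chain = gemmi.Chain(ch.chain_id)
            for res in ch.residues:
                g_res = gemmi.Residue()
                g_res.name = "MSE" if res.identity == "MET" and _was_mse(res) else res.identity
                g_res.seqid = gemmi.SeqId(res.position_key[0], res.position_key[1] or " ")
                g_res.het_flag = "A"
                for atom in res.atoms:
                    g_atom = gemmi.Atom()
                    g_atom.name = atom.name
                    g_atom.pos = gemmi.Position(*atom.coordinates)
                    g_atom.occ = atom.occupancy
                    g_atom.b_iso = 0.0
                    if atom.alt_loc:
                        g_atom.altloc = atom.alt_loc
                    if atom.element:
                        g_atom.element = gemmi.Element(atom.element)
                    g_res.add_atom(g_atom)
                g_chain.add_residue(g_res)
            g_model.add_chain(g_chain)
        st.add_model(g_model)
    st.setup_entities()  # assigns entities so TER records are emitted
    st.write_pdb(str(path))


def _was_mse(res: Residue) -> bool:
    # selenomethionine carries SE instead of SD
    return any(a.element == "SE" or a.name == "SE" for a in res.atoms)
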