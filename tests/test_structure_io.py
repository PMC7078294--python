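import numpy as np
import pytest

from pbentropy.errors import EmptyEnsembleError, PdbParseError, UnrecoverableEnsembleError
from pbentropy.structure_io import (
    AtomRecord,
    Chain,
    Ensemble,
    Residue,
    clean_ensemble,
    read_multimodel_pdb,
    write_pdb,
)
from pbentropy.synthetic_ensembles import EnsembleSpec, FaultSpec, RegionSpec, generate_fixture


def small_spec(n_models=3, length=20, seed=7):
    return EnsembleSpec(
        chain_length=length,
        n_models=n_models,
        regions=(RegionSpec(0, length, ("m",)),),
        seed=seed,
    )


def make_residue(num, atoms, chain_id="A", identity="ALA"):
    res = Residue(identity=identity, position_key=(num, ""))
    for name, xyz, occ, alt in atoms:
        res.atoms.append(
            AtomRecord(
                name=name, residue_number=num, insertion_code="", chain_id=chain_id,
                coordinates=np.asarray(xyz, float), occupancy=occ, alt_loc=alt,
                element=name[0],
            )
        )
    return res


class TestRead:
    def test_multimodel_fixture_parses_back(self, tmp_path):
        path = tmp_path / "SYN.pdb"
        generate_fixture(small_spec(), path)
        text = path.read_text()
        assert text.count("MODEL ") == 3
        ens = read_multimodel_pdb(path)
        assert ens.entry_id == "SYN"
        assert ens.n_models == 3
        keys = {tuple(ch.position_keys() for ch in m) for m in ens.models}
        assert len(keys) == 1  # all models share position keys
        assert all(len(m[0]) == 20 for m in ens.models)

    def test_single_model_without_model_records(self, tmp_path):
        path = tmp_path / "ONE.pdb"
        generate_fixture(small_spec(n_models=1, length=10), path)
        assert "MODEL" not in path.read_text()
        ens = read_multimodel_pdb(path)
        assert ens.n_models == 1
        assert len(ens.models[0]) == 1
        assert len(ens.models[0][0]) == 10
        assert all(r.backbone_complete for r in ens.models[0][0].residues)

    def test_missing_ca_marks_backbone_incomplete(self, tmp_path):
        path = tmp_path / "SYN.pdb"
        generate_fixture(small_spec(), path, faults=(FaultSpec(1, 4, ("CA",)),))
        ens = read_multimodel_pdb(path)
        assert not ens.models[1][0].residues[4].backbone_complete
        assert ens.models[0][0].residues[4].backbone_complete

    def test_unparseable_atom_line_names_line_number(self, tmp_path):
        path = tmp_path / "SYN.pdb"
        generate_fixture(small_spec(n_models=1, length=5), path)
        lines = path.read_text().splitlines(keepends=True)
        idx = next(i for i, l in enumerate(lines) if l.startswith("ATOM"))
        lines[idx] = lines[idx][:30] + "  X.0000" + lines[idx][38:]
        bad = tmp_path / "bad.pdb"
        bad.write_text("".join(lines))
        with pytest.raises(PdbParseError, match=rf"line {idx + 1}"):
            read_multimodel_pdb(bad)

    def test_no_protein_atoms_is_empty_input(self, tmp_path):
        path = tmp_path / "w.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        with pytest.raises(EmptyEnsembleError):
            read_multimodel_pdb(path)

    def test_mse_kept_as_met_other_hetatm_dropped(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "HETATM    2  SE  MSE A   2       1.000   0.000   0.000  1.00  0.00          SE\n"
            "HETATM    3 MG    MG A   3       2.000   0.000   0.000  1.00  0.00          MG\n"
            "ATOM      4  CA  XYZ A   4       3.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        ens = read_multimodel_pdb(path)
        identities = [r.identity for r in ens.models[0][0].residues]
        assert identities == ["ALA", "MET", "UNK"]


class TestClean:
    def test_clean_fixture_is_identity_with_empty_report(self, three_region_ensemble):
        cleaned, report = clean_ensemble(three_region_ensemble)
        assert report.modifications == []
        assert cleaned.signature() == three_region_ensemble.signature()

    def test_altloc_highest_occupancy_wins(self):
        res = make_residue(
            1,
            [("N", (0, 0, 0), 1.0, ""), ("CA", (1.0, 0, 0), 0.6, "A"),
             ("CA", (9.0, 0, 0), 0.4, "B"), ("C", (2, 0, 0), 1.0, "")],
        )
        ens = Ensemble("X", [[Chain("A", [res])]])
        cleaned, report = clean_ensemble(ens)
        ca = cleaned.models[0][0].residues[0].get_atom("CA")
        assert ca is not None and ca.coordinates[0] == 1.0 and ca.alt_loc == ""
        assert report.count("altloc_resolved") == 1

    def test_altloc_tie_breaks_alphabetically(self):
        res = make_residue(
            1, [("CA", (5.0, 0, 0), 0.5, "B"), ("CA", (1.0, 0, 0), 0.5, "A")]
        )
        ens = Ensemble("X", [[Chain("A", [res])]])
        cleaned, _ = clean_ensemble(ens)
        assert cleaned.models[0][0].residues[0].get_atom("CA").coordinates[0] == 1.0

    def test_residues_resorted_by_position_key(self):
        r2 = make_residue(2, [("CA", (1, 0, 0), 1.0, "")])
        r1 = make_residue(1, [("CA", (0, 0, 0), 1.0, "")])
        ens = Ensemble("X", [[Chain("A", [r2, r1])]])
        cleaned, report = clean_ensemble(ens)
        assert cleaned.models[0][0].position_keys() == ((1, ""), (2, ""))
        assert report.count("residues_resorted") == 1

    def test_model_missing_residues_dropped_with_conservation(self, tmp_path):
        path = tmp_path / "SYN.pdb"
        faults = tuple(FaultSpec(3, 7, None) for _ in range(5))  # residues 8-12 of model 4
        generate_fixture(small_spec(n_models=5), path, faults=faults)
        ens = read_multimodel_pdb(path)
        cleaned, report = clean_ensemble(ens)
        assert cleaned.n_models == 4
        assert report.models_dropped == 1
        assert cleaned.n_models + report.models_dropped == report.models_in
        assert report.count("model_dropped") == 1

    def test_inconsistent_models_can_raise_instead(self, tmp_path):
        path = tmp_path / "SYN.pdb"
        generate_fixture(small_spec(n_models=5), path, faults=(FaultSpec(3, 7, None),))
        ens = read_multimodel_pdb(path)
        with pytest.raises(UnrecoverableEnsembleError):
            clean_ensemble(ens, on_inconsistent="error")

    def test_all_models_mutually_inconsistent_is_unrecoverable(self, tmp_path):
        path = tmp_path / "SYN.pdb"
        generate_fixture(
            small_spec(n_models=3),
            path,
            faults=(FaultSpec(0, 0, None), FaultSpec(1, 5, None), FaultSpec(2, 10, None)),
        )
        ens = read_multimodel_pdb(path)
        with pytest.raises(UnrecoverableEnsembleError):
            clean_ensemble(ens)

    def test_cleaning_is_idempotent(self, tmp_path):
        path = tmp_path / "SYN.pdb"
        generate_fixture(small_spec(n_models=5), path, faults=(FaultSpec(2, 7, None),))
        ens = read_multimodel_pdb(path)
        once, _ = clean_ensemble(ens)
        twice, report2 = clean_ensemble(once)
        assert twice.signature() == once.signature()
        assert report2.modifications == []

    def test_chain_break_recorded_at_numbering_gap(self):
        residues = [
            make_residue(n, [("N", (x, 0, 0), 1.0, ""), ("CA", (x + 0.5, 0, 0), 1.0, ""),
                             ("C", (x + 1.0, 0, 0), 1.0, "")])
            for n, x in [(1, 0.0), (2, 1.2), (5, 2.4)]
        ]
        ens = Ensemble("X", [[Chain("A", residues)]])
        cleaned, _ = clean_ensemble(ens)
        assert cleaned.models[0][0].breaks == {1}

    def test_chain_break_recorded_at_long_peptide_bond(self, three_region_spec):
        from pbentropy.synthetic_ensembles import build_backbone, chain_from_backbone

        coords = build_backbone(np.full((10, 2), (-68.0, -39.5)))
        coords[5:] += 10.0  # translate the tail away: C(4)-N(5) >> 2.5 A
        chain = chain_from_backbone(coords)
        ens = Ensemble("X", [[chain]])
        cleaned, _ = clean_ensemble(ens)
        assert cleaned.models[0][0].breaks == {4}


class TestWrite:
    def test_roundtrip_is_fixed_point(self, tmp_path, three_region_ensemble):
        p1 = tmp_path / "a.pdb"
        p2 = tmp_path / "b.pdb"
        write_pdb(three_region_ensemble, p1)
        ens1 = read_multimodel_pdb(p1)
        write_pdb(ens1, p2)
        ens2 = read_multimodel_pdb(p2)
        assert ens1.signature() == ens2.signature()
        assert ens1.signature() == three_region_ensemble.signature()

    def test_empty_ensemble_write_raises(self, tmp_path):
        with pytest.raises(ValueError):
            write_pdb(Ensemble("X", []), tmp_path / "x.pdb")

    def test_many_chains_written_in_order_with_ter(self, tmp_path):
        chains = []
        for k in range(13):
            cid = "ABCDEFGHIJKLM"[k]
            res = make_residue(1, [("N", (k, 0, 0), 1.0, ""), ("CA", (k, 1, 0), 1.0, ""),
                                   ("C", (k, 2, 0), 1.0, "")], chain_id=cid)
            chains.append(Chain(cid, [res]))
        ens = Ensemble("MANY", [chains])
        path = tmp_path / "many.pdb"
        write_pdb(ens, path)
        assert path.read_text().count("TER") == 13
        back = read_multimodel_pdb(path)
        assert back.chain_ids() == list("ABCDEFGHIJKLM")
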