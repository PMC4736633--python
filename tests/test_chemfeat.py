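"""Molecule parsing, descriptors, fingerprints and Murcko frameworks."""

import numpy as np
import pytest
from rdkit import Chem

from toxqsar import chemfeat
from toxqsar.chemfeat import (
    FeatureTable,
    MoleculeRecord,
    bundled_dictionary,
    compute_descriptors,
    compute_fingerprint,
    descriptor_table,
    murcko_framework,
    parse_and_clean,
)


class TestParseAndClean:
    @pytest.mark.parametrize(
        "record, reason",
        [
            (MoleculeRecord("hi", "c1ccccc1", 7.5), "activity_range"),
            (MoleculeRecord("lo", "c1ccccc1O", -0.2), "activity_range"),
            (MoleculeRecord("bad", "C1CC", 2.0), "parse_fail"),
        ],
    )
    def test_rejection_reasons(self, record, reason):
        anchor = MoleculeRecord("ok", "CCO", 2.0)
        molset, rejections = parse_and_clean([anchor, record], 0.0, 7.0)
        assert molset.ids() == ["ok"]
        assert [r.reason for r in rejections] == [reason]
        assert rejections[0].id == record.id

    def test_valid_record_retained_with_canonical_smiles(self):
        molset, rej = parse_and_clean([MoleculeRecord("m1", "c1ccccc1", 2.0)])
        assert rej == []
        rec = molset.records[0]
        assert (rec.id, rec.activity) == ("m1", 2.0)
        assert rec.smiles == Chem.CanonSmiles("c1ccccc1")

    def test_duplicates_detected_on_canonical_smiles_first_kept(self):
        records = [
            MoleculeRecord("a", "OCC", 1.0),  # ethanol, non-canonical order
            MoleculeRecord("b", "CCO", 2.0),  # same molecule
        ]
        molset, rejections = parse_and_clean(records)
        assert molset.ids() == ["a"]
        assert rejections[0].reason == "duplicate" and rejections[0].id == "b"

    def test_boundary_activities_kept(self):
        records = [
            MoleculeRecord("z", "CCO", 0.0),
            MoleculeRecord("s", "CCN", 7.0),
        ]
        molset, rejections = parse_and_clean(records, 0.0, 7.0)
        assert len(molset) == 2 and not rejections

    def test_empty_input_and_all_rejected_error(self):
        with pytest.raises(ValueError):
            parse_and_clean([])
        with pytest.raises(ValueError):
            parse_and_clean([MoleculeRecord("x", "not_smiles", 1.0)])


class TestDescriptors:
    def test_ethanol_molecular_weight(self):
        # sum of atomic masses: 2 C + 6 H + 1 O
        val = compute_descriptors("CCO", ["MW"])["MW"]
        assert val == pytest.approx(46.07, abs=0.01)

    @pytest.mark.parametrize(
        "smiles, name, expected",
        [
            ("CC", "b_rotN", 0.0),  # ethane: no rotatable bonds
            ("c1ccccc1", "a_acc", 0.0),  # benzene: no acceptors
            ("c1ccccc1", "rings", 1.0),
            ("FC(F)(F)c1ccccc1", "a_nF", 3.0),
        ],
    )
    def test_known_counts(self, smiles, name, expected):
        assert compute_descriptors(smiles, [name])[name] == expected

    def test_unknown_descriptor_raises_with_registry(self):
        with pytest.raises(KeyError, match="registry"):
            compute_descriptors("CCO", ["no_such_descriptor"])

    def test_canonical_roundtrip_agrees_exactly(self, toy_records):
        names = list(chemfeat.DEFAULT_2D_DESCRIPTORS)
        for rec in toy_records[:10]:
            canon = Chem.CanonSmiles(rec.smiles)
            assert compute_descriptors(rec.smiles, names) == compute_descriptors(canon, names)

    def test_descriptor_table_shape_and_provenance(self, toy_molset):
        table, rejections = descriptor_table(toy_molset, ["MW", "SlogP", "TPSA"])
        assert rejections == []
        assert table.data.shape == (len(toy_molset), 3)
        assert set(table.provenance.values()) == {"descriptor"}

    def test_3d_descriptor_deterministic(self):
        a = compute_descriptors("CCOCC", ["pmi1"])["pmi1"]
        b = compute_descriptors("CCOCC", ["pmi1"])["pmi1"]
        assert a == b and a > 0


class TestFingerprints:
    def test_pyridine_nitrogen_count_bit(self):
        pub = bundled_dictionary("pubchem")
        fp = compute_fingerprint("c1ccncc1", pub)
        names = pub.column_names()
        assert fp[names.index("PubchemFP:n_count_1")] == 1
        assert fp[names.index("PubchemFP:n_count_2")] == 0

    def test_trifluoromethyl_smarts_bit(self):
        sub = bundled_dictionary("subfp")
        fp = compute_fingerprint("FC(F)(F)c1ccccc1", sub)
        assert fp[sub.column_names().index("SubFP:trifluoromethyl")] == 1

    def test_methane_matches_no_alert_bit(self):
        sub = bundled_dictionary("subfp")
        fp = compute_fingerprint("C", sub)
        names = sub.column_names()
        for key in ("trifluoromethyl", "alkylfluoride", "hetero_n_basic_h", "heterocyclic"):
            assert fp[names.index(f"SubFP:{key}")] == 0

    def test_bit_vector_length_and_binarity(self, toy_molset):
        sub = bundled_dictionary("subfp")
        fp = compute_fingerprint(toy_molset.mols[0], sub)
        assert fp.shape == (len(sub),)
        assert set(np.unique(fp)) <= {0, 1}

    @pytest.mark.parametrize(
        "variant_a, variant_b",
        [
            ("c1ccncc1", "n1ccccc1"),
            ("FC(F)(F)c1ccccc1", "c1ccccc1C(F)(F)F"),
            ("CC(=O)Nc1ccccc1", "c1ccccc1NC(C)=O"),
        ],
    )
    def test_fingerprint_invariant_to_atom_order(self, variant_a, variant_b):
        for dname in ("subfp", "pubchem"):
            d = bundled_dictionary(dname)
            assert (compute_fingerprint(variant_a, d) == compute_fingerprint(variant_b, d)).all()

    def test_dictionary_file_roundtrip(self, tmp_path):
        path = tmp_path / "mini.tsv"
        path.write_text("# comment\n0\t[OX2H]\tHydroxyl\n1\t>=2 N\tTwo nitrogens\n")
        d = chemfeat.load_dictionary(path, name="Mini")
        assert len(d) == 2
        assert (compute_fingerprint("NCCN", d) == [0, 1]).all()
        assert (compute_fingerprint("OCC", d) == [1, 0]).all()

    def test_noncontiguous_indices_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("0\t[OX2H]\ta\n2\t[NX3]\tb\n")
        with pytest.raises(ValueError, match="contiguous"):
            chemfeat.load_dictionary(path)


class TestMurckoFramework:
    @pytest.mark.parametrize(
        "smiles, expected",
        [
            ("Cc1ccccc1", "c1ccccc1"),  # toluene: methyl stripped
            ("CCCCCC", ""),  # acyclic
            ("c1ccccc1Cc1ccccc1", Chem.CanonSmiles("c1ccc(Cc2ccccc2)cc1")),
        ],
    )
    def test_known_frameworks(self, smiles, expected):
        assert murcko_framework(smiles) == expected

    def test_idempotent_on_toy_molecules(self, toy_molset):
        for mol in toy_molset.mols[:30]:
            f = murcko_framework(mol)
            if f:
                assert murcko_framework(f) == f


class TestFeatureTable:
    def test_join_and_subset(self, toy_molset):
        t1, _ = descriptor_table(toy_molset, ["MW", "TPSA"])
        t2 = chemfeat.fingerprint_table(toy_molset, bundled_dictionary("subfp"))
        joined = t1.join(t2)
        assert len(joined.columns) == 2 + len(bundled_dictionary("subfp"))
        sub = joined.subset(["MW"])
        assert sub.columns == ["MW"] and sub.provenance == {"MW": "descriptor"}

    def test_csv_roundtrip(self, tmp_path, toy_molset):
        t1, _ = descriptor_table(toy_molset, ["MW", "TPSA"])
        t1.to_csv(tmp_path / "ft.csv")
        back = FeatureTable.from_csv(tmp_path / "ft.csv")
        assert np.allclose(back.data.to_numpy(), t1.data.to_numpy())
        assert list(back.data.index) == list(t1.data.index)
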