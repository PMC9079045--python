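"""Fingerprints, molecule standardization, Ro5 profiling, matrix import."""
import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from eraqsar import (
    Ro5Profile,
    featurize_dataset,
    import_external_matrix,
    load_pattern_set,
    ro5_profile,
    standardize_molecule,
    substructure_count,
    substructure_presence,
)
from eraqsar.featurization import FeaturizationError, PatternEntry, PatternSet

from helpers import brute_force_substructure_count


class TestPatternSet:
    def test_file_order_preserved(self, tmp_path):
        p = tmp_path / "p.smarts"
        p.write_text("B_amine [NX3]\nA_phenol [OX2H]c\nC_halogen [F,Cl,Br,I]\n")
        ps = load_pattern_set(p)
        assert ps.names == ["B_amine", "A_phenol", "C_halogen"]

    def test_invalid_smarts_named_with_line(self, tmp_path):
        p = tmp_path / "p.smarts"
        p.write_text("ok [OX2H]\nbroken C(((\n")
        with pytest.raises(FeaturizationError, match=r":2"):
            load_pattern_set(p)

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "p.smarts"
        p.write_text("a [OX2H]\na [NX3]\n")
        with pytest.raises(FeaturizationError, match="duplicate"):
            load_pattern_set(p)

    def test_bundled_set_loads_with_builtins(self, pattern_set):
        assert len(pattern_set) >= 40
        assert len(set(pattern_set.names)) == len(pattern_set)
        builtins = [e for e in pattern_set.entries if e.is_builtin]
        assert {e.name for e in builtins} == {
            "ChiralCenterSpecified", "RotatableBondCount"
        }


class TestStandardize:
    def test_disabled_options_are_noop(self):
        mol = standardize_molecule("Oc1ccccc1")
        ref = Chem.MolFromSmiles("Oc1ccccc1")
        assert Chem.MolToSmiles(mol) == Chem.MolToSmiles(ref)
        assert mol.GetNumAtoms() == ref.GetNumAtoms()

    def test_polar_hydrogens_become_explicit(self):
        mol = standardize_molecule("Oc1ccccc1", add_polar_h=True)
        assert any(a.GetAtomicNum() == 1 for a in mol.GetAtoms())

    def test_keto_enol_pair_maps_to_one_tautomer(self):
        keto = standardize_molecule("CC(=O)CC(C)=O", canonical_tautomer=True)
        enol = standardize_molecule("CC(O)=CC(C)=O", canonical_tautomer=True)
        assert Chem.MolToSmiles(keto) == Chem.MolToSmiles(enol)

    def test_parse_failure_errors(self):
        with pytest.raises(FeaturizationError):
            standardize_molecule("xyzzy")


class TestCounts:
    phenol = PatternSet([PatternEntry("Phenol", "[OX2H]c")], "test")

    @pytest.mark.parametrize(
        "smiles, expected",
        [("Oc1ccccc1", 1), ("Oc1ccccc1O", 2), ("c1ccccc1", 0)],
    )
    def test_phenol_counts(self, smiles, expected):
        mol = Chem.MolFromSmiles(smiles)
        assert substructure_count(mol, self.phenol)[0] == expected

    def test_amine_absent_from_benzene(self):
        ps = PatternSet([PatternEntry("Amine", "[NX3]")], "test")
        assert substructure_count(Chem.MolFromSmiles("c1ccccc1"), ps)[0] == 0

    def test_counts_match_brute_force_oracle_on_pool(self, smiles_pool, pattern_set):
        smarts_entries = [e for e in pattern_set.entries if not e.is_builtin]
        ps = PatternSet(smarts_entries, "smarts-only")
        for smi in smiles_pool[:10]:
            mol = standardize_molecule(smi, add_polar_h=True)
            counts = substructure_count(mol, ps)
            oracle = [
                brute_force_substructure_count(mol, e.smarts) for e in smarts_entries
            ]
            assert list(counts) == oracle, smi

    def test_counts_invariant_to_atom_order(self, smiles_pool, pattern_set):
        rng = np.random.default_rng(0)
        for smi in rng.choice(smiles_pool, size=5, replace=False):
            ref = None
            mol0 = Chem.MolFromSmiles(smi)
            for _ in range(5):
                rendering = Chem.MolToSmiles(mol0, doRandom=True)
                mol = standardize_molecule(rendering, add_polar_h=True)
                counts = substructure_count(mol, pattern_set)
                if ref is None:
                    ref = counts
                assert np.array_equal(counts, ref), smi

    def test_builtin_descriptors_count_graph_features(self, pattern_set):
        mol = Chem.MolFromSmiles("N[C@@H](C)C(=O)O")  # one specified center
        counts = dict(zip(pattern_set.names, substructure_count(mol, pattern_set)))
        assert counts["ChiralCenterSpecified"] == 1
        assert counts["RotatableBondCount"] == 1  # the C-C(=O) bond


class TestPresence:
    def test_thresholding(self):
        assert list(substructure_presence([0, 2, 1])) == [0, 1, 1]
        assert list(substructure_presence([0, 0])) == [0, 0]

    def test_negative_counts_rejected(self):
        with pytest.raises(FeaturizationError):
            substructure_presence([-1, 2])

    def test_presence_equals_count_indicator_on_pool(self, smiles_pool, pattern_set):
        matrix, failures = featurize_dataset(smiles_pool, pattern_set, kind="count")
        assert not failures
        presence, _ = featurize_dataset(smiles_pool, pattern_set, kind="presence")
        assert np.array_equal(presence.values, (matrix.values > 0).astype(int))


class TestFeaturizeDataset:
    def test_shape_and_determinism(self, pattern_set):
        smiles = ["CCO", "c1ccccc1O"]
        m1, _ = featurize_dataset(smiles, pattern_set)
        m2, _ = featurize_dataset(smiles, pattern_set)
        assert m1.values.shape == (2, len(pattern_set))
        assert np.array_equal(m1.values, m2.values)
        assert m1.compound_ids == smiles

    def test_absent_pattern_gives_zero_column(self, tmp_path):
        p = tmp_path / "p.smarts"
        p.write_text("Iodine I\nCarbon C\n")
        matrix, _ = featurize_dataset(["CCO", "CCC"], load_pattern_set(p))
        frame = matrix.to_frame()
        assert (frame["Iodine"] == 0).all()
        assert frame["Iodine"].nunique() == 1  # flagged zero-variance downstream

    def test_empty_pattern_set_errors(self):
        with pytest.raises(FeaturizationError):
            featurize_dataset(["CCO"], PatternSet([], "empty"))

    def test_failures_reported_not_fatal(self, pattern_set):
        matrix, failures = featurize_dataset(["CCO", "(((("], pattern_set)
        assert len(matrix.compound_ids) == 1 and len(failures) == 1


class TestRo5:
    def test_rule_application(self):
        assert Ro5Profile(mw=600, logp=6.0, hbd=2, hba=8).violations == 2
        assert Ro5Profile(mw=350, logp=2.0, hbd=2, hba=5).violations == 0

    def test_ethanol_counts(self):
        p = ro5_profile("CCO")
        assert p.hbd == 1 and p.hba == 1 and p.violations == 0

    def test_violations_monotone_in_each_property(self):
        base = dict(mw=400, logp=4.0, hbd=4, hba=8)
        v0 = Ro5Profile(**base).violations
        for key, worse in [("mw", 700), ("logp", 7.0), ("hbd", 7), ("hba", 12)]:
            assert Ro5Profile(**{**base, key: worse}).violations >= v0


class TestExternalMatrix:
    def test_roundtrip_is_identity(self, tmp_path):
        frame = pd.DataFrame(
            [[1, 0, 3, 2], [0, 1, 0, 5], [2, 2, 1, 0]],
            index=pd.Index(["a", "b", "c"], name="compound_id"),
            columns=["f1", "f2", "f3", "f4"],
        )
        path = tmp_path / "m.csv"
        frame.to_csv(path)
        matrix = import_external_matrix(path)
        assert matrix.pattern_provenance == "external"
        pd.testing.assert_frame_equal(matrix.to_frame(), frame, check_dtype=False)

    def test_missing_cell_located(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("id,f1,f2\na,1,2\nb,,3\n")
        with pytest.raises(FeaturizationError, match="'b'.*'f1'"):
            import_external_matrix(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("id,f1\na,1\na,2\n")
        with pytest.raises(FeaturizationError, match="duplicate"):
            import_external_matrix(path)
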