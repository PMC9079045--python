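"""Curation pipeline: filtering, desalting, pIC50 conversion, deduplication."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eraqsar import (
    ActivityRecord,
    CurationConfig,
    TableCorruptionSpec,
    curate,
    deduplicate,
    desalt,
    filter_records,
    generate_activity_table,
    pic50_to_nM,
    to_pic50,
)
from eraqsar.curation import CurationError, curated_to_frame


def rec(**kw):
    defaults = dict(molecule_id="M1", smiles="CCO", standard_value=100.0,
                    standard_units="nM", standard_relation="=",
                    confidence_score=9, assay_type="B", assay_id="A1")
    defaults.update(kw)
    return ActivityRecord(**defaults)


class TestFilterRecords:
    def test_empty_table(self):
        assert filter_records([], CurationConfig()) == ([], [], [])

    def test_each_rule_fires_in_order(self):
        rows = [
            rec(),
            rec(standard_relation=">", standard_value=1000.0),
            rec(confidence_score=8, standard_value=50.0),
            rec(assay_type="F", standard_value=50.0),
            rec(standard_value=None),
        ]
        kept, censored, dropped = filter_records(rows, CurationConfig())
        assert len(kept) == 1 and len(censored) == 1
        assert [reason for _, reason in dropped] == [
            "confidence", "assay_type", "missing_value"
        ]

    def test_all_pass_is_identity(self):
        rows = [rec(molecule_id=f"M{i}") for i in range(4)]
        kept, censored, dropped = filter_records(rows, CurationConfig())
        assert kept == rows and censored == [] and dropped == []

    def test_partition_property(self):
        table, _ = generate_activity_table(
            TableCorruptionSpec(n_compounds=40, frac_censored_gt=0.2,
                                frac_low_confidence=0.2,
                                frac_nonbinding_assay=0.2,
                                frac_missing_value=0.1, seed=1)
        )
        from eraqsar.curation import records_from_frame

        records = records_from_frame(table)
        kept, censored, dropped = filter_records(records, CurationConfig())
        assert len(kept) + len(censored) + len(dropped) == len(records)

    def test_unknown_relation_dropped_with_reason(self):
        kept, censored, dropped = filter_records(
            [rec(standard_relation="~")], CurationConfig()
        )
        assert not kept and not censored
        assert dropped[0][1] == "unknown_relation"


class TestDesalt:
    @pytest.mark.parametrize(
        "smiles, expected_parent",
        [
            ("CC(=O)O.[Na+]", "CC(=O)O"),
            ("c1ccccc1", "c1ccccc1"),
            ("Cl.NCCc1ccccc1", "NCCc1ccccc1"),
        ],
    )
    def test_largest_fragment_kept(self, smiles, expected_parent):
        from rdkit import Chem

        assert desalt(smiles) == Chem.MolToSmiles(Chem.MolFromSmiles(expected_parent))

    def test_output_single_fragment_and_stereo_preserved(self):
        out = desalt("N[C@@H](C)C(=O)O.Cl")
        assert "." not in out and "@" in out

    def test_unparseable_smiles_errors(self):
        with pytest.raises(CurationError, match="not-a-smiles"):
            desalt("not-a-smiles")


class TestToPic50:
    def test_definition_values(self):
        assert to_pic50(1000, "nM") == 6.0
        assert to_pic50(1, "nM") == 9.0
        assert to_pic50(50, "nM") == pytest.approx(7.30103, abs=1e-5)

    def test_unit_policies(self):
        assert to_pic50(1.0, "uM", "convert_known_units") == 6.0
        assert to_pic50(1.0, "M", "convert_known_units") == 0.0
        with pytest.raises(CurationError):
            to_pic50(1.0, "uM", "strict_nM")
        with pytest.raises(CurationError):
            to_pic50(1.0, "furlongs", "convert_known_units")

    @pytest.mark.parametrize("bad", [0.0, -5.0, None])
    def test_nonpositive_value_errors(self, bad):
        with pytest.raises(CurationError):
            to_pic50(bad, "nM")

    @given(st.floats(min_value=0.0, max_value=12.0))
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_through_concentration(self, pic50):
        assert to_pic50(pic50_to_nM(pic50), "nM") == pytest.approx(pic50, abs=1e-12)


class TestDeduplicate:
    def test_singleton_passes_through(self):
        out, removed = deduplicate([("S", 6.0, ("M1", "A1"))], CurationConfig())
        assert len(out) == 1 and out[0].pic50 == 6.0 and not removed

    def test_tight_group_collapses_to_median(self):
        group = [("S", v, ("M1", f"A{i}")) for i, v in enumerate([6.0, 6.1, 6.2])]
        out, removed = deduplicate(group, CurationConfig(dedup_sd_threshold=1.0))
        assert len(out) == 1 and not removed
        assert out[0].pic50 == pytest.approx(6.1)
        assert out[0].n_source_records == 3

    def test_disagreeing_group_removed_whole(self):
        # SD of two points is |delta| / sqrt(2) ~ 2.83 > 1.0
        group = [("S", 5.0, ("M1", "A1")), ("S", 9.0, ("M1", "A2"))]
        out, removed = deduplicate(group, CurationConfig(dedup_sd_threshold=1.0))
        assert out == [] and removed == [("S", "value disagreement")]

    def test_nonfinite_pic50_rejected(self):
        with pytest.raises(CurationError):
            deduplicate([("S", float("nan"), ("M1", "A1"))], CurationConfig())


class TestCurate:
    def test_single_clean_record(self):
        result = curate([rec()])
        assert len(result.compounds) == 1
        assert result.report["stage_counts"]["curated"] == 1
        assert result.compounds[0].pic50 == 7.0  # 100 nM

    def test_all_censored_table_diverts_everything(self):
        rows = [rec(molecule_id=f"M{i}", standard_relation=">",
                    standard_value=1000.0) for i in range(5)]
        result = curate(rows)
        assert result.compounds == [] and len(result.gt_set) == 5
        assert all(r.relation == ">" for r in result.gt_set)
        assert result.gt_set[0].bound_pic50 == 6.0

    def test_matches_generator_ledger(self):
        spec = TableCorruptionSpec(
            n_compounds=50, frac_censored_gt=0.1, frac_censored_lt=0.1,
            frac_salts=0.3, frac_missing_value=0.1, dup_rate=0.2,
            dup_replicates=3, dup_noise_sd=0.2, frac_low_confidence=0.1,
            frac_nonbinding_assay=0.1, seed=13,
        )
        table, ledger = generate_activity_table(spec)
        result = curate(table)
        expected = sorted(
            (c["canonical_smiles"], round(c["pic50"], 9))
            for c in ledger["expected_compounds"]
        )
        got = sorted(
            (c.canonical_smiles, round(c.pic50, 9)) for c in result.compounds
        )
        assert got == expected
        assert len(result.gt_set) == len(ledger["expected_censored_gt"])
        assert len(result.lt_set) == len(ledger["expected_censored_lt"])

    def test_order_invariance(self):
        table, _ = generate_activity_table(
            TableCorruptionSpec(n_compounds=30, dup_rate=0.2, dup_noise_sd=0.1,
                                frac_salts=0.2, seed=21)
        )
        shuffled = table.sample(frac=1.0, random_state=99).reset_index(drop=True)
        a = {(c.canonical_smiles, round(c.pic50, 12)) for c in curate(table).compounds}
        b = {(c.canonical_smiles, round(c.pic50, 12)) for c in curate(shuffled).compounds}
        assert a == b

    def test_idempotence_on_reexpressed_output(self):
        table, _ = generate_activity_table(
            TableCorruptionSpec(n_compounds=25, dup_rate=0.2, dup_noise_sd=0.1,
                                frac_salts=0.2, seed=5)
        )
        first = curate(table).compounds
        frame = curated_to_frame(first).rename(columns={"pic50": "_p"})
        reexpressed = frame.assign(
            molecule_id=[f"R{i}" for i in range(len(frame))],
            standard_value=[pic50_to_nM(p) for p in frame["_p"]],
            standard_units="nM", standard_relation="=", confidence_score=9,
            assay_type="B", assay_id="rexp",
        )[["molecule_id", "canonical_smiles", "standard_value", "standard_units",
           "standard_relation", "confidence_score", "assay_type", "assay_id"]]
        second = curate(reexpressed).compounds
        assert {(c.canonical_smiles, round(c.pic50, 9)) for c in first} == {
            (c.canonical_smiles, round(c.pic50, 9)) for c in second
        }

    def test_bad_row_does_not_abort_pipeline(self):
        rows = [rec(), rec(molecule_id="M2", smiles="((((")]
        result = curate(rows)
        assert len(result.compounds) == 1
        assert any(d["rule"] == "structure_or_unit" for d in result.report["dropped"])
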