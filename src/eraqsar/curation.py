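"""Bioactivity-table curation.

Reduces a raw ChEMBL-style activity table to one pIC50 per unique desalted
structure.  The pipeline is: rule-based record filtering (confidence score,
assay type, missing values), desalting to the largest fragment, conversion of
IC50 concentrations to pIC50 = -log10(IC50 in mol/L), and deduplication of
replicate measurements of the same canonical structure.  Records reported only
as bounds (relation '<' or '>') are diverted to qualification sets rather than
dropped, so they remain available for censored-label validation.

Replicate groups are reconciled on the log scale: a group collapses to its
median pIC50 when the group standard deviation is at most
``dedup_sd_threshold`` (default 1.0 pIC50 unit) and is removed wholesale as a
value disagreement otherwise.
"""
from __future__ import annotations

import json
import math
import statistics
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

VALID_RELATIONS = ("=", "<", ">")

#: power-of-ten factors to mol/L for the units handled in convert mode
_UNIT_FACTORS = {
    "nM": 1e-9,
    "pM": 1e-12,
    "uM": 1e-6,
    "µM": 1e-6,
    "mM": 1e-3,
    "M": 1.0,
}

ACTIVITY_COLUMNS = [
    "molecule_id",
    "canonical_smiles",
    "standard_value",
    "standard_units",
    "standard_relation",
    "confidence_score",
    "assay_type",
    "assay_id",
]


class CurationError(ValueError):
    """Raised for invalid structures, units or configuration."""


@dataclass(frozen=True)
class ActivityRecord:
    """One raw bioactivity measurement as exported from a ChEMBL-style table."""

    molecule_id: str
    smiles: str
    standard_value: float | None
    standard_units: str = "nM"
    standard_relation: str = "="
    confidence_score: int = 9
    assay_type: str = "B"
    assay_id: str = ""


@dataclass(frozen=True)
class CuratedCompound:
    """A desalted canonical structure with one consolidated pIC50."""

    canonical_smiles: str
    pic50: float
    n_source_records: int
    source_ids: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class CensoredRecord:
    """A bound-only measurement; ``relation`` applies to IC50 on the
    concentration scale ('>' means IC50 above the bound, i.e. pIC50 below
    ``bound_pic50``)."""

    canonical_smiles: str
    bound_pic50: float
    relation: str
    assay_id: str = ""


@dataclass
class CurationConfig:
    required_confidence: int = 9
    required_assay_type: str = "B"
    dedup_sd_threshold: float = 1.0
    unit_policy: str = "strict_nM"  # or "convert_known_units"
    predesalt_dedup: bool = False

    def __post_init__(self) -> None:
        if self.dedup_sd_threshold <= 0:
            raise CurationError("dedup_sd_threshold must be > 0")
        if self.unit_policy not in ("strict_nM", "convert_known_units"):
            raise CurationError(f"unknown unit_policy {self.unit_policy!r}")


@dataclass
class CurationResult:
    compounds: list[CuratedCompound]
    gt_set: list[CensoredRecord]
    lt_set: list[CensoredRecord]
    report: dict


def records_from_frame(frame: pd.DataFrame) -> list[ActivityRecord]:
    """Build ActivityRecords from a DataFrame in the ChEMBL export dialect.

    Extra columns are ignored; missing optional columns get defaults.
    """
    recs = []
    for _, row in frame.iterrows():
        value = row.get("standard_value")
        try:
            value = float(value)
        except (TypeError, ValueError):
            value = None
        if value is not None and math.isnan(value):
            value = None
        recs.append(
            ActivityRecord(
                molecule_id=str(row["molecule_id"]),
                smiles=str(row["canonical_smiles"]),
                standard_value=value,
                standard_units=str(row.get("standard_units", "nM")),
                standard_relation=str(row.get("standard_relation", "=")),
                confidence_score=int(row.get("confidence_score", 9)),
                assay_type=str(row.get("assay_type", "B")),
                assay_id=str(row.get("assay_id", "")),
            )
        )
    return recs


def read_activity_table(path: str | Path) -> list[ActivityRecord]:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return records_from_frame(pd.read_csv(path, sep=sep))


def filter_records(
    table: Sequence[ActivityRecord], cfg: CurationConfig
) -> tuple[list[ActivityRecord], list[ActivityRecord], list[tuple[ActivityRecord, str]]]:
    """Partition records into (kept, censored, dropped-with-reason).

    Rules fire in a fixed order so every dropped row carries the first rule
    that removed it: unknown relation, confidence score, assay type, missing
    value.  Rows with relation '<' or '>' that pass the confidence and assay
    filters are diverted to the censored list.
    """
    kept: list[ActivityRecord] = []
    censored: list[ActivityRecord] = []
    dropped: list[tuple[ActivityRecord, str]] = []
    for rec in table:
        if rec.standard_relation not in VALID_RELATIONS:
            dropped.append((rec, "unknown_relation"))
        elif rec.confidence_score != cfg.required_confidence:
            dropped.append((rec, "confidence"))
        elif rec.assay_type != cfg.required_assay_type:
            dropped.append((rec, "assay_type"))
        elif rec.standard_value is None:
            dropped.append((rec, "missing_value"))
        elif rec.standard_relation in ("<", ">"):
            censored.append(rec)
        else:
            kept.append(rec)
    return kept, censored, dropped


def desalt(smiles: str) -> str:
    """Return the canonical SMILES of the largest fragment.

    Largest = most heavy atoms; ties broken by molecular weight, then by the
    lexicographically smallest canonical SMILES.  Stereochemistry is
    preserved.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CurationError(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    scored = []
    for frag in frags:
        can = Chem.MolToSmiles(frag)
        scored.append((-frag.GetNumHeavyAtoms(), -Descriptors.MolWt(frag), can))
    scored.sort()
    if -scored[0][0] == 0:
        raise CurationError(f"no heavy atoms in any fragment of {smiles!r}")
    return scored[0][2]


def to_pic50(value: float, units: str = "nM", unit_policy: str = "strict_nM") -> float:
    """Convert an IC50 concentration to pIC50 = -log10(value in mol/L).

    In ``strict_nM`` mode only nanomolar input is accepted (pIC50 =
    9 - log10(value)); ``convert_known_units`` additionally handles pM, uM,
    mM and M by power-of-ten scaling.
    """
    if value is None or value <= 0:
        raise CurationError(f"IC50 must be positive, got {value!r}")
    if unit_policy == "strict_nM":
        if units != "nM":
            raise CurationError(f"units {units!r} not accepted under strict_nM")
    elif units not in _UNIT_FACTORS:
        raise CurationError(f"unrecognized units {units!r}")
    return -math.log10(value * _UNIT_FACTORS[units])


def pic50_to_nM(pic50: float) -> float:
    """Inverse conversion back to a nanomolar IC50."""
    return 10.0 ** (9.0 - pic50)


def deduplicate(
    records: Sequence[tuple[str, float, tuple[str, str]]],
    cfg: CurationConfig,
) -> tuple[list[CuratedCompound], list[tuple[str, str]]]:
    """Collapse replicate measurements of identical canonical SMILES.

    ``records`` are (canonical_smiles, pic50, (molecule_id, assay_id)).
    Singleton groups pass through.  A replicate group with pIC50 sample
    standard deviation <= ``dedup_sd_threshold`` collapses to its median;
    otherwise the whole group is removed and logged as a value disagreement.
    Output order follows first appearance of each structure.
    """
    for smi, pic50, _ in records:
        if not math.isfinite(pic50):
            raise CurationError(f"non-finite pIC50 for {smi!r}")
    groups: dict[str, list[tuple[float, tuple[str, str]]]] = {}
    for smi, pic50, prov in records:
        groups.setdefault(smi, []).append((pic50, prov))
    compounds: list[CuratedCompound] = []
    removed: list[tuple[str, str]] = []
    for smi, members in groups.items():
        values = [v for v, _ in members]
        provs = tuple(p for _, p in members)
        if len(values) == 1:
            compounds.append(CuratedCompound(smi, values[0], 1, provs))
            continue
        sd = statistics.stdev(values)
        if sd <= cfg.dedup_sd_threshold:
            compounds.append(
                CuratedCompound(smi, statistics.median(values), len(values), provs)
            )
        else:
            removed.append((smi, "value disagreement"))
    return compounds, removed


def curate(
    table: Sequence[ActivityRecord] | pd.DataFrame,
    cfg: CurationConfig | None = None,
) -> CurationResult:
    """Run the full curation pipeline on a raw activity table.

    Per-row structure or unit failures are recorded in the report and the row
    dropped; the pipeline never aborts on a single bad row.
    """
    if cfg is None:
        cfg = CurationConfig()
    if isinstance(table, pd.DataFrame):
        table = records_from_frame(table)
    kept, censored, dropped = filter_records(table, cfg)
    report: dict = {
        "stage_counts": {"input": len(table), "kept_after_filter": len(kept)},
        "dropped": [
            {"molecule_id": r.molecule_id, "assay_id": r.assay_id, "rule": reason}
            for r, reason in dropped
        ],
    }

    processed: list[tuple[str, float, tuple[str, str]]] = []
    for rec in kept:
        try:
            smi = desalt(rec.smiles)
            pic50 = to_pic50(rec.standard_value, rec.standard_units, cfg.unit_policy)
        except CurationError as exc:
            report["dropped"].append(
                {"molecule_id": rec.molecule_id, "assay_id": rec.assay_id,
                 "rule": "structure_or_unit", "detail": str(exc)}
            )
            continue
        processed.append((smi, pic50, (rec.molecule_id, rec.assay_id)))
    report["stage_counts"]["converted"] = len(processed)

    compounds, dedup_removed = deduplicate(processed, cfg)
    report["dedup_removed"] = [
        {"canonical_smiles": smi, "rule": reason} for smi, reason in dedup_removed
    ]
    report["stage_counts"]["curated"] = len(compounds)

    gt_set: list[CensoredRecord] = []
    lt_set: list[CensoredRecord] = []
    for rec in censored:
        try:
            smi = desalt(rec.smiles)
            bound = to_pic50(rec.standard_value, rec.standard_units, cfg.unit_policy)
        except CurationError as exc:
            report["dropped"].append(
                {"molecule_id": rec.molecule_id, "assay_id": rec.assay_id,
                 "rule": "structure_or_unit", "detail": str(exc)}
            )
            continue
        target = gt_set if rec.standard_relation == ">" else lt_set
        target.append(CensoredRecord(smi, bound, rec.standard_relation, rec.assay_id))
    report["stage_counts"]["censored_gt"] = len(gt_set)
    report["stage_counts"]["censored_lt"] = len(lt_set)
    return CurationResult(compounds, gt_set, lt_set, report)


# ---------------------------------------------------------------------------
# writers

def curated_to_frame(compounds: Iterable[CuratedCompound]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "canonical_smiles": c.canonical_smiles,
                "pic50": c.pic50,
                "n_source_records": c.n_source_records,
            }
            for c in compounds
        ],
        columns=["canonical_smiles", "pic50", "n_source_records"],
    )


def write_curated_csv(compounds: Iterable[CuratedCompound], path: str | Path) -> None:
    curated_to_frame(compounds).to_csv(path, index=False)


def write_curated_sdf(compounds: Iterable[CuratedCompound], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for c in compounds:
            mol = Chem.MolFromSmiles(c.canonical_smiles)
            mol.SetProp("pIC50", repr(c.pic50))
            writer.write(mol)
    finally:
        writer.close()


def write_censored_csv(records: Iterable[CensoredRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "canonical_smiles": r.canonical_smiles,
                "bound_pic50": r.bound_pic50,
                "relation": r.relation,
                "assay_id": r.assay_id,
            }
            for r in records
        ],
        columns=["canonical_smiles", "bound_pic50", "relation", "assay_id"],
    ).to_csv(path, index=False)


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
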