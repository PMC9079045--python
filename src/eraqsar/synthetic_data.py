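"""Synthetic bioactivity tables and planted-signal fingerprint datasets.

Two generators make every downstream stage testable without any database
download:

* :func:`generate_activity_table` emits a raw ChEMBL-style activity table with
  controlled corruption — censored (< / >) records, salt-bearing SMILES,
  replicate measurements with multiplicative concentration noise, missing
  values, off-target confidence scores and non-binding assay codes — together
  with a ground-truth ledger stating, per row, which curation rule should
  remove or divert it and the exact compound set expected to survive curation.

* :func:`generate_planted_dataset` draws a fingerprint matrix (Poisson counts
  or Bernoulli bits) with a known linear activity signal on a chosen subset of
  features plus Gaussian noise, so model-recovery and validation behaviour can
  be checked against a known truth.

Both are deterministic for a fixed seed.
"""
from __future__ import annotations

import importlib.resources
import json
import math
import statistics
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import ACTIVITY_COLUMNS, desalt
from .featurization import FingerprintMatrix


class SyntheticDataError(ValueError):
    pass


#: counter-ion fragments appended to SMILES when injecting salts; each has a
#: single heavy atom so the largest-fragment desalting rule is unambiguous
COUNTER_IONS = ("Cl", "[Na+]", "Br")

# activity distribution of the simulated assay panel, pIC50 units
_PIC50_MEAN, _PIC50_SD, _PIC50_LO, _PIC50_HI = 6.5, 1.2, 4.0, 9.0


def default_smiles_pool() -> list[str]:
    """The bundled pool of 50 pre-verified drug-like SMILES."""
    text = (importlib.resources.files("eraqsar.data") / "smiles_pool.smi").read_text()
    pool = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            pool.append(line.split()[0])
    return pool


def extended_smiles_pool(n: int) -> list[str]:
    """The bundled pool extended with unique para-substituted benzamides.

    The generator needs one distinct base structure per simulated compound;
    beyond the 50 bundled structures it appends programmatic variants
    O=C(N-alkyl)c1ccc(O-alkyl)cc1 with varying chain lengths, all valid and
    canonically distinct.
    """
    pool = default_smiles_pool()
    a = b = 1
    while len(pool) < n:
        pool.append(f"O=C(N{'C' * a})c1ccc(O{'C' * b})cc1")
        a += 1
        if a > 25:
            a, b = 1, b + 1
            if b > 25:
                raise SyntheticDataError("extended pool exhausted")
    return pool[:n]


@dataclass
class TableCorruptionSpec:
    """Controls which corruption categories a synthetic table realizes."""

    n_compounds: int
    frac_censored_gt: float = 0.0
    frac_censored_lt: float = 0.0
    frac_salts: float = 0.0
    frac_missing_value: float = 0.0
    dup_rate: float = 0.0
    dup_replicates: int = 2
    dup_noise_sd: float = 0.0
    frac_low_confidence: float = 0.0
    frac_nonbinding_assay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds <= 0:
            raise SyntheticDataError("n_compounds must be positive")
        fracs = {
            "frac_censored_gt": self.frac_censored_gt,
            "frac_censored_lt": self.frac_censored_lt,
            "frac_salts": self.frac_salts,
            "frac_missing_value": self.frac_missing_value,
            "dup_rate": self.dup_rate,
            "frac_low_confidence": self.frac_low_confidence,
            "frac_nonbinding_assay": self.frac_nonbinding_assay,
        }
        for name, f in fracs.items():
            if not 0.0 <= f <= 1.0:
                raise SyntheticDataError(f"{name} must be in [0, 1], got {f}")
        if self.frac_censored_gt + self.frac_censored_lt + self.frac_missing_value > 1:
            raise SyntheticDataError(
                "censored + missing fractions exceed 1: no rows left for exact values"
            )
        if self.dup_replicates < 2:
            raise SyntheticDataError("dup_replicates must be >= 2")
        if self.dup_noise_sd < 0:
            raise SyntheticDataError("dup_noise_sd must be >= 0")


def generate_activity_table(
    spec: TableCorruptionSpec,
    smiles_pool: Sequence[str] | None = None,
    dedup_sd_threshold: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Generate a raw activity table plus its ground-truth curation ledger.

    The ledger's expected surviving compound set is computed from the
    generator's own category assignments (filter order: confidence, assay
    type, missing value, censored diversion; then desalting, pIC50 conversion
    and the SD/median replicate rule at ``dedup_sd_threshold``), so running
    the curation pipeline on the emitted table must reproduce it exactly.
    """
    if smiles_pool is None:
        smiles_pool = (
            default_smiles_pool()
            if spec.n_compounds <= 50
            else extended_smiles_pool(spec.n_compounds)
        )
    canon = []
    for smi in smiles_pool:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise SyntheticDataError(f"unparseable SMILES in pool: {smi!r}")
        canon.append(Chem.MolToSmiles(mol))
    if len(set(canon)) != len(canon):
        raise SyntheticDataError("smiles_pool contains duplicate structures")
    n = spec.n_compounds
    if n > len(canon):
        raise SyntheticDataError(
            f"need {n} unique base structures but pool has {len(canon)}"
        )

    rng = np.random.default_rng(spec.seed)
    base_smiles = list(canon[:n])
    true_pic50 = np.clip(
        rng.normal(_PIC50_MEAN, _PIC50_SD, size=n), _PIC50_LO, _PIC50_HI
    )

    n_gt = round(spec.frac_censored_gt * n)
    n_lt = round(spec.frac_censored_lt * n)
    n_missing = round(spec.frac_missing_value * n)
    if n_gt + n_lt + n_missing > n:
        raise SyntheticDataError("rounded corruption counts exceed n_compounds")
    order = rng.permutation(n)
    gt_idx = set(order[:n_gt].tolist())
    lt_idx = set(order[n_gt : n_gt + n_lt].tolist())
    missing_idx = set(order[n_gt + n_lt : n_gt + n_lt + n_missing].tolist())

    lowconf_idx = set(
        rng.choice(n, size=round(spec.frac_low_confidence * n), replace=False).tolist()
    )
    nonbind_idx = set(
        rng.choice(n, size=round(spec.frac_nonbinding_assay * n), replace=False).tolist()
    )
    salt_idx = set(
        rng.choice(n, size=round(spec.frac_salts * n), replace=False).tolist()
    )
    # duplicates are injected on exact-value rows so replicate groups reach the
    # deduplication stage instead of being filtered out earlier
    dup_eligible = [
        i for i in range(n)
        if i not in gt_idx | lt_idx | missing_idx | lowconf_idx | nonbind_idx
    ]
    n_dup = min(round(spec.dup_rate * n), len(dup_eligible))
    dup_idx = set(
        rng.choice(dup_eligible, size=n_dup, replace=False).tolist()
    ) if n_dup else set()

    rows: list[dict] = []
    ledger_rows: list[dict] = []
    expected_compounds: list[dict] = []
    expected_gt: list[dict] = []
    expected_lt: list[dict] = []

    for i in range(n):
        mol_id = f"SYN{i:05d}"
        confidence = 7 if i in lowconf_idx else 9
        assay_type = "F" if i in nonbind_idx else "B"
        relation = ">" if i in gt_idx else "<" if i in lt_idx else "="
        smiles = base_smiles[i]
        if i in salt_idx:
            smiles = smiles + "." + str(rng.choice(COUNTER_IONS))
        n_rows = spec.dup_replicates if i in dup_idx else 1
        group_pic50s: list[float] = []
        for k in range(n_rows):
            if i in missing_idx:
                value = None
            else:
                eps = rng.normal(0.0, spec.dup_noise_sd) if n_rows > 1 else 0.0
                pic50_k = true_pic50[i] + eps
                value = 10.0 ** (9.0 - pic50_k)
            rows.append(
                {
                    "molecule_id": mol_id,
                    "canonical_smiles": smiles,
                    "standard_value": value,
                    "standard_units": "nM",
                    "standard_relation": relation,
                    "confidence_score": confidence,
                    "assay_type": assay_type,
                    "assay_id": f"A{i:05d}_{k}",
                }
            )
            if value is not None:
                # recompute from the stored value so ledger expectations match
                # what the curation pipeline will see after CSV round-trips
                group_pic50s.append(9.0 - math.log10(value))

        if confidence != 9:
            rule = "confidence"
        elif assay_type != "B":
            rule = "assay_type"
        elif i in missing_idx:
            rule = "missing_value"
        elif i in gt_idx:
            rule = "divert_censored_gt"
        elif i in lt_idx:
            rule = "divert_censored_lt"
        elif n_rows > 1 and statistics.stdev(group_pic50s) > dedup_sd_threshold:
            rule = "value_disagreement"
        else:
            rule = None
        ledger_rows.append(
            {"molecule_id": mol_id, "n_rows": n_rows, "rule": rule}
        )
        if rule is None:
            expected_compounds.append(
                {
                    "canonical_smiles": base_smiles[i],
                    "pic50": statistics.median(group_pic50s),
                    "n_source_records": n_rows,
                }
            )
        elif rule == "divert_censored_gt":
            expected_gt.append(
                {"canonical_smiles": base_smiles[i],
                 "bound_pic50": group_pic50s[0], "relation": ">"}
            )
        elif rule == "divert_censored_lt":
            expected_lt.append(
                {"canonical_smiles": base_smiles[i],
                 "bound_pic50": group_pic50s[0], "relation": "<"}
            )

    table = pd.DataFrame(rows, columns=ACTIVITY_COLUMNS)
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    ledger = {
        "spec": asdict(spec),
        "curation_config": {"dedup_sd_threshold": dedup_sd_threshold},
        "rows": ledger_rows,
        "expected_compounds": expected_compounds,
        "expected_censored_gt": expected_gt,
        "expected_censored_lt": expected_lt,
        "counts": {
            "n_rows": len(table),
            "n_compounds": n,
            "censored_gt": n_gt,
            "censored_lt": n_lt,
            "missing_value": n_missing,
            "duplicated_compounds": len(dup_idx),
            "salted_compounds": len(salt_idx),
            "expected_curated": len(expected_compounds),
        },
    }
    return table, ledger


def write_activity_table(table: pd.DataFrame, ledger: dict, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / "activity_table.csv", index=False)
    (out_dir / "ledger.json").write_text(json.dumps(ledger, indent=2))


# ---------------------------------------------------------------------------
# planted-signal fingerprint datasets

@dataclass
class PlantedSignalSpec:
    """A fingerprint matrix with a known linear activity signal.

    Features are iid Poisson(``count_rate``) counts or Bernoulli(0.5) bits;
    activity = baseline + sum_j effect_sizes[j] * x_informative[j] +
    N(0, noise_sd).
    """

    n_compounds: int
    n_features: int
    n_informative: int
    effect_sizes: Sequence[float]
    noise_sd: float = 0.3
    feature_kind: str = "count"
    count_rate: float = 2.0
    baseline: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds <= 0 or self.n_features <= 0:
            raise SyntheticDataError("n_compounds and n_features must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise SyntheticDataError("need 0 <= n_informative <= n_features")
        if len(self.effect_sizes) != self.n_informative:
            raise SyntheticDataError(
                f"effect_sizes has length {len(self.effect_sizes)}, "
                f"expected n_informative = {self.n_informative}"
            )
        if self.noise_sd < 0:
            raise SyntheticDataError("noise_sd must be >= 0")
        if self.feature_kind not in ("count", "binary"):
            raise SyntheticDataError(f"unknown feature_kind {self.feature_kind!r}")
        if self.count_rate <= 0:
            raise SyntheticDataError("count_rate must be positive")


@dataclass
class PlantedTruth:
    """Ground truth of a planted dataset: which features carry signal."""

    informative_features: list[str]
    effect_sizes: list[float]
    baseline: float
    noise_sd: float
    feature_kind: str
    count_rate: float
    y_true: np.ndarray  # noiseless activity per compound


def _draw_features(rng: np.random.Generator, spec: PlantedSignalSpec) -> np.ndarray:
    if spec.feature_kind == "count":
        return rng.poisson(spec.count_rate, size=(spec.n_compounds, spec.n_features))
    return rng.integers(0, 2, size=(spec.n_compounds, spec.n_features))


def generate_planted_dataset(
    spec: PlantedSignalSpec,
) -> tuple[FingerprintMatrix, np.ndarray, PlantedTruth]:
    """Draw (fingerprint matrix, activity vector, truth record)."""
    rng = np.random.default_rng(spec.seed)
    X = _draw_features(rng, spec)
    feature_names = [f"FP{j:04d}" for j in range(spec.n_features)]
    informative = list(range(spec.n_informative))
    effects = np.asarray(spec.effect_sizes, dtype=float)
    y_true = spec.baseline + X[:, informative] @ effects if informative else np.full(
        spec.n_compounds, float(spec.baseline)
    )
    y = y_true + rng.normal(0.0, spec.noise_sd, size=spec.n_compounds)
    matrix = FingerprintMatrix(
        [f"CPD{i:05d}" for i in range(spec.n_compounds)],
        feature_names,
        X,
        kind="count" if spec.feature_kind == "count" else "presence",
        pattern_provenance="synthetic",
    )
    truth = PlantedTruth(
        informative_features=[feature_names[j] for j in informative],
        effect_sizes=list(effects),
        baseline=spec.baseline,
        noise_sd=spec.noise_sd,
        feature_kind=spec.feature_kind,
        count_rate=spec.count_rate,
        y_true=y_true.astype(float),
    )
    return matrix, y.astype(float), truth


def generate_censored_external(
    spec: PlantedSignalSpec,
    truth: PlantedTruth,
    n_per_sign: int,
    offset: float = 1.0,
    seed: int = 0,
) -> tuple[FingerprintMatrix, pd.DataFrame]:
    """Fresh compounds from the planted distribution with bound-only labels.

    Bounds are placed ``offset`` pIC50 units past the noiseless activity on
    the censored side: a '>' record (IC50 above the bound) gets
    bound = activity + offset so its true pIC50 lies below the bound, and a
    '<' record gets bound = activity - offset.
    """
    rng = np.random.default_rng(seed)
    draw_spec = PlantedSignalSpec(
        n_compounds=2 * n_per_sign,
        n_features=spec.n_features,
        n_informative=spec.n_informative,
        effect_sizes=spec.effect_sizes,
        noise_sd=spec.noise_sd,
        feature_kind=spec.feature_kind,
        count_rate=spec.count_rate,
        baseline=spec.baseline,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    matrix, _, ext_truth = generate_planted_dataset(draw_spec)
    relations = np.array([">"] * n_per_sign + ["<"] * n_per_sign)
    bounds = ext_truth.y_true + np.where(relations == ">", offset, -offset)
    labels = pd.DataFrame(
        {
            "compound_id": matrix.compound_ids,
            "relation": relations,
            "bound_pic50": bounds,
            "true_pic50": ext_truth.y_true,
        }
    )
    return matrix, labels
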