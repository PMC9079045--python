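"""Substructure fingerprints and drug-likeness profiling.

A fingerprint here is a named vector per compound: either the number of unique
atom-set matches of each SMARTS pattern (count kind) or its binarized presence
(presence kind).  Unique atom-set counting means symmetry-equivalent atom
mappings of the same atoms contribute one match, so symmetric groups are not
double counted.

A small bundled pattern set covers the functional-group classes that dominate
feature rankings for estrogen-receptor inhibition (phenols, amines, aromatic
systems, carboxylic-acid derivatives, ethers, tautomerizable motifs); larger
external pattern files load through the same two-column text format.  Graph
descriptors with no SMARTS expression (specified chiral centers, rotatable
bonds) are registered under ``@builtin:`` names.  Fingerprint families computed
by external software import through :func:`import_external_matrix`.
"""
from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit.Chem.MolStandardize import rdMolStandardize

from .curation import CuratedCompound


class FeaturizationError(ValueError):
    pass


_BUILTIN_DESCRIPTORS: dict[str, Callable[[Chem.Mol], int]] = {
    "chiral_centers": lambda mol: len(
        Chem.FindMolChiralCenters(mol, includeUnassigned=False, useLegacyImplementation=False)
    ),
    "rotatable_bonds": lambda mol: int(Lipinski.NumRotatableBonds(mol)),
}


@dataclass(frozen=True)
class PatternEntry:
    name: str
    smarts: str  # raw SMARTS, or "@builtin:<key>"

    @property
    def is_builtin(self) -> bool:
        return self.smarts.startswith("@builtin:")


@dataclass
class PatternSet:
    entries: list[PatternEntry]
    source_name: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def compiled(self) -> list[tuple[PatternEntry, object]]:
        """Pair each entry with its compiled query or builtin callable."""
        out = []
        for entry in self.entries:
            if entry.is_builtin:
                out.append((entry, _BUILTIN_DESCRIPTORS[entry.smarts.split(":", 1)[1]]))
            else:
                out.append((entry, Chem.MolFromSmarts(entry.smarts)))
        return out


@dataclass
class FingerprintMatrix:
    """Compounds x named features, with provenance of the pattern source."""

    compound_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    kind: str  # "count" or "presence"
    pattern_provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.compound_ids), len(self.feature_names)):
            raise FeaturizationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.compound_ids)} compounds x {len(self.feature_names)} features"
            )
        if self.kind not in ("count", "presence"):
            raise FeaturizationError(f"unknown kind {self.kind!r}")
        if (self.values < 0).any():
            raise FeaturizationError("fingerprint values must be non-negative")
        if self.kind == "presence" and not np.isin(self.values, (0, 1)).all():
            raise FeaturizationError("presence values must be 0/1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.compound_ids, name="compound_id"),
            columns=self.feature_names,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def load_pattern_set(path: str | Path) -> PatternSet:
    """Load a two-column (name, SMARTS) pattern file; '#' starts a comment.

    Every SMARTS must compile and names must be unique; failures are reported
    with their line number.
    """
    path = Path(path)
    entries: list[PatternEntry] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        # '#' opens a comment only at line start or after whitespace; SMARTS
        # itself never contains whitespace but does contain '#' (atomic number)
        line = raw.strip()
        if line.startswith("#"):
            line = ""
        else:
            line = re.split(r"\s#", line, maxsplit=1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FeaturizationError(f"{path}:{lineno}: expected 'name SMARTS', got {raw!r}")
        name, smarts = parts
        if name in seen:
            raise FeaturizationError(f"{path}:{lineno}: duplicate feature name {name!r}")
        seen.add(name)
        if smarts.startswith("@builtin:"):
            key = smarts.split(":", 1)[1]
            if key not in _BUILTIN_DESCRIPTORS:
                raise FeaturizationError(f"{path}:{lineno}: unknown builtin {key!r}")
        elif Chem.MolFromSmarts(smarts) is None:
            raise FeaturizationError(f"{path}:{lineno}: SMARTS does not compile: {smarts!r}")
        entries.append(PatternEntry(name, smarts))
    return PatternSet(entries, source_name=path.name)


def default_pattern_set() -> PatternSet:
    """The bundled ~45-pattern functional-group set."""
    with importlib.resources.as_file(
        importlib.resources.files("eraqsar.data") / "patterns.smarts"
    ) as p:
        return load_pattern_set(p)


def standardize_molecule(
    smiles: str, add_polar_h: bool = False, canonical_tautomer: bool = False
) -> Chem.Mol:
    """Parse and normalize a structure.

    ``add_polar_h`` makes hydrogens on N/O/S explicit in the graph;
    ``canonical_tautomer`` maps tautomer pairs onto one canonical form.
    Disabled options are no-ops.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}")
    if canonical_tautomer:
        mol = rdMolStandardize.TautomerEnumerator().Canonicalize(mol)
    if add_polar_h:
        polar = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O", "S")]
        if polar:
            mol = Chem.AddHs(mol, onlyOnAtoms=polar)
    return mol


def substructure_count(mol: Chem.Mol, patterns: PatternSet) -> np.ndarray:
    """Count unique atom-set matches of every pattern in the molecule."""
    counts = np.zeros(len(patterns), dtype=np.int64)
    for j, (entry, query) in enumerate(patterns.compiled()):
        if entry.is_builtin:
            counts[j] = query(mol)
        else:
            counts[j] = len(mol.GetSubstructMatches(query, uniquify=True))
    return counts


def substructure_presence(counts: np.ndarray) -> np.ndarray:
    """Binarize a count vector: bit j = 1 iff count j > 0."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise FeaturizationError("counts must be non-negative")
    return (counts > 0).astype(np.int64)


def featurize_dataset(
    compounds: Sequence[CuratedCompound | str],
    patterns: PatternSet | None = None,
    kind: str = "count",
    add_polar_h: bool = True,
    canonical_tautomer: bool = False,
) -> tuple[FingerprintMatrix, list[tuple[str, str]]]:
    """Fingerprint a curated set; returns (matrix, per-compound failures).

    Row order follows input; compounds whose structures fail to parse are
    excluded from the matrix and reported in the failure list.
    """
    if patterns is None:
        patterns = default_pattern_set()
    if len(patterns) == 0:
        raise FeaturizationError("empty pattern set")
    ids: list[str] = []
    rows: list[np.ndarray] = []
    failures: list[tuple[str, str]] = []
    for comp in compounds:
        smi = comp if isinstance(comp, str) else comp.canonical_smiles
        try:
            mol = standardize_molecule(
                smi, add_polar_h=add_polar_h, canonical_tautomer=canonical_tautomer
            )
            rows.append(substructure_count(mol, patterns))
        except FeaturizationError as exc:
            failures.append((smi, str(exc)))
            continue
        ids.append(smi)
    values = np.vstack(rows) if rows else np.zeros((0, len(patterns)), dtype=np.int64)
    if kind == "presence":
        values = (values > 0).astype(np.int64)
    elif kind != "count":
        raise FeaturizationError(f"unknown fingerprint kind {kind!r}")
    return (
        FingerprintMatrix(ids, patterns.names, values, kind, patterns.source_name),
        failures,
    )


@dataclass(frozen=True)
class Ro5Profile:
    """Lipinski rule-of-five profile.

    ``violations`` counts failed rules among mw < 500, logp < 5, hba < 10 and
    hbd <= 5 (the donor rule is applied in its canonical <=5 form).
    """

    mw: float
    logp: float
    hbd: int
    hba: int

    @property
    def violations(self) -> int:
        return sum(
            [self.mw >= 500, self.logp >= 5, self.hba >= 10, self.hbd > 5]
        )


def ro5_profile(mol_or_smiles: Chem.Mol | str) -> Ro5Profile:
    """Compute the Ro5 profile: exact MW, Crippen logP, Lipinski H-bond
    donor (N-H/O-H) and acceptor (N+O) counts."""
    if isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise FeaturizationError(f"unparseable SMILES: {mol_or_smiles!r}")
    else:
        mol = mol_or_smiles
    return Ro5Profile(
        mw=Descriptors.ExactMolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=int(Lipinski.NumHDonors(mol)),
        hba=int(Lipinski.NOCount(mol)),
    )


def ro5_frame(smiles: Iterable[str]) -> pd.DataFrame:
    """Ro5 profiles for a set of structures, as a DataFrame."""
    rows = []
    for smi in smiles:
        p = ro5_profile(smi)
        rows.append(
            {"canonical_smiles": smi, "mw": p.mw, "logp": p.logp,
             "hbd": p.hbd, "hba": p.hba, "violations": p.violations}
        )
    return pd.DataFrame(rows)


def import_external_matrix(path: str | Path, kind: str = "count") -> FingerprintMatrix:
    """Import a fingerprint matrix computed by external software.

    Expects a CSV with a leading id column and numeric feature columns;
    non-numeric cells and duplicate ids are rejected with their location.
    """
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].tolist()
        raise FeaturizationError(f"{path}: duplicate compound ids {dupes}")
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.isna().any():
            row = frame.index[numeric.isna()][0]
            raise FeaturizationError(
                f"{path}: non-numeric or missing cell at row {row!r}, column {col!r}"
            )
        frame[col] = numeric
    return FingerprintMatrix(
        [str(i) for i in frame.index],
        [str(c) for c in frame.columns],
        frame.to_numpy(),
        kind,
        pattern_provenance="external",
    )
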