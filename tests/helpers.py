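"""Independent oracles used by the test suite.

These deliberately take a different route from the library implementation so
that agreement is evidence, not tautology.
"""
from __future__ import annotations

import itertools

import numpy as np
from rdkit import Chem


def brute_force_substructure_count(mol: Chem.Mol, smarts: str) -> int:
    """Count unique atom-set matches by enumerating raw atom mappings.

    Asks RDKit for every symmetry-duplicate mapping (uniquify=False) and
    collapses them to distinct atom sets by hand — the opposite route from the
    implementation, which relies on uniquify=True.
    """
    query = Chem.MolFromSmarts(smarts)
    mappings = mol.GetSubstructMatches(query, uniquify=False, maxMatches=100000)
    return len({frozenset(m) for m in mappings})


def max_abs_offdiag_corr(X: np.ndarray) -> float:
    """Largest |Pearson r| over all column pairs, computed pair by pair."""
    n_cols = X.shape[1]
    best = 0.0
    for i, j in itertools.combinations(range(n_cols), 2):
        r = np.corrcoef(X[:, i], X[:, j])[0, 1]
        best = max(best, abs(r))
    return best


def ols_coefficients(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form least squares with intercept; returns slopes only."""
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta[1:]
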