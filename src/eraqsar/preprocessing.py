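"""Descriptor preprocessing: variance/correlation filtering, autoscaling and
repeated 70/30 data splits.

The correlation filter is a deterministic greedy pass: while any retained pair
of descriptors has |Pearson r| above the active threshold, the member of the
worst-offending pair with the larger mean absolute correlation to the other
retained descriptors is removed (ties remove the later column).  Mirroring the
two thresholds commonly quoted for descriptor pruning, a second stage at a
lower threshold (default 0.7) runs after the first (default 0.95) and can be
disabled.

Scaling is mean centering and unit variance (sample SD, n-1).  The scaler is
fitted on internal (training) rows only and applied unchanged to external
rows, so no information leaks into external validation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PreprocessingError(ValueError):
    pass


@dataclass
class ScalerModel:
    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray


@dataclass
class FilterRemoval:
    feature: str
    reason: str
    partner: str | None
    stage: int


@dataclass
class FilterResult:
    retained: list[str]
    removed: list[FilterRemoval]
    pair_threshold: float
    secondary_threshold: float | None


@dataclass
class SplitSpec:
    seed: int
    ratio_internal: float
    internal_ids: list[str]
    external_ids: list[str]


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    return matrix.to_frame()  # FingerprintMatrix


def drop_zero_variance(matrix) -> tuple[pd.DataFrame, list[str]]:
    """Remove constant columns (zero SD); errors if nothing remains."""
    frame = _as_frame(matrix)
    constant = [c for c in frame.columns if frame[c].nunique(dropna=False) <= 1]
    if len(constant) == len(frame.columns):
        raise PreprocessingError("all columns are constant; nothing to model")
    return frame.drop(columns=constant), constant


def _filter_stage(
    frame: pd.DataFrame, threshold: float, stage: int, removed: list[FilterRemoval]
) -> pd.DataFrame:
    cols = list(frame.columns)
    corr = np.corrcoef(frame.to_numpy(dtype=float), rowvar=False)
    corr = np.atleast_2d(corr)
    alive = list(range(len(cols)))
    while len(alive) > 1:
        sub = np.abs(corr[np.ix_(alive, alive)])
        np.fill_diagonal(sub, 0.0)
        i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i_loc, j_loc] <= threshold:
            break
        # offending pair in current column order
        a, b = sorted((alive[i_loc], alive[j_loc]))
        mean_abs = sub.mean(axis=1) * len(alive) / max(len(alive) - 1, 1)
        mean_a = mean_abs[alive.index(a)]
        mean_b = mean_abs[alive.index(b)]
        drop, keep = (a, b) if mean_a > mean_b else (b, a)
        removed.append(
            FilterRemoval(cols[drop], f"|r|>{threshold}", cols[keep], stage)
        )
        alive.remove(drop)
    return frame[[cols[k] for k in alive]]


def correlation_filter(
    matrix,
    pair_threshold: float = 0.95,
    secondary_threshold: float | None = 0.7,
) -> FilterResult:
    """Two-stage greedy pairwise Pearson-correlation filter.

    Stage 1 prunes at ``pair_threshold``; stage 2 (skipped when
    ``secondary_threshold`` is None) reruns at the lower threshold.  After
    filtering, every retained pair satisfies |r| <= the active threshold.
    """
    for t in (pair_threshold, secondary_threshold):
        if t is not None and not 0.0 < t <= 1.0:
            raise PreprocessingError(f"threshold must be in (0, 1], got {t}")
    frame = _as_frame(matrix)
    removed: list[FilterRemoval] = []
    out = _filter_stage(frame, pair_threshold, stage=1, removed=removed)
    if secondary_threshold is not None and len(out.columns) > 1:
        out = _filter_stage(out, secondary_threshold, stage=2, removed=removed)
    return FilterResult(
        retained=list(out.columns),
        removed=removed,
        pair_threshold=pair_threshold,
        secondary_threshold=secondary_threshold,
    )


def fit_scaler(matrix) -> ScalerModel:
    """Fit per-column mean / sample-SD; zero-variance columns are rejected."""
    frame = _as_frame(matrix)
    means = frame.mean(axis=0).to_numpy(dtype=float)
    sds = frame.std(axis=0, ddof=1).to_numpy(dtype=float)
    if (sds <= 0).any() or np.isnan(sds).any():
        bad = [c for c, s in zip(frame.columns, sds) if not s > 0]
        raise PreprocessingError(
            f"zero-variance columns must be removed before scaling: {bad}"
        )
    return ScalerModel(list(frame.columns), means, sds)


def apply_scaler(model: ScalerModel, matrix) -> pd.DataFrame:
    """Standardize with the fitted means/SDs; unknown features are an error."""
    frame = _as_frame(matrix)
    missing = set(model.feature_names) - set(frame.columns)
    extra = set(frame.columns) - set(model.feature_names)
    if missing or extra:
        raise PreprocessingError(
            f"feature mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
        )
    frame = frame[model.feature_names]
    return (frame - model.means) / model.sds


def inverse_scaler(model: ScalerModel, scaled: pd.DataFrame) -> pd.DataFrame:
    return scaled[model.feature_names] * model.sds + model.means


def make_splits(
    ids,
    n_splits: int = 10,
    ratio: float = 0.70,
    base_seed: int = 0,
) -> list[SplitSpec]:
    """Independent uniform 70/30 partitions, one per split.

    Split k uses seed ``base_seed + k``; |internal| = round(ratio * n).
    """
    ids = [str(i) for i in ids]
    if not 0.0 < ratio < 1.0:
        raise PreprocessingError(f"ratio must be in (0, 1), got {ratio}")
    if len(ids) < 10:
        raise PreprocessingError("need at least 10 ids to split")
    if len(set(ids)) != len(ids):
        raise PreprocessingError("ids must be unique")
    n_internal = round(ratio * len(ids))
    splits = []
    for k in range(n_splits):
        seed = base_seed + k
        perm = np.random.default_rng(seed).permutation(len(ids))
        internal = [ids[i] for i in sorted(perm[:n_internal])]
        external = [ids[i] for i in sorted(perm[n_internal:])]
        splits.append(SplitSpec(seed, ratio, internal, external))
    return splits
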