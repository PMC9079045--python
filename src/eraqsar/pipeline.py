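"""End-to-end workflow orchestration.

``run`` executes curate -> featurize -> preprocess/split -> train -> validate
from a single :class:`RunConfig`, writing every stage's outputs plus a
manifest (stage, output hashes, seed, row/column counts) to the output
directory.  All randomness derives from ``master_seed`` through a named seed
sequence, so a repeated run with the same config is byte-identical.

Hyperparameters are tuned once, on the internal set of the first split, and
reused for the remaining splits and for Y-scrambling; performance is reported
per split and as mean +/- SD across splits.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from . import curation, featurization, modeling, preprocessing, validation
from .curation import CurationConfig
from .modeling import RFConfig


class PipelineError(RuntimeError):
    pass


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic named sub-seed (< 2^31) from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    activity_table: str
    output_dir: str
    pattern_file: str | None = None
    master_seed: int = 0
    curation: dict = field(default_factory=dict)
    fingerprint_kind: str = "count"
    add_polar_h: bool = True
    canonical_tautomer: bool = False
    pair_threshold: float = 0.95
    secondary_threshold: float | None = 0.7
    ratio_internal: float = 0.70
    n_splits: int = 10
    tuning_grid: dict | None = None
    rf: dict = field(default_factory=dict)
    cv_folds: int = 10
    top_k: int = 20
    n_scrambles: int = 100
    ad_components: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def curation_config(self) -> CurationConfig:
        return CurationConfig(**self.curation)

    def rf_config(self, seed: int) -> RFConfig:
        return RFConfig(seed=seed, **self.rf)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.path = out_dir / "manifest.json"
        self.stages: list[dict] = []
        if self.path.exists():
            self.stages = json.loads(self.path.read_text())

    def record(self, stage: str, outputs: list[Path], seed: int | None, counts: dict):
        self.stages = [s for s in self.stages if s["stage"] != stage]
        self.stages.append(
            {
                "stage": stage,
                "outputs": {p.name: _sha256(p) for p in outputs},
                "seed": seed,
                "counts": counts,
            }
        )
        self.path.write_text(json.dumps(self.stages, indent=2))


def _load_patterns(config: RunConfig) -> featurization.PatternSet:
    if config.pattern_file:
        path = Path(config.pattern_file)
        if not path.exists():
            raise PipelineError(f"pattern file not found: {path}")
        return featurization.load_pattern_set(path)
    return featurization.default_pattern_set()


def stage_curate(config: RunConfig, out: Path, manifest: _Manifest) -> None:
    table = curation.read_activity_table(config.activity_table)
    result = curation.curate(table, config.curation_config())
    curation.write_curated_csv(result.compounds, out / "curated.csv")
    curation.write_curated_sdf(result.compounds, out / "curated.sdf")
    curation.write_censored_csv(result.gt_set, out / "censored_gt.csv")
    curation.write_censored_csv(result.lt_set, out / "censored_lt.csv")
    curation.write_report_json(result.report, out / "curation_report.json")
    manifest.record(
        "curate",
        [out / f for f in ("curated.csv", "censored_gt.csv",
                           "censored_lt.csv", "curation_report.json")],
        None,
        result.report["stage_counts"],
    )


def stage_featurize(config: RunConfig, out: Path, manifest: _Manifest) -> None:
    curated = pd.read_csv(out / "curated.csv")
    patterns = _load_patterns(config)
    matrix, failures = featurization.featurize_dataset(
        list(curated["canonical_smiles"]), patterns, kind=config.fingerprint_kind,
        add_polar_h=config.add_polar_h, canonical_tautomer=config.canonical_tautomer,
    )
    matrix.to_csv(out / "fingerprints.csv")
    featurization.ro5_frame(curated["canonical_smiles"]).to_csv(
        out / "ro5_profiles.csv", index=False
    )
    for name in ("censored_gt", "censored_lt"):
        cens = pd.read_csv(out / f"{name}.csv")
        if len(cens):
            cmat, _ = featurization.featurize_dataset(
                list(cens["canonical_smiles"]), patterns,
                kind=config.fingerprint_kind, add_polar_h=config.add_polar_h,
                canonical_tautomer=config.canonical_tautomer,
            )
            cmat.to_csv(out / f"{name}_fingerprints.csv")
    manifest.record(
        "featurize",
        [out / "fingerprints.csv", out / "ro5_profiles.csv"],
        None,
        {"compounds": len(matrix.compound_ids),
         "features": len(matrix.feature_names), "failures": len(failures)},
    )


def _prepare_split(config: RunConfig, X: pd.DataFrame, split):
    """Internal-fitted variance/correlation filter + scaler for one split."""
    X_int = X.loc[split.internal_ids]
    X_ext = X.loc[split.external_ids]
    X_int, _ = preprocessing.drop_zero_variance(X_int)
    filt = preprocessing.correlation_filter(
        X_int, config.pair_threshold, config.secondary_threshold
    )
    X_int = X_int[filt.retained]
    scaler = preprocessing.fit_scaler(X_int)
    return (
        preprocessing.apply_scaler(scaler, X_int),
        preprocessing.apply_scaler(scaler, X_ext[filt.retained]),
        filt,
        scaler,
    )


def stage_model(config: RunConfig, out: Path, manifest: _Manifest) -> None:
    X = pd.read_csv(out / "fingerprints.csv", index_col=0)
    curated = pd.read_csv(out / "curated.csv").set_index("canonical_smiles")
    y = curated.loc[X.index, "pic50"]
    splits = preprocessing.make_splits(
        X.index, config.n_splits, config.ratio_internal,
        base_seed=derive_seed(config.master_seed, "splits"),
    )

    tuned: RFConfig | None = None
    rows_full, rows_top = [], []
    top_table = None
    for k, split in enumerate(splits):
        Xtr, Xex, filt, scaler = _prepare_split(config, X, split)
        ytr = y.loc[split.internal_ids].to_numpy()
        yex = y.loc[split.external_ids].to_numpy()
        if tuned is None:
            seed = derive_seed(config.master_seed, "forest")
            if config.tuning_grid is not None:
                tuned = modeling.tune(
                    Xtr, ytr, config.tuning_grid, cv_folds=config.cv_folds,
                    seed=seed,
                )
            else:
                tuned = config.rf_config(seed)
        bundle = modeling.train(Xtr, ytr, tuned)
        cv_seed = derive_seed(config.master_seed, f"cv_{k}")
        report = modeling.evaluate_model(
            bundle, Xtr, ytr, Xex, yex, folds=config.cv_folds, cv_seed=cv_seed
        )
        bundle_top, report_top = modeling.refit_top_k(
            Xtr, ytr, bundle, k=config.top_k, X_ext=Xex, y_ext=yex,
            folds=config.cv_folds, cv_seed=cv_seed,
        )
        rows_full.append({"split": k, **report.to_dict()})
        rows_top.append({"split": k, **report_top.to_dict()})
        if k == 0:
            top_table = pd.DataFrame(
                modeling.rank_features(bundle, config.top_k),
                columns=["feature", "gini_importance"],
            )
            modeling.save_bundle_metadata(bundle, out / "model_full.json")
            modeling.save_bundle_metadata(bundle_top, out / "model_top.json")

    def summarize(rows, label):
        frame = pd.DataFrame(rows)
        stats = frame.drop(columns="split").agg(["mean", "std"])
        stats.insert(0, "split", ["mean", "sd"])
        frame = pd.concat([frame, stats], ignore_index=True)
        frame.insert(0, "model", label)
        return frame

    perf = pd.concat(
        [summarize(rows_full, "full"), summarize(rows_top, f"top{config.top_k}")],
        ignore_index=True,
    )
    perf.to_csv(out / "performance.csv", index=False)
    top_table.to_csv(out / "top_features.csv", index=False)
    manifest.record(
        "model",
        [out / "performance.csv", out / "top_features.csv",
         out / "model_full.json", out / "model_top.json"],
        derive_seed(config.master_seed, "forest"),
        {"n_splits": config.n_splits,
         "tuned": dataclasses.asdict(tuned)},
    )


def stage_validate(config: RunConfig, out: Path, manifest: _Manifest) -> None:
    X = pd.read_csv(out / "fingerprints.csv", index_col=0)
    curated = pd.read_csv(out / "curated.csv").set_index("canonical_smiles")
    y = curated.loc[X.index, "pic50"]
    split = preprocessing.make_splits(
        X.index, 1, config.ratio_internal,
        base_seed=derive_seed(config.master_seed, "splits"),
    )[0]
    Xtr, Xex, filt, scaler = _prepare_split(config, X, split)
    ytr = y.loc[split.internal_ids].to_numpy()
    tuned_meta = json.loads((out / "model_full.json").read_text())
    tuned = RFConfig(**tuned_meta["config"])

    scramble = validation.y_scramble(
        Xtr, ytr, tuned, n=config.n_scrambles,
        seed=derive_seed(config.master_seed, "scramble"), folds=config.cv_folds,
    )
    scramble.to_frame().to_csv(out / "scramble_points.csv", index=False)

    n_comp = min(config.ad_components, len(filt.retained))
    ad = validation.pca_bounding_box(Xtr, Xex, n_components=n_comp)
    scores = pd.DataFrame(
        np.vstack([PCA(n_components=n_comp, random_state=0)
                   .fit(Xtr.to_numpy()).transform(Xtr.to_numpy()), ad.external_scores]),
        columns=[f"PC{j+1}" for j in range(n_comp)],
    )
    scores.insert(0, "set", ["internal"] * len(Xtr) + ["external"] * len(Xex))
    scores.to_csv(out / "pca_scores.csv", index=False)

    top_meta = json.loads((out / "model_top.json").read_text())
    censored = {}
    cens_report = None
    gt_pair = lt_pair = None
    for name, key in (("censored_gt", "gt"), ("censored_lt", "lt")):
        fp_path = out / f"{name}_fingerprints.csv"
        if not fp_path.exists():
            continue
        cX = pd.read_csv(fp_path, index_col=0)
        bounds = pd.read_csv(out / f"{name}.csv")
        cX = preprocessing.apply_scaler(scaler, cX[list(scaler.feature_names)])
        pair = (cX, bounds["bound_pic50"].to_numpy())
        if key == "gt":
            gt_pair = pair
        else:
            lt_pair = pair
    if gt_pair is not None or lt_pair is not None:
        top_features = top_meta["feature_names"]
        bundle_top = modeling.train(
            Xtr[top_features], ytr, tuned, feature_names=top_features
        )
        predict = lambda M: bundle_top.predict(M[top_features])
        cens_report = validation.censored_accuracy(predict, gt_pair, lt_pair)

    perf = pd.read_csv(out / "performance.csv")
    first_full = perf[(perf["model"] == "full") & (perf["split"] == "0")]
    if first_full.empty:
        first_full = perf[perf["model"] == "full"].iloc[[0]]
    r2, q2cv = float(first_full["r2_train"].iloc[0]), float(first_full["q2_cv"].iloc[0])
    q2ext = float(first_full["q2_ext"].iloc[0])
    margin, flag = validation.eriksson_margin((r2, q2ext))
    summary = {
        "acceptability": dataclasses.asdict(validation.acceptability_check((r2, q2cv))),
        "eriksson": {"margin": margin, "flag": flag},
        "scrambling": {"verdict": scramble.verdict,
                       "real": scramble.real_point,
                       "max_scrambled_q2": max(q for _, q in scramble.scrambled_points)},
        "applicability_domain": {"n_components": n_comp,
                                 "fraction_inside": ad.fraction_inside},
        "censored": None if cens_report is None else {
            "n_gt": cens_report.n_gt, "accuracy_gt": cens_report.accuracy_gt,
            "n_lt": cens_report.n_lt, "accuracy_lt": cens_report.accuracy_lt,
        },
    }
    (out / "validation.json").write_text(json.dumps(summary, indent=2))
    manifest.record(
        "validate",
        [out / "validation.json", out / "scramble_points.csv",
         out / "pca_scores.csv"],
        derive_seed(config.master_seed, "scramble"),
        {"n_scrambles": config.n_scrambles},
    )


STAGES = {
    "curate": stage_curate,
    "featurize": stage_featurize,
    "model": stage_model,
    "validate": stage_validate,
}


def run(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Execute the workflow (or a subset of stages, for resuming).

    A stage failure halts the run with the stage name; outputs of completed
    stages are left intact.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    for name in stages or list(STAGES):
        if name not in STAGES:
            raise PipelineError(f"unknown stage {name!r}")
        try:
            STAGES[name](config, out, manifest)
        except Exception as exc:
            (out / "error.json").write_text(
                json.dumps({"stage": name, "error": str(exc),
                            "type": type(exc).__name__}, indent=2)
            )
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return out


def report(out_dir: str | Path) -> str:
    """Human-readable summary: performance table, top features, verdicts."""
    out = Path(out_dir)
    missing = [f for f in ("performance.csv", "top_features.csv", "validation.json")
               if not (out / f).exists()]
    if missing:
        raise PipelineError(f"incomplete artifacts, missing: {missing}")
    perf = pd.read_csv(out / "performance.csv")
    top = pd.read_csv(out / "top_features.csv")
    summary = json.loads((out / "validation.json").read_text())

    lines = ["# Performance (per split, then mean/sd)", ""]
    cols = ["model", "split", "r2_train", "rmse_train", "q2_cv", "rmse_cv",
            "q2_ext", "rmse_ext", "margin"]
    lines.append(perf[cols].round(4).to_string(index=False))
    lines += ["", "# Top features by Gini importance", "",
              top.round(4).to_string(index=False)]
    acc = summary["acceptability"]
    lines += [
        "", "# Validation verdicts", "",
        f"acceptability: {'pass' if acc['passed'] else 'FAIL'} {acc['reasons']}",
        f"eriksson margin: {summary['eriksson']['margin']:.3f} "
        f"({summary['eriksson']['flag']})",
        f"y-scrambling: {summary['scrambling']['verdict']} "
        f"(max scrambled Q2 = {summary['scrambling']['max_scrambled_q2']:.3f})",
        f"applicability domain: fraction inside = "
        f"{summary['applicability_domain']['fraction_inside']:.3f}",
    ]
    cens = summary.get("censored")
    if cens:
        lines.append(
            f"censored accuracy: '>' {cens['accuracy_gt']} (n={cens['n_gt']}), "
            f"'<' {cens['accuracy_lt']} (n={cens['n_lt']})"
        )
    return "\n".join(lines)
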