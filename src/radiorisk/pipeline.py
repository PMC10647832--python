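"""End-to-end orchestration: simulate → normalize/extract → score → fit → evaluate.

Two entry styles are provided.  :func:`build_analysis_table` and
:func:`run_cohort_analysis` work in memory and are the natural API for
scripts and notebooks.  The ``stage_*`` functions mirror them on disk
with a run-folder layout (one subdirectory per stage plus a manifest of
input hashes) and back the command-line interface.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from radiorisk import risk
from radiorisk.evaluation import ExperimentConfig, run_experiment
from radiorisk.io import ClinicalRecord, read_study
from radiorisk.modeling import ModelSpec, fit_model
from radiorisk.normalization import ReferenceTargets, normalize_study
from radiorisk.radiomics import TextureParams, extract_study_features
from radiorisk.synthetic import (
    CohortConfig,
    SyntheticCase,
    cohort_table,
    generate_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)


def score_table(df: pd.DataFrame, rules: risk.RiskRules | None = None) -> pd.DataFrame:
    """Append risk-label columns to a per-lesion cohort table.

    Computes NCCN group, Decipher category, Spratt numeric score, the
    three-tier group and the ``low_risk`` flag from the clinical columns
    and ``decipher_score``, plus the patient-level flag
    ``patient_low_risk`` (all lesions low).
    """
    out = df.copy()
    labels = []
    for _, row in df.iterrows():
        rec = ClinicalRecord(
            age=float(row["age"]), psa=row.get("psa"),
            prostate_volume=row.get("prostate_volume"),
            psad=row.get("psad"), dre=int(row["dre"]), pirads=int(row["pirads"]),
            t_stage=str(row["t_stage"]), grade_group=int(row["grade_group"]),
            pct_positive_cores=None if pd.isna(row.get("pct_positive_cores"))
            else float(row["pct_positive_cores"]),
        )
        labels.append(risk.lesion_labels(rec, float(row["decipher_score"]), rules))
    out["nccn_group"] = [int(l.nccn_group) for l in labels]
    out["decipher_category"] = [int(l.decipher_category) for l in labels]
    out["spratt_numeric"] = [l.spratt_numeric for l in labels]
    out["three_tier"] = [int(l.three_tier) for l in labels]
    out["low_risk"] = [bool(l.low_risk) for l in labels]
    out["patient_low_risk"] = out.groupby("patient_id")["low_risk"].transform("all")
    return out


def build_analysis_table(
    cases: list[SyntheticCase],
    texture_params: TextureParams | None = None,
    targets: ReferenceTargets | None = None,
) -> pd.DataFrame:
    """Normalize, extract features and score a cohort; one row per lesion.

    The resulting table carries the cohort keys, clinical variables,
    Decipher score, recomputed risk labels (``low_risk`` is the model
    outcome), ground-truth columns from the generator and the 487
    radiomic feature columns.
    """
    texture_params = texture_params or TextureParams()
    table = score_table(cohort_table(cases))
    feature_rows = []
    for case in cases:
        normalized = normalize_study(case.study, targets)
        feats = extract_study_features(normalized, texture_params)
        for lesion_id, values in feats.items():
            feature_rows.append(
                {"exam_id": case.study.exam_id, "lesion_id": lesion_id, **values})
    features = pd.DataFrame(feature_rows)
    merged = table.merge(features, on=["exam_id", "lesion_id"], validate="one_to_one")
    if len(merged) != len(table):
        raise RuntimeError("feature extraction lost lesion rows during merge")
    return merged


def run_cohort_analysis(
    config: CohortConfig,
    experiment: ExperimentConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and run the model grid; returns (lesion table, results)."""
    cases = generate_cohort(config)
    df = build_analysis_table(cases)
    results = run_experiment(df, experiment)
    return df, results


# ---------------------------------------------------------------------------
# disk-based stages


@dataclass
class RunConfig:
    """Single-file configuration of a disk-based run."""

    out_dir: str = "radiorisk_run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)        # CohortConfig overrides
    texture: dict = field(default_factory=dict)       # TextureParams overrides
    targets: dict = field(default_factory=dict)       # ReferenceTargets overrides
    models: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    intensity_only: bool = False
    evaluation: dict = field(default_factory=dict)    # ExperimentConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config key(s) {sorted(unknown)}; expected {sorted(known)}")
        return cls(**data)

    def cohort_config(self) -> CohortConfig:
        cfg = dict(self.cohort)
        cfg.setdefault("seed", self.seed)
        for key in ("grid_shape", "voxel_spacing", "radii_mm_low", "radii_mm_nonlow",
                    "dre_positive_rate_by_class", "intensity_scale_range"):
            if key in cfg and isinstance(cfg[key], list):
                cfg[key] = tuple(tuple(x) if isinstance(x, list) else x for x in cfg[key]) \
                    if isinstance(cfg[key][0], list) else tuple(cfg[key])
        return CohortConfig(**cfg)

    def texture_params(self) -> TextureParams:
        return TextureParams(**self.texture)

    def reference_targets(self) -> ReferenceTargets:
        return ReferenceTargets(**self.targets) if self.targets else ReferenceTargets()

    def experiment_config(self) -> ExperimentConfig:
        kwargs = dict(self.evaluation)
        kwargs.setdefault("seed", self.seed)
        if self.intensity_only:
            kwargs["variants"] = ("intensity_only",)
        for key in ("model_ids", "variants", "subsets", "levels"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        kwargs.setdefault("model_ids", tuple(self.models))
        return ExperimentConfig(**kwargs)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(stage_dir: Path, inputs: list[Path]) -> None:
    manifest = {str(p): _hash_file(p) for p in inputs if p.is_file()}
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def check_manifest(stage_dir: Path) -> list[str]:
    """Return the inputs whose hash changed since the stage ran."""
    mpath = stage_dir / "manifest.json"
    if not mpath.is_file():
        return []
    manifest = json.loads(mpath.read_text())
    return [p for p, h in manifest.items()
            if not Path(p).is_file() or _hash_file(Path(p)) != h]


def stage_simulate(config: RunConfig, force: bool = False) -> Path:
    out = Path(config.out_dir) / "cohort"
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use --force)")
    cases = generate_cohort(config.cohort_config())
    write_cohort(cases, config.cohort_config(), out)
    return out


def _check_stale(stage_dir: Path, strict: bool) -> None:
    stale = check_manifest(stage_dir)
    if stale:
        msg = f"stage {stage_dir.name}: inputs changed since last run: {stale}"
        if strict:
            raise ValueError(msg)
        logger.warning("%s (proceeding; use --strict to fail)", msg)


def stage_extract(config: RunConfig, strict: bool = False) -> Path:
    run = Path(config.out_dir)
    cohort_dir = run / "cohort"
    _check_stale(run / "features", strict)
    table = pd.read_csv(cohort_dir / "cohort.csv")
    params = config.texture_params()
    targets = config.reference_targets()
    rows = []
    for exam_id in sorted(table["exam_id"].astype(str).unique()):
        study = read_study(cohort_dir / "studies" / exam_id)
        normalized = normalize_study(study, targets)
        for lesion_id, values in extract_study_features(normalized, params).items():
            rows.append({"exam_id": exam_id, "lesion_id": lesion_id, **values})
    out = run / "features"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "features.csv", index=False)
    (out / "extraction_params.json").write_text(
        json.dumps({**asdict(params), "targets": asdict(targets)},
                   indent=2, default=list))
    _write_manifest(out, [cohort_dir / "cohort.csv"])
    return out / "features.csv"


def stage_score(config: RunConfig) -> Path:
    run = Path(config.out_dir)
    table = pd.read_csv(run / "cohort" / "cohort.csv")
    scored = score_table(table)
    out = run / "scored"
    out.mkdir(parents=True, exist_ok=True)
    scored.to_csv(out / "scored.csv", index=False)
    _write_manifest(out, [run / "cohort" / "cohort.csv"])
    return out / "scored.csv"


def _merged_table(run: Path) -> pd.DataFrame:
    scored = pd.read_csv(run / "scored" / "scored.csv")
    features = pd.read_csv(run / "features" / "features.csv")
    for df in (scored, features):
        df["exam_id"] = df["exam_id"].astype(str)
        df["lesion_id"] = df["lesion_id"].astype(str)
    return scored.merge(features, on=["exam_id", "lesion_id"], validate="one_to_one")


def stage_fit(config: RunConfig, strict: bool = False) -> Path:
    run = Path(config.out_dir)
    _check_stale(run / "models", strict)
    df = _merged_table(run)
    out = run / "models"
    out.mkdir(parents=True, exist_ok=True)
    for mid in config.models:
        spec = ModelSpec(mid, intensity_only=config.intensity_only, seed=config.seed)
        model = fit_model(spec, df)
        model.to_json(out / f"model_{mid}{'_int' if config.intensity_only else ''}.json")
        logger.info("model %d: %d selected variables", mid, len(model.selected))
    _write_manifest(out, [run / "scored" / "scored.csv",
                          run / "features" / "features.csv"])
    return out


def stage_evaluate(config: RunConfig, strict: bool = False) -> Path:
    run = Path(config.out_dir)
    _check_stale(run / "evaluation", strict)
    df = _merged_table(run)
    results = run_experiment(df, config.experiment_config())
    out = run / "evaluation"
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "results.csv", index=False)
    with open(out / "report.txt", "w") as fh:
        fh.write(results.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    _write_manifest(out, [run / "scored" / "scored.csv",
                          run / "features" / "features.csv"])
    return out / "results.csv"


def run_all(config: RunConfig, force: bool = False) -> Path:
    stage_simulate(config, force=force)
    stage_extract(config)
    stage_score(config)
    stage_fit(config)
    return stage_evaluate(config)
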