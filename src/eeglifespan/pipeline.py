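"""End-to-end runs: synth -> preprocess -> features -> trend tables.

Each stage reads and writes files under the run directory, so stages are
independently inspectable and a run is reproducible bit-for-bit from its
config and seed. The run directory ends up containing::

    manifest.csv            cohort manifest (one row per recording)
    data/*.csv              raw session CSVs
    qc_report.csv           per-session verdicts and rejection fractions
    features.csv            one row per user x task
    tables/coefficients.csv trend-table rows per measure x channel x task
    run_metadata.json       config hash, seed, accounting counts
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import population, preprocess, session_io, spectral, synth

logger = logging.getLogger(__name__)

DEFAULT_MEASURES = (
    "log_delta",
    "log_theta",
    "log_alpha",
    "log_beta",
    "alpha_peak",
)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    cohort: synth.CohortConfig = field(default_factory=synth.CohortConfig)
    trend: synth.SpectralTrendModel = field(default_factory=synth.SpectralTrendModel)
    artifacts: synth.ArtifactModel = field(default_factory=synth.ArtifactModel)
    preprocess: preprocess.PreprocessConfig = field(
        default_factory=preprocess.PreprocessConfig
    )
    measures: tuple[str, ...] = DEFAULT_MEASURES
    seed: int = 0
    out_dir: Path = Path("run")

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        # validate every stage config up front (dataclass __post_init__ checks
        # ran on construction; re-check cross-stage constraints here)
        self.trend.validate_age_range(self.cohort.age_range)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, factory in (
            ("cohort", synth.CohortConfig),
            ("trend", synth.SpectralTrendModel),
            ("artifacts", synth.ArtifactModel),
            ("preprocess", preprocess.PreprocessConfig),
        ):
            if key in raw:
                section = dict(raw[key])
                for tup_key in ("age_range", "sessions_per_user", "bandpass"):
                    if tup_key in section:
                        section[tup_key] = tuple(section[tup_key])
                kwargs[key] = factory(**section)
        for key in ("seed", "out_dir", "measures"):
            if key in raw:
                kwargs[key] = tuple(raw[key]) if key == "measures" else raw[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "cohort": asdict(self.cohort),
                "trend": asdict(self.trend),
                "artifacts": asdict(self.artifacts),
                "preprocess": asdict(self.preprocess),
                "measures": list(self.measures),
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def synth_stage(config: RunConfig) -> Path:
    """Generate and write the synthetic cohort; returns the manifest path."""
    cohort_cfg = synth.CohortConfig(
        **{**asdict(config.cohort), "seed": config.seed}
    )
    sessions = synth.generate_cohort(cohort_cfg, config.trend, config.artifacts)
    manifest_path = config.out_dir / "manifest.csv"
    synth.write_cohort(sessions, manifest_path, config.out_dir / "data")
    logger.info("synth: %d sessions for %d users", len(sessions), cohort_cfg.n_users)
    return manifest_path


def preprocess_stage(config: RunConfig, manifest_path: Path):
    """Clean every manifest session; writes qc_report.csv."""
    manifest = session_io.read_manifest(manifest_path, fs=config.cohort.sampling_rate)
    if manifest.n_excluded_underage:
        logger.info("excluded %d underage users", manifest.n_excluded_underage)
    raw = [
        session_io.read_session(e, profile, base_dir=manifest.base_dir, fs=manifest.fs)
        for profile, entries in manifest.users
        for e in entries
    ]
    retained, report = preprocess.preprocess_cohort(raw, config.preprocess)
    report.qc.to_csv(config.out_dir / "qc_report.csv", index=False)
    logger.info(
        "preprocess: %d/%d sessions clean (%.1f%% rejected), %d retained after cap",
        report.n_clean,
        report.n_sessions_in,
        report.rejection_pct,
        report.n_retained,
    )
    return retained, report


def features_stage(config: RunConfig, retained) -> pd.DataFrame:
    features = spectral.compute_user_features(retained)
    features.to_csv(config.out_dir / "features.csv", index=False, float_format="%.6f")
    return features


def model_stage(config: RunConfig, features: pd.DataFrame) -> pd.DataFrame:
    """Fit the age-trend model per measure x channel x task; writes tables."""
    rows = []
    for task, sub in features.groupby("task"):
        for measure in config.measures:
            for ch in session_io.CHANNELS:
                col = f"{measure}_{ch}"
                if col not in sub.columns or sub[col].notna().sum() < 10:
                    continue
                try:
                    res = population.fit_age_trend(sub, col)
                except ValueError as exc:
                    logger.info("skipping %s %s: %s", task, col, exc)
                    continue
                row = {"task": task, "measure": measure, "channel": ch}
                for t in population.TERM_NAMES:
                    row[t] = res.params[t]
                    row[f"{t}_p"] = res.pvalues[t]
                    row[f"{t}_sig"] = res.stars[t]
                row["r2"] = res.rsquared
                row["n_cells"] = res.n_cells
                row["n_users"] = res.n_users
                for sex, refit in res.sex_refits().items():
                    tag = "m" if sex == 0 else "f"
                    row[f"age_{tag}"] = refit.params["age"]
                    row[f"age2_{tag}"] = refit.params["age2"]
                rows.append(row)
    tables = pd.DataFrame(rows)
    tables_dir = config.out_dir / "tables"
    tables_dir.mkdir(parents=True, exist_ok=True)
    tables.to_csv(tables_dir / "coefficients.csv", index=False, float_format="%.6f")
    return tables


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in order under ``config.out_dir``."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    stage = "synth"
    try:
        manifest_path = synth_stage(config)
        stage = "preprocess"
        retained, report = preprocess_stage(config, manifest_path)
        stage = "features"
        features = features_stage(config, retained)
        stage = "model"
        tables = model_stage(config, features)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    metadata = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_users": config.cohort.n_users,
        "n_sessions_in": report.n_sessions_in,
        "n_sessions_clean": report.n_clean,
        "n_sessions_retained": report.n_retained,
        "session_rejection_pct": round(report.rejection_pct, 3),
        "n_users_retained": report.n_users_retained,
        "n_feature_rows": len(features),
        "n_table_rows": len(tables),
        "p_value_df_convention": "cell-level residual df",
        "refit_trigger_alpha": 0.05,
    }
    (config.out_dir / "run_metadata.json").write_text(
        json.dumps(metadata, indent=2, sort_keys=True) + "\n"
    )
    return config.out_dir
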