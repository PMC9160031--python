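"""Stepwise orchestration of the layered target-prediction strategy.

``run_pipeline`` executes the full screen from one seeded configuration:
platform prediction → identifier normalization → ≥2-platform consensus →
enrichment screen → per-target consensus SAR modelling; each stage writes an
immutable artifact into the output directory and the run closes with a
machine-readable summary JSON (validated against a shipped schema) and a
timestamped log. Externally produced docking score tables can be ingested
and juxtaposed with consensus support — docking itself is not reproduced
here.

Two small study calculations live here as well: the kinetic consistency
check ``kd_from_rates`` (K_D = koff/kon) and the caliper tumour-volume
formula ``tumor_volume`` (V = D/2 · d²).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .chemio import Molecule, parse_molecule
from .enrichment import AnnotationDB, enrich, results_to_frame
from .qsar import ConsensusQSAR, RFConfig
from .synthetic import (
    SyntheticSpec,
    gen_annotation_db,
    gen_bioactivity,
    gen_query_for_target,
    gen_reference_library,
    records_to_frame,
)
from .target_similarity import (
    DEFAULT_PLATFORMS,
    PredictorConfig,
    ReferenceLibrary,
    aggregate_consensus,
    normalize_ids,
    predict_targets,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# study calculations


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class KineticParams:
    """SPR binding kinetics: association/dissociation rates and affinity."""

    kon: float  # 1/(M*s)
    koff: float  # 1/s
    kd: float  # M

    def __post_init__(self) -> None:
        if min(self.kon, self.koff, self.kd) <= 0:
            raise ValueError("kinetic parameters must be positive")
        expected = self.koff / self.kon
        if abs(self.kd - expected) / expected > 0.005:
            raise ValueError(
                f"inconsistent kinetics: kd={self.kd:g} but koff/kon={expected:g}"
            )


def kd_from_rates(kon: float, koff: float) -> float:
    """Equilibrium dissociation constant K_D = koff / kon (M), 3 sig figs."""
    if kon <= 0 or koff <= 0:
        raise ValueError("rate constants must be positive")
    return round_sig(koff / kon, 3)


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumour volume V (mm³) = D/2 × d², D = length, d = width."""
    if width_mm <= 0 or length_mm <= 0:
        raise ValueError("dimensions must be positive")
    if width_mm > length_mm:
        logger.warning(
            "width (%g) exceeds length (%g): swapped axes suspected", width_mm, length_mm
        )
    return length_mm / 2.0 * width_mm**2


# ---------------------------------------------------------------------------
# docking-table ingestion


def ingest_docking(table: pd.DataFrame, lower_is_better: bool = True) -> pd.DataFrame:
    """Rank externally produced docking scores per target.

    Expects columns ``ligand, target, score``; non-numeric score rows are
    rejected with a log message. More-negative-is-better is the default
    convention and is recorded in the output.
    """
    if table.empty:
        logger.warning("docking table is empty")
        return pd.DataFrame(columns=["target", "ligand", "score", "rank", "lower_is_better"])
    df = table.copy()
    numeric = pd.to_numeric(df["score"], errors="coerce")
    bad = numeric.isna()
    for _, row in df[bad].iterrows():
        logger.warning("rejecting docking row with non-numeric score: %s", dict(row))
    df = df[~bad].assign(score=numeric[~bad].astype(float))
    df = df.sort_values(
        by=["target", "score", "ligand"],
        ascending=[True, lower_is_better, True],
        kind="mergesort",
    )
    df["rank"] = df.groupby("target").cumcount() + 1
    df["lower_is_better"] = lower_is_better
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# pipeline configuration and runner


@dataclass
class PipelineConfig:
    """One seeded, fully reproducible pipeline run.

    Either explicit input paths (query SMILES, library CSV, activity table,
    GMT) or a :class:`SyntheticSpec` that generates them. At least two
    pseudo-platforms are required for a consensus.
    """

    seed: int
    out_dir: str
    query_smiles: str | None = None
    library_path: str | None = None
    activity_path: str | None = None
    gmt_path: str | None = None
    docking_path: str | None = None
    synthetic: SyntheticSpec | None = None
    platforms: tuple[PredictorConfig, ...] = DEFAULT_PLATFORMS
    min_support: int = 2
    alpha: float = 0.01
    top_k: int = 15
    max_per_scaffold: int = 5
    n_trees: int = 500
    n_folds: int = 5

    def __post_init__(self) -> None:
        if len(self.platforms) < 2:
            raise ValueError("at least two pseudo-platforms are required")
        if self.synthetic is None and self.library_path is None:
            raise ValueError("either a reference library or a synthetic spec is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticSpec(**raw["synthetic"])
        if "platforms" in raw:
            raw["platforms"] = tuple(PredictorConfig(**p) for p in raw["platforms"])
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; completed-stage outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


SUMMARY_SCHEMA_FILE = "summary_schema.json"


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, (SyntheticSpec, PredictorConfig)):
            return asdict(o)
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_summary(summary: dict) -> None:
    """Check the summary JSON against the shipped schema (required keys/types)."""
    from importlib import resources

    schema = json.loads(
        resources.files("targetscreen.data").joinpath(SUMMARY_SCHEMA_FILE).read_text()
    )
    _check_schema(summary, schema["properties"], schema.get("required", []), path="summary")


def _check_schema(obj: dict, properties: dict, required: list, path: str) -> None:
    type_map = {
        "object": dict, "array": list, "string": str,
        "number": (int, float), "integer": int, "boolean": bool,
    }
    for key in required:
        if key not in obj:
            raise ValueError(f"{path}: missing required key {key!r}")
    for key, spec in properties.items():
        if key not in obj:
            continue
        expected = type_map[spec["type"]]
        if not isinstance(obj[key], expected):
            raise ValueError(f"{path}.{key}: expected {spec['type']}")
        if spec["type"] == "object" and "properties" in spec:
            _check_schema(obj[key], spec["properties"], spec.get("required", []), f"{path}.{key}")


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the layered screen end to end; returns the summary dict.

    Stages run in a fixed order and each persists its artifact before the
    next starts, so a failure (raised as :class:`StageError`) leaves all
    completed outputs on disk. With ``resume=True`` a stage whose artifact
    already exists for the identical configuration hash is skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    state_file = out / "stage_state.json"
    state = {}
    if resume and state_file.exists():
        state = json.loads(state_file.read_text())
        if state.get("config_hash") != cfg_hash:
            state = {}
    state["config_hash"] = cfg_hash
    log_path = out / "run.log"

    def log(msg: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        with open(log_path, "a") as fh:
            fh.write(f"{stamp} {msg}\n")
        logger.info(msg)

    def done(stage: str) -> None:
        state[stage] = "done"
        state_file.write_text(json.dumps(state, indent=1))

    log(f"run start (targetscreen {__version__}, seed {config.seed}, config {cfg_hash})")
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": cfg_hash,
        "stages": {},
    }

    # -- inputs ------------------------------------------------------------
    try:
        if config.synthetic is not None:
            spec = config.synthetic
            library, lib_truth = gen_reference_library(spec)
            library.to_csv(out / "reference_library.csv")
            query = (
                parse_molecule(config.query_smiles, "query")
                if config.query_smiles
                else gen_query_for_target(spec, 0)
            )
            db, planted_term, _ = gen_annotation_db(spec)
            db.to_gmt(out / "annotations.gmt")
            activity_records, truth = gen_bioactivity(spec)
            records_to_frame(activity_records).to_csv(out / "bioactivity.csv", index=False)
            truth.to_csv(out / "bioactivity_truth.csv", index=False)
            log(f"synthetic inputs generated (seed {spec.seed}); planted term {planted_term}")
        else:
            library = ReferenceLibrary.from_csv(config.library_path)
            query = parse_molecule(config.query_smiles, "query")
            db = AnnotationDB.from_gmt(config.gmt_path) if config.gmt_path else None
            activity_records = None
            if config.activity_path:
                from .qsar import records_from_table

                sep = "\t" if str(config.activity_path).endswith((".tsv", ".tab")) else ","
                activity_records = records_from_table(
                    pd.read_csv(config.activity_path, sep=sep)
                )
    except Exception as exc:
        raise StageError("inputs", exc) from exc

    # -- stage 1: platform prediction + normalization ----------------------
    stage = "predict"
    try:
        if resume and state.get(stage) == "done" and (out / "01_predictions.csv").exists():
            log("stage predict skipped (resume)")
            preds_df = pd.read_csv(out / "01_predictions.csv")
            from .target_similarity import PlatformPrediction

            predictions = [
                PlatformPrediction(
                    str(name),
                    [(str(r.target_id), float(r.score)) for r in grp.itertuples()],
                    k_kept=len(grp),
                )
                for name, grp in preds_df.groupby("platform", sort=True)
            ]
        else:
            predictions = [
                normalize_ids(predict_targets(query, library, m, top_k=config.top_k))
                for m in config.platforms
            ]
            rows = [
                {"platform": p.platform_name, "target_id": t, "score": s, "rank": i + 1}
                for p in predictions
                for i, (t, s) in enumerate(p.ranked_targets)
            ]
            pd.DataFrame(rows).to_csv(out / "01_predictions.csv", index=False)
            log(f"stage predict: {len(predictions)} platforms x top {config.top_k}")
            done(stage)
        summary["stages"]["predict"] = {
            "platforms": [p.platform_name for p in predictions],
            "n_predicted": sum(len(p.ranked_targets) for p in predictions),
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage 2: consensus ------------------------------------------------
    stage = "consensus"
    try:
        consensus = aggregate_consensus(predictions, min_support=config.min_support)
        consensus.to_frame().to_csv(out / "02_consensus.csv", index=False)
        consensus.to_json(out / "02_consensus.json")
        log(
            f"stage consensus: union {len(consensus.union_targets)}, "
            f"selected {len(consensus.consensus_targets)} at support >= {config.min_support}"
        )
        done(stage)
        summary["stages"]["consensus"] = {
            "union_size": len(consensus.union_targets),
            "consensus_size": len(consensus.consensus_targets),
            "consensus_targets": sorted(consensus.consensus_targets),
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage 3: enrichment ------------------------------------------------
    stage = "enrich"
    try:
        if db is not None:
            query_genes = sorted(consensus.consensus_targets)
            if config.synthetic is not None:
                # synthetic annotations live in their own namespace; screen the
                # generator's designated query to exercise the stage
                _, _, query_genes = gen_annotation_db(config.synthetic)
            results = enrich(query_genes, db, alpha=config.alpha)
            results_to_frame(results).to_csv(out / "03_enrichment.csv", index=False)
            selected = [r.term_id for r in results if r.selected]
            log(f"stage enrich: {len(selected)} terms at P < {config.alpha}")
            summary["stages"]["enrich"] = {
                "n_tested": len(results),
                "n_selected": len(selected),
                "selected_terms": selected,
            }
        else:
            summary["stages"]["enrich"] = {"n_tested": 0, "n_selected": 0, "selected_terms": []}
            log("stage enrich: no annotation database supplied, skipped")
        done(stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage 4: consensus SAR ---------------------------------------------
    stage = "qsar"
    try:
        if activity_records:
            model = ConsensusQSAR.from_activity_table(
                records_to_frame(activity_records),
                rf_config=RFConfig(n_trees=config.n_trees, seed=config.seed),
                max_per_scaffold=config.max_per_scaffold,
            )
            results = model.fit(n_folds=config.n_folds)
            results.save_report(out / "04_qsar_metrics.json")
            results.metrics_frame().to_csv(out / "04_qsar_metrics.csv", index=False)
            query_pred = results.predict([query])
            query_pred.to_csv(out / "04_query_prediction.csv", index=False)
            log(
                "stage qsar: consensus CV AUC "
                f"{results.consensus_metrics.auc:.3f} on {len(model.dataset)} molecules"
            )
            summary["stages"]["qsar"] = {
                "n_molecules": len(model.dataset),
                "consensus_auc": results.consensus_metrics.auc,
                "consensus_acc": results.consensus_metrics.acc,
                "query_prob_consensus": float(query_pred["prob_consensus"].iloc[0]),
                "query_call_active": bool(query_pred["call_active"].iloc[0]),
            }
        else:
            summary["stages"]["qsar"] = {"n_molecules": 0}
            log("stage qsar: no activity data supplied, skipped")
        done(stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage 5: docking ingestion (optional) -------------------------------
    stage = "docking"
    try:
        if config.docking_path:
            ranked = ingest_docking(pd.read_csv(config.docking_path))
            ranked.to_csv(out / "05_docking_ranked.csv", index=False)
            log(f"stage docking: ranked {len(ranked)} rows")
            summary["stages"]["docking"] = {"n_rows": int(len(ranked))}
        done(stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    validate_summary(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    log("run complete")
    return summary
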