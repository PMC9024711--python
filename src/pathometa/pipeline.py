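"""End-to-end orchestration: simulate/ingest -> preprocess -> train -> predict.

:func:`run_pipeline` chains the library stages under a single
:class:`RunConfig`, writes every stage's output under an output directory
and records a JSON manifest (seeds, grids, per-stage counts, the selected
model). Reruns with the same config reproduce the manifest's counts and the
selected model entry exactly. The fitted encoder and forest are serialized
with joblib next to the manifest for later prediction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import yaml

from . import __version__
from .annotation import read_annotated_vcf, write_prediction_table
from .encoders import AutoencoderConfig
from .models import grid_search
from .preprocess import class_counts, filter_complete_cases, split_by_role
from .reclassify import high_confidence_set, predict_variants, summarize_reclassification
from .synthetic import SyntheticSpec, simulate_variants, write_synthetic_vcf

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    Exactly one of ``vcf`` (ingest a ClinVar-style annotated VCF) or
    ``synthetic`` (simulate one) must be provided. ``seed`` drives every
    stochastic stage: the simulator, fold shuffling, forest bootstraps and
    autoencoder initialization.
    """

    out_dir: str | Path = "pathometa_run"
    vcf: str | Path | None = None
    synthetic: SyntheticSpec | None = None
    encodings: tuple[str, ...] = ("label", "onehot", "mca", "autoencoder")
    tree_grid: tuple[int, ...] = (100, 500, 1000)
    mtry_grid: tuple[int, ...] | None = None
    autoencoder_grid: tuple[AutoencoderConfig, ...] | None = None
    cv_folds: int = 10
    threshold: float = 0.9
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticSpec(**raw["synthetic"])
        for key in ("encodings", "tree_grid", "mtry_grid"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pathometa_version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    # -- acquire variants --------------------------------------------------
    if (config.vcf is None) == (config.synthetic is None):
        raise PipelineError("config", "provide exactly one of vcf or synthetic")
    if config.synthetic is not None:
        spec = config.synthetic
        variants = simulate_variants(spec)
        vcf_path = out / "synthetic.vcf"
        write_synthetic_vcf(variants, vcf_path)
        manifest["stages"]["simulate"] = {"n_variants": len(variants), "vcf": str(vcf_path)}
        # Hidden truths survive only in memory; re-reading would lose them.
    else:
        vcf_path = Path(config.vcf)
        if not vcf_path.exists():
            raise PipelineError("ingest", f"VCF not found: {vcf_path}")
        try:
            variants = read_annotated_vcf(vcf_path)
        except Exception as e:
            raise PipelineError("ingest", str(e)) from e
        manifest["stages"]["ingest"] = {"n_variants": len(variants), "vcf": str(vcf_path)}

    # -- preprocess --------------------------------------------------------
    table, report = filter_complete_cases(variants)
    try:
        train_table, reclass_table = split_by_role(table)
    except ValueError as e:
        raise PipelineError("preprocess", str(e)) from e
    report.to_frame().to_csv(out / "exclusions.tsv", sep="\t", index=False)
    manifest["stages"]["preprocess"] = {
        "n_input": report.n_input,
        "n_complete": report.n_retained,
        "n_excluded": report.n_excluded,
        "n_train": len(train_table),
        "n_reclass": len(reclass_table),
        "train_classes": class_counts(train_table.labels),
        "reclass_classes": class_counts(reclass_table.labels),
    }

    # -- grid search -------------------------------------------------------
    try:
        result = grid_search(
            train_table,
            encodings=config.encodings,
            tree_grid=config.tree_grid,
            mtry_grid=config.mtry_grid,
            seed=config.seed,
            k=config.cv_folds,
            autoencoder_grid=config.autoencoder_grid,
        )
    except ValueError as e:
        raise PipelineError("train", str(e)) from e
    rows = [
        {
            "encoding": e.encoding_kind,
            **{f"encoder_{k}": v for k, v in e.encoder_params.items()},
            "n_trees": e.rf_config.n_trees,
            "mtry": e.rf_config.mtry,
            "cv_auc": e.evaluation.auc,
            "cv_auc_sd": e.evaluation.auc_sd,
            "oob_error": e.evaluation.oob_error,
            "selected": i == result.best_index,
        }
        for i, e in enumerate(result.entries)
    ]
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "grid_search.tsv", sep="\t", index=False)
    best = result.best
    from .models import train_rf

    encoder = result.best_encoder()
    X_train = encoder.transform(train_table)
    model = train_rf(X_train, train_table.binary_labels(), best.rf_config)
    joblib.dump({"model": model, "encoder": encoder}, out / "model.joblib")
    manifest["stages"]["train"] = {
        "n_grid_entries": len(result.entries),
        "selected": {
            "encoding": best.encoding_kind,
            "encoder_params": best.encoder_params,
            "n_trees": best.rf_config.n_trees,
            "mtry": best.rf_config.mtry,
            "cv_auc": best.evaluation.auc,
            "oob_error": best.evaluation.oob_error,
        },
    }

    # -- reclassification --------------------------------------------------
    if len(reclass_table):
        results = predict_variants(model, encoder, reclass_table, config.threshold)
        write_prediction_table(results, out / "predictions.tsv")
        _, hc_counts = high_confidence_set(results, config.threshold)
        manifest["stages"]["predict"] = {
            "n_predicted": len(results),
            "summary": summarize_reclassification(results),
            "high_confidence": hc_counts,
        }
    else:
        manifest["stages"]["predict"] = {"n_predicted": 0}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_model(out_dir: str | Path):
    """Reload the serialized (model, encoder) pair from a run directory."""
    blob = joblib.load(Path(out_dir) / "model.joblib")
    return blob["model"], blob["encoder"]
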