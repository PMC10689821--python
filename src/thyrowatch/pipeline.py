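"""End-to-end run: ingest -> pairs -> augment -> LOOCV -> reports."""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .dataset import augment_dataset, build_dataset, write_dataset_csv
from .evaluation import confusion, loocv_predict, metrics
from .hr_windows import read_sleep_csv, read_sleep_json
from .model import feature_importance, fit
from .thyroid import read_tft_csv

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full evaluation pipeline and write all artifacts.

    Writes predictions.csv, confusion CSVs (full and with subclinical
    thyrotoxicosis excluded), metrics.json, importance.csv, dataset CSVs,
    and run_log.json with per-stage record counts.  Returns the metrics
    payload.
    """
    if config.tft_path is None or config.sleep_path is None:
        raise ValueError("run_pipeline requires tft_path and sleep_path")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"thyrowatch config_hash={config.config_hash()} seed={config.seed}"

    tfts = read_tft_csv(config.tft_path)
    reader = read_sleep_json if config.sleep_format == "json" else read_sleep_csv
    nights = reader(config.sleep_path)
    dataset = build_dataset(
        tfts,
        nights,
        n_days=config.n_days,
        coverage=config.coverage(),
        include_anchor_morning=config.include_anchor_morning,
        ranges=config.reference_ranges(),
        tsh_floor=config.tsh_floor,
        jsd_base=config.jsd_base,
    )
    n_observed_pairs = len(dataset.pairs)
    n_observed_cases = len(dataset.cases)
    augmented = augment_dataset(
        dataset, step_days=config.step_days, log_tsh=config.log_tsh_interpolation
    )
    write_dataset_csv(augmented, out, header_comment=tag)

    result = loocv_predict(
        augmented,
        model_config=config.model_config(),
        threshold=config.threshold,
        seed=config.seed,
    )
    cm_full = confusion(result.predictions, exclude_subclinical=False)
    cm_excl = confusion(result.predictions, exclude_subclinical=True)
    rep_full = metrics(cm_full)
    rep_excl = metrics(cm_excl)

    pred_frame = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in result.predictions],
            "target_date": [p.target.tft.test_date.isoformat() for p in result.predictions],
            "averaged_probability": [p.averaged_probability for p in result.predictions],
            "decision": [int(p.decision) for p in result.predictions],
            "true_label": [int(p.true_label) for p in result.predictions],
            "true_state": [p.true_state.value for p in result.predictions],
            "n_referred": [len(p.referred_probabilities) for p in result.predictions],
        }
    )
    with open(out / "predictions.csv", "w") as fh:
        fh.write(f"# {tag}\n")
        pred_frame.to_csv(fh, index=False, float_format="%.12g")

    for name, cm in (("confusion_full", cm_full), ("confusion_excluding_subclinical", cm_excl)):
        with open(out / f"{name}.csv", "w") as fh:
            fh.write(f"# {tag}\n")
            pd.DataFrame([{"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn}]).to_csv(
                fh, index=False
            )

    # one model on the full augmented pool for the importance report
    full_model = fit(augmented.cases, config=config.model_config(), seed=config.seed)
    report = feature_importance([full_model])
    with open(out / "importance.csv", "w") as fh:
        fh.write(f"# {tag}\n")
        report.frame.to_csv(fh, index=False, float_format="%.12g")

    def _clean(d: dict) -> dict:
        return {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in d.items()}

    payload = {
        "_meta": {"config_hash": config.config_hash(), "seed": config.seed},
        "full": _clean(rep_full.rounded()),
        "excluding_subclinical": _clean(rep_excl.rounded()),
        "confusion_full": {"tp": cm_full.tp, "fn": cm_full.fn, "fp": cm_full.fp, "tn": cm_full.tn},
        "confusion_excluding_subclinical": {
            "tp": cm_excl.tp, "fn": cm_excl.fn, "fp": cm_excl.fp, "tn": cm_excl.tn,
        },
        "n_targets": len(result.predictions),
        "n_skipped_targets": len(result.skipped),
        "leakage_violations": result.n_leaky_folds(),
    }
    (out / "metrics.json").write_text(json.dumps(payload, indent=2))

    run_log = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "counts": {
            "tfts": len(tfts),
            "nights": len(nights),
            "observed_pairs": n_observed_pairs,
            "rejected_pairs": len(dataset.rejected),
            "observed_cases": n_observed_cases,
            "augmented_pairs": len(augmented.pairs),
            "augmented_cases": len(augmented.cases),
            "targets_evaluated": len(result.predictions),
        },
        "per_fold_exclusions": [
            {"target": list(f.target_key), "n_train": f.n_train, "n_excluded": f.n_excluded}
            for f in result.folds
        ],
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    logger.info("pipeline complete: %s", json.dumps(run_log["counts"]))
    return payload
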