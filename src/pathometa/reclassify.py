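"""Apply the selected model to VUS/CI variants and extract the
high-confidence pathogenic set.

A variant is called pathogenic when RFprob >= 0.5, and high-confidence when
its probability is extreme on either side: RFprob >= threshold (pathogenic)
or RFprob <= 1 - threshold (benign). The headline reclassification summary
reports pathogenic counts and percentages per source stratum (VUS vs CI)
and against the combined total, since both denominators are in use in the
literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoders import FittedEncoder
from .models import TrainedModel
from .preprocess import FeatureTable
from .variants import ClinicalLabel, VariantKey
from .vocab import VOCABULARIES


@dataclass
class PredictionResult:
    key: VariantKey
    prob_pathogenic: float
    predicted_label: ClinicalLabel
    high_confidence: bool
    source_label: ClinicalLabel

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_pathogenic <= 1.0:
            raise ValueError("prob_pathogenic must be in [0, 1]")


def predict_variants(
    model: TrainedModel,
    encoder: FittedEncoder,
    reclass_table: FeatureTable,
    threshold: float = 0.9,
) -> list[PredictionResult]:
    """Score every row of the reclassification table with the fitted model.

    The boundary probability 0.5 is called pathogenic; probabilities equal
    to the threshold (or to 1 - threshold) are high-confidence.
    """
    _check_threshold(threshold)
    if reclass_table.predictor_order != tuple(VOCABULARIES):
        raise ValueError("predictor order does not match the model vocabularies")
    if len(reclass_table) == 0:
        return []
    X = encoder.transform(reclass_table)
    if X.column_names != model.feature_names:
        raise ValueError(
            "encoded columns do not match the trained model "
            f"({X.column_names} vs {model.feature_names})"
        )
    probs = model.predict_proba_pathogenic(X.values)
    out = []
    for v, label, p in zip(reclass_table.rows, reclass_table.labels, probs):
        p = float(p)
        out.append(
            PredictionResult(
                key=v.key,
                prob_pathogenic=p,
                predicted_label=(
                    ClinicalLabel.PATHOGENIC if p >= 0.5 else ClinicalLabel.BENIGN
                ),
                high_confidence=bool(p >= threshold or p <= 1.0 - threshold),
                source_label=label,
            )
        )
    return out


def _check_threshold(threshold: float) -> None:
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0.5, 1], got {threshold}")


def high_confidence_set(
    results: list[PredictionResult], threshold: float = 0.9
) -> tuple[list[PredictionResult], dict]:
    """Results with RFprob >= threshold, plus counts by stratum.

    Nesting is monotone: lowering the threshold can only add members.
    """
    _check_threshold(threshold)
    kept = [r for r in results if r.prob_pathogenic >= threshold]
    counts = {
        "threshold": threshold,
        "n_total": len(kept),
        "by_source": {
            s.value: sum(1 for r in kept if r.source_label is s)
            for s in (ClinicalLabel.VUS, ClinicalLabel.CONFLICTING)
        },
        "by_predicted": {
            l.value: sum(1 for r in kept if r.predicted_label is l)
            for l in (ClinicalLabel.BENIGN, ClinicalLabel.PATHOGENIC)
        },
    }
    return kept, counts


def summarize_reclassification(results: list[PredictionResult]) -> dict:
    """Pathogenic/benign counts and percentages per source stratum.

    Percentages are reported twice: against the stratum's own total
    (``pct_pathogenic``) and against the combined VUS+CI total
    (``pct_pathogenic_overall``); a stratum with no rows omits them.
    """
    overall = len(results)
    summary: dict = {"n_total": overall, "strata": {}}
    for stratum in (ClinicalLabel.VUS, ClinicalLabel.CONFLICTING):
        rows = [r for r in results if r.source_label is stratum]
        n = len(rows)
        n_path = sum(
            1 for r in rows if r.predicted_label is ClinicalLabel.PATHOGENIC
        )
        entry: dict = {"n": n, "n_pathogenic": n_path, "n_benign": n - n_path}
        if n > 0:
            entry["pct_pathogenic"] = 100.0 * n_path / n
        if overall > 0:
            entry["pct_pathogenic_overall"] = 100.0 * n_path / overall
        summary["strata"][stratum.value] = entry
    return summary


def recovery_rate(
    results: list[PredictionResult], reclass_table: FeatureTable
) -> dict[str, float]:
    """Fraction of hidden-truth classes recovered (synthetic data only)."""
    by_truth: dict[str, list[bool]] = {}
    for r, v in zip(results, reclass_table.rows):
        t = v.truth
        if t is None:
            continue
        by_truth.setdefault(t.value, []).append(r.predicted_label is t)
    return {t: float(np.mean(hits)) for t, hits in by_truth.items()}
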