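"""Label grouping, complete-case filtering and train/reclassification split.

ClinVar's ACMG-AMP assertion strings collapse to four analysis labels:
benign (Benign, Likely_benign and their slash compound), pathogenic
(Pathogenic, Likely_pathogenic and compound), vus (Uncertain_significance)
and conflicting (Conflicting_interpretations_of_pathogenicity). Compound
strings with comma-joined qualifiers, e.g. ``Pathogenic,_risk_factor``, map
by their leading term — ClinVar's primary assertion. Everything else is
unmapped and excluded.

The metapredictor is trained only on complete cases: variants with all eight
predictor calls present.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variants import AnnotatedVariant, ClinicalLabel
from .vocab import PREDICTOR_ORDER

logger = logging.getLogger(__name__)

_GROUPS: dict[str, ClinicalLabel] = {
    "Benign": ClinicalLabel.BENIGN,
    "Likely_benign": ClinicalLabel.BENIGN,
    "Benign/Likely_benign": ClinicalLabel.BENIGN,
    "Pathogenic": ClinicalLabel.PATHOGENIC,
    "Likely_pathogenic": ClinicalLabel.PATHOGENIC,
    "Pathogenic/Likely_pathogenic": ClinicalLabel.PATHOGENIC,
    "Uncertain_significance": ClinicalLabel.VUS,
    "Conflicting_interpretations_of_pathogenicity": ClinicalLabel.CONFLICTING,
}


def group_labels(clnsig_raw: str) -> ClinicalLabel | None:
    """Map a raw CLNSIG string to its analysis label, or None if unmapped."""
    leading = clnsig_raw.strip().split(",")[0].strip()
    return _GROUPS.get(leading)


@dataclass
class FeatureTable:
    """Complete-case variants with grouped labels, in a fixed predictor order."""

    rows: list[AnnotatedVariant]
    labels: list[ClinicalLabel]
    predictor_order: tuple[str, ...] = PREDICTOR_ORDER

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.labels):
            raise ValueError("rows and labels must be parallel")
        for v in self.rows:
            if any(v.calls.get(p) is None for p in self.predictor_order):
                raise ValueError(f"incomplete calls for {v.key}")

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        """Calls as a categorical DataFrame (one column per predictor)."""
        return pd.DataFrame(
            {p: [v.calls[p] for v in self.rows] for p in self.predictor_order}
        )

    def binary_labels(self) -> np.ndarray:
        """0/1 vector (benign=0, pathogenic=1); only valid on a train table."""
        codes = {ClinicalLabel.BENIGN: 0, ClinicalLabel.PATHOGENIC: 1}
        try:
            return np.array([codes[l] for l in self.labels], dtype=int)
        except KeyError as e:
            raise ValueError(f"non-binary label in table: {e}") from None


@dataclass
class ExclusionReport:
    """Bookkeeping for variants dropped before training."""

    n_input: int = 0
    n_retained: int = 0
    unmapped_clnsig: Counter = field(default_factory=Counter)
    missing_patterns: Counter = field(default_factory=Counter)
    n_duplicate_keys: int = 0

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_retained

    def to_frame(self) -> pd.DataFrame:
        rows = [("unmapped_clnsig", k, n) for k, n in self.unmapped_clnsig.items()]
        rows += [
            ("missing_calls", "+".join(p), n) for p, n in self.missing_patterns.items()
        ]
        if self.n_duplicate_keys:
            rows.append(("duplicate_key", "", self.n_duplicate_keys))
        return pd.DataFrame(rows, columns=["reason", "detail", "count"])


def filter_complete_cases(
    variants: Iterable[AnnotatedVariant],
) -> tuple[FeatureTable, ExclusionReport]:
    """Keep variants with a mapped label and all eight calls present.

    Order is preserved; duplicate genomic keys keep their first occurrence
    (avoids train/reclassification leakage). The report counts exclusions by
    missing-call pattern and by unmapped CLNSIG string.
    """
    report = ExclusionReport()
    rows: list[AnnotatedVariant] = []
    labels: list[ClinicalLabel] = []
    seen: set = set()
    for v in variants:
        report.n_input += 1
        label = group_labels(v.clnsig_raw)
        if label is None:
            report.unmapped_clnsig[v.clnsig_raw] += 1
            continue
        if not v.is_complete:
            report.missing_patterns[v.missing_predictors()] += 1
            continue
        ident = (v.key.chrom, v.key.pos, v.key.ref, v.key.alt)
        if ident in seen:
            report.n_duplicate_keys += 1
            logger.info("duplicate key dropped: %s", v.key)
            continue
        seen.add(ident)
        rows.append(v)
        labels.append(label)
    report.n_retained = len(rows)
    if report.n_input and not rows:
        logger.warning("no complete-case variants retained of %d", report.n_input)
    return FeatureTable(rows, labels), report


def split_by_role(table: FeatureTable) -> tuple[FeatureTable, FeatureTable]:
    """Partition into (train: benign+pathogenic, reclassification: vus+ci).

    Raises ValueError if the train side is empty or single-class — an
    unfittable dataset.
    """
    train_idx = [
        i
        for i, l in enumerate(table.labels)
        if l in (ClinicalLabel.BENIGN, ClinicalLabel.PATHOGENIC)
    ]
    reclass_idx = [i for i in range(len(table)) if i not in set(train_idx)]
    train_labels = {table.labels[i] for i in train_idx}
    if len(train_labels) < 2:
        raise ValueError(
            "train split needs both benign and pathogenic variants, "
            f"got {sorted(l.value for l in train_labels)}"
        )
    pick = lambda idx: FeatureTable(
        [table.rows[i] for i in idx],
        [table.labels[i] for i in idx],
        table.predictor_order,
    )
    return pick(train_idx), pick(reclass_idx)


def class_counts(labels: Sequence[ClinicalLabel]) -> dict[str, int]:
    c = Counter(l.value for l in labels)
    return {l.value: c.get(l.value, 0) for l in ClinicalLabel}
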