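"""Core variant records shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .vocab import VOCABULARIES


class ClinicalLabel(str, Enum):
    """The four analysis labels the ACMG-AMP significance strings collapse to."""

    BENIGN = "benign"
    PATHOGENIC = "pathogenic"
    VUS = "vus"
    CONFLICTING = "conflicting"


@dataclass(frozen=True, order=True)
class VariantKey:
    """Genomic identity of a variant: contig, 1-based position, alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r}")


@dataclass
class AnnotatedVariant:
    """One variant with its clinical assertion and predictor calls.

    ``calls`` maps predictor name -> category code; a predictor absent from
    the map (or mapped to None) is a missing call. ``truth`` carries the
    hidden ground-truth class of synthetic VUS/CI variants for recovery
    tests; it is never written to or read from VCF.
    """

    key: VariantKey
    clnsig_raw: str
    calls: dict[str, str | None]
    truth: ClinicalLabel | None = None

    def __post_init__(self) -> None:
        for predictor, code in self.calls.items():
            if predictor not in VOCABULARIES:
                raise ValueError(f"unknown predictor {predictor!r}")
            if code is not None and code not in VOCABULARIES[predictor].categories:
                raise ValueError(
                    f"unknown category {code!r} for predictor {predictor!r}"
                )

    @property
    def is_complete(self) -> bool:
        """True when all eight predictors have a call."""
        return all(self.calls.get(p) is not None for p in VOCABULARIES)

    def missing_predictors(self) -> tuple[str, ...]:
        return tuple(p for p in VOCABULARIES if self.calls.get(p) is None)
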