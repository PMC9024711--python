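"""Predictor vocabularies.

Eight categorical functional-impact predictors feed the metapredictor. Each
predictor emits a single category code per variant (per transcript, in raw
dbNSFP output). The codes, their meaning and their severity ranking follow
the tools' own documentation:

========================  ==========  ===========================================
predictor                 categories  severity (most -> least deleterious)
========================  ==========  ===========================================
FATHMM                    D, T        D (damaging) > T (tolerated)
SIFT                      D, T        D (deleterious) > T (tolerated)
Polyphen2_HDIV            B, D, P     D (probably) > P (possibly) > B (benign)
Polyphen2_HVAR            B, D, P     D > P > B
PROVEAN                   D, N        D (deleterious) > N (neutral)
MutationAssessor          H, L, M, N  H (high) > M (medium) > L (low) > N
MutationTaster            A, D, N, P  A (auto disease) > D (disease) > N > P
LRT                       D, N, U     D (deleterious) > N (neutral) > U (unknown)
========================  ==========  ===========================================

Category sets total J = 23 codes over Q = 8 predictors. LRT's ``D`` is part
of the dbNSFP definition even though some summaries list only N/U; it can be
dropped via :func:`vocabularies` if a data source never emits it.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PredictorVocabulary:
    """Category codes of one predictor and their severity ranking.

    ``categories`` is stored lexicographically sorted (the order used for
    label/one-hot column layout); ``severity_order`` is the same codes from
    most to least deleterious.
    """

    predictor_name: str
    categories: tuple[str, ...]
    severity_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if sorted(self.categories) != sorted(self.severity_order):
            raise ValueError(
                f"{self.predictor_name}: severity_order must be a permutation "
                f"of categories"
            )
        object.__setattr__(self, "categories", tuple(sorted(self.categories)))

    def severity_rank(self, code: str) -> int:
        """0 = most severe. Raises ValueError for unknown codes."""
        try:
            return self.severity_order.index(code)
        except ValueError:
            raise ValueError(
                f"unknown category {code!r} for predictor {self.predictor_name}"
            ) from None

    @property
    def most_severe(self) -> str:
        return self.severity_order[0]

    @property
    def least_severe(self) -> str:
        return self.severity_order[-1]


#: Canonical predictor order; spellings match the SnpSift `dbNSFP_<tool>_pred`
#: INFO-key dialect.
PREDICTOR_ORDER: tuple[str, ...] = (
    "FATHMM",
    "SIFT",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "PROVEAN",
    "MutationAssessor",
    "MutationTaster",
    "LRT",
)

_SEVERITY: dict[str, tuple[str, ...]] = {
    "FATHMM": ("D", "T"),
    "SIFT": ("D", "T"),
    "Polyphen2_HDIV": ("D", "P", "B"),
    "Polyphen2_HVAR": ("D", "P", "B"),
    "PROVEAN": ("D", "N"),
    "MutationAssessor": ("H", "M", "L", "N"),
    "MutationTaster": ("A", "D", "N", "P"),
    "LRT": ("D", "N", "U"),
}


def vocabularies(include_lrt_d: bool = True) -> dict[str, PredictorVocabulary]:
    """The eight predictor vocabularies, keyed by predictor name.

    Parameters
    ----------
    include_lrt_d
        If False, LRT's vocabulary is restricted to {N, U}.
    """
    out: dict[str, PredictorVocabulary] = {}
    for name in PREDICTOR_ORDER:
        sev = _SEVERITY[name]
        if name == "LRT" and not include_lrt_d:
            sev = tuple(c for c in sev if c != "D")
        out[name] = PredictorVocabulary(name, tuple(sorted(sev)), sev)
    return out


VOCABULARIES: dict[str, PredictorVocabulary] = vocabularies()

#: Number of predictors (Q) and total category count (J).
N_PREDICTORS: int = len(PREDICTOR_ORDER)
N_CATEGORIES: int = sum(len(v.categories) for v in VOCABULARIES.values())

#: SnpSift/dbNSFP INFO key for each predictor.
INFO_KEYS: dict[str, str] = {name: f"dbNSFP_{name}_pred" for name in PREDICTOR_ORDER}
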