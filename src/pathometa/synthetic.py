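"""Seeded synthetic variant sets with dbNSFP-style categorical calls.

The generator states a simple class-conditional world: every variant has a
ground-truth class (benign or pathogenic). A pathogenic variant's predictor
emits the predictor's *most severe* category with probability ``concordance``
and otherwise a uniform draw over the remaining categories; a benign
variant's predictor mirrors this with the *least severe* category. VUS and
conflicting-interpretation (CI) strata receive ClinVar-style `CLNSIG`
strings but carry a hidden ground-truth class (drawn fair-coin) so that
reclassification can be scored as parameter recovery.

Concordance is the only signal dial: at 1.0 the classes are perfectly
separable from any single predictor, at 1/k (uniform) there is no signal.
Missing calls are injected independently per predictor per variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variants import AnnotatedVariant, ClinicalLabel, VariantKey
from .vocab import INFO_KEYS, PREDICTOR_ORDER, VOCABULARIES

#: ClinVar CLNSIG strings emitted per stratum.
_CLNSIG = {
    ClinicalLabel.BENIGN: "Benign",
    ClinicalLabel.PATHOGENIC: "Pathogenic",
    ClinicalLabel.VUS: "Uncertain_significance",
    ClinicalLabel.CONFLICTING: "Conflicting_interpretations_of_pathogenicity",
}

_DEFAULT_CHROMS = tuple(str(c) for c in range(1, 23)) + ("X", "Y")

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic variant set.

    Default class counts mirror a genome-wide ClinVar complete-case split
    (benign 18,891 / pathogenic 16,471 train; VUS 93,612 / CI 7,193
    reclassification); defaults for concordance (0.9) and missing rate (0.1)
    are documented in the methods note. Same spec + same seed gives
    byte-identical VCF output.
    """

    n_benign: int = 18_891
    n_pathogenic: int = 16_471
    n_vus: int = 93_612
    n_ci: int = 7_193
    concordance: float = 0.9
    missing_rate: float = 0.1
    seed: int = 0
    chrom_pool: tuple[str, ...] = field(default=_DEFAULT_CHROMS)

    def __post_init__(self) -> None:
        for name in ("n_benign", "n_pathogenic", "n_vus", "n_ci"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("concordance", "missing_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not self.chrom_pool:
            raise ValueError("chrom_pool must be nonempty")
        object.__setattr__(self, "chrom_pool", tuple(self.chrom_pool))

    @property
    def n_total(self) -> int:
        return self.n_benign + self.n_pathogenic + self.n_vus + self.n_ci


def _draw_call(vocab, truth: ClinicalLabel, concordance: float, rng) -> str:
    consistent = (
        vocab.most_severe if truth is ClinicalLabel.PATHOGENIC else vocab.least_severe
    )
    if rng.random() < concordance:
        return consistent
    rest = [c for c in vocab.severity_order if c != consistent]
    return rest[rng.integers(len(rest))]


def simulate_variants(spec: SyntheticSpec) -> list[AnnotatedVariant]:
    """Draw the variant set described by ``spec``.

    Returns exactly ``spec.n_total`` variants, sorted by (contig, position),
    with unique genomic keys. VUS/CI variants carry their hidden class in
    ``AnnotatedVariant.truth``; benign/pathogenic variants carry it too (it
    equals the stated label).
    """
    rng = np.random.default_rng(spec.seed)

    strata: list[tuple[ClinicalLabel, ClinicalLabel]] = []
    strata += [(ClinicalLabel.BENIGN, ClinicalLabel.BENIGN)] * spec.n_benign
    strata += [(ClinicalLabel.PATHOGENIC, ClinicalLabel.PATHOGENIC)] * spec.n_pathogenic
    for stated, n in (
        (ClinicalLabel.VUS, spec.n_vus),
        (ClinicalLabel.CONFLICTING, spec.n_ci),
    ):
        hidden = rng.random(n) < 0.5
        strata += [
            (stated, ClinicalLabel.PATHOGENIC if h else ClinicalLabel.BENIGN)
            for h in hidden
        ]

    # Unique positions per contig: draw without replacement from a window
    # comfortably larger than the number of variants on any contig.
    chrom_idx = rng.integers(len(spec.chrom_pool), size=len(strata))
    window = max(1_000_000, 10 * len(strata))
    used: dict[int, set[int]] = {}
    variants: list[AnnotatedVariant] = []
    for (stated, truth), ci in zip(strata, chrom_idx):
        taken = used.setdefault(int(ci), set())
        pos = int(rng.integers(1, window + 1))
        while pos in taken:
            pos = int(rng.integers(1, window + 1))
        taken.add(pos)
        ref = _BASES[rng.integers(4)]
        alt = _BASES[rng.integers(3)]
        if alt == ref:  # remap the collision to the base the draw skipped
            alt = _BASES[3]
        calls: dict[str, str | None] = {}
        for name in PREDICTOR_ORDER:
            code: str | None = _draw_call(
                VOCABULARIES[name], truth, spec.concordance, rng
            )
            if spec.missing_rate > 0 and rng.random() < spec.missing_rate:
                code = None
            calls[name] = code
        variants.append(
            AnnotatedVariant(
                key=VariantKey(spec.chrom_pool[ci], pos, ref, alt),
                clnsig_raw=_CLNSIG[stated],
                calls=calls,
                truth=truth,
            )
        )

    order = {c: i for i, c in enumerate(spec.chrom_pool)}
    variants.sort(key=lambda v: (order[v.key.chrom], v.key.pos))
    return variants


def write_synthetic_vcf(variants: list[AnnotatedVariant], path) -> None:
    """Write variants as a plain VCF 4.2 with CLNSIG and dbNSFP INFO keys.

    Missing calls omit their INFO key entirely. Output is byte-deterministic
    in the input list and round-trips losslessly (labels and call maps)
    through :func:`pathometa.annotation.read_annotated_vcf`.
    """
    if not variants:
        raise ValueError("variants must be nonempty")
    contigs: list[str] = []
    for v in variants:
        if v.key.chrom not in contigs:
            contigs.append(v.key.chrom)
    lines = ["##fileformat=VCFv4.2", "##source=pathometa-synthetic"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        '##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">'
    )
    for name in PREDICTOR_ORDER:
        lines.append(
            f'##INFO=<ID={INFO_KEYS[name]},Number=.,Type=String,'
            f'Description="{name} categorical functional-impact call">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in variants:
        info = [f"CLNSIG={v.clnsig_raw}"]
        info += [
            f"{INFO_KEYS[p]}={v.calls[p]}"
            for p in PREDICTOR_ORDER
            if v.calls.get(p) is not None
        ]
        lines.append(
            "\t".join(
                (
                    v.key.chrom,
                    str(v.key.pos),
                    v.key.rsid or ".",
                    v.key.ref,
                    v.key.alt,
                    ".",
                    ".",
                    ";".join(info),
                )
            )
        )
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
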