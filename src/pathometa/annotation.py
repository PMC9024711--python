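"""Read ClinVar-style VCFs annotated with SnpSift/dbNSFP categorical calls.

The expected INFO dialect is the one SnpSift emits from dbNSFP:
``dbNSFP_<Tool>_pred`` holding one category code per transcript, joined by
',' or '&'. Multi-transcript calls are collapsed to the most severe code
(the conservative reading for a pathogenicity pipeline). `CLNSIG` is kept
verbatim; its interpretation lives in :mod:`pathometa.preprocess`.
"""

from __future__ import annotations

import re
from os import PathLike
from typing import Iterable

from cyvcf2 import VCF

from .variants import AnnotatedVariant, VariantKey
from .vocab import INFO_KEYS, PREDICTOR_ORDER, VOCABULARIES

_SPLIT = re.compile(r"[,&]")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


def aggregate_multivalue_call(predictor: str, values: Iterable[str]) -> str:
    """Collapse per-transcript codes to the single most severe one.

    >>> aggregate_multivalue_call("Polyphen2_HVAR", ["B", "P", "D"])
    'D'
    """
    vocab = VOCABULARIES[predictor]
    vals = list(values)
    if not vals:
        raise ValueError(f"{predictor}: empty value list")
    return min(vals, key=vocab.severity_rank)


def _parse_call(predictor: str, raw: str, context: str) -> str | None:
    codes = [c for c in _SPLIT.split(raw) if c and c != "."]
    if not codes:
        return None
    for c in codes:
        if c not in VOCABULARIES[predictor].categories:
            raise VcfParseError(
                f"{context}: unknown category {c!r} for predictor {predictor}"
            )
    return aggregate_multivalue_call(predictor, codes)


def read_annotated_vcf(path: str | PathLike) -> list[AnnotatedVariant]:
    """Parse a VCF into :class:`AnnotatedVariant` records, in file order.

    Multi-allelic rows are split into one record per ALT allele; the dbNSFP
    calls of the row apply to each split record. Absent dbNSFP keys become
    missing calls; unknown category codes raise :class:`VcfParseError`.
    """
    out: list[AnnotatedVariant] = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            context = f"{path}:{rec.CHROM}:{rec.POS}"
            clnsig = rec.INFO.get("CLNSIG")
            if isinstance(clnsig, tuple):
                clnsig = ",".join(str(c) for c in clnsig)
            calls: dict[str, str | None] = {}
            for name in PREDICTOR_ORDER:
                raw = rec.INFO.get(INFO_KEYS[name])
                if isinstance(raw, tuple):
                    raw = ",".join(str(r) for r in raw)
                calls[name] = (
                    _parse_call(name, str(raw), context) if raw is not None else None
                )
            for alt in rec.ALT:
                out.append(
                    AnnotatedVariant(
                        key=VariantKey(rec.CHROM, rec.POS, rec.REF, alt, rec.ID),
                        clnsig_raw=str(clnsig) if clnsig is not None else "",
                        calls=dict(calls),
                    )
                )
    finally:
        vcf.close()
    return out


def write_prediction_table(results, path) -> None:
    """Write prediction results as a TSV with one row per variant.

    Columns: chrom, pos, ref, alt, rsid ('.' when absent), source_label,
    prob_pathogenic (4 decimals), predicted_label, high_confidence.
    """
    header = (
        "chrom\tpos\tref\talt\trsid\tsource_label\t"
        "prob_pathogenic\tpredicted_label\thigh_confidence"
    )
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write(header + "\n")
        for r in results:
            k = r.key
            fh.write(
                f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\t{k.rsid or '.'}\t"
                f"{r.source_label.value}\t{r.prob_pathogenic:.4f}\t"
                f"{r.predicted_label.value}\t{int(r.high_confidence)}\n"
            )
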