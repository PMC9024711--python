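import numpy as np
import pytest

from pathometa.preprocess import FeatureTable
from pathometa.variants import AnnotatedVariant, ClinicalLabel, VariantKey
from pathometa.vocab import PREDICTOR_ORDER, VOCABULARIES


def make_variant(calls, clnsig="Benign", chrom="1", pos=1, ref="A", alt="C",
                 rsid=None, truth=None):
    return AnnotatedVariant(
        key=VariantKey(chrom, pos, ref, alt, rsid),
        clnsig_raw=clnsig,
        calls=dict(calls),
        truth=truth,
    )


def make_table(rows_calls, labels=None, predictors=PREDICTOR_ORDER):
    """Build a FeatureTable from a list of call dicts (predictor -> code)."""
    if labels is None:
        labels = [ClinicalLabel.BENIGN] * len(rows_calls)
    rows = [
        make_variant(calls, pos=i + 1, clnsig=label.value.capitalize())
        for i, (calls, label) in enumerate(zip(rows_calls, labels))
    ]
    return FeatureTable(rows, list(labels), tuple(predictors))


def random_toy_table(rng, predictors, n):
    """Random complete-case table over a subset of predictors."""
    rows = []
    for _ in range(n):
        rows.append(
            {p: VOCABULARIES[p].categories[rng.integers(len(VOCABULARIES[p].categories))]
             for p in predictors}
        )
    return make_table(rows, predictors=tuple(predictors))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
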