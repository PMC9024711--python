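"""Encodings: label/one-hot layout, MCA vs brute-force oracle, autoencoder."""

import numpy as np
import pytest

from conftest import make_table, random_toy_table
from helpers import assert_equal_up_to_sign, mca_row_coords_oracle
from pathometa.encoders import (
    AutoencoderConfig,
    encode_label,
    encode_onehot,
    fit_autoencoder,
    fit_mca,
    onehot_column_names,
    transform_mca,
)
from pathometa.vocab import N_CATEGORIES, N_PREDICTORS, PREDICTOR_ORDER, VOCABULARIES

MOST = {p: VOCABULARIES[p].most_severe for p in PREDICTOR_ORDER}
LEAST = {p: VOCABULARIES[p].least_severe for p in PREDICTOR_ORDER}


def cycling_table(n):
    """n rows cycling each predictor independently through its categories."""
    rows = []
    for i in range(n):
        rows.append(
            {p: VOCABULARIES[p].categories[i % len(VOCABULARIES[p].categories)]
             for p in PREDICTOR_ORDER}
        )
    return make_table(rows)


# -- label encoding --------------------------------------------------------


def test_label_codes_lexicographic():
    table = make_table(
        [
            {**MOST, "FATHMM": "D", "Polyphen2_HDIV": "B"},
            {**MOST, "FATHMM": "T", "Polyphen2_HDIV": "P"},
            {**MOST, "FATHMM": "T", "Polyphen2_HDIV": "D"},
        ]
    )
    X = encode_label(table)
    assert X.d == N_PREDICTORS
    i_f = X.column_names.index("FATHMM")
    i_h = X.column_names.index("Polyphen2_HDIV")
    assert list(X.values[:, i_f]) == [0, 1, 1]  # D=0, T=1
    assert list(X.values[:, i_h]) == [0, 2, 1]  # B=0, D=1, P=2


def test_label_identical_rows_identical_codes():
    X = encode_label(make_table([MOST, MOST]))
    assert (X.values[0] == X.values[1]).all()


# -- one-hot ---------------------------------------------------------------


def test_onehot_shape_and_row_sums():
    table = cycling_table(12)
    Z = encode_onehot(table)
    assert Z.values.shape == (12, N_CATEGORIES) == (12, 23)
    assert (Z.values.sum(axis=1) == N_PREDICTORS).all()
    assert set(np.unique(Z.values)) <= {0, 1}
    # one 1 per predictor block
    start = 0
    for p in PREDICTOR_ORDER:
        k = len(VOCABULARIES[p].categories)
        assert (Z.values[:, start : start + k].sum(axis=1) == 1).all()
        start += k


def test_onehot_specific_columns():
    Z = encode_onehot(make_table([{**MOST, "SIFT": "D"}]))
    names = Z.column_names
    assert Z.values[0, names.index("SIFT=D")] == 1
    assert Z.values[0, names.index("SIFT=T")] == 0


def test_onehot_empty_table():
    Z = encode_onehot(make_table([]))
    assert Z.values.shape == (0, 23)


def test_onehot_argmax_recovers_label_codes():
    table = cycling_table(10)
    Z, L = encode_onehot(table), encode_label(table)
    start = 0
    for j, p in enumerate(PREDICTOR_ORDER):
        k = len(VOCABULARIES[p].categories)
        assert (Z.values[:, start : start + k].argmax(axis=1) == L.values[:, j]).all()
        start += k


# -- MCA -------------------------------------------------------------------


def test_mca_matches_bruteforce_oracle_on_random_tables(rng):
    subsets = [
        ("FATHMM", "Polyphen2_HDIV", "MutationAssessor"),
        ("SIFT", "LRT", "MutationTaster"),
        PREDICTOR_ORDER,
    ]
    for trial in range(24):
        predictors = subsets[trial % len(subsets)]
        table = random_toy_table(rng, predictors, n=int(rng.integers(6, 30)))
        Z = encode_onehot(table)
        if np.unique(Z.values, axis=0).shape[0] < 3:
            continue
        model = fit_mca(Z)
        coords = transform_mca(model, Z)
        F_oracle, sig_oracle = mca_row_coords_oracle(Z.values)
        assert_equal_up_to_sign(coords.values, F_oracle, atol=1e-8)
        np.testing.assert_allclose(
            model.all_singular_values, sig_oracle, atol=1e-10
        )


def test_mca_total_inertia_closed_form():
    """All 23 categories observed: inertia = (J - Q)/Q = 15/8."""
    model = fit_mca(encode_onehot(cycling_table(12)))
    assert model.total_inertia == pytest.approx(15 / 8, abs=1e-10)


def test_mca_parseval(rng):
    """Sum of squared singular values equals (J_observed - Q)/Q."""
    table = random_toy_table(rng, PREDICTOR_ORDER, n=40)
    Z = encode_onehot(table)
    model = fit_mca(Z)
    j_obs = int((np.asarray(Z.values).sum(axis=0) > 0).sum())
    assert np.sum(model.all_singular_values**2) == pytest.approx(
        (j_obs - N_PREDICTORS) / N_PREDICTORS, abs=1e-10
    )


def test_mca_duplicate_rows_identical_coordinates(rng):
    table = random_toy_table(rng, PREDICTOR_ORDER, n=10)
    doubled = make_table(
        [{p: v.calls[p] for p in PREDICTOR_ORDER} for v in table.rows] * 2
    )
    model = fit_mca(encode_onehot(doubled))
    coords = transform_mca(model, encode_onehot(doubled)).values
    np.testing.assert_allclose(coords[:10], coords[10:], atol=1e-12)


def test_mca_too_few_distinct_rows():
    with pytest.raises(ValueError):
        fit_mca(encode_onehot(make_table([MOST, MOST, LEAST])))


def test_mca_deterministic_sign(rng):
    table = random_toy_table(rng, PREDICTOR_ORDER, n=25)
    Z = encode_onehot(table)
    a, b = fit_mca(Z), fit_mca(Z)
    np.testing.assert_array_equal(a.principal_axes, b.principal_axes)
    for k in range(2):
        j = np.argmax(np.abs(a.principal_axes[:, k]))
        assert a.principal_axes[j, k] > 0


# -- autoencoder -----------------------------------------------------------


def synthetic_onehot(n, rng):
    from pathometa.preprocess import filter_complete_cases
    from pathometa.synthetic import SyntheticSpec, simulate_variants

    spec = SyntheticSpec(
        n_benign=n // 2, n_pathogenic=n - n // 2, n_vus=0, n_ci=0,
        concordance=0.9, missing_rate=0.0, seed=int(rng.integers(2**31)),
    )
    table, _ = filter_complete_cases(simulate_variants(spec))
    return encode_onehot(table)


@pytest.mark.parametrize("activation", ["rectifier", "rectifier_dropout", "tanh"])
def test_autoencoder_loss_decreases(rng, activation):
    Z = synthetic_onehot(500, rng)
    ae = fit_autoencoder(Z, AutoencoderConfig(epochs=10, seed=0, activation=activation))
    assert ae.loss_history_[-1] < ae.loss_history_[0]


def test_autoencoder_shape_and_determinism(rng):
    Z = synthetic_onehot(200, rng)
    cfg = AutoencoderConfig(hidden_units=10, epochs=5, seed=3)
    r1 = fit_autoencoder(Z, cfg).transform(Z)
    r2 = fit_autoencoder(Z, cfg).transform(Z)
    assert r1.values.shape == (Z.n, 2)
    np.testing.assert_array_equal(r1.values, r2.values)


def test_autoencoder_separates_distinct_patterns():
    """Two distinct input patterns map to distinct bottleneck points."""
    table = make_table([MOST] * 20 + [LEAST] * 20)
    Z = encode_onehot(table)
    ae = fit_autoencoder(Z, AutoencoderConfig(epochs=10, seed=0))
    rep = ae.transform(Z).values
    between = np.linalg.norm(rep[0] - rep[-1])
    within = max(
        np.abs(rep[:20] - rep[0]).max(), np.abs(rep[20:] - rep[-1]).max()
    )
    assert between > 0
    assert between > within


def test_autoencoder_config_validation():
    with pytest.raises(ValueError):
        AutoencoderConfig(activation="sigmoid")
    with pytest.raises(ValueError):
        AutoencoderConfig(epochs=0)
    with pytest.raises(ValueError):
        AutoencoderConfig(hidden_units=1)


def test_onehot_column_names_count():
    assert len(onehot_column_names()) == 23
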