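"""Independent oracles used by the unit and acceptance tests.

These deliberately re-derive quantities from their textbook definitions
(dense SVD assembled literally, exhaustive pair counting, closed-form
posteriors) and never call the package code paths they check.
"""

import itertools

import numpy as np

from pathometa.vocab import VOCABULARIES


def mca_row_coords_oracle(Z, n_dims=2):
    """Row principal coordinates of an indicator matrix by brute force.

    Assembles P = Z/(nQ), the masses, S = D_r^{-1/2}(P - r c^T)D_c^{-1/2}
    column by column, and runs a dense SVD. Columns with zero mass are
    dropped (they carry no inertia). Returns (coords n x n_dims,
    singular values of S excluding numerical zeros).
    """
    Z = np.asarray(Z, dtype=float)
    n, J = Z.shape
    Q = Z[0].sum()
    P = Z / (n * Q)
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    keep = c > 0
    S = np.empty((n, int(keep.sum())))
    for i in range(n):
        for jj, j in enumerate(np.flatnonzero(keep)):
            S[i, jj] = (P[i, j] - r[i] * c[j]) / np.sqrt(r[i] * c[j])
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)
    F = (U / np.sqrt(r)[:, None]) * sig
    return F[:, :n_dims], sig[sig > 1e-12]


def assert_equal_up_to_sign(A, B, atol):
    """Per-column comparison allowing an overall sign flip per column."""
    A, B = np.asarray(A), np.asarray(B)
    assert A.shape == B.shape
    for k in range(A.shape[1]):
        d_plus = np.max(np.abs(A[:, k] - B[:, k]))
        d_minus = np.max(np.abs(A[:, k] + B[:, k]))
        assert min(d_plus, d_minus) < atol, (
            f"axis {k}: min sign-invariant deviation {min(d_plus, d_minus)}"
        )


def auc_pair_count_oracle(y, scores):
    """AUC as the exhaustive concordant-pair fraction (Mann-Whitney)."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        if p > q:
            total += 1.0
        elif p == q:
            total += 0.5
    return total / (len(pos) * len(neg))


def generator_posterior_oracle(table, concordance):
    """Closed-form P(pathogenic | calls) of the synthetic generator.

    Assumes balanced priors and the generator's class-conditional model:
    the class-consistent extreme category with probability `concordance`,
    uniform over the rest otherwise.
    """
    scores = []
    for v in table.rows:
        lp, lb = 0.0, 0.0
        for p in table.predictor_order:
            vocab = VOCABULARIES[p]
            k = len(vocab.categories)
            code = v.calls[p]
            p_path = concordance if code == vocab.most_severe else (1 - concordance) / (k - 1)
            p_ben = concordance if code == vocab.least_severe else (1 - concordance) / (k - 1)
            lp += np.log(p_path)
            lb += np.log(p_ben)
        scores.append(1.0 / (1.0 + np.exp(lb - lp)))
    return np.array(scores)


def planted_onehot_matrix(rng, n, informative="PROVEAN", signal=0.8,
                          predictor_order=None):
    """One-hot matrix + labels where only one predictor carries signal.

    The informative predictor emits its most severe code with probability
    `signal` for pathogenic rows and least severe for benign; every other
    predictor draws uniformly, independent of the label.
    """
    from pathometa.encoders import onehot_column_names
    from pathometa.vocab import PREDICTOR_ORDER

    order = predictor_order or PREDICTOR_ORDER
    names = onehot_column_names(order)
    y = np.zeros(n, dtype=int)
    y[n // 2 :] = 1
    Z = np.zeros((n, len(names)), dtype=int)
    col = {name: j for j, name in enumerate(names)}
    for i in range(n):
        for p in order:
            vocab = VOCABULARIES[p]
            cats = vocab.categories
            if p == informative:
                target = vocab.most_severe if y[i] == 1 else vocab.least_severe
                if rng.random() < signal:
                    code = target
                else:
                    rest = [c for c in cats if c != target]
                    code = rest[rng.integers(len(rest))]
            else:
                code = cats[rng.integers(len(cats))]
            Z[i, col[f"{p}={code}"]] = 1
    return Z, names, y
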