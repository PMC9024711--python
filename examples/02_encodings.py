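"""The four numeric representations of the categorical calls.

Label encoding keeps 8 integer columns; one-hot expands to the 23-column
indicator matrix; MCA and the bottleneck autoencoder compress the indicator
matrix to 2 dimensions.
"""

import numpy as np

from pathometa import (
    AutoencoderConfig,
    SyntheticSpec,
    encode_label,
    encode_onehot,
    filter_complete_cases,
    fit_autoencoder,
    fit_mca,
    simulate_variants,
    transform_mca,
)

spec = SyntheticSpec(n_benign=300, n_pathogenic=300, n_vus=0, n_ci=0,
                     concordance=0.9, missing_rate=0.0, seed=7)
table, _ = filter_complete_cases(simulate_variants(spec))

L = encode_label(table)
Z = encode_onehot(table)
print(f"label encoding:  {L.values.shape} integer matrix, "
      f"columns {L.column_names[:2]}...")
print(f"one-hot:         {Z.values.shape} binary matrix, row sums all "
      f"{int(np.asarray(Z.values).sum(axis=1)[0])} (one category per predictor)")

mca = fit_mca(Z)
coords = transform_mca(mca, Z)
print(f"MCA:             {coords.values.shape}, "
      f"singular values {np.round(mca.singular_values, 4)}, "
      f"total inertia {mca.total_inertia:.4f} "
      f"(= (J-Q)/Q = 15/8 when all 23 categories are observed)")

ae = fit_autoencoder(Z, AutoencoderConfig(hidden_units=20, epochs=10, seed=0))
rep = ae.transform(Z)
print(f"autoencoder:     {rep.values.shape}, reconstruction MSE "
      f"{ae.loss_history_[0]:.4f} -> {ae.loss_history_[-1]:.4f} over "
      f"{ae.config.epochs} epochs (lower is a better reconstruction)")

# The 2-D representations should separate the classes visibly: compare the
# class centroids in MCA space.
y = table.binary_labels()
c0 = coords.values[y == 0].mean(axis=0)
c1 = coords.values[y == 1].mean(axis=0)
print(f"MCA class centroid distance: {np.linalg.norm(c0 - c1):.3f} "
      "(benign vs pathogenic are far apart on the first axes)")
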