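"""Matrix hygiene: coverage filtering and KNN imputation.

Masks 5% of a synthetic beta matrix plus one poorly covered CpG, drops CpGs
missing in more than 30% of samples, and imputes the rest from the 5
nearest CpGs (Euclidean distance over shared samples).
"""

import numpy as np
import pandas as pd

import stemtoc as st

rng = np.random.default_rng(5)
signal = rng.uniform(0.2, 0.8, size=30)
vals = np.clip(signal + rng.normal(0, 0.03, size=(60, 30)), 0, 1)
mask = rng.uniform(size=vals.shape) < 0.05
vals[mask] = np.nan
vals[0, :15] = np.nan  # 50% missing -> should be dropped
m = st.BetaMatrix(pd.DataFrame(vals, index=[f"cg{i:03d}" for i in range(60)],
                               columns=[f"s{j}" for j in range(30)]))
print(f"input: {m.shape[0]} CpGs, {m.n_missing} missing cells")

filtered = st.filter_by_coverage(m, max_missing_frac=0.30)
print(f"after coverage filter (>30% missing removed): {filtered.shape[0]} CpGs")

imputed = st.knn_impute(filtered, k=5)
print(f"after KNN imputation (k=5): {imputed.n_missing} missing cells")
print("-> observed cells are untouched; imputed values are the mean of the "
      "5 most similar CpGs at that sample, clipped to [0, 1].")
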