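"""Grade a bruised phantom cohort with the full MAM + LS-SVM pipeline.

Streams a cohort of bruised phantoms through triage, selects characteristic
bands from the pooled PC2 weight curve, extracts 24 MAM features per fruit,
splits 3:1 with stratified Kennard-Stone, tunes (gamma, sigma) by 5-fold CV
and reports held-out accuracy.  A small cohort keeps this example fast; the
acceptance script runs the full 187-fruit study layout.
"""

import numpy as np

from hsibruise.pipeline import RunConfig, run_grade

cfg = RunConfig(counts={"I": 8, "II": 8, "III": 8, "IV": 8}, seed=11)
res = run_grade(cfg)

print("selected bands (nm):", np.round(res.bands.wavelengths_nm, 1))
print(f"hyperparameters: gamma={res.gamma:g}, sigma={res.sigma:g}")
print(f"train/test: {len(res.split_train)}/{len(res.split_test)}")
print(f"test accuracy: {res.confusion.accuracy:.2%}\n")
print(res.confusion.counts)
# Rows are true grades, columns predictions; residual errors, when they
# occur, sit between adjacent grades whose depression depths overlap.
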