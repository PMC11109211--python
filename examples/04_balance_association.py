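"""Association between class balance and leakage bias.

Runs the paired protocol with SMOTE on label-free datasets of increasing
balance ratio and regresses the mean AUC bias on the balance: the more
imbalanced the data, the more synthetic rows are generated, and the larger
the leakage bias.  (Small grids and few repeats for speed.)
"""

import warnings

import numpy as np

from cvbias import (
    CVScheme, ModelGrid, SyntheticSpec, associate_with_balance, compute_bias,
    generate_radiomics_like, preprocess, run_correct, run_incorrect,
)
from cvbias.resamplers import ResamplerSpec

warnings.filterwarnings("ignore")

grid = ModelGrid(scorers=("anova",), n_features_grid=(4,), classifiers=("naive_bayes",))
variants = [ResamplerSpec("smote", k=5)]
balances = (1.0, 2.0, 3.0, 4.0)
biases = []
for bal in balances:
    table = preprocess(generate_radiomics_like(SyntheticSpec(
        n_samples=120, n_features=60, n_informative=0, effect_size=0.0,
        balance=bal, seed=3,
    )))
    cv = CVScheme(n_repeats=5, base_seed=3)
    c = run_correct(table, "smote", grid, cv, variants=variants)
    i = run_incorrect(table, "smote", grid, cv, variants=variants)
    bias = np.mean([r.bias.auc for r in compute_bias(f"bal{bal}", c, i)])
    biases.append(bias)
    print(f"balance {bal:.0f}: mean AUC bias {bias:+.3f}")

res = associate_with_balance(biases, balances)
print(f"\nOLS: bias = {res.intercept:+.3f} + {res.slope:.3f} x balance "
      f"(r = {res.r:.3f}, p = {res.p_value:.3g})")
print("A positive, significant slope reproduces the balance-bias association.")
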