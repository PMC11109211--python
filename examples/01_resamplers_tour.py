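"""Tour of the seven resamplers on one imbalanced table.

Builds an 80/20 radiomics-like dataset and applies every rebalancing method,
printing the resulting class counts and how many rows are synthetic.
Synthetic rows carry provenance (their parent rows), which is what the
leakage audit downstream uses: a synthetic row in a test fold whose parent
sits in the training fold is leaked information.
"""

from cvbias import SyntheticSpec, generate_radiomics_like, preprocess, resample
from cvbias.resamplers import METHODS, ResamplerSpec

table = preprocess(generate_radiomics_like(
    SyntheticSpec(n_samples=100, n_features=40, n_informative=5,
                  effect_size=0.8, balance=4.0, seed=0)
))
c = table.class_counts()
print(f"input: {c[0]} majority / {c[1]} minority (balance {c[0]/c[1]:.1f})\n")

for method in METHODS:
    if method == "none":
        continue
    spec = ResamplerSpec(method)
    out = resample(table, spec, seed=0)
    counts = out.class_counts()
    n_syn = int(out.synthetic_mask.sum())
    print(f"{spec.label:<28} -> {counts[0]:>3} / {counts[1]:>3}  "
          f"({n_syn} synthetic, {out.n - n_syn} original rows kept)")

print("\nOversamplers equalize the classes by generating synthetic minority")
print("rows; undersamplers discard majority rows and never synthesize.")
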