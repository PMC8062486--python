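"""Repeated ten-fold cross-validation of the selected model.

Partitions the records into 10 folds stratified by subspecies, refits on
each 90% training set, predicts the held-out 10%, and reports one R^2 per
repeat on the pooled held-out predictions.  Under the study's 19 mg noise
the average R^2 lands around 0.93-0.95: the curve explains most of the
lens-weight variation out of sample.
"""

from lensage import FitSpec, GeneratorConfig, generate_dataset, repeated_kfold_cv

data = generate_dataset(GeneratorConfig(seed=1))
res = repeated_kfold_cv(
    data, FitSpec(share_a=False, share_b=True), repeats=20, folds=10, seed=1
)
print(f"{res.repeats} repeats of {res.folds}-fold CV, n = {len(data)}")
print(f"mean held-out R^2 = {res.r2_mean:.4f}")
print(f"range across repeats = [{res.r2_per_repeat.min():.4f}, {res.r2_per_repeat.max():.4f}]")
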