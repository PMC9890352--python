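"""3-fold cross-validation over several seeds on a synthetic labeled cohort.

Each run trains the model on two partitions and scores the held-out one;
comparable training and hold-out correlations argue the model does not
overfit.
"""

from noctograph import LabeledUser, compute_fingerprint, kfold_validate, localize
from noctograph.synthetic import SyntheticSpec, simulate_cohort

cohort = simulate_cohort(SyntheticSpec(n_users=45, posts_per_user=600, seed=7))
users = [
    LabeledUser(u.author_id,
                compute_fingerprint(localize(u.epochs, u.tz_name)),
                u.true_bedtime)
    for u in cohort
]

report = kfold_validate(users, k=3, seeds=(0, 1, 2))
print(f"{len(report.runs)} validation rows "
      f"({report.runs.seed.nunique()} seeds x 3 folds)")
tr, ho = report.summaries["train_corr"], report.summaries["holdout_corr"]
print(f"training   median corr {tr['median']:.3f} "
      f"(IQR {tr['iqr'][0]:.3f}-{tr['iqr'][1]:.3f})")
print(f"hold-out   median corr {ho['median']:.3f} "
      f"(IQR {ho['iqr'][0]:.3f}-{ho['iqr'][1]:.3f})")

# A hold-out median close to the training median means the fitted curve
# generalizes to users it never saw.
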