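"""Simulate a small cohort and extract the 6-D signature features.

Generates 9 synthetic subjects (25 genuine + 25 skilled forgeries each),
preprocesses every trajectory to 5000 unit-square samples and prints the
per-class feature means: forgeries should show higher and more dispersed
entropy/complexity than genuine signatures.
"""

import sigquant as sq
from sigquant.synth import GeneratorConfig, simulate_cohort

cohort = simulate_cohort(GeneratorConfig(n_subjects=9, seed=20161201))
features = sq.extract_features(cohort.signatures)

print(f"{len(features)} signatures from {features['subject_id'].nunique()} subjects")
print()
cols = list(sq.FEATURE_COLUMNS)
per_subject = features.groupby(["authenticity", "subject_id"])[cols]
stats = (
    per_subject.mean().groupby("authenticity").mean().T.add_suffix("_mean")
    .join(per_subject.std().groupby("authenticity").mean().T.add_suffix("_sd"))
)
print(stats.round(4))
print()
print("Per-subject means and within-subject SDs, averaged over subjects")
print("(G = genuine, F = forgery).  Forgeries sit higher in entropy (h_*)")
print("and complexity (c_*), lower in Fisher information (f_*), and every")
print("feature is more dispersed within a subject's forgeries -- the")
print("signature of deliberate, tremulous imitation.")
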