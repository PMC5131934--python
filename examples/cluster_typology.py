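"""Signature typology: cluster subjects by their entropy summaries.

Builds per-subject (mean, SD) entropy summaries over genuine signatures,
clusters them hierarchically and with neighbor-joining, cuts the
dendrogram into three groups and compares against the generator's planted
low/medium/high stroke-complexity classes.  Also fits the parallelepiped
(min-max box) classifier on the recovered groups.
"""

import numpy as np

import sigquant as sq
from sigquant.classify import (
    distance_matrix,
    hierarchical_tree,
    neighbor_joining_tree,
    parallelepiped_fit,
    parallelepiped_predict,
    summarize_subjects,
)
from sigquant.synth import GeneratorConfig, simulate_cohort

cohort = simulate_cohort(GeneratorConfig(n_subjects=15, seed=20161201))
features = sq.extract_features(cohort.signatures)
summaries = summarize_subjects(features)  # genuine signatures only

dist, labels = distance_matrix(summaries, quantifier="entropy", metric="euclidean")
tree = hierarchical_tree(dist, labels)
members = tree.cut(n_clusters=3)

print("subject  cluster  planted_class")
for subject in labels:
    print(f"{subject:>7}  {members[subject]:>7}  {cohort.complexity_classes[subject]}")

nj = neighbor_joining_tree(dist, labels)
print()
print("neighbor-joining tree (newick, midpoint-rooted):")
print(str(nj).strip())

# parallelepiped boxes on the entropy summary plane, per recovered cluster
pts = {
    str(c): np.array([summaries.loc[s, ["mean_h_x", "mean_h_y"]] for s in labels
                      if members[s] == c], dtype=float)
    for c in sorted(set(members.values()))
}
model = parallelepiped_fit(pts)
probe = summaries[["mean_h_x", "mean_h_y"]].iloc[0].to_numpy()
print()
print(f"parallelepiped class of {labels[0]}: {parallelepiped_predict(model, probe)}")
print("Clusters should align with the planted classes: ordinal entropy")
print("tracks how many strokes and direction changes a signature has.")
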