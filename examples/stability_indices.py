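"""Per-subject stability of genuine signatures.

Computes the global (Jensen-Shannon, eta) and local (Jensen-Fisher, xi)
instability indices over each synthetic subject's genuine ensemble and
prints them next to the planted stroke-complexity class.
"""

from sigquant.ordinal import OrdinalConfig, bandt_pompe_distribution
from sigquant.preprocess import preprocess
from sigquant.stability import SubjectEnsemble, instability_frame
from sigquant.synth import GeneratorConfig, simulate_cohort

cohort = simulate_cohort(GeneratorConfig(n_subjects=6, seed=20161201))
cfg = OrdinalConfig(5, 1)

per_subject: dict[str, tuple[list, list]] = {}
for sig in cohort.signatures:
    if sig.authenticity != "genuine":
        continue
    traj = preprocess(sig)
    dx, dy = per_subject.setdefault(sig.subject_id, ([], []))
    dx.append(bandt_pompe_distribution(traj.x, cfg))
    dy.append(bandt_pompe_distribution(traj.y, cfg))

ensembles = [SubjectEnsemble(sid, dx, dy) for sid, (dx, dy) in sorted(per_subject.items())]
frame = instability_frame(ensembles, class_labels=cohort.complexity_classes)
print(frame.round(4).to_string(index=False))
print()
print("eta_* is the square root of the Jensen-Shannon divergence over the")
print("25 genuine ordinal distributions (global inconsistency of a writer);")
print("xi_* is the Jensen-Fisher analogue (local, ordering-sensitive).")
print("Small values mean a stable writer whose features are trustworthy.")
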