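"""Healthy-like vs CHF-like surrogate cohorts: group curvature summaries,
mvac, and the Welch significance test.

Each surrogate subject is a randomized cascade; the chf-like profile
narrows the spectrum (raising its vertex curvature), emulating the loss
of multifractality in congestive heart failure.
"""

import mfhrv as M


def analyze(tg):
    spectrum = M.compute_spectrum(M.to_measure(tg))
    return M.SubjectRecord(
        subject_id=tg.subject_id, condition=tg.condition, nyha=tg.nyha,
        segment="h24", metrics=M.compute_shape_metrics(spectrum),
        profile=M.curvature_profile(spectrum))


groups = {}
for profile, seed in [("healthy_like", 10), ("chf_like", 20)]:
    cohort = M.make_cohort(profile, n=12, seed=seed, length_m=12)
    groups[profile] = [analyze(tg) for tg in cohort]

for label, recs in groups.items():
    g = M.average_profile(recs, group_label=label)
    sym = g.symmetry
    print(f"{label:13s} n={g.n}  mvac={g.mvac:8.2f} +- {g.mvac_err:6.2f} "
          f"(sem) at q={g.mvac_argmax_q:+.2f}  "
          f"right/left skew counts: {sym.right_count}/{sym.left_count}")

res = M.welch_test([r.metrics.k_max for r in groups["healthy_like"]],
                   [r.metrics.k_max for r in groups["chf_like"]])
print(f"Welch test on per-subject K_max: t={res.t:.2f}, p={res.p:.2e}, "
      f"significant at 0.05: {res.significant}")

# mvac (maximum of the average curvature profile) separates the groups:
# the chf-like cohort's spiky spectra give a far larger value, and the
# per-subject curvature maxima differ significantly.
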