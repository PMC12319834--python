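"""Behavioral PLS on a synthetic lifespan cohort with planted couplings.

The cohort generator plants two latent components whose age trajectories are
built from the piecewise quadratic polynomials knotted at 55 years (component
1 monotone across the lifespan, component 2 an inverted U peaking at 55), and
couples them into both the brain-feature block and the eight task scores.
PLS recovers the components via the SVD of the cross-covariance; the
permutation test gives component significance, and bootstrap sampling ratios
(|BSR| >= 3 = robust) flag the contributing features. The sign pattern of the
two age-polynomial saliences diagnoses the trajectory shape: opposite signs =
linear trend, same signs = inverted U.
"""

import numpy as np

import brainstates as bs
from brainstates.pls import bootstrap_bsr, fdr_adjust, permutation_test, pls_svd, prepare_cognitive_block

n = 200
rng = np.random.default_rng(0)
q, _ = np.linalg.qr(rng.normal(size=(12, 2)))
cohort_cfg = bs.CohortConfig(n_subjects=n, salience_brain=q.T, seed=5)
brain = np.random.default_rng(1).normal(size=(n, 12))
cohort, truth, X = bs.simulate_cohort(brain, cohort_cfg)

Y, y_names = prepare_cognitive_block(cohort, knot=55.0)
res = pls_svd(X, Y, y_columns=y_names)
res.perm_p = permutation_test(X, Y, n_perm=500, seed=2, result=res)
res = bootstrap_bsr(X, Y, n_boot=200, seed=3, result=res)

print("component  sing.value  explained  perm p (FDR)")
fdr = fdr_adjust(res.perm_p)
for i in range(3):
    print(f"    {i+1}      {res.singular_values[i]:8.3f}   {res.explained_fraction[i]:7.1%}"
          f"   {fdr[i]:.4f}")

r1 = abs(np.corrcoef(truth["salience_brain"][0], res.brain_saliences[:, 0])[0, 1])
print(f"|corr(planted, recovered)| for component 1 brain salience: {r1:.3f}")

i_asc, i_desc = y_names.index("age_ascending"), y_names.index("age_descending")
for i, label in ((0, "component 1"), (1, "component 2")):
    asc, desc = res.cognitive_saliences[i_asc, i], res.cognitive_saliences[i_desc, i]
    kind = "linear-like" if asc * desc < 0 else "inverted-U"
    print(f"{label}: age saliences ({asc:+.2f}, {desc:+.2f}) -> {kind} trajectory")

salient = [y_names[j] for j in range(len(y_names)) if abs(res.bsr_cognitive[j, 0]) >= 3]
print("robust cognitive features for component 1 (|BSR| >= 3):", ", ".join(salient))
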