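"""Fixel-wise group comparison with permutation FWE correction.

Simulates a two-group cohort around a template fixel mask: group B has its
fibre density reduced by 30% in a planted "tract" (a fixed subset of
fixels), with multiplicative log-normal noise everywhere.  Each subject is
matched to the template by angular correspondence, a GLM contrasts the
groups at every fixel, and family-wise error over all fixels is controlled
with max-statistic permutation testing.

The printout reports how much of the planted tract reaches corrected
significance and whether anything outside it does (it should not, at the
5% family-wise level).
"""

import numpy as np

from fixel.stats import DesignMatrix, analyse_cohort, make_synthetic_cohort
from fixel.phantom import PhantomSpec, make_phantom

spec = PhantomSpec(length_vox=16, height_vox=16, width_vox=6.0)
template = make_phantom(spec)
F = template.n_fixels

rng = np.random.default_rng(0)
tract = np.zeros(F, dtype=bool)
tract[rng.choice(F, size=F // 8, replace=False)] = True

n = 12
group_a, group_b = make_synthetic_cohort(template, n, effect=0.7,
                                         noise_sd=0.1, seed=0,
                                         effect_mask=tract)
design = DesignMatrix.two_group(n, n)
result = analyse_cohort("fd", group_a + group_b, template, design,
                        n_perm=1000, seed=0)

print(f"template: {F} fixels; planted 30% FD reduction in "
      f"{int(tract.sum())} fixels; {n} subjects per group")
print(f"significant fixels (FWE p < 0.05): {int(result.sig_mask.sum())}")
print(f"  inside the planted tract : {int(result.sig_mask[tract].sum())}"
      f" / {int(tract.sum())}")
print(f"  outside (false positives): {int(result.sig_mask[~tract].sum())}")
print(f"smallest corrected p-value: {result.p_fwe.min():.4f}")
print("the planted reduction is recovered while FWE keeps the rest clean; "
      "group A > B\nshows up in the negative-contrast mask as "
      f"{int(result.sig_mask_positive.sum())} positive fixels.")
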