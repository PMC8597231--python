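"""Junction-corrected (spliced-mRNA) editing levels vs overall levels.

Restricting the VAF denominator to reads whose record or mate spans a
splice junction enriches for mature mRNA; comparing the two levels per
site (Wilcoxon rank-sum, exact for small n) exposes sites where editing
and splicing interact.
"""

import numpy as np

from editarm.quantify import compare_overall_vs_mrna, exact_rank_sum_p

rng = np.random.default_rng(1)
n_samples = 8

# a site edited co-transcriptionally: pre-mRNA carries more editing than
# spliced mRNA, so the overall VAF exceeds the spliced VAF
overall = rng.beta(20, 60, n_samples)           # ~0.25
spliced = rng.beta(8, 72, n_samples)            # ~0.10
diff, p = compare_overall_vs_mrna(overall, spliced)
print(f"depleted-in-mRNA site: mean diff = {diff:+.3f}, p = {p:.4f}")

# a site with no splicing association
overall = rng.beta(12, 68, n_samples)
spliced = rng.beta(12, 68, n_samples)
diff, p = compare_overall_vs_mrna(overall, spliced)
print(f"neutral site:          mean diff = {diff:+.3f}, p = {p:.4f}")

print(f"textbook exact check:  p({{1,2,3}} vs {{4,5,6}}) = "
      f"{exact_rank_sum_p([1, 2, 3], [4, 5, 6]):.3f}")
# A positive difference with small p marks sites where spliced mRNA is
# less edited than the total RNA pool (pre-mRNA included).
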