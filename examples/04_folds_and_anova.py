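"""Fold bookkeeping and the ANOVA comparison of two methods' DSC."""

import numpy as np

from fibroseg import anova_dsc, make_folds, summarize

split = make_folds([f"study{i:02d}" for i in range(32)], k=5, seed=17)
print("32 studies into 5 folds:", split.sizes(), "(4 folds of 6, 1 of 8)")

rng = np.random.default_rng(3)
dsc_a = rng.normal(95.9, 1.6, 10)   # per-study test DSC, method A
dsc_b = rng.normal(95.6, 1.8, 10)   # method B
sa, sb = summarize(dsc_a), summarize(dsc_b)
print(f"method A: {sa.mean:.2f} ± {sa.std:.2f}% (CI95 ± {sa.ci95:.2f})")
print(f"method B: {sb.mean:.2f} ± {sb.std:.2f}% (CI95 ± {sb.ci95:.2f})")
res = anova_dsc(dsc_a, dsc_b)
verdict = "different" if res.significant else "not statistically different"
print(f"one-way ANOVA: F = {res.F:.3f}, F_crit = {res.F_crit:.3f}, "
      f"p = {res.p_value:.3f} -> {verdict}")
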