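"""Agreement statistics: Cohen kappa, ICC and wall-motion-group ANOVA.

Computes chance-corrected agreement of the packaged culprit-artery
confusion table, an inter-observer ICC on simulated paired SVEF readings,
and a one-way ANOVA across simulated wall-motion score groups.
"""

import numpy as np

from svef3d import cohen_kappa, icc, oneway_anova_bonferroni
from svef3d.io import fixture_confusion_matrix

kap = cohen_kappa(fixture_confusion_matrix())
print(f"culprit-artery agreement: {kap.percent_agreement:.1f}% "
      f"(kappa = {kap.kappa:.3f}, 95% CI {kap.ci[0]:.3f} to {kap.ci[1]:.3f})")

# two observers reading the same 17 segments x 20 subjects, with observer
# noise on top of a shared true segmental EF
rng = np.random.default_rng(3)
truth = rng.normal(47, 13, (17 * 20, 1))
readings = truth + rng.normal(0, 8, (17 * 20, 2))
r = icc(readings)
print(f"inter-observer ICC(2,1): {r.icc:.3f} (95% CI {r.ci[0]:.3f} to {r.ci[1]:.3f})")

groups = {
    "normal": rng.normal(52.7, 15.0, 320),
    "hypokinesis": rng.normal(38.0, 14.0, 227),
    "akinesis": rng.normal(30.0, 14.0, 14),
}
res = oneway_anova_bonferroni(groups)
print(f"ANOVA across wall-motion grades: F = {res['F']:.1f}, p = {res['p']:.2g}")
for pair, stats in res["pairwise"].items():
    print(f"  {pair[0]} vs {pair[1]}: Bonferroni-adjusted p = {stats['p_adj']:.3g}")

# kappa 0.672 with 81.8% raw agreement is 'substantial' on the usual scale.
# The tiny akinetic group (n = 14) usually fails to separate from the
# hypokinetic group after correction, unlike the normal-vs-reduced contrasts.
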