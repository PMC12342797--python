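"""Test whether a crop's IRG repertoire is reduced relative to its wild
relative.

One crop in this cohort has every one of the 14 classes reduced (with
skewed per-class deficits, so the normality gate rejects and the
Wilcoxon signed-rank branch fires); the other crops differ only by
small mixed-sign fluctuations.  With all 14 normalized differences
positive the signed-rank statistic attains its maximum V = 105 and the
exact two-sided p is 2^-13; BH correction over the 15 crops multiplies
the rank-1 p by 15.
"""

import numpy as np

from irgloss import IRG_CLASSES, RepertoireCounts, Scope, compare_repertoires

rng = np.random.default_rng(42)

deficits = [1, 2, 3, 4, 5, 6, 7, 8, 10, 13, 21, 34, 55, 89]
wild0 = {c: 200 + 5 * i for i, c in enumerate(IRG_CLASSES)}
crop0 = {c: wild0[c] - d for c, d in zip(IRG_CLASSES, deficits)}
pairs = [
    (RepertoireCounts("reduced_crop", crop0), RepertoireCounts("wild_0", wild0))
]
for k in range(1, 15):
    wild = {c: int(rng.integers(30, 60)) for c in IRG_CLASSES}
    crop = dict(wild)
    for j, c in enumerate(rng.choice(IRG_CLASSES, size=4, replace=False)):
        crop[c] += (1 if j % 2 else -1) * int(rng.integers(1, 3))
    pairs.append(
        (RepertoireCounts(f"crop_{k}", crop), RepertoireCounts(f"wild_{k}", wild))
    )

for r in compare_repertoires(pairs, Scope.FULL)[:3]:
    print(
        f"{r.crop_id:>13}: {r.test_used:<21} stat={r.statistic:8.3f} "
        f"p_raw={r.p_raw:.3e} p_BH={r.p_adjusted:.4f}"
    )
print(
    "\nThe reduced crop reaches the signed-rank maximum (V=105, p=2^-13);"
    "\nits BH-adjusted p of 0.0018 is significant, the null crops are not."
)
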