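"""Feature selection and radscore construction, plus the published fixtures.

The selection pipeline chains redundancy filtering (|r| > 0.75), mRMR
ranking and a cross-validated LASSO-logistic path; the surviving features
and their penalized coefficients form a linear radiomics score.
"""

import numpy as np
import pandas as pd
from scipy import special

import habikit as hk

# --- selection on synthetic features with 5 planted signals --------------
rng = np.random.default_rng(0)
n, p = 200, 80
x = rng.standard_normal((n, p))
eta = x[:, :5].sum(axis=1)
y = (rng.uniform(size=n) < special.expit(eta)).astype(int)
table = pd.DataFrame(x, columns=[f"f{j:03d}" for j in range(p)])

result = hk.select_features(table, y, mrmr_top=30, seed=0)
planted = {f"f{j:03d}" for j in range(5)}
print("selection trace (stage -> surviving features):")
for stage, names in result.stage_survivors.items():
    print(f"  {stage:12s}: {len(names)}")
print(f"planted features recovered: "
      f"{len(planted & set(result.selected))} of 5")

model = hk.build_radscore(result)
print(f"radscore = {model.intercept:.3f} + "
      + " + ".join(f"{c:.3f}*{f}" for f, c in
                   list(model.coefficients.items())[:3]) + " + ...")

# --- the published models ship as named fixtures --------------------------
for name in ("paper_voi", "paper_sub"):
    m = hk.load_paper_model(name)
    zero = {f: 0.0 for f in m.coefficients}
    print(f"\n{name}: {len(m.coefficients)} features; "
          f"score at all-zero features = {m.score(zero)!r} "
          "(the model intercept)")
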