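"""Isotopic niche width per sex from feather d13C/d15N.

Standard ellipse areas (SEA, small-sample SEAc) summarise each sex's
bivariate isotope scatter; the Bayesian version (SEAb) gives credible
intervals and the posterior probability that one sex's niche is smaller.
"""

from seaseg import isotope_niche as iso
from seaseg.synthetic_data import SimulationConfig, simulate_population

cfg = SimulationConfig(seed=1, n_per_sex=40)
_, _, isotopes, _ = simulate_population(cfg)

groups = {}
for sex in ("male", "female"):
    sel = isotopes.loc[isotopes["sex"] == sex]
    # one shared wintering area so the niche reflects diet, not geography
    sel = sel.loc[sel["area"] == "Benguela Current", ["d13C", "d15N"]]
    groups[sex] = sel.to_numpy()
    niche = iso.fit_niche(groups[sex], label=sex, seed=1)
    lo, hi = niche.ci95
    print(f"{sex:6s} n={niche.n:3d}  SEA {niche.sea:.2f}  SEAc {niche.seac:.2f}  "
          f"SEAb 95% CI [{lo:.2f}, {hi:.2f}] permil^2")

res = iso.seab(groups["male"], groups["female"], seed=2)
print(f"P(male ellipse smaller than female) = {res['p_a_smaller']:.3f}")
print("Areas near 1 permil^2 reflect the configured within-area isotope "
      "spread. Both sexes share the same generating spread, but at a few "
      "dozen birds the sample ellipses differ by luck and the posterior "
      "tracks the samples -- judging niche width needs replication, not one "
      "draw.")
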