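"""Contrast of population-decline amplitude between scenarios.

The amplitude of decline is the ratio r = Ne_t1 / Ne_t2 (early over recent
effective size; r > 1 means the population shrank).  Posterior ratio
distributions under a with-gene-flow scenario (SC) and a without-gene-flow
scenario (SI), fitted to the same pseudo-observed data, are compared with a
Mann-Whitney rank test — reported with the caveat that posterior draws are
not independent experimental units.
"""

import numpy as np

import parapop as pp
from parapop.abc import default_priors, estimate_posteriors, reject, run_reference_table
from parapop.synth import generate_observed_stats

base = pp.ScenarioSpec("SI", 1e3, 1e3, 1e3, 1e3, 1e3, 0, 0, 2e4, 1e4,
                       n_loci=17, n_cau=20, n_mor=20)
print("simulating 4000 reference datasets...")
table = run_reference_table(default_priors(), 4000, seed=7, base_spec=base)

truth = pp.ScenarioSpec("SC", ne_anc=5e4, ne_cau_t1=8e3, ne_mor_t1=2e4,
                        ne_cau_t2=2e3, ne_mor_t2=4e2, m1=2e-3, m2=2e-4,
                        t1=23_000, t2=18_000, n_loci=17, n_cau=20, n_mor=20)
observed = generate_observed_stats(truth, np.random.default_rng(1))

posteriors = {}
for scenario in ("SC", "SI"):
    sub = table[table["model"] == scenario]
    post = estimate_posteriors(reject(sub, observed, 300))
    posteriors[scenario] = post
    print(f"\n{scenario}: effective-size posteriors (mode / 2.5% / 97.5%):")
    print(post.summary.loc[["ne_cau_t1", "ne_cau_t2"]].round(0).to_string())

ratios = {s: pp.decline_ratios(posteriors[s], "cau", scenario=s)
          for s in ("SC", "SI")}
for s, r in ratios.items():
    print(f"\n{s}: decline ratio Ne_t1/Ne_t2 mode {r.mode:.1f} "
          f"[{r.q025:.1f}, {r.q975:.1f}]")

report = pp.compare_scenarios(ratios["SC"], ratios["SI"])
print(f"\nMann-Whitney U = {report['U']:.0f}, two-sided p = {report['p']:.3g}")
print("stochastically larger decline:", report["stochastically_larger"])
print("caveat:", report["caveat"])
# The generating SC draw declined 4-fold; the no-gene-flow SI fit must
# explain the same diversity without immigration, which shifts its size
# estimates and typically its implied decline.
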