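"""Route dose-response comparisons through the assumption gate.

Three scenarios: clean normal data (classic ANOVA + Dunnett), variance
heterogeneity (Brown-Forsythe/Welch + Dunnett T3), and log-normal data
(log transform restores normality).
"""

import numpy as np

from neuroassay import analyze_one_way

rng = np.random.default_rng(0)

scenarios = {
    "clean": {"0": rng.normal(10, 1, 8), "7": rng.normal(10, 1, 8),
              "35": rng.normal(7, 1, 8)},
    "heteroscedastic": {"0": rng.normal(10, 0.5, 8), "7": rng.normal(10, 0.5, 8),
                        "35": rng.normal(7, 6, 8)},
    "log-normal": {"0": rng.lognormal(2.0, 1.2, 10),
                   "7": rng.lognormal(2.0, 1.2, 10),
                   "35": rng.lognormal(1.0, 1.2, 10)},
}

for name, groups in scenarios.items():
    plan, res = analyze_one_way(groups, control="0")
    omni = res.omnibus.iloc[0]
    print(f"[{name}] route={plan.route} transform={plan.transform}")
    print(f"  omnibus {omni['effect']}: stat={omni['statistic']:.2f} "
          f"p={omni['p']:.4f}")
    for _, row in res.comparisons.iterrows():
        print(f"  {row['comparison']}: adjusted p={row['p_adj']:.4f} "
              f"({row['method']})")
    print()

print("Reading: the gate checks Shapiro-Wilk normality (with a log-"
      "transform rescue) and Levene homogeneity at alpha 0.05, then runs "
      "the matching omnibus test and multiplicity-corrected comparisons "
      "against the 0 mM control.")
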