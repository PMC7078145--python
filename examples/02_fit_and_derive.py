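"""Fit the constant-parameter model and derive the fate summary.

The constant model S(.) f(.) assumes every carcass, regardless of age or
date, remains afloat each day with probability S and beaches with
probability f.  From the MLEs follow the daily loss rate omega = 1 - S - f
and the overall beaching probability beta = f / (1 - S): the chance a
carcass that died at sea ever comes ashore where it can be found.
"""

import numpy as np

import driftfate as df

cfg = df.reference_config(seed=42)
marr = df.build_marray(df.simulate_study(cfg), cfg.design)

res = df.fit(marr, cfg.model, df.FitOptions(n_starts=5, seed=0))
(ci_S, ci_f) = df.wald_ci(res)

print(f"daily at-sea survival S = {res.estimates.S_values[0]:.4f} "
      f"(95% CI {ci_S[0]:.2f}-{ci_S[1]:.2f})")
print(f"daily beaching rate  f = {res.estimates.f_values[0]:.4f} "
      f"(95% CI {ci_f[0]:.3f}-{ci_f[1]:.3f})")
print(f"-2 log L = {res.minus2logl:.4f}, K = {res.K}, "
      f"deviance = {res.deviance:.4f}")

est = df.derive(res)
print(f"\ndaily loss rate        omega = {est.omega[0]:.4f}")
print(f"overall beaching prob  beta  = {est.beta:.4f}")
print(f"still afloat after 7 days:     {df.survival_to_day(est.S[0], 7):.3f}")
print(f"lost at sea within 5 days:     "
      f"{df.cumulative_loss(est.S[0], est.omega[0], 5):.4f}")
print("\nfirst five daily beaching probabilities b_i = f S^(i-1):")
for i, b in enumerate(est.b_series[:5], start=1):
    print(f"  day {i}: {b:.5f}")
# The true values behind this simulation are S = 0.829, f = 0.0242,
# omega = 0.1468, beta = 0.1415; the fit recovers them within the
# sampling error of a 195-carcass study.
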