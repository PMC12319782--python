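"""The single-case statistical battery on a toy dataset.

One patient score against five controls: Crawford's modified t, the
Bayesian single-case estimate of the percentage of controls falling below
the patient, the revised standardized difference test (RSDT) for a
dissociation between two measures, its Bayesian counterpart, and a
bootstrap confidence interval for the control mean.
"""

import numpy as np

import eegsilence as es

controls_theta = [0.21, 0.26, 0.24, 0.30, 0.23]   # control slopes, Theta
controls_alpha = [0.25, 0.28, 0.22, 0.27, 0.24]   # control slopes, Alpha
case_theta, case_alpha = 0.03, 0.24               # the patient

res = es.crawford_t(case_theta, controls_theta, direction="case<controls")
print(f"Crawford t-test (Theta): t({res.df}) = {res.statistic:.2f}, "
      f"one-tailed p = {res.p_one_tailed:.4f}"
      + ("  -> significant deficit" if res.p_one_tailed < 0.05 else ""))

bay = es.bayes_single_case(case_theta, controls_theta, n_draws=100_000, seed=0)
print(f"Bayesian single-case:   {100*bay.p_hat:.1f}% of the control population "
      f"below the case (95% interval [{100*bay.interval[0]:.1f}, "
      f"{100*bay.interval[1]:.1f}]%)")

dis = es.rsdt(case_theta, case_alpha, controls_theta, controls_alpha)
print(f"RSDT (Theta vs Alpha):  psi = {dis.statistic:.2f}, "
      f"one-tailed p = {dis.p_one_tailed:.4f}"
      + ("  -> frequency-specific dissociation" if dis.p_one_tailed < 0.05 else ""))

bs = es.bsdt(case_theta, case_alpha, controls_theta, controls_alpha,
             n_draws=100_000, seed=0)
print(f"BSDT:                   p-hat = {bs.p_hat:.4f} "
      f"(95% interval [{bs.interval[0]:.4f}, {bs.interval[1]:.4f}])")

lo, hi = es.bootstrap_ci(controls_theta, n_boot=1000, seed=0)
print(f"control Theta mean:     {np.mean(controls_theta):.3f} "
      f"(bootstrap 95% CI [{lo:.3f}, {hi:.3f}])")
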