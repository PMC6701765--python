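"""Parametric-bootstrap confidence intervals for the dosage model.

Because the training classes are quasi-separated, Wald standard errors
are unusable (the coefficients are optimizer-sensitive); percentile
intervals from a parametric bootstrap are the honest alternative.  On
a non-separated simulated dataset they bracket the generating values.
"""

import math

import numpy as np

from qfpcr import DiallelicObservation, bootstrap_ci, fit_glmm

rng = np.random.default_rng(7)
beta = (-1.5, 1.4, -0.05)
sigma_b = 0.6
u = rng.normal(0.0, sigma_b, 12)
obs = []
for i in range(1200):
    j = int(rng.integers(12))
    hr = float(rng.uniform(0.6, 2.4))
    sd = float(rng.uniform(0.0, 40.0))
    eta = beta[0] + beta[1] * hr + beta[2] * sd + u[j]
    y = rng.random() < 1.0 / (1.0 + math.exp(-eta))
    obs.append(DiallelicObservation(
        str(i), f"M{j}", hr, sd, "trisomic_2_1" if y else "normal_1_1"))

fit = fit_glmm(obs)
ci = bootstrap_ci(fit, obs, n_boot=200, seed=1)
print(f"{'term':<16}{'truth':>8}{'estimate':>10}{'95% CI':>22}")
truths = dict(zip(("intercept", "height_ratio", "size_difference"), beta))
truths["sigma_b"] = sigma_b
for term, (lo, hi) in ci.items():
    est = fit.beta.get(term, fit.sigma_b)
    print(f"{term:<16}{truths[term]:>8.3f}{est:>10.3f}"
          f"{'[%.3f, %.3f]' % (lo, hi):>22}")
# The fixed-effect intervals bracket the generating values (~95% of
# the time over repeated experiments).  sigma_b is only weakly
# identified from 12 marker levels: its estimate tracks the *realized*
# spread of the twelve drawn intercepts, not the population value, and
# a singular (sigma_b = 0) fit is a legitimate outcome on such data.
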