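"""Information-criteria ladder for the dosage model.

Fits the full model (height ratio + size difference + marker random
intercept) and the three reduced models on the 2:1 block and prints
the comparison table.  The full model should win on AIC/BIC: both
fixed effects carry real signal.
"""

from qfpcr import compare_models
from qfpcr.glmm import standard_specs
from qfpcr.simulate import simulate_training_set

rows = simulate_training_set(4000, 40, 0, seed=11)
block = [o for o in rows if o.label in ("normal_1_1", "trisomic_2_1")]
table = compare_models(block, standard_specs())
print(table[["model", "logLik", "deviance_resid", "AIC", "BIC",
             "df_residual"]].to_string(index=False))

best = table.loc[table["AIC"].idxmin(), "model"]
print(f"\nlowest AIC: {best}")
# Expect the full model ('height_ratio+size_difference') to fit best;
# the marker-only model shows how much the covariates explain.
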