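"""Maternal-cell-contamination triage of separated amniotic fluid.

A visibly blood-contaminated amniotic fluid is left to settle and the
supernatant and precipitate are genotyped separately.  Three outcomes:
the blood was actually fetal (A — both fractions show one identical
non-maternal profile), the supernatant is clean while the precipitate
is mixed (B — report from the supernatant), or both fractions are
mixed (C — unresolved).
"""

from qfpcr import triage_mcc
from qfpcr.genotyping import preprocess
from qfpcr.panel import default_panel
from qfpcr.simulate import SimulationConfig, simulate_sample

panel = default_panel()


def fraction(seed, mcc_fraction):
    cfg = SimulationConfig(karyotype="46XY", mcc_fraction=mcc_fraction)
    s = simulate_sample(cfg, seed=seed)  # same seed = same pregnancy
    genos = {m: preprocess(s.sample_id, m, pk)
             for m, pk in s.peaks.items() if pk}
    return genos, s.maternal_profile


for name, (f_sup, f_prec) in {
    "fetal blood (A)": (0.0, 0.0),
    "resolved by supernatant (B)": (0.0, 0.35),
    "unresolved (C)": (0.35, 0.35),
}.items():
    sup, mom = fraction(31, f_sup)
    prec, _ = fraction(31, f_prec)
    res = triage_mcc(sup, prec, mom, panel)
    print(f"{name}: category={res.category}, conclusive={res.conclusive}, "
          f"fractions={res.evidence}")

# In the 84-sample breakdown this package's acceptance script
# reproduces (38 A / 35 B / 11 C), categories B and C are the truly
# contaminated fluids and B is conclusive: 35/46 ~ 76% of contaminated
# samples still get a diagnosis without re-amniocentesis.
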