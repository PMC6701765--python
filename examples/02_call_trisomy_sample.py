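"""Full sample workflow: peaks -> genotypes -> chromosome verdicts.

Simulates a trisomy-18 amniocentesis, preprocesses each marker's peaks
(50 RFU floor, +A split-peak resolution), classifies every marker and
aggregates the evidence under the two-informative-marker rule.
"""

from qfpcr import call_sample, train
from qfpcr.genotyping import preprocess
from qfpcr.simulate import SimulationConfig, simulate_sample, simulate_training_set

model = train(simulate_training_set(4000, 40, 40, seed=11))

cfg = SimulationConfig(karyotype="T18")
sample = simulate_sample(cfg, seed=22, sample_id="AF-0042")
genotypes = {
    marker: preprocess(sample.sample_id, marker, peaks)
    for marker, peaks in sample.peaks.items()
    if peaks
}
report = call_sample(sample.sample_id, genotypes, cfg.panel, model)
print(report.to_text())

# chr18 should read "trisomy" backed by >= 2 informative markers; the
# other autosomes read "normal" (or a backup-panel recommendation when
# a chromosome happens to be homozygous at every marker — the reason
# real panels carry chromosome-specific backup reactions).
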