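# Methods

## Scope and data model

The package analyses quantitative fluorescent PCR (QF-PCR) fragment data
for prenatal aneuploidy testing.  Its unit of raw input is a peak: a sized
fragment (bp, fractional — sizing against an internal standard is
continuous) with a height in relative fluorescence units (RFU).  Peaks are
grouped per sample × marker, preprocessed, and reduced to genotype
patterns; heterozygous (diallelic) STR genotypes additionally yield the
regression observation `(height ratio, allele size difference, marker)`.

The bundled `panel_v1` describes a 20-marker one-tube multiplex targeting
26 genomic positions: three STRs for chromosome 13, four each for 18 and
21, six sex-chromosome markers (the X-linked STRs DXS6803 and XHPRT, the
pseudoautosomal STR DXYS218, the fixed-size X/Y marker AMELX/Y, the
X-vs-chromosome-3 dosage marker TAF9B, and SRY), and three AZFc-region
markers (MYPT2/Y, DYS448, CDY1/2) that are carried as presence/dosage
annotations only.  CDY1/2 is modeled with three Y-chromosome products
(the two CDY1 copies plus CDY2), which is what brings the panel's
targeted-position count to 26.  Marker size ranges and most
heterozygosities in the bundled panel are population-typical placeholders
rather than assay-validated values; only the D18S390/D18S391
heterozygosities (0.681/0.685) are authoritative.  Panels are YAML and
fully replaceable at runtime.

## Peak preprocessing

1. **Detection floor** — peaks below 50 RFU (the sequencer's factory
   default, configurable) are discarded.
2. **+A resolution** — incomplete non-templated adenine addition splits an
   allele into two peaks ≈1 bp apart; any pair of peaks closer than the
   split window (default 1.0 bp) is merged into the taller peak,
   iteratively, closest pair first, until no two peaks lie within the
   window.  The window is a package choice: the artifact is ~1 bp by
   mechanism, and the narrowest real allele spacing (dinucleotide repeats,
   2 bp) stays safely outside it.
3. **Pattern call** — 0/1/2/3/>3 remaining peaks map to
   absent/monoallelic/diallelic/triallelic/multiallelic; multiallelic
   patterns are flagged (possible contamination or duplication), never
   interpreted as dosage.

An optional stutter filter (peak one repeat unit below a ≥6.7× taller
peak) exists but is off by default: the PCR protocol's long final
extension removes stutter upstream, and no further correction is applied
to extracted ratios.

The **height ratio** is oriented shorter-fragment height over
longer-fragment height.  This is the only orientation simultaneously
consistent with normal ratios sitting at or slightly above 1 (shorter
fragments amplify better), the positive per-marker correlation between
ratio and size difference, and the classical cutoffs of 1.94 (2:1) and
0.94 (1:2).

## The dosage model

For the binary response *trisomic (1) vs normal (0)* at a diallelic STR:

    logit P(y=1 | r, d, marker j) = β₀ + β₁ r + β₂ d + u_j,  u_j ~ N(0, σ_b²)

with `r` the height ratio and `d` the size difference.  Two such models
are trained — one on normals + trisomic 2:1 genotypes, one on normals +
trisomic 1:2 — because the two trisomic directions sit on opposite sides
of the normal cloud and a single linear model cannot flag both tails.
The trisomic=1 coding makes the ratio coefficient positive in the 2:1
model and negative in the 1:2 model.

**Estimation.** The marginal likelihood integrates each marker's random
intercept out of the conditional Bernoulli likelihood.  We maximize its
Laplace approximation: an inner penalized iteratively-reweighted
least-squares (PIRLS) step optimizes the fixed effects and the random
intercepts jointly at fixed σ_b (joint Newton with step halving on the
penalized log-likelihood), and a derivative-free bounded scalar search
over log σ_b wraps it, with an explicit σ_b = 0 boundary evaluation so
singular fits are recognized and reported rather than erroring.  Profiling
β inside the inner step is the standard one-quadrature-point scheme of
mixed-model software; on shared test data the fit agrees with an
independent implementation of that scheme to ~10⁻² in log-likelihood and
~10⁻³ in σ_b, and the package's own order-50 adaptive Gauss–Hermite
evaluation (an independent code path used as the accuracy oracle) agrees
with the Laplace log-likelihood to <0.05 on small instances.  Convergence:
inner relative change <10⁻¹⁰ (cap 100 iterations), outer tolerance 10⁻⁶
on log σ_b.

**Separation.** Real training sets are almost perfectly separable in
`(r, d, marker)` space, so the maximum-likelihood coefficients are
unbounded: the optimizer returns very large, tolerance-sensitive values
(hundreds on the logit scale) and any Wald inference is meaningless.  The
fitter caps iterations, flags the condition (`separation_flag` when the
largest |linear predictor| exceeds 30), and everything downstream uses
fitted probabilities — which are stable under separation — never the
coefficient values.  Confidence intervals, when wanted, come from a
parametric bootstrap (simulate responses from the fitted model with
redrawn random intercepts, refit, take 2.5/97.5 percentiles; default 1000
replicates, failed replicates dropped, >50% failure is an error).

**Model comparison.** The comparison table fits the full model and the
three reductions (without size difference, without height ratio,
marker-only) and reports log-likelihood, AIC = 2k − 2·logLik and
BIC = k·ln n − 2·logLik with k = number of fixed effects + 1 (for σ_b),
residual df = n − k, and a `deviance_resid` column defined as the sum of
squared deviance residuals at the conditional modes.  That last quantity
is deliberately *not* −2·logLik: it is the conditional (penalty-free)
badness-of-fit measure conventionally printed alongside the marginal
log-likelihood in mixed-model comparison tables.

**Thresholds and classification.**  Each model's probability cutoff is
`(min fitted p over trisomic + max fitted p over normal) / 2`, with both
endpoints reported and an overlap flag when the classes cross.  On
non-overlapping training data this construction guarantees zero training
false positives and false negatives by definition — the mechanism behind
a 100%/100% training claim; the guarantee is conditional on the overlap
flag staying false.  At classification time an observation gets p from
both models (per-marker conditional mode added when the marker was seen
in training; population prediction with a warning otherwise, since panels
evolve); exceeding one cutoff gives that trisomy call, exceeding both
gives `conflict`, which is never auto-resolved because it cannot occur
under separated training and therefore signals an input problem.  The
ratio-only classifier (flag at r ≥ 1.94 / r ≤ 0.94, boundaries closed,
configurable) is retained as the comparison baseline and as the fallback
for the Y-only STR DYS448, which the regression cannot cover (hemizygous,
never diallelic in euploid samples).  ROC evaluation computes AUC as the
midrank Mann–Whitney concordance and reports the false-positive count and
specificity at the full-sensitivity operating point (cutoff at the extreme
positive score).

## Chromosome-level calling

Per-marker statuses (normal heterozygous; trisomic triallelic — all three
pairwise decay-adjusted height ratios within [0.6, 1.67]; trisomic
diallelic 2:1 / 1:2 from the classifier; uninformative homozygous/absent;
suspicious multiallelic) aggregate per chromosome under conservative
diagnostic rules:

* a normal or trisomy verdict requires ≥2 informative markers, all
  concordant;
* every marker homozygous → inconclusive, recommend the
  chromosome-specific backup multiplex;
* exactly one informative marker → insufficient evidence, recommend
  backup;
* discordant informative markers → inconclusive with an MCC suspicion
  note; never a majority vote (a primer-site SNP or contamination can
  corrupt any single marker).

The triallelic decay adjustment divides each peak's height by the
marker's fitted normals' line (ratio vs size difference) evaluated at the
peak's offset from the shortest allele, putting all three alleles on a
common dosage scale; the [0.6, 1.67] window is a package default (no
community standard exists) and is configurable.

**Sex chromosomes.** Fixed-size markers are classified by dosage-ratio
windows (1:1 → [0.8, 1.4], 2:1 → [1.6, 2.4], 1:2 → [0.35, 0.65]; the
regression covers STRs only).  The TAF9B X:chr3 ratio counts X copies
against a diploid autosomal reference with boundaries at the log-midpoints
of the expected ratios 0.5/1.0/1.5, since the multiplicative noise scales
with the ratio.  Verdicts require at least two concurring signals among
SRY, amelogenin, TAF9B and the X-STRs (SRY absence only counts when
another sex marker amplified, so a failed reaction is undetermined rather
than female).  Classic patterns: XY (SRY+, AMEL X:Y ≈ 1), XXY (SRY+,
AMEL ≈ 2:1), XYY (SRY+, AMEL ≈ 1:2), XX, X0 (TAF9B ≈ 0.5 with all X STRs
monoallelic and no Y evidence — monosomy X is only called when every
X-informative signal concurs), XXX (TAF9B ≈ 1.5 or a triallelic X STR).
Contradictory SRY/amelogenin evidence yields undetermined with a note
(possible SRY deletion or contamination).  Autosomal monosomy is never
called: the panel targets live-birth-compatible aneuploidies.

**Triploidy** is annotated when every evaluable autosome (verdict normal
or trisomy) is trisomic, with at least two evaluable — the verdicts are
then flagged as one event rather than reported as independent trisomies.

## Maternal cell contamination

**Detection** compares the fetal sample against a maternal STR profile
(≥5 autosomal STRs required): a marker is evidence when the fetal trace
shows extra alleles (beyond its two main peaks) matching maternal-specific
alleles within ±0.5 bp (allele identity uses a ±0.5 bp window throughout —
sizing is continuous and never binned to repeat units); ≥2 evidence
markers → contaminated.  A maternity check runs alongside, in the manner
of relationship testing: a true mother shares ≥1 allele with the fetus at
every marker, so ≥2 exclusion markers raise a sample mix-up warning
instead of a contamination call.

**Triage** of a visibly contaminated, physically separated amniotic fluid
classifies each fraction (supernatant, precipitate) as single-fetal,
mixed, or single-maternal, and maps the pair: both single-fetal and
identical → A (the blood was fetal; conclusive); supernatant single-fetal
over a mixed or maternal precipitate → B (report from the supernatant;
conclusive); everything else → C (unresolved).  The mapping is total over
the nine state pairs; a missing fraction, or two *different* single
non-maternal profiles, is an error.  In the 38/35/11 worked breakdown the
truly contaminated samples are B+C = 46 and the conclusive rate among
them is 35/46 ≈ 76%.

## The synthetic-data generator

The generator produces the study conditions the classifier assumes, with
Mendelian structure (the fetus inherits one maternal and one paternal
allele; the admixture mother is the same one the fetal alleles came from;
genotypes and noise are drawn from separate seed streams so one seed
defines one pregnancy across contamination settings).

Expected peak height is `baseline × dose × (1 − decay)^(size − min size)`.
Choices, set once:

* **Noise** is multiplicative log-normal with a total per-peak CV of 8%,
  decomposed into a common-mode factor shared by all of a marker's peaks
  in a sample (amplification efficiency, injection) and a 4%
  allele-specific factor.  The decomposition matters: sibling peaks of
  one marker rise and fall together in real electropherograms, so the
  *ratio* is far less dispersed than independent 8% peak noise would
  imply.  It is also the only noise structure simultaneously consistent
  with three observed features of real panels: perfect separation of
  fitted probabilities at ~9000 training genotypes, per-marker
  ratio-size correlations reaching ≈0.95, and a 1–2% ratio-only
  false-positive rate at the 1.94/0.94 cutoffs.
* **Decay** coefficients are log-spaced over 0.006–0.016 per bp and
  assigned by allele-ladder width (narrowest ladder → lowest decay).
  Fragment-length decay is mostly multiplex chemistry and varies only
  moderately between markers; the wide spread of per-marker correlations
  (≈0.27–0.95 under the defaults, echoing the 0.334–0.946 range of real
  panels) then comes from ladder width — a narrow ladder's ratio is
  noise-dominated — while the trisomic and normal classes remain
  separable by a single linear boundary (with per-marker intercepts)
  across markers.  A decay-spread-only calibration was tried and
  rejected: a shared linear size-difference slope cannot bracket both a
  steep narrow marker and a flat wide one, which produced discordant
  marker calls on ~12% of trisomic samples.
* **Allele ladders** are integer repeat-unit steps (2/4/6 bp) spanning
  each marker's size range, uniform frequencies, replaceable by published
  frequencies via configuration.
* **Trisomy** adds one extra allele drawn from the parental alleles:
  duplicating an inherited allele gives the diallelic 2:1 (shorter
  duplicated) or 1:2 (longer) pattern, a third distinct allele gives the
  triallelic pattern — as in reality, the realized pattern is a
  consequence of drawn allele identities, not a dial.
* **Contamination** scales fetal peaks by (1 − f) and adds the maternal
  genotype's peaks scaled by f, merging co-sized peaks, then applies the
  detection floor.

**What the generator does not emulate:** stutter ladders, dye pull-up,
off-scale peak clipping, electrophoretic mobility artifacts, degraded-DNA
allele dropout, population allele-frequency structure, and real
marker-specific amplification chemistry.  Passing tests therefore
demonstrate the statistical machinery under the model's own assumptions —
calibrated to the documented regime of real panels — not performance on
any particular instrument's output.

## Verification scales and numerical choices

The test suite runs the likelihood oracle on 20 random instances (≤200
observations, ≤5 markers, tolerance 0.05); parameter recovery at n = 5000
with 14 markers (relative bias bound 20%); bootstrap coverage over 200
experiments of n = 150, 3 markers, 100 bootstrap draws each (accept
90–99% coverage); the triage worked example at its original 84-sample
breakdown; and an end-to-end round trip with a 2000-observation training
table and 200 full samples across ten karyotypes (label recovery ≥99%,
and an audit that no normal/trisomy verdict is ever backed by fewer than
two informative markers).  These sizes are the package's chosen
verification scales: large enough to pin the statistical claims, small
enough to keep the suite fast.  Logistic terms are evaluated through
`log(1+e^x)`/`expit` forms with logits clamped at ±700 before
exponentiation; Cholesky solves add a 10⁻¹⁰ jitter (10⁻⁶ on failure);
ties in +A peak merging keep the shorter fragment; degenerate inputs
(empty panels, single-class responses, single-level grouping, missing
triage fractions) raise typed errors rather than returning defaults.

## Known limitations

* Coefficient magnitudes under separation are optimizer-dependent by
  nature; only probabilities and classifications are comparable across
  implementations.
* The regression models diallelic STRs only; triallelic trisomies use the
  tolerance-window rule, and fixed-size markers use dosage windows.
* Mosaicism, uniparental disomy, structural rearrangements and AZFc
  deletion classes are out of scope; AZFc markers are parsed but not
  interpreted.
* The bundled panel's size ranges and most heterozygosities are
  placeholders; labs should load their validated panel definitions.
* The MCC admixture detection limit is an empirical property of the
  50 RFU floor and the noise model, not a claimed assay sensitivity.
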