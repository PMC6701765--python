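"""Sample-level aneuploidy calling.

Aggregates per-marker evidence into chromosome verdicts under the
diagnostic evidence rule: a normal or trisomy verdict requires at
least two informative (heterozygous) markers for the chromosome; a
chromosome with all markers homozygous is inconclusive and triggers a
backup-panel recommendation; discordant informative markers are never
majority-voted but reported as inconclusive with a maternal-cell-
contamination suspicion.

Sex chromosomes are counted from the fixed-size dosage markers
(amelogenin X:Y ratio, TAF9B X:chromosome-3 ratio), SRY presence and
the X-linked STR patterns; monosomy X is only called when every
X-informative signal concurs.

Maternal cell contamination (MCC) is detected by matching extra
fetal-sample alleles against maternal-specific alleles, and triaged
across the supernatant/precipitate fractions of a physically separated
amniotic fluid: identical clean profiles in both fractions mean the
contaminating blood was fetal (category A); a clean supernatant over a
mixed precipitate is reported from the supernatant (B); two mixed
fractions remain unresolved (C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .classifier import ClassifierModel, MarkerCorrelation, classify
from .genotyping import GenotypeObservation, compute_diallelic
from .panel import MarkerDef, panel_by_name
from .tables import PeakRecord

MARKER_STATUSES = (
    "normal_heterozygous",
    "trisomic_triallelic",
    "trisomic_diallelic_2_1",
    "trisomic_diallelic_1_2",
    "uninformative_homozygous",
    "uninformative_absent",
    "suspicious_multiallelic",
)

TRISOMIC_STATUSES = (
    "trisomic_triallelic",
    "trisomic_diallelic_2_1",
    "trisomic_diallelic_1_2",
)

#: default pairwise tolerance for a decay-adjusted 1:1:1 triallelic call
TRIALLELIC_RATIO_WINDOW = (0.6, 1.67)

#: dosage-ratio windows for fixed-size markers (not covered by the
#: regression, which models STRs only)
DOSAGE_WINDOWS = {
    "1:1": (0.8, 1.4),
    "2:1": (1.6, 2.4),
    "1:2": (0.35, 0.65),
    "3:2": (1.45, 1.9),
}

BACKUP_RECOMMENDATIONS = {
    "13": "chromosome 13 backup QF-PCR multiplex",
    "18": "chromosome 18 backup QF-PCR multiplex",
    "21": "chromosome 21 backup QF-PCR multiplex",
    "X": "sex-chromosome backup reactions (DXS6809, DXS996, X22)",
    "Y": "sex-chromosome backup reactions (DXS6809, DXS996, X22)",
}

#: allele identity window for profile comparison, bp
ALLELE_MATCH_WINDOW = 0.5


class CallerError(ValueError):
    """Raised for unusable caller input."""


@dataclass(frozen=True)
class MarkerCall:
    """Per-marker dosage status in the context of one chromosome."""

    marker: str
    chromosome: str
    status: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.status not in MARKER_STATUSES:
            raise CallerError(f"unknown marker status {self.status!r}")

    @property
    def informative(self) -> bool:
        return self.status == "normal_heterozygous" or self.status in TRISOMIC_STATUSES


@dataclass(frozen=True)
class ChromosomeCall:
    chromosome: str
    verdict: str
    informative_count: int
    supporting_markers: tuple[str, ...]
    note: str = ""


@dataclass
class SampleReport:
    """Full per-sample result: chromosome verdicts, sex, flags."""

    sample_id: str
    sex: str  # male | female | undetermined
    calls: dict[str, ChromosomeCall]
    triploidy_flag: bool = False
    mcc_flag: bool = False
    notes: list[str] = field(default_factory=list)

    def summary_line(self) -> str:
        parts = [self.sample_id, self.sex]
        for chrom in ("13", "18", "21", "X", "Y"):
            c = self.calls.get(chrom)
            parts.append(f"{chrom}:{c.verdict if c else 'na'}")
        parts.append(f"triploidy:{'yes' if self.triploidy_flag else 'no'}")
        parts.append(f"mcc:{'yes' if self.mcc_flag else 'no'}")
        return "\t".join(parts)

    def to_text(self) -> str:
        lines = [f"sample\t{self.sample_id}", f"sex\t{self.sex}"]
        for chrom, call in sorted(self.calls.items()):
            lines.append(
                f"chr{chrom}\t{call.verdict}\tinformative={call.informative_count}"
                f"\tmarkers={','.join(call.supporting_markers) or '-'}"
                + (f"\t{call.note}" if call.note else "")
            )
        lines.append(f"triploidy\t{'yes' if self.triploidy_flag else 'no'}")
        lines.append(f"mcc\t{'yes' if self.mcc_flag else 'no'}")
        lines.extend(f"note\t{n}" for n in self.notes)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# marker-level calling


def _decay_adjust(
    peaks: Sequence[PeakRecord], line: MarkerCorrelation | None
) -> list[float]:
    """Heights corrected for the marker's size-dependent decay.

    The fitted normals' line (ratio vs size difference) predicts how
    much taller a fragment ``d`` bp shorter runs; dividing the observed
    height by the line value at the peak's offset from the shortest
    peak puts all alleles on a common dosage scale.
    """
    s0 = min(p.size for p in peaks)
    if line is None:
        return [p.height for p in peaks]
    # line(d) is the expected shorter/longer ratio at size difference d,
    # i.e. how much *lower* a peak d bp longer runs; scale it back up
    return [
        p.height * max(line.intercept + line.slope * (p.size - s0), 0.1)
        for p in peaks
    ]


def call_marker(
    obs: GenotypeObservation,
    model: ClassifierModel,
    chromosome: str | None = None,
    triallelic_window: tuple[float, float] = TRIALLELIC_RATIO_WINDOW,
    decay_lines: Mapping[str, MarkerCorrelation] | None = None,
) -> MarkerCall:
    """Dosage status of one preprocessed marker observation.

    Diallelic patterns go through the regression classifier (a
    ``conflict`` verdict maps to ``suspicious_multiallelic`` since it
    signals an input problem); triallelic patterns are a trisomy when
    all pairwise decay-adjusted height ratios fall inside the 1:1:1
    tolerance window.
    """
    chrom = chromosome or ""
    if obs.pattern == "absent":
        return MarkerCall(obs.marker, chrom, "uninformative_absent")
    if obs.pattern == "monoallelic":
        return MarkerCall(obs.marker, chrom, "uninformative_homozygous")
    if obs.pattern == "multiallelic":
        return MarkerCall(
            obs.marker, chrom, "suspicious_multiallelic",
            detail=f"{len(obs.peaks)} alleles",
        )
    if obs.pattern == "triallelic":
        line = (decay_lines or {}).get(obs.marker)
        h = _decay_adjust(obs.peaks, line)
        lo, hi = triallelic_window
        balanced = all(
            lo <= h[i] / h[j] <= hi
            for i in range(3)
            for j in range(3)
            if i != j
        )
        if balanced:
            return MarkerCall(obs.marker, chrom, "trisomic_triallelic")
        return MarkerCall(
            obs.marker, chrom, "suspicious_multiallelic",
            detail="unbalanced triallelic",
        )
    # diallelic
    mc = classify(model, compute_diallelic(obs))
    status = {
        "normal": "normal_heterozygous",
        "trisomic_2_1": "trisomic_diallelic_2_1",
        "trisomic_1_2": "trisomic_diallelic_1_2",
        "conflict": "suspicious_multiallelic",
    }[mc.call]
    detail = (
        f"p21={mc.p_21:.4g} p12={mc.p_12:.4g}"
        if not math.isnan(mc.p_21)
        else f"ratio={obs.peaks[0].height / obs.peaks[1].height:.3f}"
    )
    return MarkerCall(obs.marker, chrom, status, detail=detail)


# ---------------------------------------------------------------------------
# chromosome-level calling


def call_chromosome(
    chromosome: str, marker_calls: Sequence[MarkerCall]
) -> ChromosomeCall:
    """Aggregate one chromosome's marker calls under the >=2-marker rule."""
    if not marker_calls:
        raise CallerError(f"chromosome {chromosome}: no marker calls")
    informative = [c for c in marker_calls if c.informative]
    trisomic = [c for c in informative if c.status in TRISOMIC_STATUSES]
    normal = [c for c in informative if c.status == "normal_heterozygous"]
    suspicious = [c for c in marker_calls if c.status == "suspicious_multiallelic"]
    backup = BACKUP_RECOMMENDATIONS.get(chromosome, "chromosome-specific backup panel")

    if suspicious and not informative:
        return ChromosomeCall(
            chromosome, "mcc_suspected", 0,
            tuple(c.marker for c in suspicious),
            note="multiallelic patterns suggest contamination",
        )
    if not informative:
        return ChromosomeCall(
            chromosome, "inconclusive_needs_backup", 0, (),
            note=f"all markers homozygous; recommend {backup}",
        )
    if normal and trisomic:
        return ChromosomeCall(
            chromosome, "mcc_suspected", len(informative),
            tuple(c.marker for c in informative),
            note="discordant informative markers; possible MCC or primer-site SNP",
        )
    if len(informative) == 1:
        return ChromosomeCall(
            chromosome, "insufficient_informative", 1,
            (informative[0].marker,),
            note=f"single informative marker; recommend {backup}",
        )
    verdict = "trisomy" if trisomic else "normal"
    note = (
        "multiallelic pattern alongside concordant calls"
        if suspicious
        else ""
    )
    return ChromosomeCall(
        chromosome, verdict, len(informative),
        tuple(c.marker for c in informative), note=note,
    )


# ---------------------------------------------------------------------------
# sex chromosomes


@dataclass(frozen=True)
class SexCall:
    sex: str  # male | female | undetermined
    x_count: int | None
    y_count: int | None
    karyotype_label: str  # XY, XX, XXY, X0, XXX, XYY, ??
    x_call: ChromosomeCall
    y_call: ChromosomeCall
    note: str = ""


def _ratio_class(ratio: float, windows: Mapping[str, tuple[float, float]]) -> str | None:
    for name, (lo, hi) in windows.items():
        if lo <= ratio <= hi:
            return name
    return None


def _peak_height_at(
    peaks: Sequence[PeakRecord], size: float, window: float = 1.5
) -> float | None:
    best = None
    for p in peaks:
        if abs(p.size - size) <= window:
            if best is None or p.height > best.height:
                best = p
    return best.height if best else None


def call_sex(
    observations: Mapping[str, GenotypeObservation],
    panel: Sequence[MarkerDef],
    dosage_windows: Mapping[str, tuple[float, float]] = DOSAGE_WINDOWS,
) -> SexCall:
    """Sex determination and X/Y counting from the sex-marker block.

    Evidence: SRY presence; amelogenin X:Y height ratio; TAF9B
    X:chromosome-3 dosage (X-copy count against a diploid autosomal
    reference); heterozygosity of the X-linked STRs.  Contradictory
    SRY/amelogenin evidence gives ``undetermined`` with a note
    (possible SRY deletion or contamination).
    """
    by_name = panel_by_name(panel)
    sry_obs = observations.get("SRY")
    sry_present = bool(sry_obs and sry_obs.pattern != "absent")

    amel_ratio = None
    amel_y = False
    amel = observations.get("AMELX/Y")
    if amel and amel.peaks and "AMELX/Y" in by_name:
        mdef = by_name["AMELX/Y"]
        hx = _peak_height_at(amel.peaks, mdef.product_size("X"))
        hy = _peak_height_at(amel.peaks, mdef.product_size("Y"))
        amel_y = hy is not None
        if hx and hy:
            amel_ratio = hx / hy

    x_dose = None
    taf = observations.get("TAF9B")
    if taf and taf.peaks and "TAF9B" in by_name:
        mdef = by_name["TAF9B"]
        hx = _peak_height_at(taf.peaks, mdef.product_size("X"))
        h3 = _peak_height_at(taf.peaks, mdef.product_size("3"))
        if hx and h3:
            # X copies against the diploid chr3 reference: expected
            # ratios 0.5/1.0/1.5; boundaries at the log midpoints since
            # the multiplicative noise scales with the ratio
            r = hx / h3
            if r < 2.2:
                x_dose = 1 if r < 0.707 else 2 if r < 1.225 else 3

    x_het = any(
        observations.get(n) and observations[n].pattern in ("diallelic", "triallelic")
        for n in ("DXS6803", "XHPRT")
    )
    x_str_triallelic = any(
        observations.get(n) and observations[n].pattern == "triallelic"
        for n in ("DXS6803", "XHPRT")
    )
    x_all_mono = all(
        observations[n].pattern in ("monoallelic", "absent")
        for n in ("DXS6803", "XHPRT")
        if n in observations
    )

    if sry_obs is None and amel is None:
        raise CallerError("sex call needs at least SRY or AMELX/Y")

    # concurring evidence signals backing the sex-chromosome verdicts;
    # SRY absence only counts when another sex marker amplified (PCR
    # success), otherwise a failed run would look like a female pattern
    amel_signal = bool(amel and amel.peaks)
    xstr_signal = any(
        observations.get(n) and observations[n].pattern != "absent"
        for n in ("DXS6803", "XHPRT")
    )
    sry_signal = sry_present or (
        sry_obs is not None and (amel_signal or x_dose is not None or xstr_signal)
    )
    n_signals = sum((sry_signal, amel_signal, x_dose is not None, xstr_signal))

    def result(sex, x, y, label, note=""):
        x_verdict = {1: "monosomy" if y == 0 else "normal", 2: "normal",
                     3: "trisomy"}.get(x, "inconclusive_needs_backup")
        if label == "XY" or label == "XX":
            x_verdict = "normal"
        y_verdict = "normal" if y in (0, 1) else "trisomy"
        if label == "??":
            x_verdict = y_verdict = "inconclusive_needs_backup"
        return SexCall(
            sex=sex, x_count=x, y_count=y, karyotype_label=label,
            x_call=ChromosomeCall("X", x_verdict, n_signals, (), note=note),
            y_call=ChromosomeCall("Y", y_verdict, n_signals, (), note=note),
            note=note,
        )

    if n_signals < 2:
        return result("undetermined", None, None, "??",
                      "insufficient sex-marker signal")

    if sry_present and not amel_y and amel is not None and amel.peaks:
        return result("undetermined", None, None, "??",
                      "SRY present but no amelogenin Y product")
    if not sry_present and amel_y:
        return result("undetermined", None, None, "??",
                      "amelogenin Y product without SRY (possible SRY deletion or MCC)")

    if sry_present:
        if amel_ratio is None:
            return result("male", None, 1, "XY", "amelogenin ratio unavailable")
        cls = _ratio_class(amel_ratio, {
            "1:1": dosage_windows["1:1"],
            "2:1": dosage_windows["2:1"],
            "1:2": dosage_windows["1:2"],
        })
        if cls == "2:1" and (x_dose in (None, 2) or x_het):
            return result("male", 2, 1, "XXY")
        if cls == "1:2":
            return result("male", 1, 2, "XYY")
        if cls == "1:1":
            return result("male", 1, 1, "XY")
        return result("undetermined", None, None, "??",
                      f"amelogenin X:Y ratio {amel_ratio:.2f} outside all windows")

    # no Y evidence: female patterns
    if x_str_triallelic or x_dose == 3:
        return result("female", 3, 0, "XXX")
    if x_dose == 1 and x_all_mono and not x_het:
        return result("female", 1, 0, "X0",
                      "reduced X dosage with monoallelic X STRs")
    if x_dose in (None, 2):
        return result("female", 2, 0, "XX")
    return result("undetermined", x_dose, 0, "??",
                  "conflicting X dosage and X STR patterns")


# ---------------------------------------------------------------------------
# triploidy


def detect_triploidy(calls: Mapping[str, ChromosomeCall]) -> bool:
    """Flag a triploid pattern: every evaluable autosome trisomic.

    An autosome is evaluable when its verdict reached normal or
    trisomy; at least two evaluable trisomic autosomes are required so
    a single trisomy with the other chromosomes inconclusive is never
    annotated as triploidy.
    """
    evaluable = [
        calls[c].verdict
        for c in ("13", "18", "21")
        if c in calls and calls[c].verdict in ("normal", "trisomy")
    ]
    return (
        len(evaluable) >= 2
        and all(v == "trisomy" for v in evaluable)
    )


# ---------------------------------------------------------------------------
# maternal cell contamination


@dataclass(frozen=True)
class MccAssessment:
    status: str  # contaminated | clean | no_maternal_profile
    evidence_markers: tuple[str, ...]
    shared_any: bool  # fetus shares >= 1 allele/marker with mother
    mixup_warning: bool


def _match(size: float, sizes: Sequence[float], window: float = ALLELE_MATCH_WINDOW) -> bool:
    return any(abs(size - s) <= window for s in sizes)


def detect_mcc(
    fetal: Mapping[str, GenotypeObservation],
    maternal_profile: Mapping[str, Sequence[float]],
    panel: Sequence[MarkerDef],
    min_markers: int = 2,
) -> MccAssessment:
    """Maternal-contamination check against a maternal STR profile.

    A marker is evidence when the fetal sample shows extra alleles
    (beyond its two main peaks) matching maternal-specific alleles
    within +-0.5 bp.  Independently verifies maternity the way
    relationship testing does: a true mother shares at least one
    allele with the fetus at every marker, so two or more exclusion
    markers (no shared allele) raise a sample mix-up warning instead
    of a contamination call.
    """
    autosomal = {
        m.name for m in panel
        if m.is_str and all(c not in ("X", "Y") for c in m.targets)
    }
    covered = [m for m in maternal_profile if m in autosomal]
    if len(covered) < 5:
        return MccAssessment("no_maternal_profile", (), True, False)
    evidence = []
    shared_counts = []
    for marker in covered:
        obs = fetal.get(marker)
        if obs is None or not obs.peaks:
            continue
        mom = list(maternal_profile[marker])
        fetal_sorted = sorted(obs.peaks, key=lambda p: -p.height)
        main = [p.size for p in fetal_sorted[:2]]
        extras = [p.size for p in fetal_sorted[2:]]
        shared_counts.append(any(_match(s, mom) for s in main + extras))
        maternal_specific = [s for s in mom if not _match(s, main)]
        if any(_match(e, maternal_specific) for e in extras):
            evidence.append(marker)
    shared_any = any(shared_counts) if shared_counts else True
    n_exclusions = sum(1 for s in shared_counts if not s)
    if n_exclusions >= 2:
        return MccAssessment("clean", tuple(evidence), shared_any, True)
    status = "contaminated" if len(evidence) >= min_markers else "clean"
    return MccAssessment(status, tuple(evidence), shared_any, False)


# ---------------------------------------------------------------------------
# MCC triage of separated amniotic-fluid fractions


TRIAGE_CATEGORIES = ("A_fetal_blood", "B_resolved_by_supernatant", "C_unresolved")


@dataclass(frozen=True)
class MccTriageResult:
    category: str
    conclusive: bool
    evidence: dict[str, str]

    def __post_init__(self) -> None:
        if self.category not in TRIAGE_CATEGORIES:
            raise CallerError(f"unknown triage category {self.category!r}")


def _profile_of(obs: Mapping[str, GenotypeObservation]) -> dict[str, tuple[float, ...]]:
    return {
        m: tuple(sorted(p.size for p in o.peaks))
        for m, o in obs.items()
        if o.peaks
    }


def _profiles_identical(
    a: Mapping[str, Sequence[float]], b: Mapping[str, Sequence[float]]
) -> bool:
    common = set(a) & set(b)
    if not common:
        return False
    for m in common:
        xs, ys = sorted(a[m]), sorted(b[m])
        if len(xs) != len(ys) or any(
            abs(x - y) > ALLELE_MATCH_WINDOW for x, y in zip(xs, ys)
        ):
            return False
    return True


def fraction_state(
    fraction: Mapping[str, GenotypeObservation],
    maternal_profile: Mapping[str, Sequence[float]],
    panel: Sequence[MarkerDef],
) -> str:
    """One fraction's profile state: single_fetal | mixed | single_maternal."""
    mcc = detect_mcc(fraction, maternal_profile, panel)
    if mcc.status == "contaminated":
        return "mixed"
    prof = _profile_of(fraction)
    mom = {m: tuple(maternal_profile[m]) for m in maternal_profile}
    if _profiles_identical(prof, mom):
        return "single_maternal"
    return "single_fetal"


def triage_mcc(
    supernatant: Mapping[str, GenotypeObservation] | None,
    precipitate: Mapping[str, GenotypeObservation] | None,
    maternal_profile: Mapping[str, Sequence[float]],
    panel: Sequence[MarkerDef],
) -> MccTriageResult:
    """Triage a physically separated contaminated amniotic fluid.

    Categories: identical single non-maternal profiles in both
    fractions -> A (the visible blood was fetal; conclusive); a single
    non-maternal supernatant profile over a mixed or maternal
    precipitate -> B (report from the supernatant; conclusive);
    anything without a clean fetal supernatant profile -> C
    (unresolved).  A missing fraction is an error; two *different*
    single fetal profiles are a sample-integrity error.
    """
    if supernatant is None or precipitate is None:
        raise CallerError("triage needs both supernatant and precipitate profiles")
    if not maternal_profile:
        raise CallerError("triage needs the maternal profile")
    s_state = fraction_state(supernatant, maternal_profile, panel)
    p_state = fraction_state(precipitate, maternal_profile, panel)
    evidence = {"supernatant": s_state, "precipitate": p_state}
    if s_state == "single_fetal" and p_state == "single_fetal":
        if not _profiles_identical(_profile_of(supernatant), _profile_of(precipitate)):
            raise CallerError(
                "fractions show two different single non-maternal profiles"
            )
        return MccTriageResult("A_fetal_blood", True, evidence)
    if s_state == "single_fetal":
        return MccTriageResult("B_resolved_by_supernatant", True, evidence)
    return MccTriageResult("C_unresolved", False, evidence)


def triage_category_map() -> dict[tuple[str, str], str]:
    """Exhaustive (supernatant, precipitate) state -> category mapping.

    The two-different-fetal-profiles error case is not representable
    here (it depends on profile identity, not state).
    """
    states = ("single_fetal", "mixed", "single_maternal")
    out = {}
    for s in states:
        for p in states:
            if s == "single_fetal" and p == "single_fetal":
                out[(s, p)] = "A_fetal_blood"
            elif s == "single_fetal":
                out[(s, p)] = "B_resolved_by_supernatant"
            else:
                out[(s, p)] = "C_unresolved"
    return out


# ---------------------------------------------------------------------------
# sample assembly


def call_sample(
    sample_id: str,
    genotypes: Mapping[str, GenotypeObservation],
    panel: Sequence[MarkerDef],
    model: ClassifierModel,
    maternal_profile: Mapping[str, Sequence[float]] | None = None,
    decay_lines: Mapping[str, MarkerCorrelation] | None = None,
) -> SampleReport:
    """Assemble the full per-sample report.

    ``genotypes`` maps marker name to its preprocessed observation
    (absent markers may be omitted; they count as uninformative).
    """
    by_name = panel_by_name(panel)
    if decay_lines is None:
        decay_lines = getattr(model, "decay_lines", None)
    calls: dict[str, ChromosomeCall] = {}
    notes: list[str] = []

    for chrom in ("13", "18", "21"):
        mcs = []
        for m in panel:
            if chrom in m.targets and m.role == "autosome_dosage":
                obs = genotypes.get(m.name) or GenotypeObservation(
                    sample_id, m.name, (), "absent"
                )
                mcs.append(
                    call_marker(obs, model, chromosome=chrom, decay_lines=decay_lines)
                )
        calls[chrom] = call_chromosome(chrom, mcs)

    try:
        sex = call_sex(genotypes, panel)
        calls["X"], calls["Y"] = sex.x_call, sex.y_call
        sex_verdict = sex.sex
        if sex.note:
            notes.append(sex.note)
        if sex.karyotype_label not in ("XX", "XY", "??"):
            notes.append(f"sex-chromosome pattern {sex.karyotype_label}")
    except CallerError as exc:
        sex_verdict = "undetermined"
        notes.append(str(exc))

    triploidy = detect_triploidy(calls)
    if triploidy:
        notes.append(
            "trisomic pattern on all evaluable autosomes: triploidy suspected; "
            "autosome verdicts reflect one event, not independent trisomies"
        )

    mcc_flag = False
    if maternal_profile is not None:
        mcc = detect_mcc(genotypes, maternal_profile, panel)
        mcc_flag = mcc.status == "contaminated"
        if mcc.mixup_warning:
            notes.append("fetal sample shares no maternal alleles: possible mix-up")
        elif mcc_flag:
            notes.append(
                f"maternal contamination evidence at {', '.join(mcc.evidence_markers)}"
            )
    else:
        suspicious = [
            c for c in calls.values() if c.verdict == "mcc_suspected"
        ]
        mcc_flag = bool(suspicious)

    return SampleReport(
        sample_id=sample_id,
        sex=sex_verdict,
        calls=calls,
        triploidy_flag=triploidy,
        mcc_flag=mcc_flag,
        notes=notes,
    )
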