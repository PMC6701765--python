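"""Synthetic QF-PCR peak and ratio data generator.

The generator emulates the statistical structure the classifier
assumes, so every module is testable without instrument data:

* per-marker baseline amplification with a marker-specific,
  size-dependent exponential decay — shorter fragments amplify
  preferentially, so a heterozygote's shorter/longer height ratio
  drifts above 1 as the allele size difference grows.  Decay
  coefficients are log-spaced over 0.006–0.016 per bp by allele-ladder
  width, so the per-marker Pearson correlation between ratio and size
  difference spans roughly 0.3–0.95, matching the spread seen on real
  panels;
* multiplicative log-normal peak-height noise (default per-peak CV 8%,
  of which 4% is allele-specific and the rest common-mode within a
  marker);
* trisomic dosage by duplicating one allele (2:1 or 1:2 diallelic, or
  a triallelic pattern when three distinct alleles are drawn);
* maternal–fetal genotype mixtures for contamination studies.

Mendelian structure is respected: the fetus inherits one maternal and
one paternal allele per autosomal marker, and the maternal genotype
used for admixture is the same one the fetal alleles were drawn from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .panel import MarkerDef, default_panel, regression_strs
from .tables import DiallelicObservation, PeakRecord

KARYOTYPES = (
    "46XX",
    "46XY",
    "T13",
    "T18",
    "T21",
    "69XXX",
    "XXY",
    "X0",
    "XXX",
    "XYY",
)

DEFAULT_NOISE_CV = 0.08
DEFAULT_ALLELE_NOISE_CV = 0.04
DEFAULT_MIN_RFU = 50.0
_DECAY_RANGE = (0.006, 0.016)  # fractional height loss per bp, across markers


class SimulationError(ValueError):
    """Raised for an impossible configuration."""


def _default_decays(panel: Sequence[MarkerDef]) -> dict[str, float]:
    """Per-marker decay, log-spaced over the range by ladder-width rank.

    Fragment-length decay is a chemistry property and varies only
    moderately between markers of one multiplex; the narrowest allele
    ladders get the low end so the ratio-vs-size-difference
    correlation spans the wide range seen on real panels (a narrow
    ladder's ratio is noise-dominated) while the classes stay linearly
    separable across markers.
    """
    strs = sorted(
        (m for m in panel if m.is_str),
        key=lambda m: (m.size_range[1] - m.size_range[0], m.name),
    )
    lo, hi = _DECAY_RANGE
    vals = np.exp(np.linspace(math.log(lo), math.log(hi), max(len(strs), 2)))
    decays = {m.name: float(v) for m, v in zip(strs, vals)}
    for m in panel:
        decays.setdefault(m.name, 0.002)  # fixed-size products: mild decay
    return decays


def _default_baselines(panel: Sequence[MarkerDef]) -> dict[str, float]:
    # deterministic per-marker spread of amplification efficiency
    return {
        m.name: 900.0 + 160.0 * (i % 7) for i, m in enumerate(panel)
    }


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    ``decay`` is the per-bp fractional height loss of each marker;
    ``baseline_rfu`` the expected height of a single-dose product at
    the marker's minimum size.  Allele ladders are integer repeat-unit
    steps spanning each STR's size range, uniform frequencies.
    """

    panel: list[MarkerDef] = field(default_factory=default_panel)
    karyotype: str = "46XY"
    mcc_fraction: float = 0.0
    noise_cv: float = DEFAULT_NOISE_CV
    allele_noise_cv: float = DEFAULT_ALLELE_NOISE_CV
    min_rfu: float = DEFAULT_MIN_RFU
    baseline_rfu: dict[str, float] = field(default_factory=dict)
    decay: dict[str, float] = field(default_factory=dict)
    allele_freqs: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.karyotype not in KARYOTYPES:
            raise SimulationError(f"unknown karyotype {self.karyotype!r}")
        if not 0.0 <= self.mcc_fraction < 1.0:
            raise SimulationError("mcc_fraction must be in [0, 1)")
        if self.noise_cv < 0 or self.allele_noise_cv < 0:
            raise SimulationError("noise CVs must be >= 0")
        if not self.baseline_rfu:
            self.baseline_rfu = _default_baselines(self.panel)
        if not self.decay:
            self.decay = _default_decays(self.panel)
        if any(d < 0 for d in self.decay.values()):
            raise SimulationError("decay must be >= 0")
        for m in self.panel:
            if m.is_str and m.name not in self.allele_freqs:
                lo, hi = m.size_range
                step = float(m.repeat_unit or 4)
                ladder = np.arange(lo, hi + 1e-9, step)
                freqs = np.full(len(ladder), 1.0 / len(ladder))
                self.allele_freqs[m.name] = (ladder, freqs)


def _copy_numbers(karyotype: str, rng: np.random.Generator) -> dict[str, int]:
    """Chromosome copy counts implied by the karyotype.

    Trisomy karyotypes draw the fetal sex at random; triploidy is
    modeled as 69,XXX.
    """
    counts = {"1": 2, "3": 2, "13": 2, "18": 2, "21": 2}
    if karyotype == "46XX":
        counts.update(X=2, Y=0)
    elif karyotype == "46XY":
        counts.update(X=1, Y=1)
    elif karyotype in ("T13", "T18", "T21"):
        counts[karyotype[1:]] = 3
        if rng.random() < 0.5:
            counts.update(X=2, Y=0)
        else:
            counts.update(X=1, Y=1)
    elif karyotype == "69XXX":
        counts = {k: 3 for k in counts}
        counts.update(X=3, Y=0)
    elif karyotype == "XXY":
        counts.update(X=2, Y=1)
    elif karyotype == "X0":
        counts.update(X=1, Y=0)
    elif karyotype == "XXX":
        counts.update(X=3, Y=0)
    elif karyotype == "XYY":
        counts.update(X=1, Y=2)
    return counts


@dataclass
class SimulatedSample:
    """Truth record plus generated peaks for one sample."""

    sample_id: str
    karyotype: str
    sex: str  # male | female
    copy_numbers: dict[str, int]
    mcc_fraction: float
    #: per-marker fetal allele doses: {marker: {size: copies}}
    fetal_alleles: dict[str, dict[float, int]]
    maternal_alleles: dict[str, dict[float, int]]
    peaks: dict[str, list[PeakRecord]]
    maternal_peaks: dict[str, list[PeakRecord]]

    @property
    def maternal_profile(self) -> dict[str, tuple[float, ...]]:
        return {
            m: tuple(sorted(d)) for m, d in self.maternal_alleles.items() if d
        }


def _noise(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=0.0, sigma=sigma))


def _shared_cv(total_cv: float, allele_cv: float) -> float:
    """Common-mode CV so that common x allele-specific has ``total_cv``.

    Peak heights of one marker in one sample share amplification and
    injection efficiency; only the allele-specific component moves the
    height ratio.  (1+cv_t^2) = (1+cv_s^2)(1+cv_a^2).
    """
    if total_cv <= allele_cv:
        return 0.0
    return math.sqrt((1.0 + total_cv**2) / (1.0 + allele_cv**2) - 1.0)


def _marker_peaks(
    marker: MarkerDef,
    doses: dict[float, int],
    config: SimulationConfig,
    rng: np.random.Generator,
    scale: float = 1.0,
) -> list[PeakRecord]:
    """Expected-height model: baseline x dose x (1-decay)^(size-min).

    Noise is multiplicative log-normal with total per-peak CV
    ``noise_cv``, split into a common-mode factor shared by all of the
    marker's peaks in this sample (amplification/injection efficiency)
    and an allele-specific factor (CV ``allele_noise_cv``) that is the
    only part moving the height ratio.
    """
    if not doses:
        return []
    base = config.baseline_rfu[marker.name]
    decay = config.decay[marker.name]
    if marker.is_str:
        smin = marker.size_range[0]
    else:
        smin = min(s for _, s in marker.products)
    common = _noise(rng, _shared_cv(config.noise_cv, config.allele_noise_cv))
    out = []
    for size, dose in sorted(doses.items()):
        expected = base * dose * (1.0 - decay) ** (size - smin) * scale
        h = expected * common * _noise(rng, config.allele_noise_cv)
        if h > 0:
            out.append(PeakRecord(size=float(size), height=h, marker=marker.name))
    return out


def _draw_alleles(
    marker: MarkerDef, n: int, rng: np.random.Generator, config: SimulationConfig
) -> list[float]:
    ladder, freqs = config.allele_freqs[marker.name]
    return [float(rng.choice(ladder, p=freqs)) for _ in range(n)]


def _str_dose(marker: MarkerDef, copies: dict[str, int]) -> int:
    # a co-amplifying STR (pseudoautosomal DXYS218) sums its targets' copies
    return sum(copies.get(c, 2) for c in marker.targets)


def simulate_sample(
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
    sample_id: str = "S1",
) -> SimulatedSample:
    """Generate one sample's full peak set (and its mother's).

    The per-marker expected peak height is
    ``baseline x dose x (1 - decay)^(size - min size)`` with
    multiplicative log-normal noise; maternal admixture adds the
    maternal genotype's peaks scaled by ``mcc_fraction`` (the fetal
    peaks are scaled by the complement).  Peaks below the detection
    floor are dropped.

    Genotypes and peak noise are drawn from separate child streams, so
    the same seed yields the same pregnancy (fetal and maternal
    genotypes) under different ``mcc_fraction`` settings — the natural
    construction for contamination and fraction-triage studies.
    """
    if seed is None:
        raise SimulationError("simulate_sample requires a seed")
    parent = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    rng, rng_noise = parent.spawn(2)
    copies = _copy_numbers(config.karyotype, rng)
    sex = "male" if copies["Y"] > 0 else "female"

    fetal: dict[str, dict[float, int]] = {}
    maternal: dict[str, dict[float, int]] = {}
    peaks: dict[str, list[PeakRecord]] = {}
    mother_peaks: dict[str, list[PeakRecord]] = {}

    for m in config.panel:
        if m.is_str:
            n_fetal = _str_dose(m, copies)
            sex_linked = "X" in m.targets or "Y" in m.targets
            if sex_linked and "X" not in m.targets:
                mother_alleles: list[float] = []
                father = _draw_alleles(m, 1, rng, config)
                fetal_alleles = [father[0]] * n_fetal
            elif sex_linked:
                mother_alleles = _draw_alleles(m, 2, rng, config)
                father = _draw_alleles(m, 1, rng, config)
                fetal_alleles = [mother_alleles[int(rng.integers(2))]]
                pool = mother_alleles + father
                # paternal X (if any) then extra copies for aneuploid X
                while len(fetal_alleles) < n_fetal:
                    src = father if len(fetal_alleles) == 1 else pool
                    fetal_alleles.append(src[int(rng.integers(len(src)))])
            else:
                mother_alleles = _draw_alleles(m, 2, rng, config)
                father = _draw_alleles(m, 2, rng, config)
                fetal_alleles = [
                    mother_alleles[int(rng.integers(2))],
                    father[int(rng.integers(2))],
                ]
                while len(fetal_alleles) < n_fetal:
                    # extra chromosome duplicates a parental allele
                    pool = mother_alleles + father
                    fetal_alleles.append(pool[int(rng.integers(len(pool)))])
            f_dose: dict[float, int] = {}
            for a in fetal_alleles:
                f_dose[a] = f_dose.get(a, 0) + 1
            m_dose: dict[float, int] = {}
            for a in mother_alleles:
                m_dose[a] = m_dose.get(a, 0) + 1
        else:
            f_dose = {}
            m_dose = {}
            for chrom_t, size in m.products:
                c = copies.get(chrom_t, 2)
                if c > 0:
                    f_dose[size] = f_dose.get(size, 0) + c
                mc = {"X": 2, "Y": 0}.get(chrom_t, 2)
                if mc > 0:
                    m_dose[size] = m_dose.get(size, 0) + mc
        fetal[m.name] = f_dose
        maternal[m.name] = m_dose

        fp = _marker_peaks(m, f_dose, config, rng_noise, scale=1.0 - config.mcc_fraction)
        mp_mix = (
            _marker_peaks(m, m_dose, config, rng_noise, scale=config.mcc_fraction)
            if config.mcc_fraction > 0
            else []
        )
        merged: dict[float, float] = {}
        for p in fp + mp_mix:
            merged[p.size] = merged.get(p.size, 0.0) + p.height
        peaks[m.name] = [
            PeakRecord(size=s, height=h, marker=m.name)
            for s, h in sorted(merged.items())
            if h >= config.min_rfu
        ]
        mother_peaks[m.name] = [
            p
            for p in _marker_peaks(m, m_dose, config, rng_noise)
            if p.height >= config.min_rfu
        ]

    return SimulatedSample(
        sample_id=sample_id,
        karyotype=config.karyotype,
        sex=sex,
        copy_numbers=copies,
        mcc_fraction=config.mcc_fraction,
        fetal_alleles=fetal,
        maternal_alleles=maternal,
        peaks=peaks,
        maternal_peaks=mother_peaks,
    )


def simulate_batch(
    n: int,
    config: SimulationConfig,
    seed: int,
    id_prefix: str = "SIM",
) -> list[SimulatedSample]:
    """n samples under one configuration, reproducible given the seed."""
    rng = np.random.default_rng(seed)
    return [
        simulate_sample(config, rng, sample_id=f"{id_prefix}{i:04d}")
        for i in range(n)
    ]


def simulate_training_set(
    n_normal: int,
    n_tri21: int,
    n_tri12: int,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> list[DiallelicObservation]:
    """Labeled diallelic observations in the regression-table layout.

    Each row draws a regression STR uniformly, two distinct alleles
    from its ladder, applies the dosage for its label (normal 1:1,
    shorter allele duplicated for 2:1, longer for 1:2) and the decay +
    noise height model.  Labels are correct by construction.
    """
    if seed is None:
        raise SimulationError("simulate_training_set requires a seed")
    if min(n_normal, n_tri21, n_tri12) < 0:
        raise SimulationError("counts must be >= 0")
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    strs = regression_strs(config.panel)
    rows: list[DiallelicObservation] = []
    plan = (
        [("normal_1_1", (1, 1))] * n_normal
        + [("trisomic_2_1", (2, 1))] * n_tri21
        + [("trisomic_1_2", (1, 2))] * n_tri12
    )
    for i, (label, (dose_s, dose_l)) in enumerate(plan):
        m = strs[int(rng.integers(len(strs)))]
        ladder, freqs = config.allele_freqs[m.name]
        a, b = rng.choice(ladder, size=2, replace=False, p=freqs)
        s_short, s_long = (float(a), float(b)) if a < b else (float(b), float(a))
        decay = config.decay[m.name]
        base = config.baseline_rfu[m.name]
        smin = m.size_range[0]
        common = _noise(rng, _shared_cv(config.noise_cv, config.allele_noise_cv))
        h_short = (
            base * dose_s * (1 - decay) ** (s_short - smin)
            * common * _noise(rng, config.allele_noise_cv)
        )
        h_long = (
            base * dose_l * (1 - decay) ** (s_long - smin)
            * common * _noise(rng, config.allele_noise_cv)
        )
        rows.append(
            DiallelicObservation(
                sample_id=f"T{i:05d}",
                marker=m.name,
                height_ratio=h_short / h_long,
                size_difference=s_long - s_short,
                label=label,
                size_short=s_short,
                size_long=s_long,
                height_short=h_short,
                height_long=h_long,
            )
        )
    return rows


def per_marker_counts(rows: Sequence[DiallelicObservation]) -> dict[str, dict[str, int]]:
    """Per-marker breakdown of label counts (training-set report)."""
    out: dict[str, dict[str, int]] = {}
    for o in rows:
        d = out.setdefault(o.marker, {})
        d[o.label] = d.get(o.label, 0) + 1
    return out
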