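"""From raw peak lists to genotype patterns and regression observations.

The preprocessing chain for one sample x marker is::

    filter_peaks -> resolve_plus_a -> call_pattern

after which two-allele patterns are turned into
:class:`~qfpcr.tables.DiallelicObservation` rows with

* ``height_ratio`` = height(shorter-fragment allele) / height(longer),
* ``size_difference`` = size(longer) - size(shorter).

With this orientation, normal heterozygotes sit near or above 1
(shorter fragments amplify preferentially), a trisomy duplicating the
shorter allele sits near 2 and one duplicating the longer allele sits
below 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .tables import DiallelicObservation, PeakRecord

#: default minimum peak height, RFU (instrument factory default)
DEFAULT_MIN_RFU = 50.0
#: default +A split-peak collapse window, bp
DEFAULT_PLUS_A_WINDOW = 1.0

PATTERNS = ("absent", "monoallelic", "diallelic", "triallelic", "multiallelic")


@dataclass(frozen=True)
class GenotypeObservation:
    """Preprocessed peaks for one sample x marker with a called pattern."""

    sample_id: str
    marker: str
    peaks: tuple[PeakRecord, ...]  # sorted by size ascending
    pattern: str

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")


def filter_peaks(
    peaks: Sequence[PeakRecord], min_rfu: float = DEFAULT_MIN_RFU
) -> list[PeakRecord]:
    """Drop peaks below the detection floor; order preserved."""
    if not min_rfu > 0:
        raise ValueError("min_rfu must be > 0")
    return [p for p in peaks if p.height >= min_rfu]


def resolve_plus_a(
    peaks: Sequence[PeakRecord], split_window: float = DEFAULT_PLUS_A_WINDOW
) -> list[PeakRecord]:
    """Collapse split peaks caused by incomplete +A nucleotide addition.

    Any pair of peaks closer than ``split_window`` bp is merged into the
    single peak of greater height (the fully extended +A product).
    Merging is iterative, closest pair first (ties: leftmost), so the
    result contains no two peaks within the window.
    """
    out = sorted(peaks, key=lambda p: (p.size, -p.height))
    while len(out) > 1:
        gaps = [out[i + 1].size - out[i].size for i in range(len(out) - 1)]
        i = min(range(len(gaps)), key=gaps.__getitem__)
        if gaps[i] >= split_window:
            break
        keep = out[i] if out[i].height >= out[i + 1].height else out[i + 1]
        out[i : i + 2] = [keep]
    return out


def call_pattern(
    sample_id: str, marker: str, peaks: Sequence[PeakRecord]
) -> GenotypeObservation:
    """Classify a filtered, +A-resolved peak list by allele count.

    0 peaks -> ``absent``; 1 -> ``monoallelic``; 2 -> ``diallelic``;
    3 -> ``triallelic``; more -> ``multiallelic`` (possible maternal
    contamination or a duplicated allele; flagged downstream).
    """
    n = len(peaks)
    pattern = (
        "absent"
        if n == 0
        else "monoallelic"
        if n == 1
        else "diallelic"
        if n == 2
        else "triallelic"
        if n == 3
        else "multiallelic"
    )
    ordered = tuple(sorted(peaks, key=lambda p: p.size))
    return GenotypeObservation(
        sample_id=sample_id, marker=marker, peaks=ordered, pattern=pattern
    )


def preprocess(
    sample_id: str,
    marker: str,
    peaks: Sequence[PeakRecord],
    min_rfu: float = DEFAULT_MIN_RFU,
    split_window: float = DEFAULT_PLUS_A_WINDOW,
) -> GenotypeObservation:
    """filter -> +A resolve -> pattern, the idempotent standard chain."""
    return call_pattern(
        sample_id, marker, resolve_plus_a(filter_peaks(peaks, min_rfu), split_window)
    )


def compute_diallelic(obs: GenotypeObservation) -> DiallelicObservation:
    """Turn a two-allele genotype into a regression observation.

    Raises
    ------
    ValueError
        If the observation is not diallelic.
    """
    if obs.pattern != "diallelic":
        raise ValueError(
            f"{obs.sample_id}/{obs.marker}: pattern is {obs.pattern}, "
            "need diallelic"
        )
    short, long = obs.peaks
    return DiallelicObservation(
        sample_id=obs.sample_id,
        marker=obs.marker,
        height_ratio=short.height / long.height,
        size_difference=long.size - short.size,
        label="unknown",
        size_short=short.size,
        size_long=long.size,
        height_short=short.height,
        height_long=long.height,
    )


def stutter_filter(
    peaks: Sequence[PeakRecord],
    repeat_unit: float,
    max_fraction: float = 0.15,
    window: float = 0.5,
) -> list[PeakRecord]:
    """Optional stutter removal (off by default in the standard chain).

    Removes any peak sitting one repeat unit below a taller peak when
    its height is under ``max_fraction`` of that peak.  The PCR
    protocol's final long extension step removes most stutter upstream,
    so this is a safety net for legacy data only.
    """
    ordered = sorted(peaks, key=lambda p: p.size)
    keep: list[PeakRecord] = []
    for p in ordered:
        is_stutter = any(
            abs((q.size - p.size) - repeat_unit) <= window
            and p.height < max_fraction * q.height
            for q in ordered
        )
        if not is_stutter:
            keep.append(p)
    return keep
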