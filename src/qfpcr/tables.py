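"""Readers and writers for peak tables and diallelic-ratio tables.

Two tab-delimited dialects of genotype/peak exports are accepted, both
modeled on capillary-sequencer genotype tables:

* *long*: one row per peak with ``sample``, ``marker``, ``size``,
  ``height`` columns;
* *wide*: one row per sample x marker with repeated ``Size 1``,
  ``Height 1``, ``Size 2`` ... column groups.

The dialect is autodetected from the header.  Column names are matched
case-insensitively after stripping spaces/underscores, because
instrument exports are not standardized.

The diallelic table is the regression-ready layout: one row per
heterozygous STR genotype with the two allele sizes and heights, the
height ratio (shorter-fragment height over longer-fragment height), the
allele size difference in bp, and a dosage label.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd

LABELS = ("normal_1_1", "trisomic_2_1", "trisomic_1_2", "unknown")

_LABEL_ALIASES = {
    "normal11": "normal_1_1",
    "normal": "normal_1_1",
    "11": "normal_1_1",
    "1:1": "normal_1_1",
    "normal1:1": "normal_1_1",
    "trisomic21": "trisomic_2_1",
    "trisomic2:1": "trisomic_2_1",
    "2:1": "trisomic_2_1",
    "21": "trisomic_2_1",
    "trisomic12": "trisomic_1_2",
    "trisomic1:2": "trisomic_1_2",
    "1:2": "trisomic_1_2",
    "12": "trisomic_1_2",
    "unknown": "unknown",
    "": "unknown",
}

#: tolerance for stored-vs-recomputed height ratio / size difference
RATIO_TOLERANCE = 0.005


class TableFormatError(ValueError):
    """Raised when an input table is malformed."""


@dataclass(frozen=True, order=True)
class PeakRecord:
    """One sized, height-measured electrophoresis peak."""

    size: float  # fragment length, bp (fractional: sized against a standard)
    height: float  # RFU
    marker: str = ""

    def __post_init__(self) -> None:
        if not self.size > 0:
            raise ValueError(f"peak size must be > 0, got {self.size}")
        if not self.height > 0:
            raise ValueError(f"peak height must be > 0, got {self.height}")


@dataclass(frozen=True)
class DiallelicObservation:
    """One heterozygous STR genotype, the unit of the dosage regression."""

    sample_id: str
    marker: str
    height_ratio: float
    size_difference: float
    label: str = "unknown"
    size_short: float | None = None
    size_long: float | None = None
    height_short: float | None = None
    height_long: float | None = None

    def __post_init__(self) -> None:
        if not self.height_ratio > 0:
            raise ValueError("height_ratio must be > 0")
        if self.size_difference < 0:
            raise ValueError("size_difference must be >= 0")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def normalize_label(raw: str) -> str:
    """Map a free-form dosage label to the three-level scheme."""
    key = "".join(str(raw).split()).lower().replace("_", "")
    key = key.replace("heightratio", "").replace("ratio", "")
    key = key.replace("trisomy", "trisomic")
    if key in _LABEL_ALIASES:
        return _LABEL_ALIASES[key]
    raise TableFormatError(f"unknown label string {raw!r}")


def _canon(col: str) -> str:
    return "".join(str(col).split()).lower().replace("_", "").replace("-", "")


def _find_col(canon_cols: dict[str, str], *names: str) -> str | None:
    for n in names:
        if n in canon_cols:
            return canon_cols[n]
    return None


def _read_tsv(source: str | Path | IO[str]) -> pd.DataFrame:
    try:
        return pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError("empty table (no header)") from exc


def _num(value: str, what: str, line: int) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise TableFormatError(
            f"line {line}: non-numeric {what} {value!r}"
        ) from None
    if math.isnan(x):
        raise TableFormatError(f"line {line}: non-numeric {what} {value!r}")
    return x


def read_peak_table(
    source: str | Path | IO[str],
    panel: Sequence | None = None,
    column_map: dict[str, str] | None = None,
) -> list[tuple[str, list[PeakRecord]]]:
    """Read a tab-delimited peak export (long or wide dialect).

    Parameters
    ----------
    source
        Path or open stream of the tab-delimited table.
    panel
        Optional list of MarkerDef; rows for markers absent from the
        panel are kept but reported with a warning (never silently
        dropped).
    column_map
        Optional override mapping canonical names (``sample``,
        ``marker``, ``size``, ``height``) to actual column headers.

    Returns
    -------
    list of (sample_id, peaks)
        Peaks grouped per sample, each tagged with its marker, in file
        order.
    """
    df = _read_tsv(source)
    canon = {_canon(c): c for c in df.columns}
    if column_map:
        for key, col in column_map.items():
            canon[_canon(key)] = col

    sample_col = _find_col(canon, "sample", "sampleid", "samplename", "samplefile")
    marker_col = _find_col(canon, "marker", "markername", "locus")
    if sample_col is None or marker_col is None:
        raise TableFormatError("peak table needs sample and marker columns")

    size_col = _find_col(canon, "size", "sizebp", "fragmentsize")
    height_col = _find_col(canon, "height", "peakheight", "rfu")
    wide_groups: list[tuple[str, str]] = []
    i = 1
    while True:
        s = _find_col(canon, f"size{i}", f"allelesize{i}")
        h = _find_col(canon, f"height{i}", f"peakheight{i}")
        if s is None or h is None:
            break
        wide_groups.append((s, h))
        i += 1

    if not wide_groups and (size_col is None or height_col is None):
        raise TableFormatError(
            "peak table needs size/height columns (long) or "
            "'Size 1'/'Height 1' column groups (wide)"
        )

    known = {m.name for m in panel} if panel is not None else None
    unknown: set[str] = set()
    per_sample: dict[str, list[PeakRecord]] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        sample = str(row[sample_col])
        marker = str(row[marker_col])
        if known is not None and marker not in known:
            unknown.add(marker)
        cells: list[tuple[str, str]]
        if wide_groups:
            cells = [
                (row[s], row[h])
                for s, h in wide_groups
                if str(row[s]).strip() != "" or str(row[h]).strip() != ""
            ]
        else:
            cells = [(row[size_col], row[height_col])]
        peaks = per_sample.setdefault(sample, [])
        for s_val, h_val in cells:
            peaks.append(
                PeakRecord(
                    size=_num(s_val, "size", line),
                    height=_num(h_val, "height", line),
                    marker=marker,
                )
            )
    if unknown:
        warnings.warn(
            f"peak table contains markers absent from the panel: "
            f"{sorted(unknown)}",
            stacklevel=2,
        )
    return list(per_sample.items())


def write_peak_table(
    samples: Iterable[tuple[str, Iterable[PeakRecord]]],
    dest: str | Path | IO[str],
) -> None:
    """Write peaks in the long dialect (one row per peak, 4 dp)."""
    rows = [
        {
            "sample": sid,
            "marker": p.marker,
            "size": f"{p.size:.4f}",
            "height": f"{p.height:.4f}",
        }
        for sid, peaks in samples
        for p in peaks
    ]
    pd.DataFrame(rows, columns=["sample", "marker", "size", "height"]).to_csv(
        dest, sep="\t", index=False
    )


DIALLELIC_COLUMNS = [
    "sample_id",
    "marker",
    "size_short",
    "size_long",
    "height_short",
    "height_long",
    "height_ratio",
    "size_difference",
    "label",
]


def read_diallelic_table(
    source: str | Path | IO[str],
) -> list[DiallelicObservation]:
    """Read a diallelic-ratio table (the regression layout).

    Raw sizes/heights, when present, are used to recompute the height
    ratio and size difference; a stored value disagreeing with the
    recomputed one beyond 0.005 is an error.  Labels are normalized to
    ``normal_1_1`` / ``trisomic_2_1`` / ``trisomic_1_2``.
    """
    df = _read_tsv(source)
    canon = {_canon(c): c for c in df.columns}
    marker_col = _find_col(canon, "marker", "markername", "locus")
    if marker_col is None:
        raise TableFormatError("diallelic table needs a marker column")
    sample_col = _find_col(canon, "sampleid", "sample", "samplename")
    ratio_col = _find_col(canon, "heightratio", "ratio")
    diff_col = _find_col(canon, "sizedifference", "sizediff", "allelesizedifference")
    ss = _find_col(canon, "sizeshort", "size1", "shorterallele")
    sl = _find_col(canon, "sizelong", "size2", "longerallele")
    hs = _find_col(canon, "heightshort", "height1")
    hl = _find_col(canon, "heightlong", "height2")
    label_col = _find_col(canon, "label", "status", "class")
    have_raw = None not in (ss, sl, hs, hl)
    if not have_raw and (ratio_col is None or diff_col is None):
        raise TableFormatError(
            "diallelic table needs either raw sizes/heights or "
            "height_ratio + size_difference columns"
        )

    out: list[DiallelicObservation] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        kwargs: dict = {
            "sample_id": str(row[sample_col]) if sample_col else "",
            "marker": str(row[marker_col]),
            "label": normalize_label(row[label_col]) if label_col else "unknown",
        }
        if have_raw:
            s1, s2 = _num(row[ss], "size", line), _num(row[sl], "size", line)
            h1, h2 = _num(row[hs], "height", line), _num(row[hl], "height", line)
            if s1 > s2:  # tolerate unsorted allele columns
                s1, s2, h1, h2 = s2, s1, h2, h1
            ratio = h1 / h2
            diff = s2 - s1
            kwargs.update(
                size_short=s1, size_long=s2, height_short=h1, height_long=h2
            )
            if ratio_col and str(row[ratio_col]).strip() != "":
                stored = _num(row[ratio_col], "height_ratio", line)
                if abs(stored - ratio) > RATIO_TOLERANCE:
                    raise TableFormatError(
                        f"line {line}: stored height_ratio {stored} "
                        f"inconsistent with recomputed {ratio:.4f}"
                    )
            if diff_col and str(row[diff_col]).strip() != "":
                stored = _num(row[diff_col], "size_difference", line)
                if abs(stored - diff) > RATIO_TOLERANCE:
                    raise TableFormatError(
                        f"line {line}: stored size_difference {stored} "
                        f"inconsistent with recomputed {diff:.4f}"
                    )
        else:
            ratio = _num(row[ratio_col], "height_ratio", line)
            diff = _num(row[diff_col], "size_difference", line)
        out.append(
            DiallelicObservation(
                height_ratio=ratio, size_difference=diff, **kwargs
            )
        )
    return out


def write_diallelic_table(
    observations: Iterable[DiallelicObservation],
    dest: str | Path | IO[str],
) -> None:
    """Write observations in the canonical diallelic layout (4 dp)."""

    def fmt(x: float | None) -> str:
        return "" if x is None else f"{x:.4f}"

    rows = [
        {
            "sample_id": o.sample_id,
            "marker": o.marker,
            "size_short": fmt(o.size_short),
            "size_long": fmt(o.size_long),
            "height_short": fmt(o.height_short),
            "height_long": fmt(o.height_long),
            "height_ratio": fmt(o.height_ratio),
            "size_difference": fmt(o.size_difference),
            "label": o.label,
        }
        for o in observations
    ]
    pd.DataFrame(rows, columns=DIALLELIC_COLUMNS).to_csv(
        dest, sep="\t", index=False
    )


def diallelic_to_frame(
    observations: Sequence[DiallelicObservation],
) -> pd.DataFrame:
    """Observations as a DataFrame (marker, height_ratio, size_difference, label)."""
    return pd.DataFrame(
        {
            "sample_id": [o.sample_id for o in observations],
            "marker": [o.marker for o in observations],
            "height_ratio": [o.height_ratio for o in observations],
            "size_difference": [o.size_difference for o in observations],
            "label": [o.label for o in observations],
        }
    )


def round_trip_equal(
    a: Sequence[DiallelicObservation], b: Sequence[DiallelicObservation]
) -> bool:
    """Element-wise equality at the 4-decimal write precision."""
    if len(a) != len(b):
        return False
    for x, y in zip(a, b):
        if (x.sample_id, x.marker, x.label) != (y.sample_id, y.marker, y.label):
            return False
        for fx, fy in (
            (x.height_ratio, y.height_ratio),
            (x.size_difference, y.size_difference),
        ):
            if abs(fx - fy) > 5e-4:
                return False
    return True
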