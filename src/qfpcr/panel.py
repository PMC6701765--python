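"""Marker panel definitions.

A QF-PCR assay is described by a panel of markers: length-polymorphic
STRs whose two allele peak heights carry chromosome dosage information,
and fixed-size markers (amelogenin-style) whose between-chromosome
product ratio counts sex chromosomes.  The bundled default panel
(``panel_v1``) is a 20-marker one-tube multiplex targeting 26 genomic
positions: three STRs on chromosome 13, four on 18, four on 21, six
sex-chromosome markers and three AZFc-region markers that are carried
through as presence/dosage annotations only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable

import yaml

MARKER_CLASSES = ("STR", "fixed_size")
MARKER_ROLES = (
    "autosome_dosage",
    "x_count",
    "xy_count",
    "x_vs_autosome_count",
    "y_presence",
    "azfc",
)

#: Y-specific STR excluded from the height-ratio regression (hemizygous,
#: never diallelic in a normal male; carried for AZFc annotation only).
REGRESSION_EXCLUDED = ("DYS448",)


class PanelError(ValueError):
    """Raised for an invalid or inconsistent panel configuration."""


@dataclass(frozen=True)
class MarkerDef:
    """Static description of one assay marker.

    ``targets`` lists the chromosomes of every genomic position the
    primer pair amplifies; a co-amplifying marker appears once per
    position (so ``len(targets)`` is its contribution to the panel's
    targeted-position count).
    """

    name: str
    dye: str
    marker_class: str
    role: str
    targets: tuple[str, ...]
    size_range: tuple[float, float] | None = None
    repeat_unit: int | None = None
    heterozygosity: float | None = None
    position: str | None = None
    #: fixed-size markers: per-target product length in bp
    products: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.marker_class not in MARKER_CLASSES:
            raise PanelError(
                f"{self.name}: unknown marker class {self.marker_class!r}"
            )
        if self.role not in MARKER_ROLES:
            raise PanelError(f"{self.name}: unknown role {self.role!r}")
        if not self.targets:
            raise PanelError(f"{self.name}: marker maps to no chromosome")
        if self.marker_class == "STR":
            if self.size_range is None or self.size_range[0] >= self.size_range[1]:
                raise PanelError(f"{self.name}: STR marker needs a size range")
        if self.heterozygosity is not None and not 0.0 <= self.heterozygosity <= 1.0:
            raise PanelError(f"{self.name}: heterozygosity outside [0, 1]")

    @property
    def is_str(self) -> bool:
        return self.marker_class == "STR"

    def product_size(self, chrom: str) -> float:
        """Product length for one target chromosome of a fixed-size marker."""
        for c, size in self.products:
            if c == chrom:
                return size
        raise KeyError(f"{self.name}: no product on chromosome {chrom}")


def _marker_from_mapping(entry: dict) -> MarkerDef:
    try:
        name = str(entry["name"])
    except KeyError as exc:
        raise PanelError("panel entry without a marker name") from exc
    size_range = entry.get("size_range")
    products = tuple(
        (str(p["chrom"]), float(p["size"])) for p in entry.get("products", ())
    )
    return MarkerDef(
        name=name,
        dye=str(entry.get("dye", "")),
        marker_class=str(entry.get("marker_class", "STR")),
        role=str(entry.get("role", "autosome_dosage")),
        targets=tuple(str(t) for t in entry.get("targets", ())),
        size_range=tuple(float(x) for x in size_range) if size_range else None,
        repeat_unit=int(entry["repeat_unit"]) if "repeat_unit" in entry else None,
        heterozygosity=(
            float(entry["heterozygosity"]) if "heterozygosity" in entry else None
        ),
        position=entry.get("position"),
        products=products,
    )


def load_panel(source: str | Path | IO[str]) -> list[MarkerDef]:
    """Load and validate a marker panel from a YAML config.

    Parameters
    ----------
    source
        Path to a panel YAML file, or an open text stream.

    Returns
    -------
    list of MarkerDef
        The validated panel, in file order.

    Raises
    ------
    PanelError
        On an empty config, duplicate marker names, a marker with no
        target, or an STR marker without a size range.
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    if not doc or "markers" not in doc or not doc["markers"]:
        raise PanelError("panel config defines no markers")
    panel = [_marker_from_mapping(e) for e in doc["markers"]]
    seen: set[str] = set()
    for m in panel:
        if m.name in seen:
            raise PanelError(f"duplicate marker name {m.name!r}")
        seen.add(m.name)
    return panel


def default_panel() -> list[MarkerDef]:
    """The bundled 20-marker ``panel_v1`` (26 targeted positions)."""
    ref = resources.files("qfpcr.data").joinpath("panel_v1.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return load_panel(fh)


def targeted_positions(panel: Iterable[MarkerDef]) -> int:
    """Total number of genomic positions the panel amplifies."""
    return sum(len(m.targets) for m in panel)


def markers_for_chromosome(
    panel: Iterable[MarkerDef], chrom: str
) -> list[MarkerDef]:
    """Markers with at least one target on ``chrom``."""
    return [m for m in panel if str(chrom) in m.targets]


def regression_strs(panel: Iterable[MarkerDef]) -> list[MarkerDef]:
    """STR markers eligible for height-ratio regression.

    All STRs except the hemizygous Y-only DYS448, which can never show a
    diallelic pattern in a euploid sample.
    """
    return [m for m in panel if m.is_str and m.name not in REGRESSION_EXCLUDED]


def panel_by_name(panel: Iterable[MarkerDef]) -> dict[str, MarkerDef]:
    return {m.name: m for m in panel}
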