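"""Elongase/desaturase reaction operators and the measured activity panels.

Two enzyme families drive LC-PUFA biosynthesis:

* **Elovl** (elongases) condense a C2 unit onto the carboxyl end of the
  acyl chain, so the chain grows by two carbons and every Delta position
  shifts by +2 while the omega (n-x) class is preserved.
* **Fads** (front-end desaturases) insert a new double bond between an
  existing unsaturation and the carboxyl end at a fixed regioselectivity
  (Δ5, Δ6 or Δ8 here), leaving the chain length unchanged.

The packaged fixture transcribes the yeast heterologous-expression assay
results for the 13 *Hemicentrotus pulcherrimus* Elovl and 3 Fads enzymes:
substrate → product conversions for each enzyme, plus qualitative
activities reported only as chromatogram peaks (MUFA elongation by
Elovl6-like C; the Δ5 desaturation of 18:0 to 18:1n-13 by FadsA).
"""

from __future__ import annotations

import csv
import enum
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .nomenclature import FattyAcid, parse_shorthand

__all__ = [
    "ActivityError",
    "ActivityRecord",
    "Conversion",
    "ConversionStatus",
    "EnzymeKind",
    "EnzymePanel",
    "apply_desaturation",
    "apply_elongation",
    "load_activity_panels",
]

#: Longest acyl chain producible by elongation; no product beyond C24 is
#: observed in the assay panels.
DEFAULT_CHAIN_CAP = 24


class ActivityError(ValueError):
    """Raised for chemically impossible operations or invalid fixture rows."""


class EnzymeKind(enum.Enum):
    DESATURASE = "desaturase"
    ELONGASE = "elongase"


class ConversionStatus(enum.Enum):
    """How a substrate→product conversion was reported.

    ``NOT_DETECTED`` ("n.d.") is distinct from a measured 0.0: it means the
    product peak stayed below the detection limit.  ``QUALITATIVE`` marks
    activities reported only as chromatogram peaks, without a percentage.
    """

    MEASURED = "measured"
    NOT_DETECTED = "n.d."
    QUALITATIVE = "qual"


@dataclass(frozen=True)
class Conversion:
    status: ConversionStatus
    percent: float | None = None

    def __post_init__(self) -> None:
        if self.status is ConversionStatus.MEASURED:
            if self.percent is None or not 0.0 <= self.percent <= 100.0:
                raise ActivityError(f"measured conversion must lie in [0, 100]: {self.percent}")
        elif self.percent is not None:
            raise ActivityError(f"{self.status.value} conversion carries no percentage")

    @classmethod
    def from_text(cls, text: str) -> "Conversion":
        text = text.strip()
        if text == "n.d.":
            return cls(ConversionStatus.NOT_DETECTED)
        if text == "qual":
            return cls(ConversionStatus.QUALITATIVE)
        value = float(text)
        if math.isnan(value):
            raise ActivityError("conversion is NaN")
        return cls(ConversionStatus.MEASURED, value)

    def __str__(self) -> str:
        if self.status is ConversionStatus.MEASURED:
            return f"{self.percent:g}"
        return self.status.value


@dataclass(frozen=True)
class ActivityRecord:
    """One measured (or qualitative) substrate→product conversion."""

    enzyme_name: str
    kind: EnzymeKind
    substrate: FattyAcid
    product: FattyAcid
    conversion: Conversion
    activity_label: str

    def __post_init__(self) -> None:
        expected = self.expected_product()
        if expected != self.product:
            raise ActivityError(
                f"{self.enzyme_name}: product {self.product} inconsistent with "
                f"{self.kind.value} acting on {self.substrate} (expected {expected})"
            )

    def expected_product(self) -> FattyAcid:
        """Product implied by the operator for this record's substrate."""
        if self.kind is EnzymeKind.ELONGASE:
            return apply_elongation(self.substrate)
        d = self.delta_position()
        return apply_desaturation(self.substrate, d)

    def delta_position(self) -> int:
        """Regioselectivity parsed from a desaturase activity label (e.g. 'Δ5')."""
        m = re.match(r"^Δ(\d+)$", self.activity_label.replace("∆", "Δ"))
        if not m:
            raise ActivityError(
                f"{self.enzyme_name}: cannot read a Δ position from label "
                f"{self.activity_label!r}"
            )
        return int(m.group(1))


@dataclass(frozen=True)
class EnzymePanel:
    """All assayed substrate→product conversions for one enzyme.

    ``regioselectivity`` is the Δ position of a desaturase's claimed
    activity (None for elongases).  Rows assaying other positions — e.g.
    the trace Δ6 conversions of FadsC2 — are kept with their own labels.
    """

    name: str
    kind: EnzymeKind
    records: tuple[ActivityRecord, ...]
    regioselectivity: int | None = None

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.enzyme_name != self.name or rec.kind != self.kind:
                raise ActivityError(f"record {rec} does not belong to panel {self.name}")


def apply_elongation(fa: FattyAcid, cap: int = DEFAULT_CHAIN_CAP) -> FattyAcid:
    """Add a C2 unit at the carboxyl end: chain +2, every Δ position +2.

    >>> str(apply_elongation(parse_shorthand("18:3n-3")))
    '20:3^Δ11,14,17^'
    """
    if fa.chain_length + 2 > cap:
        raise ActivityError(
            f"elongation of {fa} exceeds the C{cap} chain cap"
        )
    return FattyAcid(fa.chain_length + 2, tuple(d + 2 for d in fa.double_bonds))


def apply_desaturation(fa: FattyAcid, d: int) -> FattyAcid:
    """Insert a double bond at Δ``d``; the chain length is unchanged.

    Fails if ``d`` is already unsaturated, sits within one carbon of an
    existing bond, or falls outside the chain.
    """
    if d in fa.double_bonds:
        raise ActivityError(f"{fa} already has a double bond at Δ{d}")
    if any(abs(d - e) < 2 for e in fa.double_bonds):
        raise ActivityError(f"Δ{d} overlaps an existing double bond of {fa}")
    if not 2 <= d <= fa.chain_length - 1:
        raise ActivityError(f"Δ{d} outside the C{fa.chain_length} chain")
    return FattyAcid(fa.chain_length, fa.double_bonds + (d,))


# Claimed regioselectivity per desaturase, used to annotate panels.  FadsC1
# showed only a trace Δ8 conversion; the label follows its FadsC2-like
# orthology.
_FADS_REGIOSELECTIVITY = {"FadsA": 5, "FadsC1": 8, "FadsC2": 8}


def _read_rows(path: str | Path | None) -> list[dict[str, str]]:
    if path is None:
        ref = resources.files("pufapath.data").joinpath("activity_panels.csv")
        with ref.open("r", encoding="utf-8") as fh:
            return list(csv.DictReader(fh))
    with open(path, "r", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def load_activity_panels(path: str | Path | None = None) -> list[EnzymePanel]:
    """Load and validate the enzyme-activity fixture.

    Every row is checked structurally on load: the product must equal the
    elongation/desaturation operator applied to the substrate.  Returns one
    panel per enzyme, in fixture order (8 S/MUFA Elovl, 5 PUFA Elovl,
    3 Fads).
    """
    rows = _read_rows(path)
    by_enzyme: dict[str, list[ActivityRecord]] = {}
    kinds: dict[str, EnzymeKind] = {}
    for row in rows:
        kind = EnzymeKind(row["kind"])
        rec = ActivityRecord(
            enzyme_name=row["enzyme"],
            kind=kind,
            substrate=parse_shorthand(row["substrate"]),
            product=parse_shorthand(row["product"]),
            conversion=Conversion.from_text(row["conversion"]),
            activity_label=row["activity_label"].replace("∆", "Δ"),
        )
        by_enzyme.setdefault(rec.enzyme_name, []).append(rec)
        kinds[rec.enzyme_name] = kind
    panels = []
    for name, records in by_enzyme.items():
        panels.append(
            EnzymePanel(
                name=name,
                kind=kinds[name],
                records=tuple(records),
                regioselectivity=_FADS_REGIOSELECTIVITY.get(name),
            )
        )
    return panels


def export_activity_csv(panels: list[EnzymePanel], path: str | Path) -> None:
    """Write panels back to the fixture CSV format."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["enzyme", "kind", "substrate", "product", "conversion", "activity_label"])
        for panel in panels:
            for rec in panel.records:
                writer.writerow(
                    [
                        rec.enzyme_name,
                        rec.kind.value,
                        str(rec.substrate),
                        str(rec.product),
                        str(rec.conversion),
                        rec.activity_label,
                    ]
                )
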