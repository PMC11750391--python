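"""Substrate-conversion statistics from GC-FID FAME peak areas.

The assay readout is a table of identified FAME peak areas from one yeast
culture.  The conversion of an enzyme towards its substrate is

    conversion % = 100 x (sum of product areas) / (substrate area + sum of product areas)

Areas are treated as unitless and no detector response-factor correction is
applied.  When an elongase acts iteratively (e.g. 16:1n-7 -> 18:1n-7 ->
20:1n-7), every downstream product present in the table counts in the
numerator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .enzymes import EnzymeKind, EnzymePanel
from .nomenclature import parse_shorthand, to_delta_string

__all__ = ["PeakTable", "QuantError", "conversion_percent", "multi_step_products"]


class QuantError(ValueError):
    """Raised for ill-posed conversion computations (e.g. all-zero areas)."""


def _canon(shorthand: str) -> str:
    """Canonical key for a fatty-acid shorthand (delta dialect)."""
    return to_delta_string(parse_shorthand(shorthand))


@dataclass
class PeakTable:
    """Identified FAME peak areas from one culture, plus the assay roles.

    ``areas`` maps fatty-acid shorthand (either dialect) to a non-negative
    area; ``substrate_id`` and every ``product_ids`` entry must be keys of
    ``areas`` (a zero area is legitimate — the peak was sought and absent).
    """

    sample_id: str
    areas: dict[str, float]
    substrate_id: str
    product_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        canon_areas: dict[str, float] = {}
        for name, area in self.areas.items():
            if area < 0:
                raise QuantError(f"{self.sample_id}: negative area for {name}")
            canon_areas[_canon(name)] = float(area)
        self.areas = canon_areas
        self.substrate_id = _canon(self.substrate_id)
        self.product_ids = [_canon(p) for p in self.product_ids]
        missing = [p for p in [self.substrate_id, *self.product_ids] if p not in self.areas]
        if missing:
            raise QuantError(f"{self.sample_id}: no area recorded for {missing}")

    def area_of(self, shorthand: str) -> float:
        return self.areas[_canon(shorthand)]


def conversion_percent(table: PeakTable) -> float:
    """Conversion % = 100 x products / (substrate + products).

    Raises :class:`QuantError` when substrate and products are all zero:
    that is a failed assay, not a zero conversion.
    """
    products = sum(table.areas[p] for p in table.product_ids)
    substrate = table.areas[table.substrate_id]
    denom = substrate + products
    if denom <= 0:
        raise QuantError(
            f"{table.sample_id}: substrate and product areas are all zero; "
            "the conversion is undefined"
        )
    return 100.0 * products / denom


def multi_step_products(
    table: PeakTable, panels: list[EnzymePanel], enzyme: str
) -> list[str]:
    """Direct and iterated elongation products of the substrate in ``table``.

    Follows the named elongase's own recorded activities transitively from
    the table's substrate, returning every product with a recorded area
    (delta-dialect shorthand, discovery order).  Desaturases act once and
    do not cascade, so they yield an empty list.
    """
    panel = next((p for p in panels if p.name == enzyme), None)
    if panel is None:
        raise QuantError(f"unknown enzyme {enzyme!r}")
    if panel.kind is not EnzymeKind.ELONGASE:
        return []
    steps = {to_delta_string(r.substrate): to_delta_string(r.product) for r in panel.records}
    found: list[str] = []
    current = table.substrate_id
    while current in steps:
        current = steps[current]
        if current not in table.areas or current in found:
            break
        found.append(current)
    return found


def read_peak_tables(
    peaks_csv: str | Path, assays_csv: str | Path
) -> list[PeakTable]:
    """Assemble :class:`PeakTable` objects from the two-file CSV layout.

    ``peaks_csv`` has columns ``sample_id,fatty_acid,area``; ``assays_csv``
    has ``sample_id,substrate,products`` with ';'-separated products.
    """
    peaks = pd.read_csv(peaks_csv)
    assays = pd.read_csv(assays_csv)
    tables = []
    for _, row in assays.iterrows():
        sample = row["sample_id"]
        sub = peaks[peaks["sample_id"] == sample]
        if sub.empty:
            raise QuantError(f"no peaks recorded for sample {sample!r}")
        areas = dict(zip(sub["fatty_acid"], sub["area"]))
        products = [p for p in str(row["products"]).split(";") if p]
        tables.append(
            PeakTable(
                sample_id=sample,
                areas=areas,
                substrate_id=row["substrate"],
                product_ids=products,
            )
        )
    return tables


def conversions_frame(tables: list[PeakTable]) -> pd.DataFrame:
    """One row per assay: sample, substrate, products and conversion %."""
    rows = [
        {
            "sample_id": t.sample_id,
            "substrate": t.substrate_id,
            "products": ";".join(t.product_ids),
            "conversion_percent": conversion_percent(t),
        }
        for t in tables
    ]
    return pd.DataFrame(rows)
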