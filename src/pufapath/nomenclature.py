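"""Fatty-acid structure model and shorthand nomenclature.

A fatty acid is represented by its acyl chain length and the set of its
C=C double-bond positions counted from the carboxyl carbon (C1).  A double
bond at Delta-position ``d`` sits between carbons ``d`` and ``d + 1``.
Geometry (cis/trans) is not modelled: every bond handled here is assumed
cis, which is the only configuration relevant to the desaturase and
elongase chemistry downstream.

Two shorthand dialects are understood:

* the *omega* (n-x) dialect, e.g. ``20:4n-6``, which counts the terminal
  double bond from the methyl end and implies methylene interruption
  (successive bonds spaced exactly three carbons apart);
* the *delta* dialect, e.g. ``20:2^Δ5,11^``, which lists every position
  explicitly and is the only way to name non-methylene-interrupted
  fatty acids (NMI-FAs).

Both the ``Δ`` (U+0394) and ``∆`` (U+2206) glyphs are accepted on input;
``Δ`` is always emitted.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

__all__ = [
    "FattyAcid",
    "UnsaturationClass",
    "NomenclatureError",
    "parse_shorthand",
    "to_omega",
    "to_delta_string",
    "classify_unsaturation",
]

#: Methylene-interrupted spacing between successive double bonds.
_MI_SPACING = 3


class NomenclatureError(ValueError):
    """Raised for malformed shorthand or structurally invalid fatty acids."""


class UnsaturationClass(enum.Enum):
    """Unsaturation pattern of a fatty acid.

    ``nmi`` (non-methylene-interrupted) means at least two double bonds of
    which at least one adjacent pair is *not* spaced three carbons apart —
    e.g. 20:2^Δ5,11^ with a spacing of six.
    """

    SATURATED = "saturated"
    MONOUNSATURATED = "monounsaturated"
    METHYLENE_INTERRUPTED = "methylene_interrupted"
    NMI = "nmi"


@dataclass(frozen=True, order=True)
class FattyAcid:
    """An acyl chain with Delta-numbered double bonds.

    Parameters
    ----------
    chain_length:
        Number of carbons, carboxyl carbon = C1.  Must be >= 2.
    double_bonds:
        Strictly increasing Delta positions; each ``d`` satisfies
        ``2 <= d <= chain_length - 1`` and adjacent positions differ by at
        least 2 (cumulated dienes are not representable).
    """

    chain_length: int
    double_bonds: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "double_bonds", tuple(sorted(self.double_bonds)))
        if self.chain_length < 2:
            raise NomenclatureError(f"chain length must be >= 2, got {self.chain_length}")
        for d in self.double_bonds:
            if not 2 <= d <= self.chain_length - 1:
                raise NomenclatureError(
                    f"double-bond position Δ{d} outside [2, {self.chain_length - 1}] "
                    f"for a C{self.chain_length} chain"
                )
        for a, b in zip(self.double_bonds, self.double_bonds[1:]):
            if b - a < 2:
                raise NomenclatureError(
                    f"double bonds Δ{a} and Δ{b} overlap (spacing must be >= 2)"
                )

    @property
    def n_double_bonds(self) -> int:
        return len(self.double_bonds)

    def __str__(self) -> str:
        return to_delta_string(self)


def classify_unsaturation(fa: FattyAcid) -> UnsaturationClass:
    """Classify the double-bond pattern of ``fa``."""
    db = fa.double_bonds
    if len(db) == 0:
        return UnsaturationClass.SATURATED
    if len(db) == 1:
        return UnsaturationClass.MONOUNSATURATED
    spacings = {b - a for a, b in zip(db, db[1:])}
    if spacings == {_MI_SPACING}:
        return UnsaturationClass.METHYLENE_INTERRUPTED
    return UnsaturationClass.NMI


def _normalize(text: str) -> str:
    # accept both the Greek capital delta and the increment sign
    return text.strip().replace("∆", "Δ")


_SATURATED_RE = re.compile(r"^(\d+):0$")
_OMEGA_RE = re.compile(r"^(\d+):(\d+)n-(\d+)$")
_DELTA_RE = re.compile(r"^(\d+):(\d+)\^?Δ(\d+(?:,\d+)*)\^?$")


def parse_shorthand(text: str) -> FattyAcid:
    """Parse either shorthand dialect into a :class:`FattyAcid`.

    Omega names ``C:Dn-x`` expand to positions ``C - x - 3k`` for
    ``k = 0 .. D-1`` (methylene interruption towards the carboxyl end);
    delta names list their positions literally.

    >>> parse_shorthand("20:4n-6").double_bonds
    (5, 8, 11, 14)
    >>> parse_shorthand("20:2^Δ5,11^").double_bonds
    (5, 11)
    """
    text = _normalize(text)
    m = _SATURATED_RE.match(text)
    if m:
        return FattyAcid(int(m.group(1)), ())
    m = _OMEGA_RE.match(text)
    if m:
        chain, n_db, x = (int(g) for g in m.groups())
        if n_db == 0:
            raise NomenclatureError(f"{text!r}: saturated acid cannot carry an n-x suffix")
        positions = [chain - x - _MI_SPACING * k for k in range(n_db)]
        if positions[-1] < 2:
            raise NomenclatureError(
                f"{text!r}: omega expansion reaches Δ{positions[-1]} < 2"
            )
        return FattyAcid(chain, tuple(sorted(positions)))
    m = _DELTA_RE.match(text)
    if m:
        chain, n_db = int(m.group(1)), int(m.group(2))
        positions = tuple(int(p) for p in m.group(3).split(","))
        if len(set(positions)) != len(positions):
            raise NomenclatureError(f"{text!r}: duplicate double-bond positions")
        if len(positions) != n_db:
            raise NomenclatureError(
                f"{text!r}: declares {n_db} double bonds but lists {len(positions)}"
            )
        return FattyAcid(chain, positions)
    raise NomenclatureError(f"unrecognized fatty-acid shorthand: {text!r}")


def to_omega(fa: FattyAcid) -> str:
    """Render ``fa`` in the omega (n-x) dialect.

    Only defined for saturated, monounsaturated and methylene-interrupted
    acids; an NMI structure has no canonical omega name and raises
    :class:`NomenclatureError` (use :func:`to_delta_string`).
    """
    cls = classify_unsaturation(fa)
    if cls is UnsaturationClass.SATURATED:
        return f"{fa.chain_length}:0"
    if cls is UnsaturationClass.NMI:
        raise NomenclatureError(
            f"{to_delta_string(fa)} is non-methylene-interrupted and has no "
            "omega (n-x) name; use to_delta_string"
        )
    x = fa.chain_length - max(fa.double_bonds)
    return f"{fa.chain_length}:{fa.n_double_bonds}n-{x}"


def to_delta_string(fa: FattyAcid) -> str:
    """Render ``fa`` in the delta dialect, e.g. ``20:2^Δ5,13^``.

    Saturated acids render as plain ``C:0``.  Inverse of
    :func:`parse_shorthand` on its own output.
    """
    if not fa.double_bonds:
        return f"{fa.chain_length}:0"
    pos = ",".join(str(d) for d in fa.double_bonds)
    return f"{fa.chain_length}:{fa.n_double_bonds}^Δ{pos}^"
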