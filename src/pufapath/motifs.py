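"""Motif-based classification of Elovl and Fads candidate proteins.

Elongases fall into two sequence-defined subfamilies, recognized by short
histidine-containing motifs (written PROSITE-style, ``/`` = alternation,
``X`` = any residue):

* S/MUFA Elovl: ``H-W/T-X-H-H``
* PUFA Elovl:  ``Q/H-X-T/S-X-L-H-X-X-H-H``

Front-end desaturases carry three conserved histidine boxes that must
appear in N→C order: ``H-X-X-X-H``, ``H-X-X-H-H`` and ``Q-X-X-H-H``.

An unknown residue ``X`` in an input sequence matches only wildcard
pattern positions (conservative: it never certifies a constrained match).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ELOVL_PUFA_PATTERN",
    "ELOVL_SMUFA_PATTERN",
    "FADS_BOXES",
    "ClassificationResult",
    "EnzymeClass",
    "MotifPattern",
    "ProteinRecord",
    "classify_elovl",
    "classify_fads",
    "read_fasta",
    "scan",
    "write_fasta",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class EnzymeClass(enum.Enum):
    SMUFA_ELOVL = "smufa_elovl"
    PUFA_ELOVL = "pufa_elovl"
    FADS_LIKE = "fads_like"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence; uppercase, 20-letter alphabet plus X."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if not seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(seq) - AMINO_ACIDS - {"X"}
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")
        object.__setattr__(self, "seq", seq)


@dataclass(frozen=True)
class MotifPattern:
    """Ordered positions, each a set of allowed residues (None = wildcard)."""

    name: str
    positions: tuple[frozenset[str] | None, ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 3:
            raise ValueError(f"{self.name}: pattern shorter than 3 positions")
        if all(p is None for p in self.positions):
            raise ValueError(f"{self.name}: pattern is all wildcards")

    @classmethod
    def from_text(cls, name: str, text: str) -> "MotifPattern":
        """Parse dash-separated notation, e.g. ``H-W/T-X-H-H``."""
        positions: list[frozenset[str] | None] = []
        for token in text.split("-"):
            token = token.strip().upper()
            if token == "X":
                positions.append(None)
            else:
                residues = frozenset(token.split("/"))
                if not residues <= AMINO_ACIDS:
                    raise ValueError(f"{name}: invalid residues in token {token!r}")
                positions.append(residues)
        return cls(name, tuple(positions))

    def __len__(self) -> int:
        return len(self.positions)


ELOVL_SMUFA_PATTERN = MotifPattern.from_text("elovl_smufa", "H-W/T-X-H-H")
ELOVL_PUFA_PATTERN = MotifPattern.from_text("elovl_pufa", "Q/H-X-T/S-X-L-H-X-X-H-H")
FADS_BOXES = (
    MotifPattern.from_text("fads_box1", "H-X-X-X-H"),
    MotifPattern.from_text("fads_box2", "H-X-X-H-H"),
    MotifPattern.from_text("fads_box3", "Q-X-X-H-H"),
)


@dataclass(frozen=True)
class ClassificationResult:
    id: str
    label: EnzymeClass
    matches: tuple[tuple[str, int], ...] = ()  # (pattern name, 1-based start)
    ambiguous: bool = False


def scan(record: ProteinRecord, pattern: MotifPattern) -> list[int]:
    """1-based start positions of every window matching ``pattern``.

    A sequence 'X' (unknown residue) matches only wildcard positions.
    """
    seq, hits = record.seq, []
    for start in range(len(seq) - len(pattern) + 1):
        ok = True
        for offset, allowed in enumerate(pattern.positions):
            if allowed is not None and seq[start + offset] not in allowed:
                ok = False
                break
        if ok:
            hits.append(start + 1)
    return hits


def classify_elovl(record: ProteinRecord) -> ClassificationResult:
    """Assign an Elovl subfamily from the two histidine motifs.

    The longer, more specific PUFA motif takes precedence when both match;
    the double match is flagged ambiguous.
    """
    pufa_hits = scan(record, ELOVL_PUFA_PATTERN)
    smufa_hits = scan(record, ELOVL_SMUFA_PATTERN)
    matches = tuple(
        [(ELOVL_PUFA_PATTERN.name, p) for p in pufa_hits]
        + [(ELOVL_SMUFA_PATTERN.name, p) for p in smufa_hits]
    )
    if pufa_hits:
        return ClassificationResult(
            record.id, EnzymeClass.PUFA_ELOVL, matches, ambiguous=bool(smufa_hits)
        )
    if smufa_hits:
        return ClassificationResult(record.id, EnzymeClass.SMUFA_ELOVL, matches)
    return ClassificationResult(record.id, EnzymeClass.UNCLASSIFIED)


def classify_fads(record: ProteinRecord) -> ClassificationResult:
    """Screen for the three desaturase histidine boxes in N→C order.

    The first occurrence of each box is used; the screen passes only when
    box1 < box2 < box3.
    """
    firsts: list[tuple[str, int]] = []
    for box in FADS_BOXES:
        hits = scan(record, box)
        if not hits:
            return ClassificationResult(record.id, EnzymeClass.UNCLASSIFIED)
        firsts.append((box.name, hits[0]))
    starts = [pos for _, pos in firsts]
    if starts[0] < starts[1] < starts[2]:
        return ClassificationResult(record.id, EnzymeClass.FADS_LIKE, tuple(firsts))
    return ClassificationResult(record.id, EnzymeClass.UNCLASSIFIED, tuple(firsts))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def results_frame(results: list[ClassificationResult]) -> pd.DataFrame:
    """Tabulate classification results (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "label": r.label.value,
                "ambiguous": r.ambiguous,
                "match_positions": ";".join(f"{name}@{pos}" for name, pos in r.matches),
            }
            for r in results
        ]
    )


def fetch_deposited_sequences(out_path: str | Path, email: str) -> list[ProteinRecord]:
    """Download the deposited GenBank ORFs' protein translations (needs network).

    Accessions OR859744–OR859751 and OR753998–OR754002 (elongases) and
    OR545538–OR545540 (desaturases).  Writes a FASTA next to returning the
    records.
    """
    from Bio import Entrez

    accessions = (
        [f"OR8597{n}" for n in range(44, 52)]
        + [f"OR7539{n}" for n in range(98, 100)]
        + [f"OR7540{n:02d}" for n in range(0, 3)]
        + [f"OR5455{n}" for n in range(38, 41)]
    )
    Entrez.email = email
    records: list[ProteinRecord] = []
    with Entrez.efetch(
        db="nuccore", id=",".join(accessions), rettype="fasta_cds_aa", retmode="text"
    ) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append(ProteinRecord(rec.id, str(rec.seq).rstrip("*")))
    write_fasta(records, out_path)
    return records
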