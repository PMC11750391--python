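"""DMOX-derivative EI-MS fragment prediction and double-bond inference.

4,4-dimethyloxazoline (DMOX) derivatives of fatty acids fragment under
electron ionization into a ladder of ions each containing one more acyl
carbon than the last.  At unit-mass resolution the ladder obeys a simple
arithmetic: the ions containing 2 and 3 acyl carbons sit at m/z 113 and
126, and each further carbon adds 14 u across a saturated centre but only
12 u across a carbon that starts a C=C double bond.  A gap of 12 u between
the ions with n-1 and n carbons therefore localizes a double bond at
Delta-n.  The Δ5 bond is a special case: it is read from a diagnostic ion
at m/z 153 rather than from the (unreliable) low-mass gap region.

Inference inverts the model: enumerate candidate double-bond sets, predict
each candidate's peaks, and score the fraction of predicted peaks present
in the observed spectrum.

Everything here is unit-mass integer arithmetic; isotopes and intensities
(beyond peak presence) are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from pathlib import Path

import numpy as np

from .nomenclature import FattyAcid

__all__ = [
    "DmoxError",
    "DmoxSpectrum",
    "FragmentSeries",
    "UninterpretableSpectrum",
    "diagnostic_ions",
    "infer_double_bonds",
    "predict_series",
]

#: m/z of the fragments containing 2 and 3 acyl carbons.
ANCHOR_MZ = {2: 113, 3: 126}
#: Mass step per added acyl carbon: saturated vs double-bond-bearing.
STEP_SATURATED = 14
STEP_UNSATURATED = 12
#: The molecular ion sits 15 u above the (chain_length - 1)-carbon fragment.
MOLECULAR_ION_OFFSET = 15

#: Diagnostic ions keyed by Delta position.  Only the Δ5 rule (m/z 153) is
#: established; the table is the extension point for further positions.
DIAGNOSTIC_RULES: dict[int, int] = {5: 153}

#: Double bonds are only localizable within [4, chain_length - 2]: below the
#: fragment ladder's anchor region and at the methyl terminus the model
#: carries no signal.
DETECTABLE_MIN = 4


class DmoxError(ValueError):
    """Raised for structures or spectra outside the model."""


class UninterpretableSpectrum(DmoxError):
    """No candidate structure explains the spectrum above the score floor."""


def detectable_range(chain_length: int) -> tuple[int, int]:
    return (DETECTABLE_MIN, chain_length - 2)


@dataclass(frozen=True)
class FragmentSeries:
    """The predicted fragment ladder of one DMOX derivative."""

    entries: tuple[tuple[int, int], ...]  # (n_acyl_carbons, mz)
    molecular_ion: int

    def mz_of(self, n_carbons: int) -> int:
        for n, mz in self.entries:
            if n == n_carbons:
                return mz
        raise KeyError(f"no fragment with {n_carbons} acyl carbons")

    @property
    def mz_values(self) -> tuple[int, ...]:
        return tuple(mz for _, mz in self.entries)

    def gaps_of_12(self) -> list[int]:
        """Delta positions flagged by a 12-u step in the ladder."""
        return [
            n
            for (n_prev, mz_prev), (n, mz) in zip(self.entries, self.entries[1:])
            if mz - mz_prev == STEP_UNSATURATED
        ]


@dataclass(frozen=True)
class DmoxSpectrum:
    """Observed (or simulated) unit-mass peak list."""

    peaks: tuple[tuple[int, float], ...]  # (mz, intensity)
    chain_length_hint: int | None = None

    def __post_init__(self) -> None:
        mzs = [mz for mz, _ in self.peaks]
        if any(mz <= 0 for mz in mzs):
            raise DmoxError("m/z values must be positive")
        if len(set(mzs)) != len(mzs):
            raise DmoxError("duplicate m/z values in spectrum")
        if any(i < 0 for _, i in self.peaks):
            raise DmoxError("intensities must be non-negative")
        object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))

    @property
    def mz_set(self) -> frozenset[int]:
        return frozenset(mz for mz, _ in self.peaks)

    @classmethod
    def from_csv(cls, path: str | Path, chain_length_hint: int | None = None) -> "DmoxSpectrum":
        peaks = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.lower().startswith("mz"):
                    continue
                mz_text, intensity_text = line.split(",")[:2]
                peaks.append((int(round(float(mz_text))), float(intensity_text)))
        return cls(tuple(peaks), chain_length_hint)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("mz,intensity\n")
            for mz, intensity in self.peaks:
                fh.write(f"{mz},{intensity:g}\n")


def _series_mz(chain_length: int, double_bonds: tuple[int, ...]) -> list[int]:
    mz = [ANCHOR_MZ[2], ANCHOR_MZ[3]]
    bonds = set(double_bonds)
    for n in range(4, chain_length):
        step = STEP_UNSATURATED if n in bonds else STEP_SATURATED
        mz.append(mz[-1] + step)
    return mz


def predict_series(fa: FattyAcid) -> FragmentSeries:
    """Predict the fragment ladder and molecular ion for ``fa``.

    >>> s = predict_series(FattyAcid(20, (5, 11)))
    >>> s.mz_of(10), s.mz_of(11)
    (222, 234)
    """
    if fa.chain_length < 4:
        raise DmoxError(f"chain too short for a fragment ladder: {fa}")
    lo, hi = detectable_range(fa.chain_length)
    outside = [d for d in fa.double_bonds if not lo <= d <= hi]
    if outside:
        raise DmoxError(
            f"double bond(s) at Δ{outside} outside the detectable range "
            f"[{lo}, {hi}] — structure out of model"
        )
    mz = _series_mz(fa.chain_length, fa.double_bonds)
    entries = tuple(zip(range(2, fa.chain_length), mz))
    return FragmentSeries(entries=entries, molecular_ion=mz[-1] + MOLECULAR_ION_OFFSET)


def diagnostic_ions(fa: FattyAcid) -> dict[int, int]:
    """Diagnostic ions expected for ``fa``, keyed by Delta position."""
    return {d: mz for d, mz in DIAGNOSTIC_RULES.items() if d in fa.double_bonds}


def predicted_peaks(fa: FattyAcid) -> frozenset[int]:
    """All m/z the model expects: ladder + diagnostics + molecular ion."""
    series = predict_series(fa)
    return frozenset(series.mz_values) | frozenset(diagnostic_ions(fa).values()) | {
        series.molecular_ion
    }


@lru_cache(maxsize=32)
def _candidates(chain_length: int, max_bonds: int) -> tuple[tuple[tuple[int, ...], ...], np.ndarray, np.ndarray]:
    """Enumerate candidate double-bond sets and their predicted-peak matrix.

    Returns (candidate tuples, boolean peak matrix over m/z 0..max, peak
    counts per candidate).  Candidates have positions in the detectable
    range with spacing >= 2 and at most ``max_bonds`` bonds.
    """
    lo, hi = detectable_range(chain_length)
    positions = range(lo, hi + 1)
    cands: list[tuple[int, ...]] = []
    for k in range(0, max_bonds + 1):
        for combo in combinations(positions, k):
            if all(b - a >= 2 for a, b in zip(combo, combo[1:])):
                cands.append(combo)
    max_mz = ANCHOR_MZ[3] + STEP_SATURATED * chain_length + MOLECULAR_ION_OFFSET + 1
    matrix = np.zeros((len(cands), max_mz), dtype=bool)
    for i, combo in enumerate(cands):
        mz = _series_mz(chain_length, combo)
        matrix[i, mz] = True
        matrix[i, mz[-1] + MOLECULAR_ION_OFFSET] = True
        for d, diag in DIAGNOSTIC_RULES.items():
            if d in combo:
                matrix[i, diag] = True
    return tuple(cands), matrix, matrix.sum(axis=1)


def infer_double_bonds(
    spectrum: DmoxSpectrum,
    chain_length: int | None = None,
    max_bonds: int = 6,
    score_floor: float = 0.5,
) -> tuple[FattyAcid, float]:
    """Infer double-bond positions from an observed spectrum.

    Scores every candidate set by the fraction of its predicted peaks
    present (exact unit-mass match) in the spectrum and returns the best
    candidate with its score.  Ties prefer fewer double bonds, then the
    lexicographically smallest position set.

    Raises :class:`UninterpretableSpectrum` if no candidate reaches
    ``score_floor``.
    """
    if chain_length is None:
        chain_length = spectrum.chain_length_hint
    if chain_length is None:
        raise DmoxError("chain length must be given (argument or spectrum hint)")
    if chain_length < 4:
        raise DmoxError("chain too short for inference")

    cands, matrix, counts = _candidates(chain_length, max_bonds)
    observed = np.zeros(matrix.shape[1], dtype=bool)
    mzs = [mz for mz in spectrum.mz_set if mz < matrix.shape[1]]
    observed[mzs] = True
    scores = (matrix & observed).sum(axis=1) / counts
    # ties: max score, then fewest bonds, then smallest position set
    order = sorted(
        range(len(cands)), key=lambda i: (-scores[i], len(cands[i]), cands[i])
    )
    best = order[0]
    if scores[best] < score_floor:
        raise UninterpretableSpectrum(
            f"best candidate {cands[best]} scores {scores[best]:.2f} < {score_floor}"
        )
    return FattyAcid(chain_length, cands[best]), float(scores[best])
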