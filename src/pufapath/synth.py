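"""Seeded generators for synthetic test inputs.

Each generator emulates the statistical shape of one assay input so every
analysis stage can be exercised without instrument data:

* motif-bearing protein sequences of each enzyme class (uniform random
  background with the class motif embedded, rejection-sampled until the
  classifier returns exactly the requested class);
* GC-FID peak tables with a known true conversion fraction, log-normal
  multiplicative area noise, and the yeast endogenous background FAMEs;
* DMOX spectra with decreasing ladder intensities, seeded peak dropout
  (never erasing both flanks of a diagnostic 12-u gap) and uniform noise
  peaks kept >= 2 u away from true peaks.

All randomness flows from a single integer seed through one
``numpy.random.Generator`` per call, so identical configs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dmox import (
    DmoxSpectrum,
    diagnostic_ions,
    predict_series,
)
from .gc_quant import PeakTable
from .motifs import (
    AMINO_ACIDS,
    ELOVL_PUFA_PATTERN,
    ELOVL_SMUFA_PATTERN,
    FADS_BOXES,
    EnzymeClass,
    MotifPattern,
    ProteinRecord,
    classify_elovl,
    classify_fads,
)
from .nomenclature import FattyAcid

__all__ = [
    "SynthConfig",
    "gen_dmox_spectrum",
    "gen_peak_table",
    "gen_protein",
    "gen_protein_panel",
]

_ALPHABET = sorted(AMINO_ACIDS)

#: Endogenous yeast FAMEs present in every chromatogram, with typical
#: relative areas.
_BACKGROUND_FAMES = {"16:0": 800.0, "16:1n-7": 600.0, "18:0": 500.0, "18:1n-9": 700.0}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for all three generators; unused fields are ignored per call."""

    seed: int = 0
    # proteins
    seq_length: int = 300
    rejection_budget: int = 1000
    # peak tables
    true_conversion: float = 50.0
    noise_cv: float = 0.1
    total_assay_area: float = 1000.0
    # spectra
    n_noise_peaks: int = 10
    dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_conversion <= 100.0:
            raise ValueError("true_conversion must lie in [0, 100]")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.noise_cv < 0 or self.seq_length <= 0:
            raise ValueError("invalid config")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _instantiate(pattern: MotifPattern, rng: np.random.Generator) -> str:
    return "".join(
        _ALPHABET[rng.integers(len(_ALPHABET))] if allowed is None
        else sorted(allowed)[rng.integers(len(allowed))]
        for allowed in pattern.positions
    )


def _random_seq(length: int, rng: np.random.Generator) -> list[str]:
    return [_ALPHABET[i] for i in rng.integers(len(_ALPHABET), size=length)]


def _embed(seq: list[str], motif: str, start: int) -> None:
    seq[start : start + len(motif)] = list(motif)


def gen_protein(
    cls: EnzymeClass, cfg: SynthConfig, rng: np.random.Generator | None = None
) -> ProteinRecord:
    """One synthetic protein whose classification is exactly ``cls``.

    Rejection-samples until the relevant classifier returns ``cls`` with
    ``ambiguous`` False (for ``UNCLASSIFIED``: until neither the Elovl nor
    the Fads screen fires).
    """
    if rng is None:
        rng = cfg.rng()
    for attempt in range(cfg.rejection_budget):
        seq = _random_seq(cfg.seq_length, rng)
        if cls is EnzymeClass.SMUFA_ELOVL:
            start = int(rng.integers(cfg.seq_length - len(ELOVL_SMUFA_PATTERN)))
            _embed(seq, _instantiate(ELOVL_SMUFA_PATTERN, rng), start)
        elif cls is EnzymeClass.PUFA_ELOVL:
            start = int(rng.integers(cfg.seq_length - len(ELOVL_PUFA_PATTERN)))
            _embed(seq, _instantiate(ELOVL_PUFA_PATTERN, rng), start)
        elif cls is EnzymeClass.FADS_LIKE:
            # one box per third of the sequence guarantees N→C order
            third = cfg.seq_length // 3
            for i, box in enumerate(FADS_BOXES):
                start = i * third + int(rng.integers(third - len(box)))
                _embed(seq, _instantiate(box, rng), start)
        record = ProteinRecord(f"synth_{cls.value}_{attempt}", "".join(seq))
        elovl = classify_elovl(record)
        fads = classify_fads(record)
        if cls is EnzymeClass.UNCLASSIFIED:
            if (
                elovl.label is EnzymeClass.UNCLASSIFIED
                and fads.label is EnzymeClass.UNCLASSIFIED
            ):
                return record
        elif cls is EnzymeClass.FADS_LIKE:
            if fads.label is cls:
                return record
        elif elovl.label is cls and not elovl.ambiguous:
            return record
    raise RuntimeError(f"rejection budget exceeded generating a {cls.value} sequence")


def gen_protein_panel(
    counts: dict[EnzymeClass, int], cfg: SynthConfig
) -> list[ProteinRecord]:
    """A panel of labelled synthetic proteins, e.g. the 8 + 5 + 3 layout of
    a sea-urchin enzyme complement."""
    rng = cfg.rng()
    records = []
    for cls, n in counts.items():
        for i in range(n):
            rec = gen_protein(cls, cfg, rng)
            records.append(ProteinRecord(f"synth_{cls.value}_{i + 1}", rec.seq))
    return records


def _lognormal_factors(n: int, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)


def gen_peak_table(
    substrate: str,
    products: list[str],
    cfg: SynthConfig,
    sample_id: str = "synth",
    rng: np.random.Generator | None = None,
) -> PeakTable:
    """Peak table whose noiseless conversion equals ``cfg.true_conversion``.

    The substrate+product mass is split so products/(substrate+products)
    equals the true conversion, each area is then multiplied by unit-mean
    log-normal noise of CV ``noise_cv``, and the endogenous background
    FAMEs are added (unless they already play a role in the assay).
    A true conversion of zero produces exactly-zero product areas.
    """
    if rng is None:
        rng = cfg.rng()
    p = cfg.true_conversion / 100.0
    substrate_area = cfg.total_assay_area * (1.0 - p)
    product_total = cfg.total_assay_area * p
    areas: dict[str, float] = {substrate: substrate_area}
    for prod in products:
        areas[prod] = product_total / len(products) if products else 0.0
    factors = _lognormal_factors(len(areas), cfg.noise_cv, rng)
    areas = {
        name: (area * f if area > 0 else 0.0)
        for (name, area), f in zip(areas.items(), factors)
    }
    roles = {substrate, *products}
    for fame, base in _BACKGROUND_FAMES.items():
        if fame not in roles:
            areas[fame] = base * _lognormal_factors(1, cfg.noise_cv, rng)[0]
    return PeakTable(
        sample_id=sample_id,
        areas=areas,
        substrate_id=substrate,
        product_ids=list(products),
    )


def gen_dmox_spectrum(
    fa: FattyAcid, cfg: SynthConfig, rng: np.random.Generator | None = None
) -> DmoxSpectrum:
    """Noisy but ground-truth-faithful DMOX spectrum for ``fa``.

    Ladder intensities decay with fragment size; the molecular ion and all
    diagnostic ions are never dropped, and of the two peaks flanking any
    12-u gap at least one always survives so the double-bond signal stays
    readable at the configured dropout rate.
    """
    if rng is None:
        rng = cfg.rng()
    series = predict_series(fa)
    diagnostics = diagnostic_ions(fa)

    peaks: dict[int, float] = {}
    for i, (n, mz) in enumerate(series.entries):
        peaks[mz] = 100.0 * 0.95**i
    for mz in diagnostics.values():
        peaks[mz] = max(peaks.get(mz, 0.0), 60.0)
    peaks[series.molecular_ion] = 25.0

    # the diagnostic region — both flanks of every 12-u gap, the Δ5 ion and
    # the molecular ion — is never dropped: losing a single flank would make
    # the 12/14 step order inside the widened gap genuinely ambiguous
    never_drop = set(diagnostics.values()) | {series.molecular_ion}
    for (_, mz_prev), (_, mz) in zip(series.entries, series.entries[1:]):
        if mz - mz_prev == 12:
            never_drop.update((mz_prev, mz))

    droppable = [mz for mz in peaks if mz not in never_drop]
    dropped = {mz for mz in droppable if rng.random() < cfg.dropout_rate}
    kept = {mz: inten for mz, inten in peaks.items() if mz not in dropped}

    # noise is kept >= 3 u away from every true-ladder position (dropped or
    # not): a structure differing by one bond position predicts peaks exactly
    # 2 u below true ones, so a +/-2 exclusion zone is what keeps the ground
    # truth unambiguous at unit-mass resolution
    forbidden = set(peaks)
    lo_mz, hi_mz = 100, series.molecular_ion + 30
    added = 0
    while added < cfg.n_noise_peaks:
        mz = int(rng.integers(lo_mz, hi_mz + 1))
        if any(abs(mz - t) <= 2 for t in forbidden) or mz in kept:
            continue
        kept[mz] = float(rng.uniform(1.0, 10.0))
        added += 1
    return DmoxSpectrum(tuple(sorted(kept.items())), chain_length_hint=fa.chain_length)
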