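"""DMOX fragment-ladder prediction and double-bond inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pufapath.dmox import (
    DmoxError,
    DmoxSpectrum,
    UninterpretableSpectrum,
    _candidates,
    detectable_range,
    diagnostic_ions,
    infer_double_bonds,
    predict_series,
    predicted_peaks,
)
from pufapath.nomenclature import FattyAcid, parse_shorthand
from pufapath.synth import SynthConfig, gen_dmox_spectrum

from test_nomenclature import fatty_acids


def fa(text):
    return parse_shorthand(text)


class TestPredict:
    def test_anchors_and_saturated_ladder(self):
        series = predict_series(fa("16:0"))
        assert series.mz_of(2) == 113
        assert series.mz_of(3) == 126
        assert series.mz_of(4) == 140
        assert series.molecular_ion == 309  # nominal mass of the C20H39NO derivative

    @pytest.mark.parametrize(
        "shorthand, n, mz",
        [
            ("20:2^Δ5,11^", 10, 222),
            ("20:2^Δ5,11^", 11, 234),
            ("20:2^Δ5,13^", 12, 250),
            ("20:2^Δ5,13^", 13, 262),
        ],
    )
    def test_printed_gap_positions(self, shorthand, n, mz):
        assert predict_series(fa(shorthand)).mz_of(n) == mz

    def test_gap_of_12_flags_each_double_bond(self):
        assert predict_series(fa("20:3^Δ5,11,14^")).gaps_of_12() == [5, 11, 14]

    def test_chain_too_short(self):
        with pytest.raises(DmoxError):
            predict_series(FattyAcid(3))

    def test_out_of_model_positions_refused(self):
        with pytest.raises(DmoxError):
            predict_series(FattyAcid(20, (2,)))
        with pytest.raises(DmoxError):
            predict_series(FattyAcid(20, (19,)))

    @settings(deadline=None, max_examples=200)
    @given(fatty_acids(max_chain=24))
    def test_series_telescoping_identity(self, acid):
        """M+ - 113 == 14*(C - 2) - 2*(number of double bonds): each carbon
        past the 2-carbon anchor adds 14, minus 2 per unsaturation."""
        lo, hi = detectable_range(acid.chain_length)
        if acid.chain_length < 4 or any(not lo <= d <= hi for d in acid.double_bonds):
            return
        series = predict_series(acid)
        assert series.molecular_ion - 113 == 14 * (acid.chain_length - 2) - 2 * acid.n_double_bonds
        steps = set(np.diff(series.mz_values))
        assert steps <= {12, 13, 14}


class TestDiagnostics:
    @pytest.mark.parametrize(
        "shorthand, expected",
        [
            ("20:4^Δ5,11,14,17^", {5: 153}),
            ("20:2n-6", {}),
            ("18:1^Δ5^", {5: 153}),
        ],
    )
    def test_delta5_rule(self, shorthand, expected):
        assert diagnostic_ions(fa(shorthand)) == expected


class TestSpectrumContainer:
    def test_validation(self):
        with pytest.raises(DmoxError):
            DmoxSpectrum(((0, 1.0),))
        with pytest.raises(DmoxError):
            DmoxSpectrum(((100, 1.0), (100, 2.0)))
        with pytest.raises(DmoxError):
            DmoxSpectrum(((100, -1.0),))

    def test_csv_round_trip(self, tmp_path):
        spectrum = gen_dmox_spectrum(fa("20:2^Δ5,11^"), SynthConfig(seed=1))
        path = tmp_path / "spec.csv"
        spectrum.to_csv(path)
        again = DmoxSpectrum.from_csv(path)
        assert again.mz_set == spectrum.mz_set


def noiseless_spectrum(acid):
    return DmoxSpectrum(tuple((mz, 10.0) for mz in sorted(predicted_peaks(acid))))


class TestInference:
    def test_self_consistency_noiseless(self):
        acid = fa("20:2^Δ5,11^")
        inferred, score = infer_double_bonds(noiseless_spectrum(acid), 20)
        assert inferred == acid and score == 1.0

    def test_printed_assignment_logic(self):
        # a single high-mass 12-gap at 250->262 plus the 153 diagnostic
        # pins down 20:2^Δ5,13^
        acid = fa("20:2^Δ5,13^")
        inferred, _ = infer_double_bonds(noiseless_spectrum(acid), 20)
        assert inferred == acid

    def test_saturated_series(self):
        inferred, score = infer_double_bonds(noiseless_spectrum(fa("18:0")), 18)
        assert inferred == fa("18:0") and score == 1.0

    def test_uninterpretable_spectrum(self):
        junk = DmoxSpectrum(tuple((mz, 1.0) for mz in range(401, 441)))
        with pytest.raises(UninterpretableSpectrum):
            infer_double_bonds(junk, 20)

    def test_chain_length_required(self):
        with pytest.raises(DmoxError):
            infer_double_bonds(noiseless_spectrum(fa("18:0")))

    def test_inversion_exhaustive(self):
        """predict -> infer recovers every structure with C <= 22 and up to
        four double bonds in the detectable range, exactly."""
        for chain in range(4, 23):
            cands, matrix, counts = _candidates(chain, 6)
            # score all true spectra against all candidates in one product
            scores = (matrix.astype(np.uint16) @ matrix.T.astype(np.uint16)) / counts[None, :]
            truths = [i for i, c in enumerate(cands) if len(c) <= 4]
            for i in truths:
                truth = cands[i]
                row = scores[i]
                best = min(
                    range(len(cands)),
                    key=lambda j: (-row[j], len(cands[j]), cands[j]),
                )
                assert cands[best] == truth, (chain, truth, cands[best])

    def test_inversion_spot_checks_via_public_api(self):
        for shorthand in ("20:2^Δ5,11^", "22:4n-6", "18:3n-3", "20:5n-3", "16:1n-7"):
            acid = fa(shorthand)
            inferred, score = infer_double_bonds(noiseless_spectrum(acid), acid.chain_length)
            assert inferred == acid and score == 1.0

    def test_recovery_under_noise_and_dropout(self):
        """>= 95% exact recovery on seeded noisy spectra (10 noise peaks,
        10% dropout outside the protected diagnostic peaks)."""
        rng = np.random.default_rng(2024)
        cfg = SynthConfig(seed=2024, n_noise_peaks=10, dropout_rate=0.1)
        cands_by_chain = {c: _candidates(c, 4)[0] for c in (16, 18, 20, 22)}
        hits = trials = 0
        for _ in range(200):
            chain = int(rng.choice((16, 18, 20, 22)))
            truth = cands_by_chain[chain][int(rng.integers(len(cands_by_chain[chain])))]
            acid = FattyAcid(chain, truth)
            spectrum = gen_dmox_spectrum(acid, cfg, rng=rng)
            inferred, _ = infer_double_bonds(spectrum, chain)
            trials += 1
            hits += inferred == acid
        assert hits / trials >= 0.95
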