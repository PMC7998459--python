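"""Fragment ion tables, spectrum matching, and the assignment rule."""

import pytest

from cyclomine.chem import PROTON_MASS, adduct_mz, peptide_mass
from cyclomine.ms1 import Peak
from cyclomine.ms2 import (
    AssignConfig,
    Ms2Spectrum,
    assign,
    compare_spectra,
    match_spectrum,
    theoretical_ions,
)
from cyclomine.simulate import SimConfig, simulate_ms2

FIXTURE_CORES = ["TFLPPLFVPP", "AFFPPFFIPP", "IWGIGCNP", "AWLVDCP",
                 "FIPLGIITILP", "MHILAPPP", "VFSLPVFFP"]


def ions_by(core, series):
    return {i.index: i.mz for i in theoretical_ions(core, (series,))}


class TestTheoreticalIons:
    def test_y_series_values(self):
        y = ions_by("TFLPPLFVPP", "y")
        assert y[1] == pytest.approx(116.0706, abs=5e-4)   # C-terminal Pro
        assert y[2] == pytest.approx(213.1234, abs=5e-4)   # + Pro

    def test_b_series_values(self):
        b = ions_by("GGG", "b")
        assert b[1] == pytest.approx(58.0287, abs=5e-4)
        assert b[2] == pytest.approx(115.0502, abs=5e-4)

    def test_immonium_set(self):
        imm = ions_by("TFLPPLFVPP", "immonium")
        assert imm["F"] == pytest.approx(120.0808, abs=5e-4)
        assert imm["L"] == pytest.approx(86.0964, abs=5e-4)
        assert imm["P"] == pytest.approx(70.0651, abs=5e-4)
        assert set(imm) == set("TFLPV")

    @pytest.mark.parametrize("core", FIXTURE_CORES)
    def test_by_complementarity(self, core):
        """y_k + b_(n-k) equals the linear [M+H]+ plus one proton."""
        n = len(core)
        y = ions_by(core, "y")
        b = ions_by(core, "b")
        linear_mh = adduct_mz(peptide_mass(core, "linear"), "H")
        for k in range(1, n):
            assert y[k] + b[n - k] == pytest.approx(linear_mh + PROTON_MASS,
                                                    abs=1e-4)

    @pytest.mark.parametrize("core", ["TFLPPLFVPP", "AWLVDCP"])
    def test_ring_b_rotation_invariant(self, core):
        def ring_set(seq):
            return sorted(i.mz for i in theoretical_ions(seq, ("ring_b",)))

        base = ring_set(core)
        for j in range(1, len(core)):
            rotated = core[j:] + core[:j]
            assert ring_set(rotated) == pytest.approx(base, abs=1e-3)

    def test_too_short_core(self):
        with pytest.raises(Exception):
            theoretical_ions("GG")


class TestMatchSpectrum:
    def spectrum_of(self, core, **kw):
        return simulate_ms2(core, SimConfig(seed=9, **kw))

    def test_all_y_ions_found_in_clean_spectrum(self):
        core = "TFLPPLFVPP"
        spec = self.spectrum_of(core)
        ions = theoretical_ions(core, ("y",))
        matched = {i.index for i, _ in match_spectrum(spec, ions)}
        assert set(range(2, len(core))) <= matched

    def test_pure_noise_matches_nothing(self):
        ions = theoretical_ions("TFLPPLFVPP", ("y",))
        spec = Ms2Spectrum(None, [Peak(i.mz + 1.0) for i in ions])
        assert match_spectrum(spec, ions, tol=0.02) == []

    def test_nearest_peak_wins(self):
        ions = [theoretical_ions("GGG", ("b",))[0]]
        target = ions[0].mz
        spec = Ms2Spectrum(None, [Peak(target + 0.015), Peak(target + 0.005)])
        matches = match_spectrum(spec, ions, tol=0.02)
        assert len(matches) == 1
        assert matches[0][1].mz == pytest.approx(target + 0.005)

    def test_empty_spectrum(self):
        ions = theoretical_ions("GGG")
        assert match_spectrum(Ms2Spectrum(None, []), ions) == []


class TestAssign:
    def test_roundtrip_confirms_all_fixture_cores(self, reference_rows):
        """Noiseless simulated spectra confirm every published core with
        full residue coverage."""
        config = SimConfig(seed=2)
        for core in sorted(set(reference_rows["core"])):
            spec = simulate_ms2(core, config)
            result = assign(core, spec)
            assert result.confirmed, core
            assert result.residue_coverage == 1.0

    def test_decoys_of_different_composition_rejected(self, reference_rows):
        """Shuffled-composition decoys are rejected against every true
        spectrum (zero false discoveries on noiseless data)."""
        import random

        rng = random.Random(77)
        cores = sorted(set(reference_rows["core"]))[:20]
        spectra = {c: simulate_ms2(c, SimConfig(seed=4)) for c in cores}
        decoys = []
        while len(decoys) < 25:
            base = rng.choice(cores)
            decoy = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                            for _ in base)
            if sorted(decoy) != sorted(base):
                decoys.append(decoy)
        false_hits = sum(
            assign(d, s).confirmed for d in decoys for s in spectra.values())
        assert false_hits == 0

    def test_sparse_y_coverage_rejected(self):
        """Only y2 and y3 of a 10-mer cannot reach the coverage threshold,
        even with the immonium requirement waived."""
        core = "TFLPPLFVPP"
        keep = [i.mz for i in theoretical_ions(core, ("y",))
                if i.index in (2, 3)]
        spec = Ms2Spectrum(adduct_mz(peptide_mass(core), "H"),
                           [Peak(mz) for mz in keep])
        result = assign(core, spec, AssignConfig(min_immonium=0))
        assert result.verdict == "rejected"
        assert result.residue_coverage < 0.8

    def test_missing_immonium_rejected(self):
        core = "AFFPPFFIPP"
        spec = simulate_ms2(core, SimConfig(seed=3, immonium_probability=0.0))
        result = assign(core, spec)
        assert result.matched_immonium == set()
        assert result.verdict == "rejected"

    def test_il_substitution_gives_identical_result(self):
        spec = simulate_ms2("FIPLGIITILP", SimConfig(seed=5))
        a = assign("FIPLGIITILP", spec)
        b = assign("FLPLGLLTLLP", spec)
        assert a.il_ambiguous and b.il_ambiguous
        assert (a.verdict, a.residue_coverage, a.matched_y) == \
               (b.verdict, b.residue_coverage, b.matched_y)

    def test_precursor_mismatch_rejected(self):
        """A spectrum of one mass cannot confirm a core of another."""
        spec = simulate_ms2("TFLPPLFVPP", SimConfig(seed=6))
        assert not assign("AWDSKHP", spec).confirmed

    def test_gate_disabled_reverts_to_coverage_rule(self):
        spec = simulate_ms2("TFLPPLFVPP", SimConfig(seed=6))
        config = AssignConfig(check_precursor=False)
        assert assign("TFLPPLFVPP", spec, config).confirmed


class TestCompareSpectra:
    def test_identity(self):
        spec = simulate_ms2("AFFPPFFIPP", SimConfig(seed=8))
        shared, pairs = compare_spectra(spec, spec)
        assert shared == len(spec.peaks)

    def test_replicates_share_most_ions(self):
        """Two noisy replicates of the same peptide share >= 90% of ions."""
        config_a = SimConfig(seed=10, ms2_jitter_sd=0.003)
        config_b = SimConfig(seed=11, ms2_jitter_sd=0.003)
        a = simulate_ms2("TFLPPLFVPP", config_a)
        b = simulate_ms2("TFLPPLFVPP", config_b)
        shared, _ = compare_spectra(a, b, tol=0.02)
        assert shared >= 0.9 * min(len(a.peaks), len(b.peaks))

    def test_disjoint_spectra_share_nothing(self):
        a = Ms2Spectrum(None, [Peak(mz) for mz in (100.0, 200.0, 300.0)])
        b = Ms2Spectrum(None, [Peak(p.mz + 5.0) for p in a.peaks])
        shared, _ = compare_spectra(a, b, tol=0.02)
        assert shared == 0

    def test_symmetric_count(self):
        a = simulate_ms2("MHILAPPP", SimConfig(seed=13, b_ion_probability=0.5))
        b = simulate_ms2("MHILAPPP", SimConfig(seed=14, b_ion_probability=0.5))
        ab, _ = compare_spectra(a, b)
        ba, _ = compare_spectra(b, a)
        assert ab == ba

    def test_empty_spectrum_errors(self):
        a = simulate_ms2("AWDSKHP", SimConfig(seed=12))
        with pytest.raises(ValueError):
            compare_spectra(a, Ms2Spectrum(None, []))
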