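"""Deconvolution, infusion-spectrum processing, blank rules, combination."""

import math

import numpy as np
import pandas as pd
import pytest

from ozfad.chem import precursor_composition, precursor_mz, isotope_pattern
from ozfad.config import PipelineConfig
from ozfad.lcms import Chromatogram, Spectrum
from ozfad.nomenclature import parse_shorthand
from ozfad.quantify import (
    DeconvolutionComponent,
    DeconvolutionProblem,
    apply_blank_rules,
    baseline_subtract,
    combine_absolute,
    deconvolve_isomers,
    infusion_quant,
    isotope_correct,
    recalibrate_mz,
)
from ozfad.simulate import (
    GroundTruthMixture,
    InstrumentModel,
    MixtureEntry,
    default_internal_standard,
    simulate_infusion,
)


def gaussians(t, components, sigma):
    y = np.zeros_like(t)
    for center, amp in components:
        y += amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return y


class TestDeconvolution:
    sigma = 0.025

    def chrom(self, components):
        t = np.arange(8.0, 9.5, 0.1 / 60)
        return Chromatogram(t, gaussians(t, components, self.sigma), 449.35, 20.0)

    def test_single_isomer_fraction_one(self):
        prob = DeconvolutionProblem(self.chrom([(8.5, 100.0)]),
                                    [DeconvolutionComponent("a", 8.5)], self.sigma)
        res = deconvolve_isomers(prob)
        assert res.fractions == {"a": pytest.approx(1.0)}

    def test_three_to_one_resolved_pair(self):
        prob = DeconvolutionProblem(
            self.chrom([(8.4, 300.0), (8.8, 100.0)]),
            [DeconvolutionComponent("major", 8.4), DeconvolutionComponent("minor", 8.8)],
            self.sigma)
        res = deconvolve_isomers(prob)
        assert res.fractions["major"] == pytest.approx(0.75, abs=1e-3)
        assert res.fractions["minor"] == pytest.approx(0.25, abs=1e-3)
        assert res.flags == {}

    def test_buried_minor_switches_to_product_fallback(self):
        # 100:1 fully co-eluting pair: precursor deconvolution is degenerate,
        # the product-ion route gives the upper-limit estimate
        prob = DeconvolutionProblem(
            self.chrom([(8.5, 101.0)]),
            [DeconvolutionComponent("major", 8.5, product_area=1000.0),
             DeconvolutionComponent("minor", 8.5, product_area=10.0)],
            self.sigma)
        res = deconvolve_isomers(prob)
        assert res.flags.get("minor") == "upper_limit"
        truth = 1.0 / 101.0
        assert abs(res.fractions["minor"] - truth) <= 0.04 * truth + 1e-4
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-6)

    def test_fractions_sum_to_one(self):
        prob = DeconvolutionProblem(
            self.chrom([(8.3, 50.0), (8.5, 120.0), (8.9, 5.0)]),
            [DeconvolutionComponent(k, c) for k, c in
             (("a", 8.3), ("b", 8.5), ("c", 8.9))], self.sigma)
        assert sum(deconvolve_isomers(prob).fractions.values()) == pytest.approx(1.0)

    def test_center_outside_chromatogram_rejected(self):
        prob = DeconvolutionProblem(self.chrom([(8.5, 10.0)]),
                                    [DeconvolutionComponent("a", 20.0)], self.sigma)
        with pytest.raises(ValueError):
            deconvolve_isomers(prob)

    def test_worksheet_export(self, tmp_path):
        prob = DeconvolutionProblem(self.chrom([(8.5, 100.0)]),
                                    [DeconvolutionComponent("a", 8.5)], self.sigma)
        res = deconvolve_isomers(prob)
        path = tmp_path / "deconv.tsv"
        res.to_table(path)
        assert "upper_limit" not in path.read_text()
        assert "amplitude" in path.read_text()


class TestBaseline:
    def test_all_zero_unchanged(self):
        s = Spectrum(rt=0.0, ms_level=1, mz=np.linspace(400, 500, 50),
                     intensity=np.zeros(50))
        out = baseline_subtract(s)
        np.testing.assert_array_equal(out.intensity, np.zeros(50))

    def test_constant_offset_removed(self, rng):
        mz = np.sort(rng.uniform(400, 500, 400))
        grass = rng.uniform(0, 1, 400)
        peaks = np.zeros(400)
        peaks[::40] = 500.0
        offset = 50.0
        s = Spectrum(rt=0.0, ms_level=1, mz=mz, intensity=grass + peaks + offset)
        out = baseline_subtract(s)
        apex = out.intensity[::40]
        assert np.all(np.abs(apex - 500.0) <= 0.05 * 500.0)

    def test_no_negative_output(self, rng):
        mz = np.sort(rng.uniform(400, 500, 200))
        s = Spectrum(rt=0.0, ms_level=1, mz=mz, intensity=rng.uniform(0, 10, 200))
        assert np.all(baseline_subtract(s).intensity >= 0)


class TestRecalibration:
    def spectrum(self, ampp, shift16, shift18):
        mz16 = precursor_mz(parse_shorthand("FA 16:0"), ampp)
        mz18 = precursor_mz(parse_shorthand("FA 18:0"), ampp)
        mz = np.array([mz16 + shift16, mz18 + shift18, 500.0])
        return Spectrum(rt=0.0, ms_level=1, mz=mz, intensity=np.array([100.0, 80.0, 10.0]))

    def test_on_theory_no_shift(self, ampp):
        _, shift, ok = recalibrate_mz(self.spectrum(ampp, 0.0, 0.0), ampp)
        assert ok and shift == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_shift_removed(self, ampp):
        out, shift, ok = recalibrate_mz(self.spectrum(ampp, 0.01, 0.01), ampp)
        assert shift == pytest.approx(0.01, abs=1e-9)
        assert out.mz[2] == pytest.approx(500.0 - 0.01)

    def test_average_of_deviations(self, ampp):
        _, shift, ok = recalibrate_mz(self.spectrum(ampp, 0.008, 0.012), ampp)
        assert shift == pytest.approx(0.010, abs=1e-12)

    def test_missing_anchor_flags_not_raises(self, ampp):
        s = Spectrum(rt=0.0, ms_level=1, mz=np.array([500.0]), intensity=np.array([1.0]))
        out, shift, ok = recalibrate_mz(s, ampp)
        assert not ok and shift == 0.0


def envelope_spectrum(species_scale, ampp, n_peaks=5):
    """Noiseless merged envelope spectrum for (sum-composition, scale) pairs."""
    sticks = {}
    for comp_key, scale in species_scale.items():
        comp = precursor_composition(
            parse_shorthand(comp_key), ampp) if isinstance(comp_key, str) else comp_key
        from ozfad.chem import monoisotopic_mass, ELECTRON_MASS

        mono = monoisotopic_mass(comp) - ELECTRON_MASS
        for off, ab in isotope_pattern(comp, n_peaks):
            pattern_sum = sum(a for _, a in isotope_pattern(comp, n_peaks))
            sticks[mono + off] = sticks.get(mono + off, 0.0) + scale * ab / pattern_sum
    mz = np.array(sorted(sticks))
    inten = np.array([sticks[m] for m in mz])
    # merge anything closer than the modelled centroid resolution
    merged_mz, merged_i = [], []
    for m, i in zip(mz, inten):
        if merged_mz and m - merged_mz[-1] < 0.012:
            total = merged_i[-1] + i
            merged_mz[-1] = (merged_mz[-1] * merged_i[-1] + m * i) / total
            merged_i[-1] = total
        else:
            merged_mz.append(m)
            merged_i.append(i)
    return Spectrum(rt=0.0, ms_level=1, mz=np.array(merged_mz),
                    intensity=np.array(merged_i))


class TestIsotopeCorrection:
    def test_single_species_envelope_total(self, ampp):
        spec = envelope_spectrum({"FA 18:1n-9": 1000.0}, ampp)
        tab = isotope_correct(spec, [(18, 1)], ampp)
        assert tab.corrected_abundance.iloc[0] == pytest.approx(1000.0, rel=1e-3)

    def test_dha_dpa_overlap_recovered(self, ampp):
        spec = envelope_spectrum(
            {"FA 22:6n-3,6,9,12,15,18": 1000.0, "FA 22:5n-3,6,9,12,15": 1000.0}, ampp)
        tab = isotope_correct(spec, [(22, 6), (22, 5)], ampp).set_index("species")
        ratio = (tab.loc["FA 22:5", "corrected_abundance"]
                 / tab.loc["FA 22:6", "corrected_abundance"])
        assert ratio == pytest.approx(1.0, rel=0.01)

    def test_dha_alone_leaves_no_apparent_dpa(self, ampp):
        spec = envelope_spectrum({"FA 22:6n-3,6,9,12,15,18": 1000.0}, ampp)
        tab = isotope_correct(spec, [(22, 6), (22, 5)], ampp).set_index("species")
        assert tab.loc["FA 22:5", "corrected_abundance"] <= 1e-6 * 1000.0

    def test_exactly_invertible_on_noiseless_envelopes(self, ampp):
        truth = {"FA 22:6n-3,6,9,12,15,18": 500.0, "FA 22:5n-3,6,9,12,15": 50.0,
                 "FA 22:4n-6,9,12,15": 5.0}
        spec = envelope_spectrum(truth, ampp)
        tab = isotope_correct(spec, [(22, 6), (22, 5), (22, 4)], ampp).set_index("species")
        for key, scale in truth.items():
            comp = f"FA 22:{parse_shorthand(key).n_double_bonds}"
            assert tab.loc[comp, "corrected_abundance"] == pytest.approx(scale, rel=1e-3)


class TestBlankRules:
    @pytest.mark.parametrize("ratio,action", [
        (0.005, "keep"), (0.5, "subtract"), (0.8, "exclude"),
    ])
    def test_rule_boundaries(self, ratio, action):
        act, amount = apply_blank_rules(100.0, ratio * 100.0)
        assert act == action
        if action == "keep":
            assert amount == 100.0
        elif action == "subtract":
            assert amount == pytest.approx(100.0 - ratio * 100.0)


class TestInfusionQuant:
    def build_runs(self, ampp, entries, seed=4):
        mix = GroundTruthMixture(entries, default_internal_standard())
        inst = InstrumentModel(noise_peak_density=0.002)
        return mix, simulate_infusion(mix, inst, ampp, seed=seed)

    def test_recovers_concentrations_within_five_percent(self, ampp, config):
        entries = tuple(
            MixtureEntry(parse_shorthand(t), c, 0.0) for t, c in (
                ("FA 16:0", 60.0),   # saturated anchors, as in any real extract
                ("FA 18:0", 30.0),
                ("FA 16:1n-7 cis", 40.0),
                ("FA 18:1n-9 cis", 120.0),
                ("FA 20:1n-9 cis", 8.0),
                ("FA 18:2n-6,9 cis", 2.0),
            ))
        mix, run = self.build_runs(ampp, entries)
        istd, conc = mix.internal_standard
        comps = [(16, 0), (18, 0), (16, 1), (18, 1), (20, 1), (18, 2)]
        tab = infusion_quant(run, None, ampp, istd, conc, comps, config).set_index("species")
        for e in entries:
            key = f"FA {e.species.carbons}:{e.species.n_double_bonds}"
            assert tab.loc[key, "concentration"] == pytest.approx(e.concentration, rel=0.05)

    def test_istd_missing_raises(self, ampp, config):
        entries = (MixtureEntry(parse_shorthand("FA 18:1n-9 cis"), 10.0, 0.0),)
        mix = GroundTruthMixture(entries, default_internal_standard())
        inst = InstrumentModel(noise_peak_density=0.0)
        run = simulate_infusion(mix, inst, ampp, seed=4, include_istd=False)
        with pytest.raises(RuntimeError, match="internal standard"):
            infusion_quant(run, None, ampp, *mix.internal_standard, [(18, 1)], config)

    def test_linearity_via_istd_scaling(self, ampp, config):
        concs = []
        for scale in (1.0, 2.0):
            entries = (MixtureEntry(parse_shorthand("FA 16:0"), 40.0, 0.0),
                       MixtureEntry(parse_shorthand("FA 18:0"), 20.0, 0.0),
                       MixtureEntry(parse_shorthand("FA 18:1n-9 cis"), 50.0 * scale, 0.0))
            mix, run = self.build_runs(ampp, entries)
            istd, c = mix.internal_standard
            tab = infusion_quant(run, None, ampp, istd, c, [(18, 1)], config)
            concs.append(tab.concentration.iloc[0])
        assert concs[1] / concs[0] == pytest.approx(2.0, rel=0.02)


class TestCombineAbsolute:
    def quant_table(self):
        return pd.DataFrame([
            {"species": "FA 18:1", "concentration": 100.0, "sd": 10.0, "cov": 0.1},
        ])

    def test_single_isomer_inherits_composition_amount(self):
        out = combine_absolute({(18, 1): {"FA 18:1n-9 cis": 1.0}}, self.quant_table())
        assert out.concentration.iloc[0] == pytest.approx(100.0)

    def test_fraction_split(self):
        out = combine_absolute(
            {(18, 1): {"a": 0.75, "b": 0.25}}, self.quant_table()).set_index("species")
        assert out.loc["a", "concentration"] == pytest.approx(75.0)
        assert out.loc["b", "concentration"] == pytest.approx(25.0)

    def test_replicate_cov_matches_direct_recomputation(self, ampp, config):
        entries = (MixtureEntry(parse_shorthand("FA 16:0"), 40.0, 0.0),
                   MixtureEntry(parse_shorthand("FA 18:0"), 20.0, 0.0),
                   MixtureEntry(parse_shorthand("FA 18:1n-9 cis"), 50.0, 0.0))
        mix = GroundTruthMixture(entries, default_internal_standard())
        inst = InstrumentModel(noise_peak_density=0.002)
        runs = [simulate_infusion(mix, inst, ampp, seed=s) for s in (11, 12, 13)]
        istd, c = mix.internal_standard
        tab = infusion_quant(runs, None, ampp, istd, c, [(18, 1)], config)
        singles = [
            infusion_quant(r, None, ampp, istd, c, [(18, 1)], config).concentration.iloc[0]
            for r in runs
        ]
        assert tab.concentration.iloc[0] == pytest.approx(np.mean(singles), rel=1e-9)
        assert tab.sd.iloc[0] == pytest.approx(np.std(singles, ddof=1), rel=1e-9)
        assert tab["cov"].iloc[0] == pytest.approx(
            np.std(singles, ddof=1) / np.mean(singles), rel=1e-9)
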