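"""Retention-window prediction, target-list scheduling, S/N scoring, search."""

import math

import numpy as np
import pytest

from ozfad.chem import ozid_transitions, precursor_mz
from ozfad.config import PipelineConfig
from ozfad.discovery import (
    IsomerCandidate,
    PrecursorObservation,
    SnrResult,
    build_target_list,
    classify_and_dedupe,
    compute_snr,
    find_precursors,
    possible_product_mz,
    precursor_envelope_mz,
    predict_rt_window,
    search_double_bonds,
)
from ozfad.lcms import Spectrum
from ozfad.nomenclature import parse_shorthand
from ozfad.simulate import (
    GroundTruthMixture,
    InstrumentModel,
    MixtureEntry,
    default_internal_standard,
    simulate_dia,
)


class TestRtWindow:
    def test_anchor_identities(self, config):
        lo16, hi16 = predict_rt_window(16, 0, (8.0, 9.0), config)
        assert lo16 < 8.0 < hi16
        assert (lo16 + hi16) / 2 == pytest.approx(8.0)
        lo18, hi18 = predict_rt_window(18, 0, (8.0, 9.0), config)
        assert (lo18 + hi18) / 2 == pytest.approx(9.0)

    def test_unsaturation_shifts_window_earlier(self, config):
        sat_lo, sat_hi = predict_rt_window(17, 0, (8.0, 9.0), config)
        uns_lo, uns_hi = predict_rt_window(17, 1, (8.0, 9.0), config)
        assert uns_hi < (sat_lo + sat_hi) / 2  # strictly earlier than rt(17:0)

    def test_missing_anchor_raises_helpful_error(self, config):
        from ozfad.discovery import AnchorError

        with pytest.raises(AnchorError, match="anchor"):
            predict_rt_window(18, 1, (None, 9.0), config)


def make_obs(carbons=18, d=1, mz=449.3526, rt=8.78, abundance=1000.0, fwhm=0.06):
    return PrecursorObservation(
        carbons=carbons, n_double_bonds=d, theoretical_mz=mz, observed_mz=mz,
        ppm_error=0.0, apex_rt=rt, height=abundance, abundance=abundance, fwhm=fwhm)


class TestTargetList:
    def test_slot_count_for_20min_gradient(self, config):
        targets = build_target_list([make_obs()], config)
        assert len(targets) == 4000  # 20 min / 0.3 s

    def test_single_precursor_owns_its_window(self, config):
        obs = make_obs(rt=8.78)
        targets = build_target_list([obs], config)
        w = config.raw_halfwidth_fwhm * obs.fwhm
        in_window = [s for s in targets.slots
                     if obs.apex_rt - w <= (s.start_min + s.end_min) / 2 <= obs.apex_rt + w]
        assert all(s.target_mz == obs.theoretical_mz for s in in_window)

    def test_coeluting_trace_precursor_keeps_enough_slots(self, config):
        abundant = make_obs(mz=449.3526, abundance=1e6)
        trace = make_obs(carbons=20, d=3, mz=473.3526, abundance=1e2)
        targets = build_target_list([abundant, trace], config)
        trace_slots = [s for s in targets.slots if s.target_mz == trace.theoretical_mz]
        abundant_slots = [s for s in targets.slots if s.target_mz == abundant.theoretical_mz]
        assert len(trace_slots) >= config.min_points_per_peak
        assert len(abundant_slots) >= config.min_points_per_peak
        # fully overlapping windows are shared roughly evenly
        assert 0.3 <= len(trace_slots) / (len(trace_slots) + len(abundant_slots)) <= 0.7

    def test_grid_contiguous_one_target_per_slot(self, config):
        targets = build_target_list([make_obs()], config)
        starts = [s.start_min for s in targets.slots]
        ends = [s.end_min for s in targets.slots]
        np.testing.assert_allclose(starts[1:], ends[:-1], atol=1e-12)
        assert all(s.target_mz > 0 for s in targets.slots)

    def test_export_dialect(self, config, tmp_path):
        targets = build_target_list([make_obs()], config)
        path = tmp_path / "targets.tsv"
        targets.export(path, config)
        text = path.read_text()
        assert "150" in text.splitlines()[0] and "0.15" in text.splitlines()[0]
        assert len(text.splitlines()) == 2 + len(targets)


def snr_oracle(spectra, transitions, exclusion_mz, config):
    """Brute-force reimplementation of the S/N definition with plain loops."""
    pairs = []
    for s in spectra:
        pairs.extend(zip(s.mz.tolist(), s.intensity.tolist()))
    pairs.sort()
    clusters = []
    for mz, inten in pairs:
        if clusters and mz - clusters[-1][-1][0] <= clusters[-1][-1][0] * config.noise_proximity_ppm * 1e-6:
            clusters[-1].append((mz, inten))
        else:
            clusters.append([(mz, inten)])
    centers, integrals = [], []
    for cl in clusters:
        tot = sum(i for _, i in cl)
        centers.append(sum(m * i for m, i in cl) / tot)
        integrals.append(tot)
    products = list(transitions.product_mz)
    signal = 0.0
    matched = [False] * len(centers)
    n_detected = 0
    for pmz in products:
        found = False
        for k, c in enumerate(centers):
            if abs(c - pmz) <= pmz * config.product_match_ppm * 1e-6:
                signal += integrals[k]
                matched[k] = True
                found = True
        n_detected += found
    noise_sum, n_noise = 0.0, 0
    for k, c in enumerate(centers):
        if matched[k]:
            continue
        near = any(abs(c - e) <= c * config.noise_proximity_ppm * 1e-6 for e in exclusion_mz)
        if not near:
            noise_sum += integrals[k]
            n_noise += 1
    sig_mean = signal / len(products)
    if n_noise == 0:
        return math.inf
    return sig_mean / (noise_sum / n_noise)


def spectrum_at(mz_int_pairs, rt=1.0, target=449.3526):
    mz = np.array([m for m, _ in mz_int_pairs])
    inten = np.array([i for _, i in mz_int_pairs])
    order = np.argsort(mz)
    return Spectrum(rt=rt, ms_level=2, mz=mz[order], intensity=inten[order],
                    isolation_target=target)


class TestComputeSnr:
    def make_inputs(self, ampp, config):
        fa = parse_shorthand("FA 18:1n-9")
        ts = ozid_transitions(fa, ampp)
        excl = np.concatenate([
            precursor_envelope_mz(18, 1, ampp),
            possible_product_mz(18, 1, ampp, config.min_db_position),
        ])
        return fa, ts, excl

    def test_direct_evaluation_example(self, ampp, config):
        """Two products integrating 50 each, ten noise peaks totaling 100:
        S/N = (100/2) / (100/10) = 5."""
        fa, ts, excl = self.make_inputs(ampp, config)
        pairs = [(ts.transitions[0].aldehyde_mz, 50.0),
                 (ts.transitions[0].criegee_mz, 50.0)]
        noise_mz = np.linspace(200.0, 209.0, 10)  # far from any possible product
        pairs += [(m, 10.0) for m in noise_mz]
        spec = spectrum_at(pairs)
        res = compute_snr([spec], ts, excl, config)
        assert res.snr == pytest.approx(5.0, rel=1e-12)
        assert res.n_signal_peaks == 2 and res.n_noise_peaks == 10

    def test_no_products_means_zero(self, ampp, config):
        fa, ts, excl = self.make_inputs(ampp, config)
        spec = spectrum_at([(200.0, 10.0), (205.0, 10.0)])
        assert compute_snr([spec], ts, excl, config).snr == 0.0

    def test_signal_peak_counts_mono_vs_hexa(self, ampp, config):
        mono = ozid_transitions(parse_shorthand("FA 18:1n-9"), ampp)
        hexa = ozid_transitions(parse_shorthand("FA 22:6n-3,6,9,12,15,18"), ampp)
        assert len(mono) == 2 and len(hexa) == 12

    def test_noise_free_spectrum_flagged_infinite(self, ampp, config):
        fa, ts, excl = self.make_inputs(ampp, config)
        spec = spectrum_at([(ts.transitions[0].aldehyde_mz, 50.0),
                            (ts.transitions[0].criegee_mz, 40.0)])
        res = compute_snr([spec], ts, excl, config)
        assert math.isinf(res.snr) and res.infinite_noise_free

    def test_matches_brute_force_on_random_spectra(self, ampp, config, rng):
        fa, ts, excl = self.make_inputs(ampp, config)
        for _ in range(100):
            pairs = []
            for pmz in ts.product_mz:
                if rng.random() < 0.8:
                    pairs.append((pmz * (1 + rng.normal(0, 2e-6)), rng.uniform(10, 1e4)))
            n_noise = int(rng.integers(0, 30))
            pairs += [(float(m), float(i)) for m, i in
                      zip(rng.uniform(150, 500, n_noise), rng.lognormal(2, 1, n_noise))]
            n_spec = int(rng.integers(1, 4))
            spectra = []
            for k in range(n_spec):
                sel = [p for p in pairs if rng.random() < 0.9]
                if not sel:
                    sel = pairs[:1] or [(200.0, 1.0)]
                spectra.append(spectrum_at(sel, rt=1.0 + 0.01 * k))
            got = compute_snr(spectra, ts, excl, config).snr
            want = snr_oracle(spectra, ts, excl, config)
            if math.isinf(want):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(want, rel=1e-9)


class TestClassifyAndDedupe:
    def candidate(self, ampp, text, rt, snr_value, area=None):
        fa = parse_shorthand(text)
        ts = ozid_transitions(fa, ampp)
        obs = make_obs(carbons=fa.carbons, d=fa.n_double_bonds)
        res = SnrResult(signal_mean=snr_value, noise_mean=1.0,
                        n_signal_peaks=len(ts), n_noise_peaks=5, snr=snr_value)
        return IsomerCandidate(fa, rt, res, "DDA", tuple(ts.product_mz),
                               area if area is not None else snr_value * len(ts), obs)

    @pytest.mark.parametrize("snr_value,tier", [
        (2.9, "rejected"), (3.0, "tentative"), (9.9, "tentative"), (10.0, "confident"),
    ])
    def test_tier_boundaries(self, ampp, config, snr_value, tier):
        cand = self.candidate(ampp, "FA 18:1n-9", 8.78, snr_value)
        classify_and_dedupe([cand], config)
        assert cand.tier == tier

    def test_shared_product_duplicate_removed(self, ampp, config):
        # two tri-unsaturated patterns explaining one feature via shared ions
        a = self.candidate(ampp, "FA 20:3n-6,9,12", 8.50, 100.0, area=600.0)
        b = self.candidate(ampp, "FA 20:3n-6,9,14", 8.505, 80.0, area=400.0)
        curated, _ = classify_and_dedupe([a, b], config)
        assert curated == [a]
        assert "duplicate" in b.flags

    def test_separated_features_both_kept(self, ampp, config):
        a = self.candidate(ampp, "FA 18:1n-9", 8.78, 100.0)
        b = self.candidate(ampp, "FA 18:1n-9", 8.94, 50.0)  # cis/trans pair
        curated, _ = classify_and_dedupe([a, b], config)
        assert len(curated) == 2

    def test_overoxidation_prescreen_flag(self, ampp, config):
        parent = self.candidate(ampp, "FA 18:1n-9", 8.78, 1e4, area=1e6)
        artifact = self.candidate(ampp, "FA 18:1n-10", 8.781, 100.0, area=1.4e4)
        curated, _ = classify_and_dedupe([parent, artifact], config)
        assert "putative_overoxidation" in artifact.flags
        assert "putative_overoxidation" not in parent.flags


@pytest.fixture(scope="module")
def oleic_dia(agents):
    rm_rt = {"16:0": 1.5, "18:0": 2.6, "oleic": 2.1}
    entries = (
        MixtureEntry(parse_shorthand("FA 16:0"), 200.0, rm_rt["16:0"]),
        MixtureEntry(parse_shorthand("FA 18:0"), 100.0, rm_rt["18:0"]),
        MixtureEntry(parse_shorthand("FA 18:1n-9 cis"), 150.0, rm_rt["oleic"]),
    )
    mix = GroundTruthMixture(entries, default_internal_standard())
    inst = InstrumentModel(gradient_min=4.0, noise_peak_density=0.005)
    return mix, inst, simulate_dia(mix, inst, agents["AMPP"], seed=6)


class TestFindPrecursors:
    def config_for(self):
        # anchors 1.5/2.6 imply a steep pseudo-gradient; keep windows inside it
        return PipelineConfig(gradient_min=4.0, carbons_max=20)

    def test_oleic_recovered_at_true_rt(self, ampp, oleic_dia):
        mix, inst, run = oleic_dia
        obs = find_precursors(run, ampp, self.config_for())
        oleic = [o for o in obs if o.sum_composition == (18, 1)]
        assert len(oleic) == 1
        assert oleic[0].apex_rt == pytest.approx(2.1, abs=inst.scan_interval_s / 60)

    def test_below_threshold_species_absent(self, ampp, oleic_dia):
        mix, inst, run = oleic_dia
        cfg = self.config_for()
        cfg.abundance_threshold = 1e9
        obs = find_precursors(run, ampp, cfg)
        assert [o for o in obs if o.sum_composition == (18, 1)] == []

    def test_large_mass_error_rejected(self, ampp, oleic_dia):
        mix, inst, run = oleic_dia
        cfg = self.config_for()
        shifted = []
        for s in run.spectra:  # apply an 80 ppm systematic shift
            shifted.append(Spectrum(rt=s.rt, ms_level=1, mz=s.mz * (1 + 80e-6),
                                    intensity=s.intensity.copy()))
        from ozfad.lcms import LcmsRun

        shifted_run = LcmsRun("DIA", shifted)
        anchors = (1.5, 2.6)  # supply anchors: the anchor peaks moved too
        obs = find_precursors(shifted_run, ampp, cfg, anchor_rts=anchors)
        assert [o for o in obs if o.sum_composition == (18, 1)] == []


class TestDiaEvidenceSearch:
    def test_oleic_candidate_found_in_dia_mode(self, ampp, oleic_dia):
        mix, inst, run = oleic_dia
        cfg = PipelineConfig(gradient_min=4.0, carbons_max=20)
        obs = [o for o in find_precursors(run, ampp, cfg) if o.n_double_bonds]
        cands = search_double_bonds(run, obs, ampp, cfg)
        names = {(c.species.carbons, c.positions) for c in cands}
        assert (18, (9,)) in names
        assert all(c.evidence_mode == "DIA" for c in cands)
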