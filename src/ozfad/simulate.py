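"""Synthetic LC-OzID-MS runs with ground truth.

The generator emulates the statistical structure the pipeline assumes:

* Gaussian chromatographic peaks for fixed-charge derivatized fatty acids
  across >= 4 orders of magnitude of abundance,
* co-eluting double-bond isomers (retention times follow a built-in model
  that is linear in carbons with additive per-bond dECL offsets; cis elutes
  before trans, branched before straight),
* OzID aldehyde/Criegee product ions co-eluting exactly with their precursor,
* isotope envelopes, ppm-scale mass error, log-normal chemical noise and
  Poisson shot noise,
* over-oxidation artifact ions at the n-(x+1) transition m/z (1.5% of the
  genuine product intensity for cis bonds, 3% for trans),
* DIA MS1 scans at 0.1 s cadence; DDA MS2 scans scheduled from a 0.3 s
  inclusion-list grid (few points per chromatographic peak),
* loop-injection (infusion) runs of the precursor envelopes only, including
  the perdeuterated FA 16:0d31 internal standard and 2-Da-spaced isobaric
  overlaps merged at the configured resolution.

Every simulated run is reproducible from its seed, and the ground truth is
serializable next to it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import chem
from .chem import DerivatizationAgent, DoubleBond, FattyAcidSpecies
from .lcms import LcmsRun, Spectrum
from .nomenclature import parse_shorthand, shorthand_name

__all__ = [
    "RetentionModel",
    "InstrumentModel",
    "MixtureEntry",
    "GroundTruthMixture",
    "simulate_dia",
    "simulate_dda",
    "simulate_infusion",
    "make_blank",
    "plasma_like_mixture",
    "blank_contaminants",
    "default_internal_standard",
]


@dataclass(frozen=True)
class RetentionModel:
    """Built-in retention model: rt = t0 + per_carbon * ECL.

    Each double bond shifts the equivalent chain length by
    ``decl_intercept(config) + decl_position_slope * position``; a branched
    chain shifts it once more by ``decl_branched``. The coefficients are
    calibrated so that derivatized oleic and mead acid co-elute near 8.8 min
    on a 20-min gradient while dihomo-gamma-linolenic and sciadonic acid
    fall near 8.5 and 8.6 min -- the elution structure characteristic of
    reversed-phase plasma runs. Offsets are at least twice the downstream
    decision tolerances (cis/trans separation 0.35 ECL units vs a 0.15
    assignment tolerance; branched offset 0.7 vs a 0.3 flagging offset).
    """

    t0: float = 1.28  # min
    per_carbon: float = 0.45  # min per ECL unit
    decl_cis: float = -2.0
    decl_trans: float = -1.65
    decl_unknown: float = -2.0
    decl_position_slope: float = 0.074
    decl_branched: float = -0.70

    def rt_saturated(self, carbons: int) -> float:
        return self.t0 + self.per_carbon * carbons

    def decl(self, fa: FattyAcidSpecies) -> float:
        base = {"cis": self.decl_cis, "trans": self.decl_trans, "unknown": self.decl_unknown}
        d = sum(base[b.configuration] + self.decl_position_slope * b.position for b in fa.double_bonds)
        if fa.branch_class == "branched":
            d += self.decl_branched
        return d

    def rt(self, fa: FattyAcidSpecies) -> float:
        return self.rt_saturated(fa.carbons) + self.per_carbon * self.decl(fa)


@dataclass(frozen=True)
class InstrumentModel:
    """Acquisition and response parameters shared by all simulated runs."""

    scan_interval_s: float = 0.1
    slot_width_s: float = 0.3
    gradient_min: float = 20.0
    peak_sigma_min: float = 0.025  # ~3.5 s FWHM, typical sub-2-um UPLC
    ozonolysis_efficiency: float | dict = 0.25  # fraction of precursor, per product ion
    overoxidation_rate_cis: float = 0.015
    overoxidation_rate_trans: float = 0.03
    mass_error_ppm: float = 2.0  # 1 sigma centroid jitter
    noise_peak_density: float = 0.02  # chemical-noise peaks per Da per MS1 scan
    noise_peak_density_ms2: float = 0.002
    noise_lognorm_mu: float = 1.1  # log intensity
    noise_lognorm_sigma: float = 0.7
    response_factor: float = 5000.0  # apex counts per (nmol/mL)
    shot_noise: bool = True
    shot_noise_floor: float = 5.0
    mz_range: tuple = (150.0, 760.0)
    isolation_window_da: float = 2.0
    centroid_merge_da: float = 0.012  # instrument resolution at the centroid level
    n_isotope_peaks: int = 5
    criegee_fraction: float = 0.85  # Criegee vs aldehyde ion yield
    infusion_duration_min: float = 2.0
    infusion_apex_min: float = 0.6
    infusion_sigma_min: float = 0.18
    rng_seed: int = 0

    def __post_init__(self):
        for r in (self.overoxidation_rate_cis, self.overoxidation_rate_trans):
            if not 0.0 <= r <= 1.0:
                raise ValueError("over-oxidation rates must be in [0, 1]")
        if self.scan_interval_s <= 0:
            raise ValueError("scan interval must be positive")

    def efficiency(self, position: int) -> float:
        if isinstance(self.ozonolysis_efficiency, dict):
            return self.ozonolysis_efficiency.get(position, 0.25)
        return float(self.ozonolysis_efficiency)


@dataclass(frozen=True)
class MixtureEntry:
    species: FattyAcidSpecies
    concentration: float  # nmol/mL
    rt: float  # minutes


@dataclass(frozen=True)
class GroundTruthMixture:
    """True composition of a simulated sample.

    ``internal_standard`` is a (species, concentration) pair; by default the
    perdeuterated palmitic acid FA 16:0d31 at 1.348 nmol/mL (µmol/L).
    """

    entries: tuple
    internal_standard: tuple

    def __post_init__(self):
        for e in self.entries:
            if e.concentration <= 0:
                raise ValueError("concentrations must be positive")

    @property
    def species(self) -> tuple:
        return tuple(e.species for e in self.entries)

    def to_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("shorthand\tconcentration_nmol_ml\trt_min\tbranch_class\trole\n")
            for e in self.entries:
                fh.write(
                    f"{shorthand_name(e.species)}\t{e.concentration:.6g}\t{e.rt:.4f}\t"
                    f"{e.species.branch_class}\tanalyte\n"
                )
            istd, conc = self.internal_standard
            fh.write(f"{shorthand_name(istd)}\t{conc:.6g}\t\tstraight\tinternal_standard\n")

    @classmethod
    def from_table(cls, path) -> "GroundTruthMixture":
        entries = []
        istd = None
        with open(path) as fh:
            fh.readline()
            for line in fh:
                name, conc, rt, branch, role = line.rstrip("\n").split("\t")
                fa = parse_shorthand(name)
                fa = replace(fa, branch_class=branch)
                if role == "internal_standard":
                    istd = (fa, float(conc))
                else:
                    entries.append(MixtureEntry(fa, float(conc), float(rt)))
        return cls(tuple(entries), istd)


def default_internal_standard() -> tuple:
    return (parse_shorthand("FA 16:0d31"), 1.348)


def _derive_seed(seed: int, label: str) -> int:
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# ion sets
# ---------------------------------------------------------------------------

def _species_ions(entry: MixtureEntry, agent: DerivatizationAgent, instrument: InstrumentModel,
                  with_products: bool) -> tuple:
    """(mz array, relative intensity array) for one species at unit apex height.

    Relative intensities are per monoisotopic precursor ion = 1. Product ions
    carry their own isotope envelopes; over-oxidation artifact ions mirror
    the n-(x+1) transitions at the configured per-configuration rate.
    """
    fa = entry.species
    mzs, rel = [], []
    prec_comp = chem.precursor_composition(fa, agent)
    prec_mz = chem.monoisotopic_mass(prec_comp) - chem.ELECTRON_MASS
    pattern = chem.isotope_pattern(prec_comp, instrument.n_isotope_peaks)
    pattern_sum = sum(ab for _, ab in pattern)
    # the species' ion current is distributed across its isotope envelope
    for off, ab in pattern:
        mzs.append(prec_mz + off)
        rel.append(ab / pattern_sum)
    if with_products:
        for bond in fa.double_bonds:
            eff = instrument.efficiency(bond.position)
            rate = (
                instrument.overoxidation_rate_cis
                if bond.configuration != "trans"
                else instrument.overoxidation_rate_trans
            )
            for kind_scale, criegee in ((1.0, False), (instrument.criegee_fraction, True)):
                comp = chem.product_composition(fa, agent, bond.position, criegee=criegee)
                base = chem.monoisotopic_mass(comp) - chem.ELECTRON_MASS
                ppat = chem.isotope_pattern(comp, 2)
                psum = sum(ab for _, ab in ppat)
                for off, ab in ppat:
                    mzs.append(base + off)
                    rel.append(eff * kind_scale * ab / psum)
                # over-oxidation artifact: same ion type, apparent bond one
                # carbon further from the methyl terminus (n-(x+1)), at the
                # configured rate relative to the genuine product ion
                if bond.position + 1 <= fa.carbons - 2 and rate > 0:
                    mzs.append(base - chem.MASS_CH2)
                    rel.append(eff * kind_scale * rate / psum)
    return np.array(mzs), np.array(rel)


def _assemble_scan(rng, centers, heights, instrument: InstrumentModel, noise_density: float,
                   mz_lo: float, mz_hi: float) -> tuple:
    """Apply noise models and centroid merging to one scan's stick list."""
    n_noise = rng.poisson(noise_density * (mz_hi - mz_lo))
    if n_noise:
        noise_mz = rng.uniform(mz_lo, mz_hi, n_noise)
        noise_i = rng.lognormal(instrument.noise_lognorm_mu, instrument.noise_lognorm_sigma, n_noise)
        centers = np.concatenate([centers, noise_mz])
        heights = np.concatenate([heights, noise_i])
    if centers.size == 0:
        return centers, heights
    if instrument.mass_error_ppm > 0:
        centers = centers * (1.0 + rng.normal(0.0, instrument.mass_error_ppm * 1e-6, centers.size))
    if instrument.shot_noise:
        big = heights > instrument.shot_noise_floor
        heights = heights.copy()
        heights[big] = rng.poisson(heights[big]).astype(float)
    keep = heights > 0
    centers, heights = centers[keep], heights[keep]
    order = np.argsort(centers, kind="stable")
    centers, heights = centers[order], heights[order]
    # merge centroids closer than the instrument resolution
    if centers.size > 1:
        new = np.concatenate([[True], np.diff(centers) > instrument.centroid_merge_da])
        ids = np.cumsum(new) - 1
        k = ids[-1] + 1
        merged_w = np.bincount(ids, weights=heights, minlength=k)
        merged_mz = np.bincount(ids, weights=centers * heights, minlength=k) / merged_w
        centers, heights = merged_mz, merged_w
    return centers, heights


def _elution(heights_apex, rts, t, sigma):
    scale = np.exp(-0.5 * ((t - rts) / sigma) ** 2)
    scale[np.abs(t - rts) > 4.5 * sigma] = 0.0
    return heights_apex * scale


def simulate_dia(mixture: GroundTruthMixture, instrument: InstrumentModel,
                 agent: DerivatizationAgent, seed: int | None = None) -> LcmsRun:
    """MS1-only run: every ion is ozonolysed, products co-elute with precursors."""
    for e in mixture.entries:
        if not 0.0 <= e.rt <= instrument.gradient_min:
            raise ValueError(f"retention time {e.rt} outside the gradient")
    rng = np.random.default_rng(_derive_seed(seed if seed is not None else instrument.rng_seed, "dia"))
    ion_sets = [_species_ions(e, agent, instrument, with_products=True) for e in mixture.entries]
    apex = np.array([instrument.response_factor * e.concentration for e in mixture.entries])
    rts = np.array([e.rt for e in mixture.entries])
    dt = instrument.scan_interval_s / 60.0
    times = np.arange(0.0, instrument.gradient_min, dt)
    lo, hi = instrument.mz_range
    spectra = []
    for t in times:
        scale = _elution(apex, rts, t, instrument.peak_sigma_min)
        live = np.nonzero(scale)[0]
        if live.size:
            centers = np.concatenate([ion_sets[i][0] for i in live])
            heights = np.concatenate([ion_sets[i][1] * scale[i] for i in live])
        else:
            centers = np.empty(0)
            heights = np.empty(0)
        mz, inten = _assemble_scan(rng, centers, heights, instrument,
                                   instrument.noise_peak_density, lo, hi)
        spectra.append(Spectrum(rt=float(t), ms_level=1, mz=mz, intensity=inten))
    return LcmsRun("DIA", spectra, {"agent": agent.code, "mode": "DIA",
                                    "gradient_min": str(instrument.gradient_min)})


def simulate_dda(mixture: GroundTruthMixture, instrument: InstrumentModel,
                 agent: DerivatizationAgent, targets, seed: int | None = None) -> LcmsRun:
    """One MS2 scan per inclusion-list slot: only ions whose precursor falls
    inside the quadrupole isolation window contribute, so product S/N gains
    from the removal of off-target chemical noise."""
    rng = np.random.default_rng(_derive_seed(seed if seed is not None else instrument.rng_seed, "dda"))
    ion_sets = [_species_ions(e, agent, instrument, with_products=True) for e in mixture.entries]
    prec_mz = np.array(
        [chem.precursor_mz(e.species, agent) for e in mixture.entries]
    )
    apex = np.array([instrument.response_factor * e.concentration for e in mixture.entries])
    rts = np.array([e.rt for e in mixture.entries])
    lo = instrument.mz_range[0]
    spectra = []
    for slot in targets.slots:
        t = 0.5 * (slot.start_min + slot.end_min)
        scale = _elution(apex, rts, t, instrument.peak_sigma_min)
        selected = np.abs(prec_mz - slot.target_mz) <= instrument.isolation_window_da
        live = np.nonzero(scale * selected)[0]
        if live.size:
            centers = np.concatenate([ion_sets[i][0] for i in live])
            heights = np.concatenate([ion_sets[i][1] * scale[i] for i in live])
        else:
            centers = np.empty(0)
            heights = np.empty(0)
        hi = slot.target_mz + 2 * instrument.isolation_window_da
        mz, inten = _assemble_scan(rng, centers, heights, instrument,
                                   instrument.noise_peak_density_ms2, lo, hi)
        spectra.append(Spectrum(rt=float(t), ms_level=2, mz=mz, intensity=inten,
                                isolation_target=float(slot.target_mz)))
    return LcmsRun("DDA", spectra, {"agent": agent.code, "mode": "DDA",
                                    "gradient_min": str(instrument.gradient_min)})


def simulate_infusion(mixture: GroundTruthMixture, instrument: InstrumentModel,
                      agent: DerivatizationAgent, seed: int | None = None,
                      include_istd: bool = True) -> LcmsRun:
    """Loop-injection ESI-MS run without ozone: precursor envelopes only."""
    rng = np.random.default_rng(
        _derive_seed(seed if seed is not None else instrument.rng_seed, "infusion"))
    entries = list(mixture.entries)
    if include_istd:
        istd, conc = mixture.internal_standard
        entries.append(MixtureEntry(istd, conc, instrument.infusion_apex_min))
    ion_sets = [_species_ions(MixtureEntry(e.species, e.concentration, 0.0), agent,
                              instrument, with_products=False) for e in entries]
    apex = np.array([instrument.response_factor * e.concentration for e in entries])
    dt = instrument.scan_interval_s / 60.0
    times = np.arange(0.0, instrument.infusion_duration_min, dt)
    lo, hi = instrument.mz_range
    spectra = []
    for t in times:
        g = np.exp(-0.5 * ((t - instrument.infusion_apex_min) / instrument.infusion_sigma_min) ** 2)
        if entries:
            centers = np.concatenate([s[0] for s in ion_sets])
            heights = np.concatenate([s[1] * a * g for s, a in zip(ion_sets, apex)])
        else:
            centers = np.empty(0)
            heights = np.empty(0)
        mz, inten = _assemble_scan(rng, centers, heights, instrument,
                                   instrument.noise_peak_density, lo, hi)
        spectra.append(Spectrum(rt=float(t), ms_level=1, mz=mz, intensity=inten))
    return LcmsRun("infusion", spectra, {"agent": agent.code, "mode": "infusion"})


def make_blank(instrument: InstrumentModel, agent: DerivatizationAgent,
               contaminants: GroundTruthMixture | None = None,
               seed: int | None = None) -> dict:
    """Process-blank runs: contaminant fatty acids plus noise, same instrument."""
    if contaminants is None:
        contaminants = GroundTruthMixture((), default_internal_standard())
    base = seed if seed is not None else instrument.rng_seed
    return {
        "dia": simulate_dia(contaminants, instrument, agent, seed=_derive_seed(base, "blank")),
        "infusion": simulate_infusion(contaminants, instrument, agent,
                                      seed=_derive_seed(base, "blank-inf")),
    }


# ---------------------------------------------------------------------------
# reference mixtures
# ---------------------------------------------------------------------------

def _species(text: str, branched: bool = False) -> FattyAcidSpecies:
    fa = parse_shorthand(text)
    if branched:
        fa = replace(fa, branch_class="branched")
    return fa


def plasma_like_mixture(retention: RetentionModel | None = None) -> GroundTruthMixture:
    """A 20-species mixture emulating a hydrolyzed plasma extract.

    Concentrations span four orders of magnitude (0.05-500 nmol/mL). Three
    pairs fully co-elute: oleic acid with mead acid (different m/z, the
    classic abundant/trace pairing), oleic with a 1% FA 18:1n-12 positional
    isomer (same m/z; exercises the product-ion fallback quantification),
    and sapienic-type FA 16:1n-10 with a trace FA 19:2. Saturated palmitic
    and stearic acid anchor retention-time prediction and recalibration.
    """
    rm = retention or RetentionModel()

    def entry(text, conc, rt=None):
        fa = _species(text)
        return MixtureEntry(fa, conc, rm.rt(fa) if rt is None else rt)

    oleic = entry("FA 18:1n-9 cis", 500.0)
    sapienic = entry("FA 16:1n-10 cis", 30.0)
    entries = [
        entry("FA 16:0", 400.0),
        entry("FA 18:0", 150.0),
        oleic,
        entry("FA 18:1n-9 trans", 20.0),
        entry("FA 18:1n-12 cis", 5.0, rt=oleic.rt),          # co-elutes with oleic, same m/z
        entry("FA 18:1n-5 cis", 60.0),
        entry("FA 20:3n-9,12,15 cis", 2.0, rt=oleic.rt),     # mead acid under the oleic peak
        entry("FA 20:3n-6,9,12 cis", 80.0),                   # resolved ~0.1 min from sciadonic
        entry("FA 20:3n-6,9,15 cis", 8.0),
        sapienic,
        entry("FA 16:1n-7 cis", 100.0),
        entry("FA 16:1n-7 trans", 3.0),
        entry("FA 22:6n-3,6,9,12,15,18 cis", 120.0),
        entry("FA 22:5n-3,6,9,12,15 cis", 12.0),
        entry("FA 22:4n-6,9,12,15 cis", 1.2),
        entry("FA 17:1n-8 cis", 6.0),
        entry("FA 20:1n-9 cis", 40.0),
        entry("FA 19:2n-6,9 cis", 0.5, rt=sapienic.rt),      # trace diene under sapienic
        entry("FA 24:1n-6 cis", 0.05),
        entry("FA 20:5n-3,6,9,12,15 cis", 25.0),
    ]
    return GroundTruthMixture(tuple(entries), default_internal_standard())


def blank_contaminants(sample: GroundTruthMixture,
                       retention: RetentionModel | None = None) -> GroundTruthMixture:
    """Saturated contaminants at levels typical of a process blank."""
    rm = retention or RetentionModel()
    levels = {"FA 16:0": 200.0, "FA 18:0": 90.0}
    entries = tuple(
        MixtureEntry(_species(name), conc, rm.rt(_species(name)))
        for name, conc in levels.items()
    )
    return GroundTruthMixture(entries, sample.internal_standard)
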