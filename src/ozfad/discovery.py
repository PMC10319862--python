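"""Precursor analysis, DDA target-list scheduling and the exhaustive
double-bond search with signal-to-noise scoring.

The discovery stage mirrors the acquisition logic: retention-time windows
for every sum composition are predicted from the palmitic/stearic anchors,
precursor peaks found in the DIA run seed a 0.3 s-gridded inclusion list for
the tandem (DDA) run, and every chemically feasible double-bond pattern is
searched in the mass-selected OzID spectra. Candidates are scored by the
product-ion signal-to-noise ratio

    S/N = (sum of product-peak integrals / number of product peaks)
          / (sum of eligible-noise integrals / number of noise peaks)

where a peak is eligible noise only if it is near neither the precursor
isotope envelope nor any m/z that could arise from any feasible OzID
product of the selected precursor; the precursor peak itself is never
counted as signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import chem
from .chem import DerivatizationAgent, FattyAcidSpecies, OzidTransitionSet
from .config import PipelineConfig
from .lcms import Chromatogram, GAUSS_FWHM, LcmsRun, PeakFit, Spectrum, detect_peaks, extract_xic
from .nomenclature import shorthand_name

__all__ = [
    "PrecursorObservation",
    "TargetSlot",
    "TargetList",
    "SnrResult",
    "IsomerCandidate",
    "predict_rt_window",
    "find_anchor_rts",
    "find_precursors",
    "build_target_list",
    "search_double_bonds",
    "compute_snr",
    "classify_and_dedupe",
]


class AnchorError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# retention-window prediction
# ---------------------------------------------------------------------------

def predict_rt_window(
    carbons: int,
    n_double_bonds: int,
    anchor_rts: tuple,
    config: PipelineConfig | None = None,
) -> tuple:
    """Retention window for a sum composition from the 16:0/18:0 anchors.

    The saturated retention time is linear in carbon number with slope
    (rt18 - rt16)/2; unsaturation shifts it by a per-double-bond dECL band
    (defaults: [-2.2 d - 0.3, -0.4 d + 0.3] chain-length units). The window
    is clamped to the gradient.
    """
    cfg = config or PipelineConfig()
    rt16, rt18 = anchor_rts
    if rt16 is None or rt18 is None:
        raise AnchorError(
            "retention prediction needs both FA 16:0 and FA 18:0 anchor retention "
            "times; supply them or ensure the anchors are detectable"
        )
    slope = (rt18 - rt16) / 2.0
    rt_sat = rt16 + (carbons - 16) * slope
    d = n_double_bonds
    lo = rt_sat + (cfg.decl_lo_per_db * d + cfg.decl_lo_const) * slope
    hi = rt_sat + (cfg.decl_hi_per_db * d + cfg.decl_hi_const) * slope
    lo, hi = min(lo, hi), max(lo, hi)
    return (max(lo, 0.0), min(hi, cfg.gradient_min))


@dataclass
class PrecursorObservation:
    """One chromatographic feature of a derivatized-fatty-acid precursor."""

    carbons: int
    n_double_bonds: int
    theoretical_mz: float
    observed_mz: float
    ppm_error: float
    apex_rt: float
    height: float
    abundance: float  # Gaussian peak area
    fwhm: float

    @property
    def sum_composition(self) -> tuple:
        return (self.carbons, self.n_double_bonds)


def find_anchor_rts(run: LcmsRun, agent: DerivatizationAgent, config: PipelineConfig) -> tuple:
    """Locate the palmitic (16:0) and stearic (18:0) acid precursor peaks."""
    rts = []
    for carbons in (16, 18):
        fa = FattyAcidSpecies(carbons)
        mz = chem.precursor_mz(fa, agent)
        chrom = extract_xic(run, mz, config.precursor_xic_ppm)
        peaks = detect_peaks(chrom, config.min_peak_height, config.min_peak_points)
        if not peaks:
            raise AnchorError(
                f"saturated anchor FA {carbons}:0 not detected at m/z {mz:.4f}"
            )
        rts.append(max(peaks, key=lambda p: p.height).apex_rt)
    return tuple(rts)


def _observed_mz(run: LcmsRun, mz: float, tol_ppm: float, rt_lo: float, rt_hi: float) -> float:
    """Intensity-weighted mean matched centroid m/z across a retention window."""
    idx = run._build_index()
    tol = mz * tol_ppm * 1e-6
    lo = np.searchsorted(idx["mz"], mz - tol, "left")
    hi = np.searchsorted(idx["mz"], mz + tol, "right")
    if hi <= lo:
        return math.nan
    sel_mz = idx["mz"][lo:hi]
    sel_i = idx["intensity"][lo:hi]
    rts = idx["rt"][idx["scan"][lo:hi]]
    keep = (rts >= rt_lo) & (rts <= rt_hi)
    if not np.any(keep):
        return math.nan
    return float(np.average(sel_mz[keep], weights=sel_i[keep]))


def find_precursors(
    run: LcmsRun,
    agent: DerivatizationAgent,
    config: PipelineConfig,
    anchor_rts: tuple | None = None,
) -> list:
    """Precursor-analysis step on the DIA run.

    For every sum composition in the configured carbon/double-bond ranges the
    precursor XIC is extracted; peaks inside the predicted retention window
    that pass the abundance and ppm-error filters become observations, one
    per distinct chromatographic peak.
    """
    anchors = anchor_rts or find_anchor_rts(run, agent, config)
    observations = []
    for carbons in range(config.carbons_min, config.carbons_max + 1):
        for d in range(0, config.double_bonds_max + 1):
            if d > (carbons - 3) // 2 + 1:
                continue
            mz = _sum_composition_mz(carbons, d, agent)
            window = predict_rt_window(carbons, d, anchors, config)
            chrom = extract_xic(run, mz, config.precursor_xic_ppm)
            for peak in detect_peaks(chrom, config.min_peak_height, config.min_peak_points):
                if not (window[0] <= peak.apex_rt <= window[1]):
                    continue
                if peak.area < config.abundance_threshold:
                    continue
                obs_mz = _observed_mz(
                    run, mz, config.precursor_xic_ppm,
                    peak.apex_rt - peak.sigma, peak.apex_rt + peak.sigma,
                )
                if math.isnan(obs_mz):
                    continue
                ppm = (obs_mz - mz) / mz * 1e6
                if abs(ppm) > config.max_precursor_ppm_error:
                    continue
                observations.append(
                    PrecursorObservation(
                        carbons=carbons,
                        n_double_bonds=d,
                        theoretical_mz=mz,
                        observed_mz=obs_mz,
                        ppm_error=ppm,
                        apex_rt=peak.apex_rt,
                        height=peak.height,
                        abundance=peak.area,
                        fwhm=peak.fwhm,
                    )
                )
    return observations


def _sum_composition_mz(carbons: int, n_db: int, agent: DerivatizationAgent) -> float:
    comp = {"C": carbons, "H": 2 * carbons - 2 * n_db, "O": 2}
    from pyteomics import mass as _pm

    total = _pm.Composition(comp) + _pm.Composition(agent.cation_composition) - _pm.Composition(formula="H2O")
    return _pm.calculate_mass(composition=total) - chem.ELECTRON_MASS


# ---------------------------------------------------------------------------
# target list
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetSlot:
    start_min: float
    end_min: float
    target_mz: float
    composition: tuple  # (carbons, n_double_bonds)


@dataclass
class TargetList:
    """A contiguous 0.3 s grid with exactly one precursor target per slot."""

    slots: list
    slot_width_s: float

    def __len__(self) -> int:
        return len(self.slots)

    def export(self, path, config: PipelineConfig | None = None) -> None:
        """DDA include-list dialect: m/z, slot start/end in seconds.

        Instrument acceptance of entries is within +/-150 mDa and +/-0.15 s
        by default.
        """
        cfg = config or PipelineConfig()
        with open(path, "w") as fh:
            fh.write("# include list; acceptance +/-%g mDa, +/-%g s\n"
                     % (cfg.include_window_mda, cfg.include_window_s))
            fh.write("mz\tstart_s\tend_s\tcarbons\tdouble_bonds\n")
            for s in self.slots:
                fh.write(f"{s.target_mz:.5f}\t{s.start_min * 60:.2f}\t{s.end_min * 60:.2f}\t"
                         f"{s.composition[0]}\t{s.composition[1]}\n")


def build_target_list(observations: Sequence[PrecursorObservation],
                      config: PipelineConfig) -> TargetList:
    """Resample precursor claims onto the 0.3 s slot grid.

    Every observation claims the slots within apex +/- w (w = 1.5 x FWHM by
    default). Slots with several claimants go to the claimant with the
    fewest slots over the recent allocation window (ties: lower abundance,
    then lower m/z). Counting locally rather than over the whole gradient
    keeps the fairness goal at the scale that matters -- points per
    chromatographic peak -- so a precursor with a wide uncontested claim
    cannot be starved where it co-elutes with others, and every detected
    precursor retains targets irrespective of abundance. Unclaimed slots
    fall to the nearest observation in time, keeping the grid contiguous
    with exactly one target per slot.
    """
    if not observations:
        raise ValueError("target-list construction needs at least one observation")
    width_min = config.slot_width_s / 60.0
    n_slots = config.n_slots
    claims = [[] for _ in range(n_slots)]
    for k, obs in enumerate(observations):
        w = config.raw_halfwidth_fwhm * obs.fwhm
        first = max(0, int((obs.apex_rt - w) / width_min))
        last = min(n_slots - 1, int((obs.apex_rt + w) / width_min))
        for i in range(first, last + 1):
            claims[i].append(k)
    slot_owner = [-1] * n_slots
    window = max(1, config.fairness_window_slots)
    for i, claimants in enumerate(claims):
        if not claimants:
            continue
        recent = slot_owner[max(0, i - window) : i]
        owner = min(
            claimants,
            key=lambda k: (recent.count(k), observations[k].abundance,
                           observations[k].theoretical_mz),
        )
        slot_owner[i] = owner
    # fill unclaimed slots with the nearest claimed owner so the grid stays full
    owned = [i for i, o in enumerate(slot_owner) if o >= 0]
    for i in range(n_slots):
        if slot_owner[i] < 0:
            nearest = min(owned, key=lambda j: abs(j - i))
            slot_owner[i] = slot_owner[nearest]
    slots = []
    for i, owner in enumerate(slot_owner):
        obs = observations[owner]
        slots.append(
            TargetSlot(
                start_min=i * width_min,
                end_min=(i + 1) * width_min,
                target_mz=obs.theoretical_mz,
                composition=obs.sum_composition,
            )
        )
    return TargetList(slots, config.slot_width_s)


# ---------------------------------------------------------------------------
# S/N scoring
# ---------------------------------------------------------------------------

@dataclass
class SnrResult:
    signal_mean: float
    noise_mean: float
    n_signal_peaks: int
    n_noise_peaks: int
    snr: float
    infinite_noise_free: bool = False


def _cluster_spectra(spectra: Iterable[Spectrum], gap_ppm: float):
    """Sum spectra onto a common grid and cluster centroids into peaks."""
    mz = np.concatenate([s.mz for s in spectra]) if spectra else np.empty(0)
    inten = np.concatenate([s.intensity for s in spectra]) if spectra else np.empty(0)
    if mz.size == 0:
        return np.empty(0), np.empty(0)
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    new = np.concatenate([[True], np.diff(mz) > mz[:-1] * gap_ppm * 1e-6])
    ids = np.cumsum(new) - 1
    k = ids[-1] + 1
    integral = np.bincount(ids, weights=inten, minlength=k)
    center = np.bincount(ids, weights=mz * inten, minlength=k) / integral
    return center, integral


def possible_product_mz(carbons: int, n_double_bonds: int, agent: DerivatizationAgent,
                        min_position: int = 2, n_isotopes: int = 3) -> np.ndarray:
    """Every m/z that could arise from any feasible OzID product of (c, d).

    Covers both ion types at every feasible cleavage position with every
    feasible count of double bonds lost in the methyl-side fragment, plus
    the first isotopologues of each product (an M+1/M+2 of a product ion
    still arises from that product and is not eligible noise).
    """
    pmz = _sum_composition_mz(carbons, n_double_bonds, agent)
    iso_offsets = [k * 1.00335 for k in range(n_isotopes)]
    out = set()
    for x in range(min_position, carbons - 1):
        fit_below = (x - 1 - min_position) // 2 + 1 if x - 1 >= min_position else 0
        max_contained = min(max(n_double_bonds - 1, 0), fit_below)
        for m in range(0, max_contained + 1):
            loss = chem.monoisotopic_mass({"C": x, "H": 2 * x - 2 * m})
            aldehyde = pmz - loss + chem.MASS_O
            for off in iso_offsets:
                out.add(aldehyde + off)
                out.add(aldehyde + chem.MASS_O + off)
    return np.array(sorted(out))


def precursor_envelope_mz(carbons: int, n_double_bonds: int, agent: DerivatizationAgent,
                          n_peaks: int = 5) -> np.ndarray:
    comp = {"C": carbons, "H": 2 * carbons - 2 * n_double_bonds, "O": 2}
    from pyteomics import mass as _pm

    total = dict(_pm.Composition(comp) + _pm.Composition(agent.cation_composition)
                 - _pm.Composition(formula="H2O"))
    mono = chem.monoisotopic_mass(total) - chem.ELECTRON_MASS
    return np.array([mono + off for off, _ in chem.isotope_pattern(total, n_peaks)])


def compute_snr(
    spectra: Sequence[Spectrum],
    transitions: OzidTransitionSet,
    exclusion_mz: np.ndarray,
    config: PipelineConfig,
) -> SnrResult:
    """Product-ion signal-to-noise ratio over combined MS2 spectra.

    ``exclusion_mz`` lists every m/z near which a peak is not eligible noise
    (the precursor isotope envelope and all feasible OzID products of the
    selected precursor). The signal count is the structural product count
    (two ions per double bond) whether or not each was detected; the
    precursor peak is never part of the signal.
    """
    if not spectra:
        raise ValueError("S/N needs at least one spectrum")
    center, integral = _cluster_spectra(list(spectra), config.noise_proximity_ppm)
    products = np.array(transitions.product_mz)
    n_products = products.size
    if n_products == 0:
        return SnrResult(0.0, 0.0, 0, 0, 0.0)
    signal_sum = 0.0
    n_detected = 0
    matched = np.zeros(center.size, dtype=bool)
    for pmz in products:
        tol = pmz * config.product_match_ppm * 1e-6
        sel = (center >= pmz - tol) & (center <= pmz + tol)
        if np.any(sel):
            signal_sum += float(integral[sel].sum())
            n_detected += 1
            matched |= sel
    excl = np.sort(np.asarray(exclusion_mz, dtype=float))
    if excl.size and center.size:
        pos = np.clip(np.searchsorted(excl, center), 1, excl.size - 1)
        nearest = np.minimum(np.abs(center - excl[pos - 1]),
                             np.abs(center - excl[np.minimum(pos, excl.size - 1)]))
        near_excluded = nearest <= center * config.noise_proximity_ppm * 1e-6
    else:
        near_excluded = np.zeros(center.size, dtype=bool)
    noise_mask = ~near_excluded & ~matched
    n_noise = int(noise_mask.sum())
    signal_mean = signal_sum / n_products
    if n_noise == 0:
        return SnrResult(signal_mean, 0.0, n_detected, 0, math.inf,
                         infinite_noise_free=True)
    noise_mean = float(integral[noise_mask].sum()) / n_noise
    snr = signal_mean / noise_mean if noise_mean > 0 else math.inf
    return SnrResult(signal_mean, noise_mean, n_detected, n_noise, snr)


# ---------------------------------------------------------------------------
# exhaustive double-bond search
# ---------------------------------------------------------------------------

@dataclass
class IsomerCandidate:
    species: FattyAcidSpecies
    apex_rt: float
    snr: SnrResult
    evidence_mode: str  # DIA | DDA
    product_mz: tuple
    product_area: float
    observation: PrecursorObservation
    tier: str = "unclassified"
    flags: list = field(default_factory=list)

    @property
    def positions(self) -> tuple:
        return self.species.positions

    @property
    def sum_composition(self) -> tuple:
        return self.observation.sum_composition


def _candidate_apexes_dda(run: LcmsRun, products: np.ndarray, target_mz: float,
                          config: PipelineConfig) -> list:
    """Candidate apexes of the summed product-ion trace, co-elution checked.

    One pattern can describe several chromatographic features (e.g. a cis and
    a trans isomer sharing the same diagnostic m/z), so every detected peak
    of the summed product trace yields its own candidate retention time --
    including features that never resolve at the precursor level. The trace
    spans the whole run (every scan targeting this precursor) so that peaks
    are never truncated at arbitrary window edges. An apex is kept only if
    every individual product trace also peaks there (within the co-elution
    tolerance): all diagnostic ions must derive from the same feature, which
    rejects chimeric patterns assembled from the tails of features eluting
    elsewhere.
    """
    traces = []
    rt = None
    for pmz in products:
        x = extract_xic(run, float(pmz), config.product_match_ppm, ms_level=2,
                        isolation_target=target_mz, isolation_window_da=0.02)
        traces.append(x.intensity)
        rt = x.rt
    if rt is None or rt.size == 0:
        return []
    summed = np.sum(traces, axis=0)
    chrom = Chromatogram(rt, summed, float(products[0]), config.product_match_ppm)
    floor = max(config.product_presence_min,
                float(np.max(summed)) * config.relative_peak_floor)
    peaks = detect_peaks(chrom, min_height=floor, min_points=3, smooth_sigma_samples=1.0)
    if peaks:
        apexes = [p.apex_rt for p in peaks]
    else:
        i = int(np.argmax(summed))
        if not 1 < i < summed.size - 2:  # only a clear interior maximum
            return []
        apexes = [float(rt[i])]
    per_product_apexes = []
    for y in traces:
        tchrom = Chromatogram(rt, y, float(products[0]), config.product_match_ppm)
        tfloor = max(config.product_presence_min,
                     float(np.max(y)) * config.relative_peak_floor)
        ppeaks = detect_peaks(tchrom, min_height=tfloor, min_points=3,
                              smooth_sigma_samples=1.0)
        per_product_apexes.append(np.array([p.apex_rt for p in ppeaks]))
    out = []
    for apex in apexes:
        nearest = []
        for pa in per_product_apexes:
            if pa.size == 0:
                nearest = None
                break
            j = int(np.argmin(np.abs(pa - apex)))
            if abs(pa[j] - apex) > config.co_elution_tol_min:
                nearest = None
                break
            nearest.append(pa[j])
        if nearest is None:
            continue
        # the median per-product apex is robust against shared-product traces
        # whose summed fit is pulled toward a neighbouring feature
        out.append(float(np.median(nearest)))
    return sorted(set(out))


def search_double_bonds(
    run: LcmsRun,
    observations: Sequence[PrecursorObservation],
    agent: DerivatizationAgent,
    config: PipelineConfig,
    mode: str | None = None,
    library: Sequence[Sequence[int]] | None = None,
) -> list:
    """Exhaustive (or library) double-bond search against DDA or DIA evidence.

    A pattern becomes a candidate only when its complete transition set --
    every aldehyde and every Criegee ion -- is present. With DDA evidence
    products are read from MS2 scans of the matching isolation target; with
    DIA evidence each product XIC must show a peak co-eluting with the
    precursor apex.
    """
    mode = mode or config.search_mode
    dda = run.mode == "DDA"
    candidates = []
    if dda:
        groups: dict = {}
        for obs in observations:
            if obs.n_double_bonds:
                groups.setdefault(obs.sum_composition, []).append(obs)
        for (carbons, d), group in sorted(groups.items()):
            patterns = chem.enumerate_double_bond_patterns(
                carbons, d, mode=mode, library=library, min_position=config.min_db_position)
            excl = np.concatenate([
                precursor_envelope_mz(carbons, d, agent),
                possible_product_mz(carbons, d, agent, config.min_db_position),
            ])
            candidates.extend(_search_dda(run, group, patterns, agent, config, excl))
        return candidates
    for obs in observations:
        d = obs.n_double_bonds
        if d == 0:
            continue
        patterns = chem.enumerate_double_bond_patterns(
            obs.carbons, d, mode=mode, library=library, min_position=config.min_db_position)
        excl = np.concatenate([
            precursor_envelope_mz(obs.carbons, d, agent),
            possible_product_mz(obs.carbons, d, agent, config.min_db_position),
        ])
        candidates.extend(_search_dia(run, obs, patterns, agent, config, excl))
    return candidates


def _spectra_in_window(run: LcmsRun, obs: PrecursorObservation, lo: float, hi: float) -> list:
    return [
        s for s in run.spectra
        if s.ms_level == 2
        and s.isolation_target is not None
        and abs(s.isolation_target - obs.theoretical_mz) <= 0.02
        and lo <= s.rt <= hi
    ]


def _search_dda(run, group, patterns, agent, config, excl) -> list:
    """Search one sum composition against all of its matching MS2 scans."""
    out = []
    target_mz = group[0].theoretical_mz
    carbons = group[0].carbons
    wide = [
        s for s in run.spectra
        if s.ms_level == 2 and s.isolation_target is not None
        and abs(s.isolation_target - target_mz) <= 0.02
    ]
    if not wide:
        return out
    center, integral = _cluster_spectra(wide, config.noise_proximity_ppm)
    fwhm_ref = float(np.median([o.fwhm for o in group]))
    half_fwhm = fwhm_ref / 2.0
    for pattern in patterns:
        fa = chem.species_from_pattern(carbons, pattern)
        ts = chem.ozid_transitions(fa, agent)
        products = np.array(ts.product_mz)
        present = True
        for pmz in products:
            tol = pmz * config.product_match_ppm * 1e-6
            sel = (center >= pmz - tol) & (center <= pmz + tol)
            if not np.any(sel) or integral[sel].sum() < config.product_presence_min:
                present = False
                break
        if not present:
            continue
        for apex in _candidate_apexes_dda(run, products, target_mz, config):
            obs = min(group, key=lambda o: abs(o.apex_rt - apex))
            # candidates must belong to an observed precursor feature
            if abs(obs.apex_rt - apex) > config.raw_halfwidth_fwhm * obs.fwhm:
                continue
            local = [s for s in wide if apex - half_fwhm <= s.rt <= apex + half_fwhm]
            if not local:
                continue
            snr = compute_snr(local, ts, excl, config)
            if snr.n_signal_peaks < len(products):
                continue  # incomplete transition set at this feature
            area = snr.signal_mean * len(products)
            out.append(IsomerCandidate(fa, apex, snr, "DDA", tuple(products), area, obs))
    return out


def _search_dia(run, obs, patterns, agent, config, excl) -> list:
    out = []
    for pattern in patterns:
        fa = chem.species_from_pattern(obs.carbons, pattern)
        ts = chem.ozid_transitions(fa, agent)
        products = np.array(ts.product_mz)
        apexes = []
        ok = True
        for pmz in products:
            x = extract_xic(run, float(pmz), config.product_match_ppm)
            peaks = detect_peaks(x, config.min_peak_height / 10.0, config.min_peak_points)
            near = [p for p in peaks if abs(p.apex_rt - obs.apex_rt) <= config.co_elution_tol_min]
            if not near:
                ok = False
                break
            apexes.append(max(near, key=lambda p: p.height).apex_rt)
        if not ok:
            continue
        apex = float(np.mean(apexes))
        half_fwhm = obs.fwhm / 2.0
        local = [s for s in run.spectra
                 if s.ms_level == 1 and apex - half_fwhm <= s.rt <= apex + half_fwhm]
        snr = compute_snr(local, ts, excl, config)
        area = snr.signal_mean * len(products)
        out.append(IsomerCandidate(fa, apex, snr, "DIA", tuple(products), area, obs))
    return out


# ---------------------------------------------------------------------------
# tiering and deduplication
# ---------------------------------------------------------------------------

def _tier(snr: float, config: PipelineConfig) -> str:
    if snr >= config.snr_confident:
        return "confident"
    if snr >= config.snr_tentative:
        return "tentative"
    return "rejected"


def _share_products(a: IsomerCandidate, b: IsomerCandidate, ppm: float) -> bool:
    for pa in a.product_mz:
        for pb in b.product_mz:
            if abs(pa - pb) <= pa * ppm * 1e-6:
                return True
    return False


def classify_and_dedupe(candidates: Sequence[IsomerCandidate],
                        config: PipelineConfig) -> tuple:
    """Assign confidence tiers and remove duplicate assignments.

    Tiers: S/N in [0, 3) rejected, [3, 10) tentative (excluded from
    quantification), [10, inf) confident. Among candidates of the same sum
    composition whose apexes co-elute and whose product sets overlap -- i.e.
    several transition patterns assigning one chromatographic feature -- only
    the highest-S/N candidate survives. Returns (curated, all_candidates);
    the full pre-dedupe list backs the manual-override export.
    """
    for c in candidates:
        c.tier = _tier(c.snr.snr, config)
    # duplicates assign one feature, so they share its noise; the integrated
    # product signal is the noise-robust statistic for ranking them
    ordered = sorted(candidates, key=lambda c: (-c.product_area, c.positions))
    curated = []
    for cand in ordered:
        if cand.tier == "rejected":
            continue
        duplicate = False
        for kept in curated:
            if (kept.sum_composition == cand.sum_composition
                    and abs(kept.apex_rt - cand.apex_rt) <= config.duplicate_apex_tol_min
                    and _share_products(kept, cand, config.product_match_ppm)):
                duplicate = True
                break
        if duplicate:
            cand.flags.append("duplicate")
            continue
        curated.append(cand)
    # pre-screen: flag putative over-oxidation artifacts (final call in annotate)
    for cand in curated:
        parent_pos = tuple(p - 1 for p in cand.positions)
        for other in curated:
            if (other is not cand
                    and other.sum_composition == cand.sum_composition
                    and other.positions == parent_pos
                    and abs(other.apex_rt - cand.apex_rt) <= config.co_elution_tol_min
                    and other.product_area > 0):
                ratio = cand.product_area / other.product_area
                if ratio <= config.overox_rate_trans * config.overox_guard:
                    cand.flags.append("putative_overoxidation")
                    break
    curated.sort(key=lambda c: (c.sum_composition, c.apex_rt, c.positions))
    return curated, list(candidates)


def refine_apexes(dda_run: LcmsRun, dia_run: LcmsRun,
                  candidates: Sequence[IsomerCandidate],
                  agent: DerivatizationAgent, config: PipelineConfig) -> None:
    """Re-center candidate retention times on densely sampled DIA traces.

    Apexes estimated from the segmented DDA traces carry the sampling error
    of a few points per peak. Because every product ion co-elutes exactly
    with its precursor feature, and the DIA run records the same product
    m/z at full scan cadence, each candidate's apex is re-located as the
    median over its products of the nearest DIA-trace peak (within the
    co-elution tolerance). S/N and product area are then recomputed from
    the DDA spectra at the corrected apex.
    """
    fwhm_med = float(np.median([c.observation.fwhm for c in candidates])) if candidates else 0.06
    trace_cache: dict = {}

    def dia_peaks(pmz: float) -> np.ndarray:
        key = round(pmz, 5)
        if key not in trace_cache:
            x = extract_xic(dia_run, float(pmz), config.product_match_ppm)
            if x.intensity.size == 0 or x.intensity.max() <= 0:
                trace_cache[key] = np.empty(0)
            else:
                peaks = detect_peaks(
                    x, max(config.product_presence_min,
                           float(np.max(x.intensity)) * config.relative_peak_floor),
                    config.min_peak_points)
                trace_cache[key] = np.array([p.apex_rt for p in peaks])
        return trace_cache[key]

    for cand in candidates:
        located = []
        for pmz in cand.product_mz:
            pa = dia_peaks(pmz)
            if pa.size:
                j = int(np.argmin(np.abs(pa - cand.apex_rt)))
                if abs(pa[j] - cand.apex_rt) <= config.co_elution_tol_min:
                    located.append(float(pa[j]))
        if located:
            cand.apex_rt = float(np.median(located))
    # rescore every candidate at its (possibly corrected) apex with one
    # uniform spectrum window, so product-area ratios compare like with like
    if dda_run.mode != "DDA":
        return
    excl_cache: dict = {}
    half = fwhm_med / 2.0
    for cand in candidates:
        local = [
            s for s in dda_run.spectra
            if s.ms_level == 2 and s.isolation_target is not None
            and abs(s.isolation_target - cand.observation.theoretical_mz) <= 0.02
            and cand.apex_rt - half <= s.rt <= cand.apex_rt + half
        ]
        if not local:
            continue
        comp = cand.sum_composition
        if comp not in excl_cache:
            excl_cache[comp] = np.concatenate([
                precursor_envelope_mz(comp[0], comp[1], agent),
                possible_product_mz(comp[0], comp[1], agent, config.min_db_position),
            ])
        ts = chem.ozid_transitions(cand.species, agent)
        snr = compute_snr(local, ts, excl_cache[comp], config)
        cand.snr = snr
        cand.product_area = snr.signal_mean * len(cand.product_mz)


def export_candidates(candidates: Sequence[IsomerCandidate], path) -> None:
    """Delimited candidate report for external review/override."""
    with open(path, "w") as fh:
        fh.write("shorthand\tapex_rt_min\tsnr\tsignal_mean\tnoise_mean\t"
                 "n_signal_peaks\tn_noise_peaks\ttier\tevidence\tflags\n")
        for c in candidates:
            fh.write(
                f"{shorthand_name(c.species)}\t{c.apex_rt:.4f}\t{c.snr.snr:.4g}\t"
                f"{c.snr.signal_mean:.4g}\t{c.snr.noise_mean:.4g}\t"
                f"{c.snr.n_signal_peaks}\t{c.snr.n_noise_peaks}\t{c.tier}\t"
                f"{c.evidence_mode}\t{';'.join(c.flags)}\n"
            )
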