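"""Relative isomer quantification and absolute sum-composition quantification.

Relative quantification deconvolves the precursor extracted-ion chromatogram
into Gaussians with centers fixed at the OzID-derived isomer retention
times; working on the precursor signal minimizes bias from
position-dependent ozonolysis efficiency. Components that cannot be
resolved at the precursor level (a trace isomer buried under a much larger
co-eluting one) fall back to a product-ion estimate flagged as an upper
limit.

Absolute quantification uses the loop-injection (direct infusion) run:
average over the injection-peak FWHM, subtract a numerical baseline,
recalibrate m/z on the palmitic/stearic anchors, correct isotopic overlap
(including the 2-Da overlap of species differing by one double bond), scale
to the perdeuterated palmitic acid internal standard, and apply the
process-blank rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from . import chem
from .chem import DerivatizationAgent, FattyAcidSpecies
from .config import PipelineConfig
from .lcms import Chromatogram, LcmsRun, Spectrum, average_spectra_over_fwhm
from .nomenclature import shorthand_name

__all__ = [
    "DeconvolutionComponent",
    "DeconvolutionProblem",
    "DeconvolutionResult",
    "deconvolve_isomers",
    "baseline_subtract",
    "recalibrate_mz",
    "isotope_correct",
    "infusion_quant",
    "apply_blank_rules",
    "combine_absolute",
]


# ---------------------------------------------------------------------------
# relative quantification: Gaussian deconvolution with fixed centers
# ---------------------------------------------------------------------------

@dataclass
class DeconvolutionComponent:
    isomer_id: str
    center_rt: float  # fixed; from the OzID product-ion apex
    product_area: float = 0.0  # summed OzID product peak area (fallback route)


@dataclass
class DeconvolutionProblem:
    xic: Chromatogram
    components: list
    sigma: float  # shared peak width (minutes)


@dataclass
class DeconvolutionResult:
    fractions: dict
    amplitudes: dict
    sigma: float
    residual_norm: float
    flags: dict

    def to_table(self, path) -> None:
        """Editable worksheet mirroring the manual-correction step."""
        with open(path, "w") as fh:
            fh.write("isomer\tcenter_rt\tsigma\tamplitude\tfraction\tflag\n")
            for iso in self.fractions:
                fh.write(
                    f"{iso}\t\t{self.sigma:.5f}\t{self.amplitudes[iso]:.6g}\t"
                    f"{self.fractions[iso]:.6g}\t{self.flags.get(iso, '')}\n"
                )


def deconvolve_isomers(problem: DeconvolutionProblem,
                       degenerate_ratio: float = 20.0,
                       degenerate_sep_sigma: float = 0.5) -> DeconvolutionResult:
    """Non-negative least squares over Gaussian amplitudes with fixed centers.

    A component is non-identifiable when its center lies within
    ``degenerate_sep_sigma`` peak widths of a component at least
    ``degenerate_ratio`` times larger (or exactly coincides with a larger
    one); such components switch to the product-ion fallback: their fraction
    is the ratio of summed OzID product areas to the dominant co-eluting
    component's, scaled by that component's fraction, and is flagged as an
    upper limit (it assumes equal ozonolysis efficiency across positions).
    """
    comps = problem.components
    if not comps:
        raise ValueError("deconvolution needs at least one component")
    t = problem.xic.rt
    y = problem.xic.intensity
    sigma = problem.sigma
    for c in comps:
        if not (t[0] - 3 * sigma <= c.center_rt <= t[-1] + 3 * sigma):
            raise ValueError(f"component {c.isomer_id} center outside the chromatogram")
    design = np.column_stack(
        [np.exp(-0.5 * ((t - c.center_rt) / sigma) ** 2) for c in comps]
    )
    amps, rnorm = nnls(design, y)
    if not np.all(np.isfinite(amps)):
        raise RuntimeError(f"deconvolution failed to converge (residual {rnorm:.3g})")
    flags = {}
    areas = {c.isomer_id: a * sigma * math.sqrt(2 * math.pi) for c, a in zip(comps, amps)}
    # detect non-identifiable minors and re-estimate from product ions
    for i, ci in enumerate(comps):
        for j, cj in enumerate(comps):
            if i == j:
                continue
            sep = abs(ci.center_rt - cj.center_rt)
            if sep > degenerate_sep_sigma * sigma:
                continue
            bigger = amps[j] >= degenerate_ratio * amps[i] or (
                sep <= 0.05 * sigma and ci.product_area < cj.product_area
            )
            if bigger and cj.product_area > 0:
                # whatever the degenerate fit put on the minor column belongs
                # to the dominant feature; return it before re-estimating
                areas[cj.isomer_id] += areas[ci.isomer_id]
                ratio = ci.product_area / cj.product_area
                areas[ci.isomer_id] = ratio * areas[cj.isomer_id]
                flags[ci.isomer_id] = "upper_limit"
                break
    total = sum(areas.values())
    if total <= 0:
        raise RuntimeError("deconvolution found no signal for any component")
    fractions = {k: v / total for k, v in areas.items()}
    amplitudes = {c.isomer_id: float(a) for c, a in zip(comps, amps)}
    return DeconvolutionResult(fractions, amplitudes, sigma, float(rnorm), flags)


# ---------------------------------------------------------------------------
# direct-infusion processing
# ---------------------------------------------------------------------------

def baseline_subtract(spectrum: Spectrum, window_da: float = 5.0,
                      percentile: float = 10.0, min_window_points: int = 10) -> Spectrum:
    """Subtract a numerically estimated baseline; clamp negatives to zero.

    The baseline under each centroid is the ``percentile``-th percentile of
    centroid intensities within a +/- ``window_da``/2 neighbourhood. Windows
    holding fewer than ``min_window_points`` centroids carry no baseline: in
    sparse centroid data a low percentile over a handful of isotope sticks
    is signal, not background.
    """
    mz, inten = spectrum.mz, spectrum.intensity
    if mz.size == 0:
        return spectrum
    baseline = np.zeros_like(inten)
    half = window_da / 2.0
    lo = np.searchsorted(mz, mz - half, side="left")
    hi = np.searchsorted(mz, mz + half, side="right")
    for i in range(mz.size):
        if hi[i] - lo[i] >= min_window_points:
            baseline[i] = np.percentile(inten[lo[i]:hi[i]], percentile)
    corrected = np.maximum(inten - baseline, 0.0)
    return Spectrum(rt=spectrum.rt, ms_level=spectrum.ms_level, mz=mz.copy(),
                    intensity=corrected, isolation_target=spectrum.isolation_target)


def recalibrate_mz(spectrum: Spectrum, agent: DerivatizationAgent,
                   search_da: float = 0.03, min_height: float = 0.0) -> tuple:
    """Shift the m/z axis by the mean deviation of the 16:0/18:0 anchor peaks.

    Returns ``(spectrum, shift_da, ok)``; when either anchor is missing the
    spectrum is returned unshifted with ``ok=False``. The anchors are assumed
    to dominate their search windows, which holds whenever palmitic and
    stearic acid are present (they are the main components of any process
    blank).
    """
    deviations = []
    for carbons in (16, 18):
        theo = chem.precursor_mz(FattyAcidSpecies(carbons), agent)
        sel = (spectrum.mz >= theo - search_da) & (spectrum.mz <= theo + search_da)
        if not np.any(sel) or spectrum.intensity[sel].max() <= min_height:
            return spectrum, 0.0, False
        apex = spectrum.mz[sel][np.argmax(spectrum.intensity[sel])]
        deviations.append(apex - theo)
    shift = float(np.mean(deviations))
    out = Spectrum(rt=spectrum.rt, ms_level=spectrum.ms_level,
                   mz=spectrum.mz - shift, intensity=spectrum.intensity.copy(),
                   isolation_target=spectrum.isolation_target)
    return out, shift, True


def _cluster_intensity(spectrum: Spectrum, mz: float, tol_ppm: float) -> float:
    tol = mz * tol_ppm * 1e-6
    sel = (spectrum.mz >= mz - tol) & (spectrum.mz <= mz + tol)
    return float(spectrum.intensity[sel].sum())


def _composition_of(entry, agent: DerivatizationAgent) -> dict:
    from pyteomics import mass as _pm

    if isinstance(entry, FattyAcidSpecies):
        return chem.precursor_composition(entry, agent)
    carbons, d = entry  # mass depends only on the sum composition
    total = (_pm.Composition({"C": carbons, "H": 2 * carbons - 2 * d, "O": 2})
             + _pm.Composition(agent.cation_composition) - _pm.Composition(formula="H2O"))
    return dict(total)


def isotope_correct(spectrum: Spectrum, species: list, agent: DerivatizationAgent,
                    tol_ppm: float = 20.0, n_peaks: int = 5,
                    overlap_tol_da: float = 0.02) -> pd.DataFrame:
    """Isotope-corrected, envelope-total abundances per species.

    ``species`` may mix ``FattyAcidSpecies`` (e.g. the deuterated internal
    standard) and ``(carbons, n_double_bonds)`` sum compositions. Within
    each carbon count, species are processed from most to least unsaturated:
    each is assigned its monoisotopic cluster intensity minus the
    isotopologue contributions of already-processed species whose M+2k peaks
    land on it (DHA's M+2 on DPA's monoisotope and so on). Negative
    residuals clamp to zero with a flag. The reported abundance is the
    envelope-total equivalent (monoisotopic intensity times the pattern
    sum), which removes the chain-length dependence of the monoisotopic
    fraction.
    """

    def key(entry):
        if isinstance(entry, FattyAcidSpecies):
            return (entry.carbons + 0.5 * entry.deuterium_count, entry.n_double_bonds)
        return (float(entry[0]), entry[1])

    records = []
    corrections: list = []  # (mz, amount to subtract)
    for entry in sorted(species, key=lambda e: (key(e)[0], -key(e)[1])):
        comp = _composition_of(entry, agent)
        mono = chem.monoisotopic_mass(comp) - chem.ELECTRON_MASS
        pattern = chem.isotope_pattern(comp, n_peaks)
        raw = _cluster_intensity(spectrum, mono, tol_ppm)
        overlap = sum(a for mzc, a in corrections if abs(mzc - mono) <= overlap_tol_da)
        assigned = raw - overlap
        clamped = assigned < 0
        assigned = max(assigned, 0.0)
        for off, ab in pattern[1:]:
            corrections.append((mono + off, ab * assigned))
        pattern_sum = sum(ab for _, ab in pattern)
        name = (
            shorthand_name(entry) if isinstance(entry, FattyAcidSpecies)
            else f"FA {entry[0]}:{entry[1]}"
        )
        records.append({
            "species": name,
            "carbons": entry.carbons if isinstance(entry, FattyAcidSpecies) else entry[0],
            "n_double_bonds": (entry.n_double_bonds if isinstance(entry, FattyAcidSpecies)
                               else entry[1]),
            "monoisotopic_mz": mono,
            "raw_intensity": raw,
            "corrected_monoisotopic": assigned,
            "corrected_abundance": assigned * pattern_sum,
            "clamped": clamped,
        })
    return pd.DataFrame.from_records(records)


def apply_blank_rules(sample_amount: float, blank_amount: float,
                      config: PipelineConfig | None = None) -> tuple:
    """Process-blank handling per species.

    ratio r = blank/sample: r > 0.75 excludes the species; 0.01 <= r <= 0.75
    subtracts the blank amount; r < 0.01 keeps the amount unmodified.
    Returns ``(action, corrected_amount)``.
    """
    cfg = config or PipelineConfig()
    if sample_amount <= 0:
        return ("exclude", 0.0)
    r = blank_amount / sample_amount
    if r > cfg.blank_exclude_above:
        return ("exclude", 0.0)
    if r >= cfg.blank_keep_below:
        return ("subtract", sample_amount - blank_amount)
    return ("keep", sample_amount)


def infusion_quant(
    infusion_runs,
    blank_run: LcmsRun | None,
    agent: DerivatizationAgent,
    istd_species: FattyAcidSpecies,
    istd_concentration: float,
    compositions: list,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Absolute sum-composition concentrations from loop-injection runs.

    Each run is averaged over its TIC-peak FWHM, baseline-subtracted,
    recalibrated and isotope-corrected; concentrations are scaled to the
    internal standard, blank-corrected per the process-blank rules, and
    replicates aggregated to mean, SD and COV.
    """
    cfg = config or PipelineConfig()
    if isinstance(infusion_runs, LcmsRun):
        infusion_runs = [infusion_runs]
    scope = list(compositions) + [istd_species]

    def process(run: LcmsRun) -> pd.DataFrame:
        spec = average_spectra_over_fwhm(run)
        spec = baseline_subtract(spec)
        spec, _, _ = recalibrate_mz(spec, agent)
        return isotope_correct(spec, scope, agent, tol_ppm=cfg.noise_proximity_ppm)

    istd_name = shorthand_name(istd_species)
    blank_conc = {}
    if blank_run is not None:
        tab = process(blank_run)
        istd_row = tab[tab.species == istd_name]
        if istd_row.empty or istd_row.corrected_abundance.iloc[0] <= 0:
            raise RuntimeError("internal standard not detected in the blank run")
        scale = istd_concentration / istd_row.corrected_abundance.iloc[0]
        for _, row in tab.iterrows():
            if row.species != istd_name:
                blank_conc[row.species] = row.corrected_abundance * scale

    per_run = []
    for run in infusion_runs:
        tab = process(run)
        istd_row = tab[tab.species == istd_name]
        if istd_row.empty or istd_row.corrected_abundance.iloc[0] <= 0:
            raise RuntimeError("internal standard not detected in the infusion run")
        scale = istd_concentration / istd_row.corrected_abundance.iloc[0]
        conc = {}
        action = {}
        for _, row in tab.iterrows():
            if row.species == istd_name:
                continue
            c = row.corrected_abundance * scale
            act, corrected = apply_blank_rules(c, blank_conc.get(row.species, 0.0), cfg)
            conc[row.species] = corrected if act != "exclude" else math.nan
            action[row.species] = act
        per_run.append((conc, action))

    names = sorted({n for conc, _ in per_run for n in conc})
    records = []
    for name in names:
        values = np.array([conc.get(name, math.nan) for conc, _ in per_run])
        acts = {a.get(name, "keep") for _, a in per_run}
        mean = float(np.nanmean(values)) if not np.all(np.isnan(values)) else math.nan
        sd = float(np.nanstd(values, ddof=1)) if np.sum(~np.isnan(values)) > 1 else 0.0
        records.append({
            "species": name,
            "concentration": mean,
            "sd": sd,
            "cov": sd / mean if mean and not math.isnan(mean) else math.nan,
            "n_replicates": int(np.sum(~np.isnan(values))),
            "blank_action": "exclude" if acts == {"exclude"} else ";".join(sorted(acts)),
        })
    return pd.DataFrame.from_records(records)


def combine_absolute(fractions: dict, sumcomp_quant: pd.DataFrame,
                     fraction_flags: dict | None = None) -> pd.DataFrame:
    """Per-isomer concentrations: fraction x sum-composition concentration.

    ``fractions`` maps ``(carbons, n_double_bonds)`` to ``{isomer: fraction}``
    dictionaries (fractions within a composition sum to one).
    """
    flags = fraction_flags or {}
    lookup = {row.species: row for row in sumcomp_quant.itertuples()}
    records = []
    for (carbons, d), isomers in sorted(fractions.items()):
        row = lookup.get(f"FA {carbons}:{d}")
        for isomer, frac in isomers.items():
            conc = row.concentration * frac if row is not None else math.nan
            sd = row.sd * frac if row is not None else math.nan
            records.append({
                "species": isomer,
                "carbons": carbons,
                "n_double_bonds": d,
                "fraction": frac,
                "concentration": conc,
                "sd": sd,
                "cov": (sd / conc) if conc else math.nan,
                "flags": flags.get(isomer, ""),
            })
    return pd.DataFrame.from_records(records)
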