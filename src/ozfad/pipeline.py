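"""End-to-end orchestration of the discovery/quantification workflow.

Stages mirror the acquisition logic: the DIA run yields precursor
observations and a DDA inclusion list; the DDA run yields isomer candidates
scored by product-ion S/N; annotation assigns configuration and branch
class and removes over-oxidation artifacts; quantification deconvolves the
DIA precursor chromatograms into isomer fractions and scales them to the
direct-infusion sum-composition concentrations. Each stage reports the
count of instances it carried forward, reproducing the funnel from
hundreds of thousands of putative assignments down to the curated list.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate as _annotate
from . import chem, discovery, quantify
from .chem import DerivatizationAgent
from .config import PipelineConfig
from .lcms import GAUSS_FWHM, LcmsRun, extract_xic
from .nomenclature import shorthand_name

__all__ = ["PipelineResult", "discover", "annotate_candidates", "quantify_isomers",
           "run_simulated_pipeline"]


@dataclass
class PipelineResult:
    anchors: tuple
    observations: list
    targets: object
    curated: list
    all_candidates: list
    records: list  # DeclRecords of retained candidates
    excluded: list
    fractions: dict
    fraction_flags: dict
    sumcomp_quant: pd.DataFrame | None
    report: pd.DataFrame
    counts: dict

    def write(self, out_dir: str, config: PipelineConfig) -> None:
        os.makedirs(out_dir, exist_ok=True)
        stamp = f"# config_hash={config.config_hash} seed={config.rng_seed}\n"
        self.targets.export(os.path.join(out_dir, "target_list.tsv"), config)
        discovery.export_candidates(
            self.all_candidates, os.path.join(out_dir, "candidates_all.tsv"))
        discovery.export_candidates(
            self.curated, os.path.join(out_dir, "candidates_curated.tsv"))
        for name, df in (("report.tsv", self.report),
                         ("sumcomp_quant.tsv", self.sumcomp_quant)):
            if df is not None:
                path = os.path.join(out_dir, name)
                with open(path, "w") as fh:
                    fh.write(stamp)
                    df.to_csv(fh, sep="\t", index=False)
        with open(os.path.join(out_dir, "counts.tsv"), "w") as fh:
            fh.write(stamp + "stage\tcount\n")
            for k, v in self.counts.items():
                fh.write(f"{k}\t{v}\n")


def discover(dia_run: LcmsRun, agent: DerivatizationAgent, config: PipelineConfig):
    """DIA precursor analysis and target-list construction."""
    anchors = discovery.find_anchor_rts(dia_run, agent, config)
    observations = discovery.find_precursors(dia_run, agent, config, anchors)
    targets = discovery.build_target_list(observations, config)
    return anchors, observations, targets


def annotate_candidates(curated, anchors, config: PipelineConfig):
    """dECL computation, configuration/branch assignment, artifact exclusion."""
    anchor_map = {16: anchors[0], 18: anchors[1]}
    records = _annotate.make_decl_records(curated, anchor_map, config)
    _annotate.flag_branched(records, config)
    _annotate.assign_configuration(records, config)
    retained, excluded = _annotate.overoxidation_filter(curated, config)
    retained_ids = {id(c) for c in retained}
    records = [r for r in records if id(r.candidate) in retained_ids]
    return records, retained, excluded


def quantify_isomers(dia_run: LcmsRun, records, agent: DerivatizationAgent,
                     config: PipelineConfig):
    """Relative isomer fractions by precursor-XIC deconvolution per composition."""
    groups: dict = {}
    for r in records:
        if r.candidate.tier != "confident":
            continue  # tentative identifications are not quantified
        groups.setdefault(r.candidate.sum_composition, []).append(r)
    fractions, flags = {}, {}
    # a single shared peak width, robust against occasional blended fits
    all_fwhm = [r.candidate.observation.fwhm for rs in groups.values() for r in rs]
    sigma = float(np.median(all_fwhm)) / GAUSS_FWHM if all_fwhm else 0.025
    for (carbons, d), recs in sorted(groups.items()):
        mz = recs[0].candidate.observation.theoretical_mz
        xic = extract_xic(dia_run, mz, config.precursor_xic_ppm)
        comps = [
            quantify.DeconvolutionComponent(
                shorthand_name(r.candidate.species), r.candidate.apex_rt,
                r.candidate.product_area)
            for r in recs
        ]
        problem = quantify.DeconvolutionProblem(xic, comps, sigma)
        result = quantify.deconvolve_isomers(problem)
        fractions[(carbons, d)] = result.fractions
        for iso, flag in result.flags.items():
            flags[iso] = flag
    return fractions, flags


def run_simulated_pipeline(mixture, instrument, agent: DerivatizationAgent,
                           config: PipelineConfig, seed: int | None = None,
                           out_dir: str | None = None,
                           contaminants=None) -> PipelineResult:
    """Simulate a full study (DIA + DDA + infusion + blank) and analyse it."""
    from . import simulate as sim

    seed = config.rng_seed if seed is None else seed
    counts = {}
    dia = sim.simulate_dia(mixture, instrument, agent, seed=seed)
    anchors, observations, targets = discover(dia, agent, config)
    counts["precursor_observations"] = len(observations)
    counts["target_slots"] = len(targets)
    dda = sim.simulate_dda(mixture, instrument, agent, targets, seed=seed)
    counts["patterns_searched"] = sum(
        chem.count_double_bond_patterns(o.carbons, o.n_double_bonds,
                                        config.min_db_position)
        for o in observations
    )
    candidates = discovery.search_double_bonds(
        dda, observations, agent, config)
    counts["raw_candidates"] = len(candidates)
    discovery.refine_apexes(dda, dia, candidates, agent, config)
    curated, all_candidates = discovery.classify_and_dedupe(candidates, config)
    counts["curated_candidates"] = len(curated)
    counts["confident_candidates"] = sum(c.tier == "confident" for c in curated)
    records, retained, excluded = annotate_candidates(curated, anchors, config)
    counts["overoxidation_excluded"] = len(excluded)
    counts["annotated"] = len(records)
    fractions, flags = quantify_isomers(dia, records, agent, config)

    infusion = sim.simulate_infusion(mixture, instrument, agent, seed=seed)
    blank = sim.make_blank(instrument, agent, contaminants, seed=seed)
    compositions = sorted({r.candidate.sum_composition for r in records})
    for e in mixture.entries:  # saturated species are quantified too
        if e.species.n_double_bonds == 0:
            compositions.append(e.species.sum_composition)
    compositions = sorted(set(compositions))
    istd, istd_conc = mixture.internal_standard
    sumcomp = quantify.infusion_quant(
        infusion, blank["infusion"], agent, istd, istd_conc, compositions, config)
    combined = quantify.combine_absolute(fractions, sumcomp, flags)
    report = _annotate.generate_report(records, combined)
    counts["reported"] = len(report)
    result = PipelineResult(
        anchors=anchors, observations=observations, targets=targets,
        curated=curated, all_candidates=all_candidates, records=records,
        excluded=excluded, fractions=fractions, fraction_flags=flags,
        sumcomp_quant=sumcomp, report=report, counts=counts,
    )
    if out_dir is not None:
        result.write(out_dir, config)
    return result
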