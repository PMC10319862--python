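"""Retention-index annotation and final curation.

The equivalent chain length (ECL) expresses a retention time in saturated
straight-chain carbon units by interpolating between saturated anchors;
dECL = ECL - carbons removes the chain-length trend so isomer retention
behaviour is comparable across chain lengths. Within the dECL coordinate,
cis monounsaturates elute before their trans counterparts, and branched
chains elute before straight chains of the same carbon count -- the basis
for configuration assignment and branch flagging. Over-oxidation artifacts
(apparent double bond one carbon closer to the carboxyl terminus,
co-eluting with the genuine isomer at up to 1.5% for cis / 3% for trans
parents) are excluded here, with a retention-time shift rescuing genuine
low-abundance isomers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .chem import DoubleBond, FattyAcidSpecies
from .config import PipelineConfig
from .discovery import IsomerCandidate
from .nomenclature import shorthand_name, systematic_name

__all__ = [
    "compute_ecl",
    "compute_decl",
    "DeclRecord",
    "assign_configuration",
    "flag_branched",
    "overoxidation_filter",
    "classify_db_spacing",
    "generate_report",
]


def compute_ecl(rt: float, anchor_rts: dict, log_interpolation: bool = False) -> tuple:
    """ECL by piecewise-linear interpolation between saturated anchors.

    Returns ``(ecl, extrapolated)``. ``anchor_rts`` maps carbon number to
    the saturated standard's retention time; at least two anchors are
    required. Outside the anchor span the nearest segment is extrapolated
    and flagged. ``log_interpolation`` switches to the classical GC-style
    interpolation in log retention time.
    """
    if len(anchor_rts) < 2:
        raise ValueError("ECL computation needs at least two saturated anchors")
    carbons = sorted(anchor_rts)
    rts = np.array([anchor_rts[c] for c in carbons], dtype=float)
    f = np.log if log_interpolation else (lambda x: x)
    val = f(rt)
    grid = f(rts)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("anchor retention times must increase with chain length")
    extrapolated = not (grid[0] <= val <= grid[-1])
    i = int(np.clip(np.searchsorted(grid, val) - 1, 0, len(carbons) - 2))
    c_lo, c_hi = carbons[i], carbons[i + 1]
    ecl = c_lo + (val - grid[i]) / (grid[i + 1] - grid[i]) * (c_hi - c_lo)
    return float(ecl), bool(extrapolated)


def compute_decl(ecl: float, carbons: int) -> float:
    return ecl - carbons


@dataclass
class DeclRecord:
    candidate: IsomerCandidate
    ecl: float
    decl: float
    extrapolated: bool


def make_decl_records(candidates, anchor_rts: dict,
                      config: PipelineConfig | None = None) -> list:
    cfg = config or PipelineConfig()
    out = []
    for cand in candidates:
        ecl, extrap = compute_ecl(cand.apex_rt, anchor_rts, cfg.ecl_log_interpolation)
        out.append(DeclRecord(cand, ecl, compute_decl(ecl, cand.species.carbons), extrap))
    return out


# ---------------------------------------------------------------------------
# configuration and branch assignment from elution behaviour
# ---------------------------------------------------------------------------

def flag_branched(records, config: PipelineConfig | None = None,
                  max_iter: int = 5) -> None:
    """Flag early-eluting monounsaturated features as branched chains.

    A straight-chain dECL trend (linear in double-bond position) is fitted
    iteratively to all monounsaturated features; features falling below the
    trend by more than the configured offset are classed branched and
    removed from the next fit. Duplicate (carbons, position) features left
    over once the cis/trans slots are filled are also classed branched.
    """
    cfg = config or PipelineConfig()
    mono = [r for r in records if r.candidate.species.n_double_bonds == 1]
    if not mono:
        return
    x = np.array([r.candidate.species.positions[0] for r in mono], dtype=float)
    y = np.array([r.decl for r in mono])
    branched = np.zeros(len(mono), dtype=bool)
    for _ in range(max_iter):
        keep = ~branched
        if keep.sum() < 2:
            break
        coeffs = np.polyfit(x[keep], y[keep], 1)
        resid = y - np.polyval(coeffs, x)
        new = resid < -cfg.decl_branch_offset
        if np.array_equal(new, branched):
            break
        branched = new
    for r, b in zip(mono, branched):
        cls = "branched" if b else "straight"
        r.candidate.species = replace(r.candidate.species, branch_class=cls)
        if b:
            r.candidate.flags.append("branched")


def assign_configuration(records, config: PipelineConfig | None = None) -> None:
    """Assign cis/trans to monounsaturates from elution order and dECL trends.

    Within a (carbons, position) group holding two straight-chain features
    the earlier is cis and the later trans. Singletons are assigned from the
    dECL trend of already-assigned features at the same methyl-referenced
    position across chain lengths (linear fit in carbons, agreement within
    the configured tolerance), else left unknown. Polyunsaturates default
    to cis as a tentative assignment.
    """
    cfg = config or PipelineConfig()
    for r in records:
        if r.candidate.species.n_double_bonds > 1:
            r.candidate.species = r.candidate.species.with_configuration("cis")
            r.candidate.flags.append("configuration_tentative")
    mono = [r for r in records
            if r.candidate.species.n_double_bonds == 1
            and r.candidate.species.branch_class != "branched"]
    groups: dict = {}
    for r in mono:
        groups.setdefault(
            (r.candidate.species.carbons, r.candidate.species.positions[0]), []
        ).append(r)
    assigned: dict = {"cis": [], "trans": []}  # (position, carbons, decl)
    singletons = []
    for (carbons, pos), group in sorted(groups.items()):
        group.sort(key=lambda r: r.candidate.apex_rt)
        if len(group) >= 2:
            pair = sorted(group, key=lambda r: r.decl)[:2] if len(group) > 2 else group
            early, late = sorted(pair, key=lambda r: r.candidate.apex_rt)
            _set_conf(early, "cis")
            _set_conf(late, "trans")
            assigned["cis"].append((pos, carbons, early.decl))
            assigned["trans"].append((pos, carbons, late.decl))
            for extra in group:
                if extra not in (early, late):
                    singletons.append(extra)
        else:
            singletons.append(group[0])
    for r in singletons:
        pos = r.candidate.species.positions[0]
        best, best_dev = None, math.inf
        for conf, entries in assigned.items():
            same_pos = [(c, d) for p, c, d in entries if p == pos]
            if not same_pos:
                continue
            if len(same_pos) >= 2:
                cs = np.array([c for c, _ in same_pos], dtype=float)
                ds = np.array([d for _, d in same_pos])
                if np.ptp(cs) > 0:
                    coeffs = np.polyfit(cs, ds, 1)
                    pred = float(np.polyval(coeffs, r.candidate.species.carbons))
                else:
                    pred = float(ds.mean())
            else:
                pred = same_pos[0][1]
            dev = abs(r.decl - pred)
            if dev < best_dev:
                best, best_dev = conf, dev
        if best is not None and best_dev <= cfg.decl_config_tol:
            _set_conf(r, best)
        # else: configuration remains unknown -- a valid outcome


def _set_conf(record, configuration: str) -> None:
    record.candidate.species = record.candidate.species.with_configuration(configuration)


# ---------------------------------------------------------------------------
# over-oxidation exclusion
# ---------------------------------------------------------------------------

def overoxidation_filter(candidates, config: PipelineConfig | None = None) -> tuple:
    """Exclude co-eluting over-oxidation artifacts; rescue shifted features.

    A candidate whose positions all sit one carbon closer to the carboxyl
    terminus (n-(x+1)) than a co-eluting candidate of the same sum
    composition is excluded when its product-area ratio to that parent is
    at or below the parent-configuration cap (1.5% cis / 3% trans, with a
    guard factor plus a counting-statistics allowance, since the caps are
    stated maxima and a trace artifact's area carries shot noise). An apex
    shift beyond the co-elution tolerance rescues the candidate. Returns
    ``(retained, excluded)``.
    """
    cfg = config or PipelineConfig()
    retained, excluded = [], []
    for cand in candidates:
        parent_pos = tuple(p - 1 for p in cand.species.positions)
        artifact = False
        for other in candidates:
            if other is cand or other.sum_composition != cand.sum_composition:
                continue
            if other.species.positions != parent_pos:
                continue
            if abs(other.apex_rt - cand.apex_rt) > cfg.co_elution_tol_min:
                continue  # retention shift: not the artifact of this parent
            if other.product_area <= 0:
                continue
            confs = {b.configuration for b in other.species.double_bonds}
            cap = cfg.overox_rate_trans if confs == {"trans"} else cfg.overox_rate_cis
            ratio = cand.product_area / other.product_area
            shot = 2.0 * math.sqrt(max(cand.product_area, 1.0)) / other.product_area
            if ratio <= cap * cfg.overox_guard + shot:
                artifact = True
                break
        if artifact:
            cand.flags.append("overoxidation_excluded")
            excluded.append(cand)
        else:
            retained.append(cand)
    return retained, excluded


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def classify_db_spacing(fa: FattyAcidSpecies) -> str:
    """Methylene-interrupted / conjugated / butylene-interrupted (NMI) class."""
    pos = fa.positions
    if len(pos) < 2:
        return ""
    spacings = {b - a for a, b in zip(pos, pos[1:])}
    if spacings == {3}:
        return "methylene-interrupted"
    if spacings == {2}:
        return "conjugated"
    if 6 in spacings:
        return "NMI-butylene-interrupted"
    return "NMI-other"


def _load_id_table() -> dict:
    table = {}
    path = resources.files("ozfad.data") / "lipid_ids.tsv"
    with open(path) as fh:
        fh.readline()
        for line in fh:
            name, db_id, common = line.rstrip("\n").split("\t")
            table[name] = (db_id, common)
    return table


def generate_report(records, quant_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Final per-isomer report with names, offline database IDs and flags."""
    ids = _load_id_table()
    rows = []
    for r in records:
        fa = r.candidate.species
        try:
            sysname = systematic_name(fa)
        except Exception:
            sysname = ""
        db_id, common = ids.get(sysname, ("", ""))
        rows.append({
            "shorthand": shorthand_name(fa),
            "systematic_name": sysname,
            "common_name": common,
            "database_id": db_id,
            "apex_rt": r.candidate.apex_rt,
            "ecl": r.ecl,
            "decl": r.decl,
            "snr": r.candidate.snr.snr,
            "tier": r.candidate.tier,
            "branch_class": fa.branch_class,
            "db_spacing_class": classify_db_spacing(fa),
            "flags": ";".join(dict.fromkeys(r.candidate.flags)),
        })
    report = pd.DataFrame.from_records(rows)
    if quant_table is not None and not report.empty:
        report = report.merge(
            quant_table[["species", "fraction", "concentration", "sd", "cov"]],
            how="left", left_on="shorthand", right_on="species",
        ).drop(columns=["species"])
    return report


def chart_data(fractions_by_replicate: dict) -> pd.DataFrame:
    """Segmented bar-chart data: one row per (composition, isomer, replicate)."""
    rows = []
    for rep, fracs in sorted(fractions_by_replicate.items()):
        for (carbons, d), isomers in sorted(fracs.items()):
            for isomer, frac in isomers.items():
                rows.append({
                    "composition": f"FA {carbons}:{d}",
                    "isomer": isomer,
                    "replicate": rep,
                    "fraction": frac,
                })
    return pd.DataFrame.from_records(rows)
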