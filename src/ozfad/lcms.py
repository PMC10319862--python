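"""Spectra, runs, chromatograms and peaks.

Retention times are minutes everywhere inside the package; the 0.3 s DDA
slot grid is converted at the boundary. m/z matching tolerances are ppm,
DDA isolation matching is +/-2 Da by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "Spectrum",
    "LcmsRun",
    "Chromatogram",
    "PeakFit",
    "extract_xic",
    "detect_peaks",
    "average_spectra_over_fwhm",
    "write_run_tables",
    "read_run_tables",
]

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548... sigma -> FWHM

MODES = ("DIA", "DDA", "infusion")


class RunFormatError(ValueError):
    pass


@dataclass
class Spectrum:
    """One centroided scan: ascending m/z array with non-negative intensities."""

    rt: float  # minutes
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    isolation_target: float | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise RunFormatError("mz and intensity arrays differ in length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if not np.all(np.diff(self.mz) > 0):
                raise RunFormatError("duplicate m/z centroids within one scan")
        if np.any(self.intensity < 0):
            raise RunFormatError("negative intensities")
        if self.ms_level == 1 and self.isolation_target is not None:
            raise RunFormatError("MS1 scan must not carry an isolation target")
        if self.ms_level == 2 and self.isolation_target is None:
            raise RunFormatError("MS2 scan requires an isolation target")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class LcmsRun:
    """A time-ordered acquisition.

    DIA runs hold only MS1 scans (all ions are ozonolysed without mass
    selection); DDA runs hold MS2 scans with isolation targets; infusion
    runs hold MS1 scans of a loop injection.
    """

    mode: str
    spectra: list
    metadata: dict = field(default_factory=dict)
    _index: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.mode not in MODES:
            raise RunFormatError(f"unknown acquisition mode {self.mode!r}")
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise RunFormatError("retention times must be non-decreasing")
        if self.mode in ("DIA", "infusion") and any(s.ms_level != 1 for s in self.spectra):
            raise RunFormatError(f"{self.mode} run must contain only MS1 scans")
        if self.mode == "DDA":
            if not any(s.ms_level == 2 for s in self.spectra):
                raise RunFormatError("DDA run contains no MS2 scans")
            for s in self.spectra:
                if s.ms_level == 2 and s.isolation_target is None:
                    raise RunFormatError("DDA MS2 scan without isolation target")

    # -- flat centroid index for fast XIC extraction ------------------------
    def _build_index(self) -> dict:
        if self._index is None:
            n = len(self.spectra)
            counts = np.array([s.mz.size for s in self.spectra], dtype=np.int64)
            mz = np.concatenate([s.mz for s in self.spectra]) if n else np.empty(0)
            inten = np.concatenate([s.intensity for s in self.spectra]) if n else np.empty(0)
            scan = np.repeat(np.arange(n), counts) if n else np.empty(0, dtype=np.int64)
            order = np.argsort(mz, kind="stable")
            self._index = {
                "mz": mz[order],
                "intensity": inten[order],
                "scan": scan[order],
                "rt": np.array([s.rt for s in self.spectra]),
                "level": np.array([s.ms_level for s in self.spectra]),
                "iso": np.array(
                    [s.isolation_target if s.isolation_target is not None else np.nan for s in self.spectra]
                ),
            }
        return self._index


@dataclass
class Chromatogram:
    rt: np.ndarray
    intensity: np.ndarray
    query_mz: float
    tolerance_ppm: float

    def area(self) -> float:
        return float(np.trapezoid(self.intensity, self.rt))


@dataclass
class PeakFit:
    """Gaussian fit of one chromatographic peak."""

    apex_rt: float
    height: float
    sigma: float

    @property
    def fwhm(self) -> float:
        return GAUSS_FWHM * self.sigma

    @property
    def area(self) -> float:
        return self.height * self.sigma * np.sqrt(2.0 * np.pi)


def extract_xic(
    run: LcmsRun,
    mz: float,
    tolerance_ppm: float = 20.0,
    ms_level: int = 1,
    isolation_target: float | None = None,
    isolation_window_da: float = 2.0,
) -> Chromatogram:
    """Extracted ion chromatogram: summed centroid intensity within +/-tol per scan.

    For DDA data ``isolation_target`` restricts to MS2 scans whose quadrupole
    target lies within ``isolation_window_da`` of it; scans without matching
    centroids contribute zero.
    """
    if mz <= 0:
        raise ValueError("query m/z must be positive")
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    idx = run._build_index()
    scan_mask = idx["level"] == ms_level
    if isolation_target is not None:
        scan_mask &= np.abs(idx["iso"] - isolation_target) <= isolation_window_da
    sel = np.nonzero(scan_mask)[0]
    intensity = np.zeros(sel.size)
    if sel.size:
        tol = mz * tolerance_ppm * 1e-6
        lo = np.searchsorted(idx["mz"], mz - tol, side="left")
        hi = np.searchsorted(idx["mz"], mz + tol, side="right")
        if hi > lo:
            scans = idx["scan"][lo:hi]
            vals = idx["intensity"][lo:hi]
            keep = scan_mask[scans]
            # map absolute scan index -> position in the selected subset
            pos = np.searchsorted(sel, scans[keep])
            np.add.at(intensity, pos, vals[keep])
    return Chromatogram(idx["rt"][sel], intensity, mz, tolerance_ppm)


def _gauss(t, h, mu, sigma):
    return h * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def detect_peaks(
    chrom: Chromatogram,
    min_height: float,
    min_points: int = 4,
    max_peaks: int | None = None,
    smooth_sigma_samples: float = 2.0,
) -> list:
    """Find local maxima above ``min_height`` and fit each with a Gaussian.

    Maxima are located on a lightly smoothed copy of the trace (suppressing
    shot-noise splitting of one chromatographic peak into several), and each
    must span at least ``min_points`` samples at half height, which also
    rejects single-scan spikes. The Gaussian is then fitted by least squares
    on the raw trace over apex +/- 2 FWHM with sigma bounded to
    [0.2x, 5x] of the half-height estimate.
    """
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    y = chrom.intensity
    t = chrom.rt
    if y.size < min_points:
        return []
    y_loc = y
    if smooth_sigma_samples and y.size > 4:
        from scipy.ndimage import gaussian_filter1d

        y_loc = gaussian_filter1d(y, smooth_sigma_samples, mode="nearest")
    peaks, props = find_peaks(y_loc, height=min_height, width=min_points / 2.0, rel_height=0.5)
    fits = []
    for i, p in enumerate(peaks):
        width_samples = props["widths"][i]
        dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
        sigma0 = max(width_samples * dt / GAUSS_FWHM, dt / 2)
        h0, mu0 = float(y[p]), float(t[p])
        half = 2.0 * GAUSS_FWHM * sigma0
        # fit region: +/- 2 FWHM, clipped at the valley to any adjacent peak
        # so a large neighbour cannot drag the fit off this maximum
        t_lo, t_hi = mu0 - half, mu0 + half
        if i > 0:
            valley = peaks[i - 1] + int(np.argmin(y_loc[peaks[i - 1]:p + 1]))
            t_lo = max(t_lo, t[valley])
        if i < len(peaks) - 1:
            valley = p + int(np.argmin(y_loc[p:peaks[i + 1] + 1]))
            t_hi = min(t_hi, t[valley])
        sel = (t >= t_lo) & (t <= t_hi)
        if sel.sum() < 3:  # sparse trace: fall back to the unclipped window
            sel = (t >= mu0 - half) & (t <= mu0 + half)
        if sel.sum() < 3:
            fits.append(PeakFit(apex_rt=mu0, height=h0, sigma=sigma0))
            continue
        mu_slack = GAUSS_FWHM * sigma0 / 2.0  # apex stays at this local maximum
        try:
            popt, _ = curve_fit(
                _gauss,
                t[sel],
                y[sel],
                p0=(h0, mu0, sigma0),
                bounds=([0.0, mu0 - mu_slack, 0.2 * sigma0],
                        [np.inf, mu0 + mu_slack, 5.0 * sigma0]),
                maxfev=2000,
            )
            fit = PeakFit(apex_rt=float(popt[1]), height=float(popt[0]), sigma=float(popt[2]))
        except RuntimeError:
            fit = PeakFit(apex_rt=mu0, height=h0, sigma=sigma0)
        if fit.height >= min_height:
            fits.append(fit)
    fits.sort(key=lambda f: f.apex_rt)
    if max_peaks is not None:
        fits = sorted(fits, key=lambda f: -f.height)[:max_peaks]
        fits.sort(key=lambda f: f.apex_rt)
    return fits


def _merge_centroids(mz: np.ndarray, weight: np.ndarray, tol_da: np.ndarray | float):
    """Cluster sorted centroids whose gaps are below tolerance.

    Returns (cluster id per centroid, cluster count).
    """
    if mz.size == 0:
        return np.empty(0, dtype=np.int64), 0
    gaps = np.diff(mz)
    tol = tol_da if np.isscalar(tol_da) else tol_da[1:]
    new_cluster = np.concatenate([[True], gaps > tol])
    ids = np.cumsum(new_cluster) - 1
    return ids, int(ids[-1]) + 1


def average_spectra_over_fwhm(run: LcmsRun, merge_tol_ppm: float = 10.0) -> Spectrum:
    """Average an infusion run's scans over the FWHM of its TIC peak.

    The total-ion chromatogram is computed, its tallest peak located, and all
    scans inside the full width at half maximum are averaged on a common
    centroid grid (nearest-centroid merge within ``merge_tol_ppm``); each
    merged centroid reports the mean intensity over the selected scans.
    """
    if run.mode != "infusion":
        raise RunFormatError("FWHM averaging applies to loop-injection (infusion) runs")
    if not run.spectra:
        raise RunFormatError("empty run has no TIC peak")
    if len(run.spectra) == 1:
        return run.spectra[0]
    tic = np.array([s.tic for s in run.spectra])
    rts = np.array([s.rt for s in run.spectra])
    if not np.any(tic > 0):
        raise RunFormatError("no detectable TIC peak")
    apex = int(np.argmax(tic))
    half = tic[apex] / 2.0
    lo = apex
    while lo > 0 and tic[lo - 1] >= half:
        lo -= 1
    hi = apex
    while hi < tic.size - 1 and tic[hi + 1] >= half:
        hi += 1
    window = run.spectra[lo : hi + 1]
    n = len(window)
    mz = np.concatenate([s.mz for s in window])
    inten = np.concatenate([s.intensity for s in window])
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    ids, k = _merge_centroids(mz, inten, mz * merge_tol_ppm * 1e-6)
    out_mz = np.bincount(ids, weights=mz * inten, minlength=k)
    out_w = np.bincount(ids, weights=inten, minlength=k)
    out_i = out_w / n
    with np.errstate(invalid="ignore"):
        centers = np.where(out_w > 0, out_mz / np.maximum(out_w, 1e-300),
                           np.bincount(ids, weights=mz, minlength=k) / np.bincount(ids, minlength=k))
    keep = out_i > 0
    return Spectrum(rt=float(rts[lo:hi + 1].mean()), ms_level=1, mz=centers[keep], intensity=out_i[keep])


# ---------------------------------------------------------------------------
# lightweight delimited run format (fixture-friendly)
# ---------------------------------------------------------------------------

def write_run_tables(run: LcmsRun, directory) -> None:
    """Write a run as two TSV tables: scans.tsv and centroids.tsv."""
    import os

    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "scans.tsv"), "w") as fh:
        fh.write("scan\trt_min\tms_level\tisolation_mz\n")
        for i, s in enumerate(run.spectra):
            iso = "" if s.isolation_target is None else f"{s.isolation_target:.5f}"
            fh.write(f"{i}\t{s.rt:.6f}\t{s.ms_level}\t{iso}\n")
    with open(os.path.join(directory, "centroids.tsv"), "w") as fh:
        fh.write("scan\tmz\tintensity\n")
        for i, s in enumerate(run.spectra):
            for m, v in zip(s.mz, s.intensity):
                fh.write(f"{i}\t{m:.6f}\t{v:.6f}\n")
    with open(os.path.join(directory, "run.tsv"), "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"mode\t{run.mode}\n")
        for k, v in run.metadata.items():
            fh.write(f"{k}\t{v}\n")


def read_run_tables(directory) -> LcmsRun:
    import os

    meta = {}
    with open(os.path.join(directory, "run.tsv")) as fh:
        fh.readline()
        for line in fh:
            k, _, v = line.rstrip("\n").partition("\t")
            meta[k] = v
    mode = meta.pop("mode")
    scans = []
    with open(os.path.join(directory, "scans.tsv")) as fh:
        fh.readline()
        for line in fh:
            i, rt, level, iso = line.rstrip("\n").split("\t")
            scans.append((float(rt), int(level), float(iso) if iso else None))
    per_scan_mz = [[] for _ in scans]
    per_scan_i = [[] for _ in scans]
    with open(os.path.join(directory, "centroids.tsv")) as fh:
        fh.readline()
        for line in fh:
            i, m, v = line.rstrip("\n").split("\t")
            per_scan_mz[int(i)].append(float(m))
            per_scan_i[int(i)].append(float(v))
    spectra = [
        Spectrum(rt=rt, ms_level=level, mz=np.array(mzs), intensity=np.array(vals), isolation_target=iso)
        for (rt, level, iso), mzs, vals in zip(scans, per_scan_mz, per_scan_i)
    ]
    return LcmsRun(mode=mode, spectra=spectra, metadata=meta)
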