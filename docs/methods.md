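# Methods

## The measurement model

A fatty acid is described by its chain length *c*, an ordered set of
double-bond positions counted from the methyl terminus (*n*−*x*: the bond
joins carbons *x* and *x*+1), per-bond configuration (cis/trans/unknown) and
a branch class. Positions run from *n*−2 (the *n*−1 bond, an enol-ether-like
terminal alkene, is chemically implausible and never searched; the bound is
configurable) to Δ2 on the carboxyl side, with pairwise spacing ≥ 2 so
conjugated dienes are included but cumulated dienes (allenes) are not. A
*de novo* search over chain length *c* with *d* bonds therefore enumerates
C(*c*−2−*d*, *d*) patterns.

Derivatization couples the fixed-charge reagent amine (AMPP,
cation C12H13N2+, or its 4-iodo analog) to the carboxylic acid with loss of
water; the precursor m/z is the monoisotopic mass of acid + reagent cation −
H2O minus one electron. Ozonolysis of the bond at *n*−*x* loses the
methyl-side fragment C*x*H(2*x*−2*m*) (*m* = bonds fully contained in the
lost fragment) and retains the charge-tagged aldehyde; the Criegee ion is
one oxygen heavier. All m/z arithmetic subtracts the electron mass — the
matching tolerances downstream are 10–20 ppm and the electron is 1.2 ppm at
m/z 450.

Aggregated isotope patterns are computed by per-element convolution over
nucleon-number offsets (binary exponentiation of the single-atom
distribution, abundance-weighted mean mass per offset), normalized to the
monoisotopic peak. Deuterium in the FA 16:0d31 internal standard is treated
as a fixed label: positions are irrelevant to mass, so only the count is
stored.

## Discovery

Retention windows per sum composition are predicted from the observed
palmitic (16:0) and stearic (18:0) anchors: saturated retention is linear in
carbon number with slope (rt18 − rt16)/2, and *d* double bonds shift the
expected equivalent chain length into the band [−2.2 *d* − 0.3,
−0.4 *d* + 0.3] (configurable; these bounds are calibration parameters).
Precursor XIC peaks inside the window passing abundance and ppm-error
filters (default gate 10 ppm — tight enough to reject the M+2 shoulder of
the (*c*, *d*+1) species, which sits ~9 mDa ≈ 19 ppm below the (*c*, *d*)
monoisotope) become observations.

The DDA inclusion list divides the gradient into 0.3 s slots (4000 for a
20-min gradient). Every observation claims the slots within ±1.5 × FWHM of
its apex; contested slots go to the claimant with the fewest slots within
the previous 10 slots (ties: lower abundance, then lower m/z). Counting
locally rather than globally is deliberate: the fairness that matters is
points per chromatographic peak, and a global counter starves a precursor
exactly where it co-elutes with others after it has banked slots in
uncontested stretches.

The exhaustive search runs per sum composition over all MS2 scans of the
matching isolation target. A pattern becomes a candidate only where its
complete transition set is present, and each detected peak of the summed
product trace yields its own candidate retention time — this is how a cis
isomer and its trans counterpart, which share every diagnostic m/z, are both
recovered even when the smaller never resolves at the precursor level. An
apex is accepted only if **every** individual product trace peaks there
(co-elution tolerance 0.05 min): all diagnostic ions must derive from the
same feature, which rejects chimeric patterns assembled from tails of
features eluting elsewhere. Apexes are then re-centred on the densely
sampled DIA traces (the same product ions at full 0.1 s cadence; the
segmented DDA traces carry a few-points-per-peak sampling error), and S/N is
re-scored at the corrected apex with a uniform spectrum window so that
product-area ratios compare like with like.

S/N is the mean integrated product peak over the mean integrated
eligible-noise peak, computed on the combined spectra within ±FWHM/2 of the
candidate apex. The structural product count (2 per bond: 2 for a
monounsaturate, 12 for a hexaunsaturate) divides the signal whether or not
each ion was detected; a peak is eligible noise only if it is near neither
the precursor isotope envelope nor any m/z a feasible OzID product of that
precursor could produce — including product isotopologues, which arise from
products and are not noise. The precursor peak is never counted as signal.
Tiers use half-open intervals: [0, 3) rejected, [3, 10) tentative (excluded
from quantification), [10, ∞) confident. Zero eligible noise reports S/N as
+∞ with a flag.

Duplicates — multiple patterns assigning one chromatographic feature through
shared product m/z — are removed greedily. Ranking uses the integrated
product signal rather than S/N: duplicates share the feature's noise, and
the Eq.-style denominator varies with ±1 scan at the window edge, enough to
flip ranks between a genuine pattern and a chimera. The survivor set is then
pre-screened for putative over-oxidation (final exclusion happens at
annotation, after configurations are known).

## Quantification

Relative isomer fractions come from non-negative least squares over
Gaussians with centers fixed at the OzID-derived apexes and one shared width
(the median observation width; a shared σ stabilizes near-degenerate fits
across a narrow retention span). A component whose center lies within 0.5 σ
of a ≥20×-larger component (or exactly coincides with a larger one) is not
identifiable from the precursor trace: its NNLS amplitude is first returned
to the dominant component — with coincident centers the fit splits the
shared mass arbitrarily — and its fraction re-estimated from the ratio of
summed OzID product areas, flagged `upper_limit` because it assumes equal
ozonolysis efficiency across positions (the generator exposes a per-position
efficiency hook, but no published values exist). All parameters and
residuals export to an editable worksheet.

Absolute quantification processes each loop-injection run as: average over
the TIC-peak FWHM → numerical baseline (moving 10th percentile over a 5-Da
window; windows holding fewer than 10 centroids carry no baseline, since a
low percentile over a handful of isotope sticks is signal) → m/z
recalibration by the mean deviation of the 16:0/18:0 anchor peaks (assumed
dominant in their ±0.03 Da search windows; they are the main components of
any process blank) → isotope correction. Correction proceeds per carbon
count from most to least unsaturated, subtracting each species' predicted
isotopologues from heavier monoisotopes before those are assigned — in
particular the M+2 of (*c*, *d*) landing ~9 mDa from the (*c*, *d*−1)
monoisotope, unresolved at the modelled centroid resolution. The reported
abundance is the envelope-total equivalent (monoisotope × pattern sum),
removing the chain-length dependence of the monoisotopic fraction before
internal-standard scaling. Process-blank rules per species: blank/sample
> 0.75 excludes, 0.01–0.75 subtracts, < 0.01 keeps. Per-isomer
concentration is fraction × sum-composition concentration, with replicate
mean, SD and COV.

## Annotation

ECL interpolates retention linearly between saturated anchors (log-rt
interpolation, the classical GC convention, is a config switch);
dECL = ECL − carbons. Branch flagging fits a straight-chain dECL trend
(linear in bond position) iteratively and classes features more than 0.3 ECL
units below it as branched; configuration assignment labels the earlier of
two straight features at the same (carbons, position) cis and the later
trans, assigns singletons from the dECL trend of assigned features at the
same position across chain lengths (tolerance 0.15), leaves unmatched
features unknown, and marks polyunsaturates cis as a tentative default.

Over-oxidation exclusion: a candidate whose positions all sit at
parent + 1 and which co-elutes with that parent (≤0.05 min) is excluded when
its product-area ratio is at or below the parent-configuration cap — 1.5 %
cis / 3 % trans — times a guard factor (default 1.25, because the caps are
stated maxima) plus a 2 σ counting-statistics allowance
(2·√area_artifact/area_parent): at trace level the artifact area is a
~10-count Poisson variate and the bare cap would pass about half of all
artifacts. A retention shift beyond the co-elution tolerance rescues the
candidate. Double-bond spacing classes in the report: all spacings 3 →
methylene-interrupted; 2 → conjugated; any 6 → butylene-interrupted (NMI);
otherwise NMI-other.

## The synthetic-data generator

The generator is the package's study-condition definition, not a fixture.
It emulates: Gaussian elution (σ = 0.025 min, ≈3.5 s FWHM, typical of
sub-2-µm reversed-phase columns) over a 20-min gradient; MS1 scans every
0.1 s; DDA MS2 scans at the 0.3 s slot grid with ±2 Da quadrupole isolation;
isotope envelopes distributing each species' ion current; OzID products at
25 % of the precursor response (Criegee/aldehyde yield 0.85); over-oxidation
ions at the *n*−(*x*+1) transition m/z at 1.5 % (cis) / 3 % (trans) of the
genuine products, co-eluting exactly; 2-ppm mass jitter; uniform-m/z,
log-normal chemical noise; Poisson shot noise above a floor; centroid
merging at 12 mDa (so the DHA M+2 / DPA monoisotope overlap is genuinely
unresolved); and a 2-min loop injection without ozone. Everything derives
from one seed and the ground truth serializes next to each run.

Retention times follow a built-in model, rt = t0 + 0.45 min × ECL with
t0 = 1.28 min, each bond contributing dECL = −2.0 (cis) or −1.65 (trans)
+ 0.074 × position, and branching −0.70. The coefficients are calibrated so
that derivatized oleic and mead acid co-elute near 8.8 min while
dihomo-γ-linolenic and sciadonic acid fall near 8.5 and 8.6 min — the
elution structure characteristic of reversed-phase plasma runs — and so that
the cis/trans (0.35) and branched (0.70) offsets are at least twice the
decision tolerances (0.15 and 0.3), which is what a "noiseless
classification is exact" test can legitimately demand.

The bundled `plasma_like_mixture` holds 20 species across four orders of
magnitude (0.05–500 nmol/mL) with three fully co-eluting pairs — oleic/mead
(different m/z), oleic with 1 % FA 18:1*n*−12 (same m/z; exercises the
product-ion fallback), and sapienic-type FA 16:1*n*−10 with a trace
FA 19:2 — plus saturated anchors and the d31 internal standard at
1.348 nmol/mL.

What the generator does **not** model — peak tailing, detector saturation,
gradient-dependent ionization drift, position-dependent ozonolysis
efficiency, real chemical backgrounds, lock-mass drift — bounds what passing
tests show: they demonstrate that the algorithms are correct under the
stated statistical structure, not that the thresholds are optimal for any
particular instrument. The parameters most likely to need retuning on real
data (ppm gates, dECL window coefficients, S/N tiers, co-elution tolerance,
over-oxidation guard) are all exposed in `PipelineConfig`.

## Numerical choices and degenerate inputs

Peak detection locates maxima on a lightly smoothed trace (σ = 2 samples),
requires ≥ `min_points` samples at half height (suppressing single-scan
spikes), and fits each Gaussian on the raw trace over ±2 FWHM with σ bounded
to [0.2×, 5×] the half-height estimate and the center held within ±FWHM/2 of
the local maximum; the fit region is clipped at the valley toward any
adjacent detected peak so a large neighbour cannot drag the fit off its
maximum, falling back to the unclipped window (or moment estimates) on
sparse traces. Spectral clustering for S/N and averaging merges centroids
whose gaps are below the ppm tolerance; empty compositions, missing anchors,
non-increasing retention times, MS2 scans without isolation targets and
profile-mode spectra raise immediately. Deconvolution reports +∞-free
fractions that sum to one over quantified components and raises with
residual diagnostics if NNLS fails.

## Problem sizes

The default test suite simulates full 20-min/0.1-s DIA runs (12 000 scans)
and 4000-slot DDA runs; the complete simulated study analysed in the
acceptance tests runs in well under a minute on one core. The de novo search
spans ~10⁴ patterns for the bundled mixture; real vernix-scale studies
(c up to 30, d up to 6) enumerate into the 10⁵–10⁶ range, which the same
code paths handle by the library/streamlined modes.
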