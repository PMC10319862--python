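# ozfad

Isomer-resolved discovery and quantification of unsaturated fatty acids from
LC-OzID-MS data.

Unsaturated fatty acid isomers — species sharing a chain length and degree of
unsaturation but differing in double-bond position or configuration — are
largely invisible to conventional LC–MS: collision-induced dissociation gives
near-identical spectra, and reversed-phase chromatography rarely resolves
them. Ozone-induced dissociation (OzID) solves the selectivity problem
chemically: ozone cleaves each C=C bond of the ionized, fixed-charge
(AMPP-derivatized) fatty acid into an **aldehyde** ion and a **Criegee** ion
(one oxygen heavier), whose m/z values pinpoint the bond position. For
derivatized oleic acid (FA 18:1*n*−9) the precursor at *m/z* 449.35 yields
the diagnostic pair at *m/z* 339.21 and 355.20.

This package implements the complete data-analysis workflow around that
chemistry, for lipidomics researchers and mass-spectrometry method
developers:

- **Transition prediction** for any chain length, double-bond pattern
  (including conjugated, excluding cumulated dienes) and derivatization
  agent (`ozfad.chem`), with shorthand/systematic nomenclature
  (`ozfad.nomenclature`).
- **Acquisition modelling and I/O**: centroided mzML read/write, extracted
  ion chromatograms, Gaussian peak fitting, FWHM spectral averaging
  (`ozfad.lcms`, `ozfad.mzml_io`).
- **Discovery**: retention-window prediction from the palmitic/stearic
  anchors, DIA precursor analysis, resampling of precursor claims onto a
  0.3 s DDA inclusion-list grid, the de novo exhaustive double-bond search
  against the mass-selected OzID spectra, and confidence filtering by the
  product-ion signal-to-noise ratio
  (S/N = mean product-peak integral / mean eligible-noise integral;
  S/N < 3 rejected, 3 ≤ S/N < 10 tentative, S/N ≥ 10 confident)
  (`ozfad.discovery`).
- **Quantification**: relative isomer fractions by non-negative Gaussian
  deconvolution of the precursor chromatogram with centers fixed at the
  OzID-derived retention times (with a flagged product-ion fallback for
  buried trace isomers), and absolute sum-composition concentrations from
  loop-injection spectra via baseline subtraction, anchor recalibration,
  isotope correction and internal-standard (FA 16:0d31) scaling, with
  process-blank rules (`ozfad.quantify`).
- **Annotation**: equivalent-chain-length retention indexing
  (dECL = ECL − carbons), cis/trans assignment from elution order and dECL
  trends, branched-chain flagging, exclusion of over-oxidation artifacts
  (apparent bond one carbon closer to the carboxyl terminus, ≤1.5 % of a
  cis / ≤3 % of a trans parent, rescued by a retention shift), and report
  generation with offline database IDs (`ozfad.annotate`).
- **A synthetic-run generator** (`ozfad.simulate`) that emulates DIA, DDA,
  infusion and blank acquisitions with ground truth, so the entire pipeline
  is testable without an instrument.

## Worked example

`examples/full_pipeline.py` simulates a 20-species plasma-like study
(concentrations 0.05–500 nmol/mL, three fully co-eluting isomer pairs,
over-oxidation artifacts at their 1.5 %/3 % caps) and analyses it end to
end:

```
funnel:
  precursor_observations     18
  target_slots               4000
  patterns_searched          10708
  raw_candidates             191
  curated_candidates         35
  confident_candidates       34
  overoxidation_excluded     17
  annotated                  18
  reported                   18

                  shorthand  apex_rt    decl      tier  fraction  concentration
             FA 16:1n-7 cis    7.813  -1.482 confident     0.752          100.2
            FA 16:1n-10 cis    7.913   -1.26 confident    0.2256          30.05
           FA 16:1n-7 trans    7.971  -1.132 confident   0.02238          2.982
             FA 17:1n-8 cis    8.296  -1.408 confident         1          6.006
                 FA 18:1n-5    8.647   -1.63 confident    0.1017          59.57
                FA 18:1n-12     8.78  -1.334 confident  0.008708          5.102
             FA 18:1n-9 cis     8.78  -1.334 confident    0.8557          501.3
           FA 18:1n-9 trans    8.937 -0.9841 confident   0.03388          19.85
  ...
```

The funnel shows the discovery logic at work: ~10⁴ putative double-bond
patterns are searched, 191 become candidates (every pattern whose complete
aldehyde/Criegee transition set is present), curation and artifact exclusion
reduce them to the 18 genuine species, and every injected unsaturated
species — including mead acid fully co-eluting with a 250-fold excess of
oleic acid, and a 1 % FA 18:1*n*−12 hidden under the oleic peak (quantified
through its product ions, flagged as an upper limit) — is recovered at
S/N ≥ 10 with its fraction and concentration. `apex_rt` is minutes; `decl`
is the retention index used for the cis/trans and branched assignments;
`concentration` is nmol/mL.

The other examples cover transition prediction, DIA precursor analysis with
inclusion-list construction, and direct-infusion quantification. A thin CLI
(`ozfad simulate | discover-dia | discover-dda | demo`) wraps the same
stages for shell use.

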