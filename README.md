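# cemqa — quality assurance for contrast-enhanced mammography phantom studies

Contrast-enhanced mammography (CEM) acquires a low-energy (LE) image, which
looks like a standard mammogram, and a high-energy (HE) image whose spectrum
sits just above the 33.2-keV k-edge of iodine. A dual-energy subtraction
(DES) image recombines the two so that iodinated contrast is enhanced while
the anatomical tissue background is suppressed. Medical physicists verify
this chain with a dual-energy phantom (CIRS Model 022 style): a 55-mm stack
whose target plate carries two mirrored sets of iodine plugs at
0.2/0.5/1.0/2.0 mg/cm² plus a central 100%-glandular plug, over a contrast
plate that is half 100% adipose and half 100% glandular.

`cemqa` implements the full measurement chain for such studies:

* **Image quality.** For each plug, a circular ROI inside the target and a
  circular ring around it give the contrast-to-noise ratio

  ```
  CNR = |MPV_bkg − MPV_target| / SD_bkg
  ```

  measured on LE, HE and DES images; the *residual CNR* at the
  100%-glandular plug positions on the DES image quantifies how much tissue
  signal the recombination failed to cancel. Linearity of the DES signal
  difference versus iodine surface density serves as an algorithm QC
  criterion.
* **Recombination.** A generic tissue-nulling weighted log subtraction
  `DES = ln I_HE − w · ln I_LE`, with `w` estimated per study from plug-free
  patches on the two contrast-plate halves (vendor DES images can be
  analyzed instead, unchanged, thanks to CNR's affine invariance).
* **Dosimetry.** Mean glandular dose per image via the Dance factor model,
  `MGD = K · g · c · s`, from the exposure technical factors in standard
  DICOM tags, plus total dose per CEM study (LE + HE), dose-increase
  percentages and the EU 2.64-mGy limit check for a 55-mm breast.
* **Aggregation.** Repeated acquisitions are summarized as mean ± maximum
  half-dispersion `(max − min)/2`; inter-system tables divide a reference
  system's mean CNRs by a comparator's, cell by cell.
* **Synthetic studies.** A seeded generator renders LE/HE raw pairs of the
  phantom under an energy-lumped attenuation model with quantum-plus-
  electronic noise (`variance = a·mean + b`), so every stage is testable
  without a mammography unit. Profiles can be calibrated so their analytic
  plug CNRs match a measured table; the package bundles a transcription of
  a published three-vendor intercomparison (GE, Hologic, Siemens) for this.

## Worked example

Simulate one GE-like acquisition, recombine it and measure it:

```python
from cemqa import (default_cirs022_layout, default_frame, simulate_acquisition,
                   measure_study, estimate_weight, recombine, analytic_cnr)
from cemqa.profiles import reference_profile

profile = reference_profile("GE")            # calibrated to the bundled CNR table
spec = default_cirs022_layout()              # 55-mm phantom, 10 plugs
frame = default_frame()                      # 1000 x 800 px at 0.1 mm
study = simulate_acquisition(spec, profile, frame, seed=1)
w = estimate_weight(study.le_image, study.he_image, spec, frame)
des = recombine(study.le_image, study.he_image, w)
meas = measure_study({"LE": study.le_image, "HE": study.he_image,
                      "DES": des.image}, spec, frame)
```

which prints, for the adipose-half LE plugs:

```
tissue-nulling weight w = 0.261
LE  2.0 mg/cm2  CNR = 4.85  (model truth 4.84)
LE  1.0 mg/cm2  CNR = 2.66  (model truth 2.58)
LE  0.5 mg/cm2  CNR = 1.34  (model truth 1.33)
LE  0.2 mg/cm2  CNR = 0.52  (model truth 0.54)
residual DES CNR at glandular plugs: 0.013, 0.022
```

The 2.0 mg/cm² anchor reproduces the calibration target (4.84), the CNRs
fall monotonically with iodine density, and the residual CNR at the
glandular plugs is far below the faintest iodine plug — the recombination
cancels tissue while preserving iodine.

The same chain is available from the shell:

```sh
cemqa simulate --profile GE --repeats 3 --seed 1 --out studies/
cemqa analyze  --study studies/ --system GE --out meas.csv
cemqa compare  --measurements meas.csv --reference GE --out report/
cemqa tables   --out tables/     # regenerate the bundled published tables
```

`cemqa tables` rebuilds every derived dose quantity from the bundled
technical-factor transcription:

```
       label  mgd_le_mgy  mgd_he_mgy  total_mgy  he_fraction_pct  increase_vs_ref_pct  within_limit
          GE        1.64        0.70       2.34        42.682927             0.000000          True
     Hologic        2.66        0.84       3.50        31.578947            49.572650         False
Siemens 125%        2.39        0.75       3.14        31.380753            34.188034         False
...
```

GE delivers the lowest total dose (2.34 mGy, under the 2.64-mGy EU limit
for a 55-mm breast), Hologic the highest (3.50 mGy, +49.6%); cells whose
recomputed-from-rounded value differs from the source's printed
presentation are listed in `rounding_flags.csv` rather than silently
corrected.

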