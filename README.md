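# invpetdose

Reconstruction-parameter selection and image-based internal dosimetry for
small-animal PET, built around a simulated Cu-64 study on a preclinical
scanner geometry.

## Scientific problem

The absorbed radiation dose estimated from PET images depends strongly on
how the images were reconstructed. Filtered back-projection (FBP) with a
smooth apodization window, ordered-subsets EM (OSEM) at different iteration
numbers, and penalized MAP-EM at different smoothing strengths all trade
quantitative recovery against noise differently, and the resulting dose
estimates for the same subject can differ by almost a factor of two. This
package implements the full chain needed to study and control that effect:

1. **Phantom and kinetics simulation** — a voxelized NEMA NU4-2008
   image-quality phantom (hot-rod section, uniform section, two cold
   chambers) filled with 3.7 MBq, plus biexponential antibody-like mouse
   time-activity curves for Cu-64 (half-life 12.7 h).
2. **Reconstruction** — a parallel-beam 2D projector with attenuation and
   scatter models; FBP with six apodization windows (ramp, Butterworth,
   Hamming, Hanning, Parzen, Shepp-Logan), OSEM (16 subsets, iterations
   1-10), and one-step-late MAP-EM with a quadratic 8-neighborhood prior
   (beta 0.1 / 1.0 / 1.5), at selectable correction levels (none, AC,
   AC+SC).
3. **Image-quality metrics** — NEMA NU4 non-uniformity (NU, %SD in a
   central uniform VOI), rod recovery coefficients (RC, ROI-max based), and
   spill-over ratios (SOR) in the air and water cold chambers.
4. **Selection** — a strict acceptance box `0.9 < RC(3 mm) < 1.0` and
   `NU < 10%` that picks reconstruction configurations suitable for
   quantitative dosimetry.
5. **Dosimetry** — decay-uncorrected time-activity curves are integrated
   (trapezoid with a physical-decay tail) to residence times; tumor dose
   comes from a power-law fit of sphere S-values, organ and effective dose
   from an organ S-factor matrix, with mouse-to-human residence-time
   scaling.
6. **Comparison engine** — dose tables across all 19 reconstruction
   configurations are compared against the OSEM iteration-1 gold standard
   with the symmetric percent difference `200 (x - ref)/(x + ref)`.

A packaged dose table (tumor + 23 organs x 19 configurations) and its
percent-difference table ship as CSV fixtures, together with synthetic
(clearly labelled) sphere S-value and organ S-matrix tables.

## Worked example

```python
from invpetdose import study, selection, compare

# Simulate one noisy acquisition (5e6 counts, seed 42) and score the
# whole reconstruction family at two correction levels.
res = study.run_phantom_study(seed=42, total_counts=5e6)

rep = res.report("osem2d_iter1", "partial")
print(rep.nu.percent_sd, rep.rc[3.0])     # 16.27  0.860

rep = res.report("osem2d_iter1", "AC_SC")
print(rep.nu.percent_sd, rep.rc[3.0])     # 16.22  1.127

# NU grows with OSEM iteration number ...
print(res.nu_series(study.OSEM_CONFIG_IDS, "partial")[-1])  # 58.77 at iter 10

# ... and Parzen is the smoothest FBP window.
print(res.report("fbp_parzen", "AC_SC").nu.percent_sd)      # 3.90

# Strict selection: 0.9 < RC(3mm) < 1.0 and NU < 10 %.
entries = [
    selection.TradeoffEntry(c, res.report(c, "AC_SC").rc[3.0],
                            res.report(c, "AC_SC").nu.percent_sd, "AC_SC")
    for c, level in res.reports if level == "AC_SC"
]
print(selection.apply_rc_nu_criterion(entries).selected)    # ['mapem_beta1.5']

# Dose-table comparison against the OSEM iteration-1 gold standard.
doses = compare.load_published_dose_table()
diff = compare.compare_to_reference(doses)
print(round(diff.loc["Tumor", "osem2d_iter10"], 1))         # 32.4
print(round(diff.loc["Tumor", "fbp_butterworth"], 1))       # -35.4
print(compare.range_spread(doses.loc["Tumor"]))
# {'min': 923.0, 'max': 1830.0, 'rel_spread_percent': 98.27}
```

The tumor dose across reconstruction configurations spans 923 to
1830 mGy/MBq — a 98% relative spread caused purely by the choice of
reconstruction parameters.

A command-line interface mirrors the library:

```bash
petdose simulate --nx 48 --nz 63 --counts 2e5 --seed 1 --out-dir sim/
petdose reconstruct --sino sim/sinogram.raw --mumap sim/mumap.nii.gz \
    --scatter sim/scatter_estimate.raw --algorithm OSEM --iterations 1 \
    --ac --sc --out rec.nii.gz
petdose iq --image rec.nii.gz --activity sim/activity.nii.gz \
    --config-id osem2d_iter1 --out iq.json
petdose compare --out comparison.csv
```

## Reproduction

All headline quantities are recomputed by

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which runs the seeded phantom study (per-configuration NU/RC/SOR and the
surviving configurations of the selection criterion), the dose-table
comparison (anchored percent-difference cells and the tumor dose range),
and the dosimetry chain (residence times from noiseless and noisy 4-point
time-activity curves, tumor dose, organ and effective dose). All
randomness flows through `--seed`. See `docs/methods.md` for model and
numerical details.
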