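# sifyield

Plot-level solar-induced fluorescence (SIF) phenotyping pipeline: from
hyperspectral canopy imagery and downwelling irradiance to photosynthetic
capacity, with a full synthetic-data generator for testing every stage.

The pipeline implements the chain used in push-broom field phenotyping of
photosynthesis:

1. **Synthetic inputs** (`sifyield.synthetic`) — irradiance spectra with a
   Gaussian O2-A absorption trough at 761 nm, scene cubes (white reference
   panel, sunlit/shaded foliage, soil, background) rendered under the
   Lambertian forward model `L = r·E/π + F` and encoded to 12-bit DN, plot
   fluorescence yields tied negatively to an assigned Jmax, and FvCB-forward
   A/Ci curves at the standard 12 chamber CO2 setpoints. Every generator
   returns its ground truth.
2. **Radiometric primitives** (`sifyield.spectra`) — `Spectrum` container,
   cubic-spline resampling (0.35 nm → 2.1 nm), band means, NDVI
   ((R770–780 − R650–660)/(R770–780 + R650–660)), trapezoidal PAR
   integration over 400–700 nm, and white-panel reflectance conversion
   `R = (S_cluster/S_white)·R_white`.
3. **Image pipeline** (`sifyield.imaging`) — DN→radiance calibration with
   saturation flagging, k-means segmentation (k = 6) of per-pixel radiance
   spectra, white-panel identification (brightest cluster), sunlit-leaf
   identification (NDVI > 0.1, then brightest), the ±15° scan-angle mask of
   a ±46.1° push-broom line (640 channels → columns 216–423), and masked
   plot-mean spectra. ENVI cube I/O lives in `sifyield.envi`.
4. **SIF retrieval** (`sifyield.retrieval`) — FLD and iFLD at the O2-A band
   (λ_in = 761 nm, λ_out = 754 nm), correction factors α_R/α_F estimated by
   cubic-spline interpolation of apparent reflectance across an exclusion
   window around the line, and SIF yield
   `SIFy = SIF / (PAR · fAPAR)` with NDVI as the fAPAR proxy.
5. **Gas exchange** (`sifyield.fvcb`) — FvCB forward model (min of
   Rubisco- and RuBP-limited rates), mesophyll-conductance temperature
   response (`Cc = Ci − A/gm`), multi-start least-squares A/Ci fitting of
   (Vcmax, Jmax, Rd) with an identifiability guard (Jmax reported
   unavailable when no setpoint is electron-transport limited), and
   leaf-to-plot averaging.
6. **Statistics** (`sifyield.regression`) — per-group and pooled OLS with
   R², in-sample RMSE, Pearson correlation and slope t-tests; groups are
   acquisition-date bins supplied as configuration.
7. **Orchestration** (`sifyield.orchestrate`, `sifyield.experiment`,
   `sifyield.cli`) — YAML configuration, cube↔irradiance timestamp
   matching, and the end-to-end synthetic campaign runner.

## CLI

```bash
sifyield simulate --seed 1 --out outputs/sim        # ENVI scene + irradiance + truth
sifyield retrieve outputs/sim/scene.hdr outputs/sim/irradiance.csv \
    --gain-csv outputs/sim/gain.csv                 # SIF + SIF yield for one scene
sifyield fit-aci aci.csv                            # per-leaf Vcmax/Jmax/Rd
sifyield regress merged.csv --x sif_yield --y jmax  # group-binned OLS
sifyield run-all --seed 1 --out outputs/run         # full synthetic campaign
```

`run-all` generates a three-group campaign (negative fluorescence-yield↔Jmax
link, NDVI↔Vcmax light-capture link), retrieves SIF and SIF yield per plot,
refits capacity from synthetic A/Ci curves, and writes `sif_records.csv`,
`fvcb_params.csv`, `regression_results.csv` and a self-documenting
`run_log.json`. Identical config + seed gives byte-identical outputs.

## Conventions worth knowing

- Radiance is W m⁻² sr⁻¹ nm⁻¹, irradiance W m⁻² nm⁻¹; the Lambertian
  factor π links them, so apparent reflectance is π·L/E.
- PAR is kept in energy units (W m⁻²), making SIF yield a ratio with units
  sr⁻¹ μm⁻¹; a quantum-units helper (`par_to_quantum`) exists but is not
  used in SIF yield.
- Band selection for retrieval is nearest-band-centre on the 2.1 nm camera
  grid; α factors are evaluated at those actual band centres.
- α_F defaults to α_R; pass a smooth fluorescence shape to
  `estimate_alphas` to decouple them.
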