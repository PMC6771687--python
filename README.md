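# locmorph

SMLM localization post-processing, endosomal nanodomain morphometry,
and fiducial-based correlative (CLEM) registration.

`locmorph` is for microscopists who image membrane nanodomains —
specifically Rab5 domains on early endosomes — with multi-color
single-molecule localization microscopy (dSTORM/PALM) of thin sections,
and who want the quantification chain from the raw localization tables
to per-endosome domain statistics and overlay-precision reports,
with every stage testable against simulated ground truth.

## What it computes

Starting from per-channel localization tables (frame, x, y in nm,
photons, PSF FWHM):

* **Filtering** — PSF-width window (e.g. 250–450 nm for sections) and
  per-dye photon thresholds (3000 / 1500 / 450 photons), inclusive
  boundaries.
* **Localization precision** — localizations are linked into tracks by
  mutual nearest neighbours in consecutive frames; per track
  s = √((s_x² + s_y²)/2) from the unbiased per-axis variances about the
  track mean; the **median of s** over tracks is the data set's
  precision.
* **Drift** — linear lateral drift x′ = x − v_x·(frame − frame₀),
  estimated from long fiducial tracks by length-weighted least squares
  (robust to pseudo-track outliers) or supplied explicitly.
* **Rendering** — 10 nm/px count histograms; a 0–1 px median filter on
  the Rab5 channel suppresses monomeric cytosolic signal.
* **Morphometry** — combined cargo+Rab5 signal → Gaussian blur
  (σ = 2 px) → IsoData (iterative intermeans) threshold → hole-filled,
  8-connected particles with a 4 px² floor → the endosome-area proxy;
  the Rab5 channel alone, same chain, gives the nanodomains. Each
  domain is an area-matched second-moment ellipse (diameter = mean of
  axes; sizes measured on the half-maximum support to remove the blur
  halo). Per endosome: domain count, Rab5-covered area, coverage
  fraction; population summary with mean ± SD, singleton subset, and
  OLS fits (covered area vs count; count vs endosome area).
* **Registration** — rod-fiducial landmarks (intensity centre of mass,
  and endpoints along the principal axis), similarity / affine /
  rigid / thin-plate-spline least-squares fits, and leave-one-out
  overlay precision reported as mean ± SD and median ± MAD (Rayleigh
  median σ√(2 ln 2) under isotropic jitter σ).
* **Synthetic data** — a deterministic generator producing
  endosome/domain/tubule/rod scenes with known geometry, blinking
  emitters, photon statistics, background, drift, and an EM reference
  image under a known transform: the ground truth every stage is
  validated against.

See `docs/methods.md` for models, conventions and parameter rationale.

## Worked example

Simulate the bundled reference scene (12 endosomes carrying on average
five 55 nm Rab5 domains, three channels, rod fiducials, slow drift)
and analyze it:

```bash
locmorph simulate --preset paper-like --seed 0 --out sim
locmorph analyze --config run.yaml        # channels point at sim/locs_*.csv
```

with `run.yaml`:

```yaml
seed: 0
output_dir: analysis
extent: [0, 10000, 0, 10000]
channels:
  egf:  {path: sim/locs_egf.csv}
  tfn:  {path: sim/locs_tfn.csv}
  rab5: {path: sim/locs_rab5.csv}
```

The run prints (abridged):

```
drift[rab5]: (+0.0176, -0.0089) nm/frame (track-lsq(min_len=100, n_tracks=59/63))
precision[rab5]: median 9.48 nm from 12101 tracks
render[rab5]: (1000, 1000) px, 0 out of field
excluded rod-fiducial footprint (46893 px) from the morphometry images
morphometry: 12 endosomes, 5.42 +- 3.48 domains, diameter 61.7 +- 2.3 nm
```

Reading the numbers: the injected drift was (+0.02, −0.01) nm/frame
and the track-based fit recovers it; the median per-track precision
(9.5 nm) sits just below the simulated 10 nm localization error, as
expected for short tracks; the pipeline finds all 12 endosomes and
recovers the generator's true mean of 5.42 domains per endosome
exactly, with the 55 nm domains measured at 61.7 nm (the documented
blur broadening at σ = 10 nm). `analysis/summary.json` additionally
reports the covered-area-versus-count fit — here r = 0.99, the linear
relation expected when domains of similar size accumulate on an
endosome — plus the singleton-domain subset and both OLS fits, and
`analysis/domains.csv`, `analysis/endosomes.csv` carry the per-particle
and per-endosome tables.

`locmorph overlay-qc` runs the registration workflow on the same
channels (and optionally an EM overview), and `locmorph benchmark`
sweeps generator truth against pipeline estimates.

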