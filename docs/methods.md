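# Methods

`locmorph` re-implements, as a tested pipeline, the post-processing
chain used to quantify Rab5 membrane nanodomains on early endosomes in
three-color single-molecule localization microscopy (SMLM) of thin
sections, together with the fiducial-based registration used to overlay
color channels and an electron-microscopy (EM) overview. This note
records the models, the conventions, the parameters that matter, and
the design choices made where the procedure left room.

## Localization tables and filtering

The pipeline starts from localization tables (one per color channel):
frame index (0-based), lateral position x, y in nm (camera frame,
origin upper-left, y down), fitted photon count, and fitted PSF FWHM in
nm. Raw-frame PSF fitting is out of scope; any fitter that emits this
schema can feed the pipeline. Pixel-unit input is converted with the
camera pixel size (default 104 nm) and the conversion is logged.

Quality filtering keeps records with `fwhm_min <= FWHM <= fwhm_max`
and `photons >= photon_min`. All boundaries are **inclusive**; the
source procedure does not state a convention and inclusivity avoids
silently dropping exactly-at-threshold fits. Defaults: FWHM window
250–450 nm (thin sections; whole-cell data typically uses 250–650 nm —
the window is a parameter, not a constant), photon thresholds 3000
(AF647-like), 1500 (AF568-like), 450 (Dronpa/GFP-like) keyed by
channel name. Discard counts per criterion are recorded in the output
table's metadata.

## Track linking and the localization-precision statistic

Localizations in consecutive frames are linked by greedy
mutual-nearest-neighbour matching within a link radius (default
104 nm = one camera pixel); chains extend while links exist, each
localization joins at most one track, and only tracks of length >= 2
are kept. The matching is symmetric under time reversal. Exact
distance ties resolve toward the lowest record index.

For each track the unbiased per-axis sample variances about the track
mean are pooled,

    s = sqrt((s_x^2 + s_y^2) / 2),

and the **median** of s over all tracks is reported as the
localization precision of the data set. Notes:

* For finite track length the median of s is biased slightly below the
  true per-axis sigma (for length-5 tracks with sigma = 10 nm the
  statistic's median is ~9.6 nm); it converges to sigma as track
  length grows. The tests pin this against a direct Monte-Carlo
  simulation of the same statistic.
* A `variant="euclidean"` switch reports sqrt(s_x^2 + s_y^2) instead
  (larger by sqrt(2) for isotropic error), and `ddof=0` gives the
  divisor-n sensitivity check; the report names the variant used.
* Tracks from several fields of view may be concatenated before the
  median (pooled reporting).

## Linear drift

Lateral stage drift is modelled as x(t) = x0 + v_x * t (same for y),
in nm/frame. The correction `x' = x - v_x (frame - frame0)` accepts
an explicit velocity; when estimated from data, per-track
displacement-versus-frame slopes from long tracks (default minimum
length 100) are combined by length-weighted least squares, with the
analytic slope standard error propagated to the result. Before the
weighted combination, tracks whose slope lies more than 5 robust
scales (1.4826 x weighted MAD) from the weighted median are discarded:
on dense structures the linker occasionally chains *different* nearby
emitters into a long pseudo-track whose slope is wild, and a handful
of such chains can otherwise outvote the genuine fiducial tracks. On
clean fiducial data nothing is rejected and the estimator is exactly
the weighted least-squares one.

## Rendering

Super-resolution images are 2-D count histograms at a fixed pixel size
(default 10 nm). Pixel (i, j) covers the half-open square
[origin + j*px, origin + (j+1)*px) x [...] — a localization exactly on
an interior boundary lands in the higher-index pixel (floor
convention) — and pixel centres sit at origin + (index + 0.5) * px,
the convention shared by all landmark and centroid code. In-field
counts are conserved exactly; out-of-field localizations are counted
on the image object.

The Rab5 channel receives a post-rendering median filter of radius 0
or 1 pixel (3x3 neighbourhood; edge pixels use the in-image
neighbourhood only) to suppress the monomeric cytosolic signal, which
renders as isolated single-count pixels. Radii outside {0, 1} are
rejected.

## Endosome-area proxy and nanodomain morphometry

The total endosomal area is approximated from the **combined** cargo +
Rab5 signal, without ultrastructural confirmation. Channels are
normalized to [0, 1] and combined by pixel-wise maximum. The
normalization scale is the 99.5th percentile of each channel's
positive pixels (clipped to 1) rather than the raw maximum: in a count
histogram the single brightest pixel is an unstable scale (one
persistent bright emitter, or a Poisson extreme, would crush the rest
of the channel below the segmentation threshold); the percentile
preserves the intent — no channel's dynamic range dominates — robustly.

Segmentation of the combined image (endosome proxy) and of the Rab5
image (nanodomains) follows the same chain: Gaussian blur with sigma =
2 rendered pixels (20 nm; the source tool's "radius" is read as sigma,
configurable), IsoData auto-threshold, binarize at >= T, fill enclosed
holes (background regions not connected to the border), label with
8-connectivity, and drop components below 4 px² (the area floor).

**IsoData** is iterative intermeans on a 256-bin histogram:
T_{k+1} = (mean below T_k + mean above T_k)/2 to a fixed point,
reported in intensity units. It is equivariant under affine intensity
maps to within a bin width, and agrees with an exhaustive scan of all
bin splits at histogram-bin resolution (both properties are tested;
scikit-image's implementation serves as an independent cross-check).
A constant image raises a degenerate-input error.

**Particle measurement.** Area = pixel count x px². Shape comes from
the second-central-moment matrix of the component's pixels under a
unit-square pixel model (each pixel contributes 1/12 to the diagonal
moments, so 1-pixel-wide components keep a nonzero minor axis). The
axis *ratio* is the square root of the eigenvalue ratio; the ellipse
is rescaled so pi*a*b equals the component area (area-matched moment
ellipse, the same convention as common particle analyzers); the
reported diameter is the mean of major and minor axes, with both axes
exported so either convention can be recovered.

**Size estimate and broadening.** The global-threshold mask of a
blurred sub-diffraction particle extends down the blur halo: with the
20 nm analysis blur, a 55 nm disc measures ~75 nm on the raw IsoData
mask (the threshold lands near 30% of the blurred peak). Domain *sizes*
are therefore measured on a per-particle refinement of the mask to the
half-maximum support of the blurred intensity — classic FWHM sizing,
which is independent of where the global threshold landed — while
*counting* and covered-area statistics keep the unrefined IsoData
components. Raw mask-based diameters are exported alongside
(`diameter_mask_nm`) for comparison with threshold-mask tools. The
residual broadening of the half-max estimate grows monotonically with
localization error (tested at sigma = 2, 5, 10, 20 nm); at sigma =
5 nm it is ~+7%, at 10 nm ~+15% for 55 nm domains.

**Per-endosome aggregation.** The quantified structures are
cargo-and-Rab5 *triple positive*: combined-mask components lacking at
least 20 raw counts from every channel are dropped (diffuse background
blobs otherwise register as zero-domain endosomes). Each Rab5 domain
is assigned to the endosome component containing its centroid; a
centroid on background snaps to the nearest component within 50 nm,
else the domain is excluded and counted as unassigned. Per endosome
the pipeline reports domain count, covered area (union of member
domain pixels), and coverage fraction; the population summary carries
mean ± SD of counts and diameters, the singleton (count = 1) subset,
and OLS fits of covered area vs count and count vs endosome area.

**Fiducial exclusion.** Rod fiducials are broadband and would enter
every channel's morphometry. Their footprint — large
(>= 2x10^5 nm²), elongated (moment axis ratio >= 2.5; rods are >= 1000
x 300 nm, aspect >= 3.3 before halo dilation) components of the summed
any-signal support — is masked out of the images before thresholding.
Always-on fiducial emitters render as extreme single-pixel count
spikes (hundreds of counts against ~10 for the brightest genuine
structure pixels) that would skew the IsoData histogram even when
their rod evades the shape test, so pixels above 10x the 99th
percentile of a channel's positive pixels are masked as well, and any
rod-shaped component that still survives segmentation is removed from
the masks.

## Registration and overlay precision

Landmarks come from rod fiducials in two modes, matching how
cross-cut and lengthwise-cut rods are used: the intensity centre of
mass of an ROI encircling the rod, and the two **endpoints along the
principal axis** — the points *on* the axis at the extreme signed
projections of the component pixels, so a flat or ragged end face
cannot pull the reference point sideways. Endpoints are returned in a
fixed order (smaller x, then smaller y). In the automated detector the
rod silhouette is refined at half the median interior level (immune to
the blur halo and to bright spikes) and the CoM uses weights capped at
twice that level.

Transforms are least-squares fits to matched landmark pairs in nm:
similarity (closed-form Umeyama), affine (ordinary least squares on
homogeneous coordinates — the scikit-image affine estimator minimizes
a different, normalized total-least-squares criterion and is not
used), rigid (Kabsch, scale locked — the automated surrogate for
"manual refinement without changing the scale"), and thin-plate spline
with bending-energy regularization lambda (lambda = 0 interpolates;
lambda -> infinity approaches the affine fit; both properties are
tested). RMS landmark residuals are stored on the model; EM-side
coordinates enter in nm via the EM pixel size.

Overlay precision is the Euclidean distance between matched landmarks
after alignment, reported **both** as mean ± SD and median ± MAD (MAD
unscaled). Because an in-sample residual understates the error, the
default is leave-one-out: each fiducial is scored by a transform
fitted to all the others. Under isotropic per-axis jitter sigma the
distances are Rayleigh; the median is sigma*sqrt(2 ln 2), the oracle
used in the tests.

Fiducial correspondence across modalities: channel pairs share the
camera frame, so landmarks pair by mutual nearest neighbour. For
SMLM-to-EM the generator's exact landmark table stands in for the
manual fiducial picking of the original workflow — it resolves *which*
rod matches which; the transform is always re-fitted from the
extracted coordinates.

## The synthetic-data generator

The generator is the acceptance surface: it produces scenes with known
ground truth and localization streams that exercise every module.

Scene model (defaults in parentheses): circular endosomes (radius
150–400 nm, >= 600 nm edge clearance) carrying disc-shaped membrane
nanodomains centred on the contour (diameter 55 nm, minimum arc gap
40 nm, non-overlapping where feasible with an equal-spacing fallback),
roughly radial tubules (Poisson(1) per endosome, 200–800 nm), and
capsule-shaped rod fiducials (4 per field, tip-to-tip length 1–3 µm,
width 300 nm) placed clear of endosomes. The reference preset draws
domain counts as Poisson with mean proportional to endosome radius
(population mean 5) — matching the observation that larger endosomes
carry more domains and avoiding geometrically impossible crowding of
55 nm domains on the smallest endosomes; fixed-K benchmark scenes use
exact counts on 250–400 nm endosomes.

Channel assignment mirrors the biology: the EGF-like channel samples
the endosome lumen (disc to 0.95 r — in projection, luminal cargo
extends essentially to the membrane), the Tfn-like channel samples the
membrane ring (0.5 emitters/nm of contour, ~10 nm radial spread;
"densely labeled ring-like" structures) and the tubules, and the
Rab5 channel samples the domain discs (0.02 emitters/nm²). Rods emit
in every channel (0.005 emitters/nm², the dense quasi-continuous
coverage of strongly autofluorescent fiducials), plus two always-on,
bright, stably-fitted emitters per rod that provide the long tracks a
linear drift fit needs.

Stream model: each emitter switches on once at a uniform random frame
for a geometrically distributed number of consecutive frames (mean 3)
— a memoryless blinking surrogate; re-blinking, dark-state kinetics
and photon-count/precision coupling are deliberately not modelled
(localizations, not photophysics, are the unit under test). Each
on-frame yields one localization at the emitter position plus
isotropic Gaussian error (sigma 10 nm per channel by default; 5 nm in
the recovery benchmarks), a lognormal photon count whose per-channel
median sits above the standard amplitude threshold, and a Gaussian PSF
FWHM (330 ± 40 nm). Uniform background localizations arrive at
0.01 /µm²/frame ("cytosolic monomers"). Linear drift (preset
(0.02, −0.01) nm/frame over 2000 frames) displaces recorded positions
by v * frame. Every localization is traceable to its structure id;
everything is deterministic under (spec, model, seed).

What passing tests therefore do **not** show about real data: the
generator has no re-blinking (precision statistics on real data mix
repeated blink trains), no spatially structured background, no
astigmatism or depth-dependent PSF, no chromatic aberration beyond the
registration transform, and perfectly circular endosomes; recovery
numbers quantify the pipeline under the stated noise model, not
instrument-specific systematics.

## Problem sizes and numerical choices

* Recovery benchmark: 50 endosomes per condition, K = 1..8, sigma =
  5 nm, 20x20 µm fields — chosen to give ~2% counting noise per cell
  while a full sweep runs in a couple of minutes.
* Precision oracle: 1e5 tracks of length 5 (2% tolerance against the
  Monte-Carlo oracle) and 1e4 tracks of length 50 (1% convergence to
  sigma).
* Drift benchmark: 20 fiducial tracks of 20 000 frames at sigma =
  5 nm; the analytic slope SE is ~9e-7 nm/frame.
* Ties, degenerate inputs: linking ties -> lowest record index;
  constant images -> error; collinear affine landmarks -> error;
  empty track set -> error instructing an explicit drift model;
  all tolerances for float comparisons are stated in the tests.

## Known limitations

* The endosome-area proxy inherits the original caveat: combined
  signal, no ultrastructural confirmation; touching endosomes merge
  into one component.
* Domain counting saturates when domain spacing approaches the 20 nm
  analysis blur (crowded small endosomes); the size estimate carries
  the documented sigma-dependent broadening.
* The drift model is strictly linear; no spline or redundant
  cross-correlation drift correction.
* Image resampling under a fitted transform supports the linear
  models only (points map under any model including TPS).
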