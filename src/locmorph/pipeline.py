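"""Workflow orchestration: domain analysis, overlay QC, recovery benchmark.

Three workflows tie the library modules together:

* **domain analysis** — per-channel filtering, linear drift correction,
  10 nm histogram rendering, Rab5 median filtering, multicolor
  combination, IsoData segmentation of the endosome-area proxy and of
  the Rab5 nanodomain channel, particle measurement and per-endosome
  statistics (plus per-channel localization-precision estimates from
  the same tracks the drift fit uses).
* **overlay QC** — rod-fiducial landmark extraction (centre-of-mass
  and endpoint modes) per channel and optionally against an EM
  reference, transform fitting, and leave-one-out overlay-precision
  reports.
* **recovery benchmark** — a sweep over generator ground truth
  (domains per endosome, diameter, localization error) scoring the
  bias of the recovered morphometry.

All randomness flows from the single config seed; two runs with the
same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .drift import (
    DriftModel,
    apply_drift,
    estimate_linear_drift,
    estimate_precision,
    link_consecutive,
)
from .loc_table import FilterSpec, LocalizationTable, filter_localizations, read_localizations
from .morphometry import (
    domains_to_dataframe,
    endosome_domain_stats,
    endosomes_to_dataframe,
    halfmax_refine,
    measure_domains,
    moment_axis_ratio,
    isodata_threshold,
    segment_structures,
)
from .registration import (
    PointMatch,
    fiducial_center_of_mass,
    fiducial_endpoints,
    fit_transform,
    leave_one_out_precision,
)
from .render import RenderedImage, RenderSpec, combine_channels, median_filter_image, render_histogram
from . import synth

#: Standard per-dye amplitude thresholds (photons) keyed by channel label.
DEFAULT_PHOTON_MIN = {"egf": 3000.0, "tfn": 1500.0, "rab5": 450.0}


@dataclass
class ChannelConfig:
    path: str | None = None
    dialect: str = "csv"
    fwhm_min: float = 250.0
    fwhm_max: float = 450.0
    photon_min: float | None = None  # None -> per-dye default by channel name

    def filter_spec(self, channel: str) -> FilterSpec:
        pmin = self.photon_min
        if pmin is None:
            pmin = DEFAULT_PHOTON_MIN.get(channel, 0.0)
        return FilterSpec(self.fwhm_min, self.fwhm_max, pmin)


@dataclass
class RunConfig:
    """Run configuration for all workflows (YAML-serializable)."""

    seed: int = 0
    output_dir: str = "locmorph_out"
    channels: dict = field(default_factory=dict)  # name -> ChannelConfig
    rab5_channel: str = "rab5"
    pixel_size: float = 10.0
    extent: tuple | None = None  # nm, None -> auto from data
    blur_radius: float = 2.0
    min_area: int = 4
    median_radius: int = 1
    combine_percentile: float = 99.5
    snap_radius: float = 50.0
    drift_mode: str = "estimate"  # estimate | explicit | none
    drift_velocity: tuple = (0.0, 0.0)
    min_track_length: int = 100
    link_radius: float = 104.0
    model_kind: str = "similarity"
    min_rod_area_nm2: float = 2.0e5
    # rods are >= 1000 x 300 nm (aspect 3.3); the blur halo dilates the
    # support and lowers the measured moment ratio to ~2.6-3
    min_rod_elongation: float = 2.5
    # support level (counts) for rod detection: above the blurred
    # footprint of an isolated localization (~1/(2 pi blur^2) ~ 0.04)
    rod_support_level: float = 0.1
    em_pixel_size: float = 20.0
    exclude_fiducials: bool = True
    # the quantified endosomes are triple positive: a combined-mask
    # component must contain raw signal from every channel
    require_all_channels: bool = True
    min_channel_counts: float = 20.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        channels = {
            name: ChannelConfig(**c) for name, c in (raw.pop("channels", {}) or {}).items()
        }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(channels=channels, **raw)
        if cfg.extent is not None:
            cfg.extent = tuple(float(v) for v in cfg.extent)
        cfg.drift_velocity = tuple(float(v) for v in cfg.drift_velocity)
        return cfg

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)  # hash the analysis, not its destination
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _provenance(cfg: RunConfig) -> str:
    return f"# locmorph v{__version__} config={cfg.digest()} seed={cfg.seed}"


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _write_json(obj: dict, path: Path, cfg: RunConfig) -> None:
    payload = {"provenance": _provenance(cfg).lstrip("# "), **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)


def load_channel_tables(cfg: RunConfig) -> dict[str, LocalizationTable]:
    tables = {}
    for name, ch in cfg.channels.items():
        if ch.path is None:
            raise ValueError(f"channel {name!r} has no input path")
        tables[name] = read_localizations(ch.path, dialect=ch.dialect, channel=name)
    return tables


# ---------------------------------------------------------------------------
# Domain analysis
# ---------------------------------------------------------------------------


@dataclass
class DomainAnalysisResult:
    """Bundle returned by the domain-analysis workflow.

    ``domains`` carries the half-maximum-refined size estimates used by
    the summary; ``domains_mask_based`` the raw IsoData-mask
    measurements (same labels) for comparison with tools that size on
    the global threshold mask.
    """

    images: dict
    combined: RenderedImage
    combined_mask: np.ndarray
    rab5_mask: np.ndarray
    domains: list
    domains_mask_based: list
    endosomes: list
    summary: object
    precision: dict
    drift_models: dict
    log: list


def _auto_extent(tables: dict[str, LocalizationTable], pixel_size: float) -> tuple:
    xy = np.vstack([t.xy for t in tables.values() if len(t)])
    x0, y0 = np.floor(xy.min(0) / pixel_size) * pixel_size
    x1, y1 = np.ceil(xy.max(0) / pixel_size) * pixel_size
    return (float(x0), float(x1), float(y0), float(y1))


def fiducial_footprint(
    images: dict[str, RenderedImage], cfg: RunConfig, dilate_px: int = 5
) -> np.ndarray:
    """Boolean mask of rod-fiducial support across all channels.

    Rod fiducials are broadband (visible in every channel), large and
    elongated; their footprint is detected on the summed any-signal
    support and dilated.  Masking them out of the channel images before
    thresholding keeps their bright persistent emitters from skewing
    the IsoData histogram of the endosome analysis.
    """
    from scipy import ndimage

    total = np.zeros(next(iter(images.values())).shape)
    for im in images.values():
        total += im.grid
    blurred = ndimage.gaussian_filter(total, cfg.blur_radius)
    labels, n = ndimage.label(
        blurred > cfg.rod_support_level, structure=np.ones((3, 3), bool)
    )
    min_px = cfg.min_rod_area_nm2 / cfg.pixel_size**2
    mask = np.zeros(total.shape, dtype=bool)
    objs = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = objs[lab - 1]
        rr, cc = np.nonzero(labels[sl] == lab)
        if len(rr) < min_px:
            continue
        if moment_axis_ratio(rr.astype(float), cc.astype(float)) >= cfg.min_rod_elongation:
            mask[sl] |= labels[sl] == lab
    if mask.any() and dilate_px:
        mask = ndimage.binary_dilation(mask, iterations=dilate_px)
    return mask


def analyze_tables(
    tables: dict[str, LocalizationTable], cfg: RunConfig
) -> DomainAnalysisResult:
    """Run the domain-analysis workflow on in-memory channel tables."""
    if len(tables) < 2:
        raise ValueError("domain analysis needs >= 2 channels (cargo + Rab5)")
    if cfg.rab5_channel not in tables:
        raise ValueError(f"Rab5 channel {cfg.rab5_channel!r} not among inputs")
    log: list[str] = []

    # 1. record-level filtering
    filtered = {}
    for name, t in tables.items():
        ch_cfg = cfg.channels.get(name, ChannelConfig())
        ft = filter_localizations(t, ch_cfg.filter_spec(name))
        d = ft.metadata["filter_discards"]
        log.append(
            f"filter[{name}]: kept {len(ft)}/{len(t)} "
            f"(fwhm -{d['fwhm']}, photons -{d['photons']})"
        )
        filtered[name] = ft

    # 2. drift correction + per-channel precision from the same tracks
    drift_models: dict[str, DriftModel] = {}
    precision: dict[str, object] = {}
    corrected = {}
    for name, t in filtered.items():
        tracks = link_consecutive(t, cfg.link_radius)
        if cfg.drift_mode == "estimate":
            model = estimate_linear_drift(tracks, cfg.min_track_length)
        elif cfg.drift_mode == "explicit":
            model = DriftModel(*cfg.drift_velocity, method="explicit")
        elif cfg.drift_mode == "none":
            model = DriftModel(0.0, 0.0, method="none")
        else:
            raise ValueError(f"unknown drift_mode {cfg.drift_mode!r}")
        ct = apply_drift(t, model)
        drift_models[name] = model
        log.append(
            f"drift[{name}]: ({model.vx:+.4f}, {model.vy:+.4f}) nm/frame ({model.method})"
        )
        tracks_c = link_consecutive(ct, cfg.link_radius)
        if tracks_c:
            precision[name] = estimate_precision(tracks_c)
            log.append(
                f"precision[{name}]: median {precision[name].median_precision:.2f} nm "
                f"from {precision[name].n_tracks} tracks"
            )
        corrected[name] = ct

    # 3. rendering
    extent = cfg.extent or _auto_extent(corrected, cfg.pixel_size)
    spec = RenderSpec(pixel_size=cfg.pixel_size, extent=extent)
    images = {name: render_histogram(t, spec) for name, t in corrected.items()}
    for name, im in images.items():
        log.append(f"render[{name}]: {im.shape} px, {im.n_out_of_field} out of field")

    # 4. Rab5 post-localization median filter, then combination
    images[cfg.rab5_channel] = median_filter_image(
        images[cfg.rab5_channel], cfg.median_radius
    )
    # the morphometry works on copies with the fiducial signal removed;
    # the rendered images themselves (returned to the caller, used by
    # overlay QC) keep the rods
    morph_images = images
    if cfg.exclude_fiducials:
        rod_mask = fiducial_footprint(images, cfg)
        # persistent fiducial emitters render as extreme single-pixel
        # count spikes (hundreds of counts vs ~10 for the brightest
        # structure pixels); mask them even when their rod evaded the
        # shape test, or they alone wreck the IsoData histogram
        from scipy import ndimage as _spike_ndi

        for im in images.values():
            pos = im.grid[im.grid > 0]
            if len(pos) == 0:
                continue
            level = 10.0 * np.percentile(pos, 99.0)
            spikes = im.grid > level
            if spikes.any():
                rod_mask |= _spike_ndi.binary_dilation(spikes, iterations=3)
        if rod_mask.any():
            morph_images = {
                name: RenderedImage(
                    np.where(rod_mask, 0.0, im.grid), im.pixel_size, im.origin
                )
                for name, im in images.items()
            }
            log.append(
                f"excluded rod-fiducial footprint ({int(rod_mask.sum())} px) "
                "from the morphometry images"
            )
    combined = combine_channels(list(morph_images.values()), cfg.combine_percentile)

    # 5. segmentation
    combined_mask = segment_structures(
        combined, cfg.blur_radius, cfg.min_area, fill_holes=True
    )
    rab5_mask = segment_structures(
        morph_images[cfg.rab5_channel], cfg.blur_radius, cfg.min_area, fill_holes=True
    )

    # 5a. safety net: drop rod-shaped components that survived the
    # image-level exclusion (e.g. a rod bridged to an endosome)
    if cfg.exclude_fiducials:
        for mask in (combined_mask, rab5_mask):
            dropped_rodlike = 0
            min_px = cfg.min_rod_area_nm2 / cfg.pixel_size**2
            for lab in range(1, int(mask.max()) + 1):
                rr, cc = np.nonzero(mask == lab)
                if len(rr) < min_px:
                    continue
                if (
                    moment_axis_ratio(rr.astype(float), cc.astype(float))
                    >= cfg.min_rod_elongation
                ):
                    mask[mask == lab] = 0
                    dropped_rodlike += 1
            if dropped_rodlike:
                log.append(f"dropped {dropped_rodlike} rod-shaped component(s) from a mask")
        combined_mask = _relabel(combined_mask)
        rab5_mask = _relabel(rab5_mask)

    # 5b. keep only multi-channel-positive endosome components
    from scipy import ndimage as _ndi

    if cfg.require_all_channels:
        n_comp = int(combined_mask.max())
        if n_comp:
            keep = np.ones(n_comp + 1, dtype=bool)
            keep[0] = False
            for im in morph_images.values():
                sums = _ndi.sum_labels(
                    im.grid, combined_mask, index=np.arange(1, n_comp + 1)
                )
                keep[1:] &= sums >= cfg.min_channel_counts
            dropped = int(n_comp - keep[1:].sum())
            if dropped:
                combined_mask = np.where(keep[combined_mask], combined_mask, 0)
                combined_mask = _relabel(combined_mask)
                log.append(
                    f"dropped {dropped} combined component(s) not positive in "
                    "all channels"
                )

    # 6. measurement + aggregation: particle sizes come from the
    # half-maximum-refined masks, counts from the IsoData masks
    origin = (extent[0], extent[2])
    rab5_blurred = _ndi.gaussian_filter(
        morph_images[cfg.rab5_channel].grid, cfg.blur_radius
    )
    refined = halfmax_refine(rab5_mask, rab5_blurred)
    domains = measure_domains(refined, cfg.pixel_size, origin)
    domains_mask_based = measure_domains(rab5_mask, cfg.pixel_size, origin)
    endosomes, summary = endosome_domain_stats(
        combined_mask, domains, rab5_mask, cfg.pixel_size, origin, cfg.snap_radius
    )
    log.append(
        f"morphometry: {summary.n_endosomes} endosomes, "
        f"{summary.domain_count_mean:.2f} +- {summary.domain_count_sd:.2f} domains, "
        f"diameter {summary.diameter_mean:.1f} +- {summary.diameter_sd:.1f} nm"
    )
    return DomainAnalysisResult(
        images=images,
        combined=combined,
        combined_mask=combined_mask,
        rab5_mask=rab5_mask,
        domains=domains,
        domains_mask_based=domains_mask_based,
        endosomes=endosomes,
        summary=summary,
        precision=precision,
        drift_models=drift_models,
        log=log,
    )


def _relabel(labels: np.ndarray) -> np.ndarray:
    vals = np.unique(labels)
    vals = vals[vals > 0]
    remap = np.zeros(labels.max() + 1 if labels.size else 1, dtype=labels.dtype)
    remap[vals] = np.arange(1, len(vals) + 1)
    return remap[labels]


def run_domain_analysis(
    cfg: RunConfig, tables: dict[str, LocalizationTable] | None = None
) -> DomainAnalysisResult:
    """Config-driven domain analysis; writes the report bundle to
    ``cfg.output_dir`` (tables as CSV, summary as JSON, images as TIFF,
    figures as PNG, stage log as text)."""
    if tables is None:
        tables = load_channel_tables(cfg)
    res = analyze_tables(tables, cfg)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    ddf = domains_to_dataframe(res.domains)
    mask_d = {d.label: d.diameter for d in res.domains_mask_based}
    ddf["diameter_mask_nm"] = ddf["label"].map(mask_d)
    _write_csv(ddf, out / "domains.csv", cfg)
    _write_csv(endosomes_to_dataframe(res.endosomes), out / "endosomes.csv", cfg)
    _write_json(res.summary.to_dict(), out / "summary.json", cfg)
    for name, im in res.images.items():
        im.to_tiff(out / f"render_{name}.tif")
    res.combined.to_tiff(out / "render_combined.tif")
    import tifffile

    tifffile.imwrite(out / "mask_endosomes.tif", res.combined_mask.astype(np.uint16))
    tifffile.imwrite(out / "mask_domains.tif", res.rab5_mask.astype(np.uint16))
    for name, pe in res.precision.items():
        _write_csv(pe.histogram, out / f"precision_hist_{name}.csv", cfg)
    (out / "stages.log").write_text("\n".join(res.log) + "\n")
    _figure_domains(res, out / "overview.png")
    return res


def _figure_domains(res: DomainAnalysisResult, path: Path) -> None:
    fig, axes = plt.subplots(1, 3, figsize=(13, 4.2))
    axes[0].imshow(np.sqrt(res.combined.grid), cmap="gray")
    axes[0].set_title("combined (sqrt scale)")
    axes[1].imshow(res.combined_mask > 0, cmap="gray")
    axes[1].set_title("endosome-area proxy mask")
    axes[2].imshow(res.rab5_mask > 0, cmap="gray")
    axes[2].set_title("Rab5 nanodomain mask")
    for ax in axes:
        ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=110, metadata={"Software": None})
    plt.close(fig)


# ---------------------------------------------------------------------------
# Rod-fiducial landmark extraction + overlay QC
# ---------------------------------------------------------------------------


def detect_rod_landmarks(
    image: RenderedImage,
    min_area_nm2: float = 2.0e5,
    min_elongation: float = 3.0,
    blur_sigma: float = 2.0,
    support_level: float = 0.1,
) -> pd.DataFrame:
    """Detect rod fiducials in a rendered image and extract landmarks.

    Candidate components come from any-signal support of the blurred
    image; large, elongated components are kept, then each candidate's
    mask is refined by a local IsoData threshold inside its padded
    bounding box (so the blur does not inflate the silhouette), and
    the intensity centre of mass plus the two principal-axis endpoints
    are measured.  Returns a table with columns rod_index, kind, x, y
    (nm, this image's frame).
    """
    from scipy import ndimage

    blurred = ndimage.gaussian_filter(image.grid, blur_sigma)
    labels, n = ndimage.label(
        blurred > support_level, structure=np.ones((3, 3), bool)
    )
    min_px = min_area_nm2 / image.pixel_size**2
    rows = []
    idx = 0
    objs = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = objs[lab - 1]
        comp = labels[sl] == lab
        rr, cc = np.nonzero(comp)
        if len(rr) < min_px:
            continue
        if moment_axis_ratio(rr.astype(float), cc.astype(float)) < min_elongation:
            continue
        # refinement at half the median interior level: the median is
        # immune both to the dim blur halo and to isolated bright
        # pixels (e.g. persistent fiducial emitters), either of which
        # would mislead a histogram threshold inside the bbox
        patch = blurred[sl]
        level = float(np.median(patch[comp]))
        local = comp & (patch >= 0.5 * level)
        lab2, n2 = ndimage.label(local, structure=np.ones((3, 3), bool))
        if n2 == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab2), lab2, index=np.arange(1, n2 + 1))
        local = lab2 == (int(np.argmax(sizes)) + 1)
        if local.sum() < min_px / 2:
            continue
        mask_full = np.zeros(image.shape, dtype=bool)
        mask_full[sl] = local
        try:
            p1, p2 = fiducial_endpoints(
                mask_full, image.pixel_size, image.origin, min_elongation=min_elongation
            )
        except ValueError:
            continue
        # CoM with capped weights: intensity-weighted over the rod
        # silhouette, single hot pixels limited to twice the median level
        w = np.where(local, np.minimum(patch, 2.0 * level), 0.0)
        rloc, cloc = np.mgrid[sl[0].start : sl[0].stop, sl[1].start : sl[1].stop]
        com_x = image.origin[0] + ((w * cloc).sum() / w.sum() + 0.5) * image.pixel_size
        com_y = image.origin[1] + ((w * rloc).sum() / w.sum() + 0.5) * image.pixel_size
        rows.append((idx, "center_of_mass", com_x, com_y))
        rows.append((idx, "endpoint", p1[0], p1[1]))
        rows.append((idx, "endpoint", p2[0], p2[1]))
        idx += 1
    return pd.DataFrame(rows, columns=["rod_index", "kind", "x", "y"])


def match_landmarks(
    ref: pd.DataFrame, mov: pd.DataFrame, max_dist: float = 500.0
) -> list[PointMatch]:
    """Pair landmarks of equal kind across two modalities by mutual
    nearest neighbour (assumes a coarse prealignment, as for channel
    pairs sharing the camera frame)."""
    from scipy.spatial import cKDTree

    matches = []
    fid = 0
    for kind in ("center_of_mass", "endpoint"):
        a = ref[ref["kind"] == kind][["x", "y"]].to_numpy()
        b = mov[mov["kind"] == kind][["x", "y"]].to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        ta, tb = cKDTree(a), cKDTree(b)
        d_ab, j_ab = tb.query(a)
        d_ba, i_ba = ta.query(b)
        for i in range(len(a)):
            j = int(j_ab[i])
            if d_ab[i] <= max_dist and int(i_ba[j]) == i:
                matches.append(
                    PointMatch(tuple(a[i]), tuple(b[j]), kind=kind, fiducial_id=fid)
                )
                fid += 1
    return matches


@dataclass
class OverlayQCResult:
    reports: dict  # pair label -> OverlayPrecisionReport
    transforms: dict
    log: list


def overlay_qc_images(
    images: dict[str, RenderedImage],
    cfg: RunConfig,
    reference: str | None = None,
    em_image: RenderedImage | None = None,
    em_landmarks: pd.DataFrame | None = None,
) -> OverlayQCResult:
    """Overlay QC on rendered channel images (plus optional EM reference).

    The reference channel (first by default) is fixed; every other
    channel is registered to it from rod-fiducial landmarks and scored
    by leave-one-out overlay precision.  If an EM image is supplied,
    its rods are extracted the same way and paired with the reference
    channel's rods; ``em_landmarks`` (the generator's ground-truth
    landmark table, or a user-clicked equivalent with columns
    x_smlm/y_smlm/x_em/y_em) resolves the cross-modality
    correspondence — the transform itself is always re-fitted from the
    extracted coordinates.
    """
    names = list(images)
    if reference is None:
        reference = names[0]
    lms = {
        name: detect_rod_landmarks(
            im, cfg.min_rod_area_nm2, cfg.min_rod_elongation, cfg.blur_radius,
            cfg.rod_support_level,
        )
        for name, im in images.items()
    }
    log = [f"rods[{n}]: {len(df) // 3}" for n, df in lms.items()]
    reports, transforms = {}, {}
    for name in names:
        if name == reference:
            continue
        matches = match_landmarks(lms[reference], lms[name])
        if len(matches) < 3:
            raise ValueError(
                f"insufficient fiducials between {reference} and {name} "
                f"({len(matches)} matches; need >= 2 rods)"
            )
        pair = f"{reference}-{name}"
        transforms[pair] = fit_transform(matches, cfg.model_kind)
        reports[pair] = leave_one_out_precision(
            matches, cfg.model_kind, channel_pair=pair
        )
        log.append(
            f"overlay[{pair}]: median {reports[pair].median:.2f} nm "
            f"(mad {reports[pair].mad:.2f}) over {reports[pair].n_fiducials} landmarks"
        )

    if em_image is not None:
        em_lms = detect_rod_landmarks(
            em_image, cfg.min_rod_area_nm2, cfg.min_rod_elongation, blur_sigma=1.0
        )
        if em_landmarks is None:
            matches = match_landmarks(lms[reference], em_lms)
        else:
            matches = _match_via_truth_table(lms[reference], em_lms, em_landmarks)
        if len(matches) < 3:
            raise ValueError("insufficient fiducials for SMLM-to-EM registration")
        pair = f"{reference}-em"
        # EM frame is the fixed reference: map SMLM (moving) onto EM
        em_matches = [
            PointMatch(m.p_mov, m.p_ref, m.kind, m.fiducial_id) for m in matches
        ]
        transforms[pair] = fit_transform(em_matches, cfg.model_kind)
        reports[pair] = leave_one_out_precision(
            em_matches, cfg.model_kind, channel_pair=pair
        )
        log.append(
            f"overlay[{pair}]: median {reports[pair].median:.2f} nm "
            f"(mad {reports[pair].mad:.2f}) over {reports[pair].n_fiducials} landmarks"
        )
    return OverlayQCResult(reports=reports, transforms=transforms, log=log)


def _match_via_truth_table(
    smlm_lms: pd.DataFrame, em_lms: pd.DataFrame, table: pd.DataFrame
) -> list[PointMatch]:
    """Correspondence via a landmark table giving paired nominal
    coordinates in both frames (stand-in for manual fiducial picking):
    each nominal pair adopts the nearest extracted landmark of the same
    kind on each side."""
    from scipy.spatial import cKDTree

    matches = []
    for kind in ("center_of_mass", "endpoint"):
        nom = table[table["kind"] == kind]
        s = smlm_lms[smlm_lms["kind"] == kind][["x", "y"]].to_numpy()
        e = em_lms[em_lms["kind"] == kind][["x", "y"]].to_numpy()
        if len(nom) == 0 or len(s) == 0 or len(e) == 0:
            continue
        ts, te = cKDTree(s), cKDTree(e)
        ds, is_ = ts.query(nom[["x_smlm", "y_smlm"]].to_numpy())
        de, ie = te.query(nom[["x_em", "y_em"]].to_numpy())
        used_s, used_e = set(), set()
        for k in range(len(nom)):
            si, ei = int(is_[k]), int(ie[k])
            if ds[k] > 500.0 or de[k] > 500.0 or si in used_s or ei in used_e:
                continue
            used_s.add(si)
            used_e.add(ei)
            matches.append(
                PointMatch(tuple(s[si]), tuple(e[ei]), kind=kind, fiducial_id=k)
            )
    return matches


def run_overlay_qc(
    cfg: RunConfig,
    images: dict[str, RenderedImage] | None = None,
    tables: dict[str, LocalizationTable] | None = None,
    em_image: RenderedImage | None = None,
    em_landmarks: pd.DataFrame | None = None,
) -> OverlayQCResult:
    """Config-driven overlay QC; renders channels from tables when
    images are not given and writes reports to ``cfg.output_dir``."""
    if images is None:
        if tables is None:
            tables = load_channel_tables(cfg)
        extent = cfg.extent or _auto_extent(tables, cfg.pixel_size)
        spec = RenderSpec(pixel_size=cfg.pixel_size, extent=extent)
        images = {name: render_histogram(t, spec) for name, t in tables.items()}
    res = overlay_qc_images(
        images, cfg, em_image=em_image, em_landmarks=em_landmarks
    )
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json(
        {pair: r.summary() for pair, r in res.reports.items()},
        out / "overlay_precision.json",
        cfg,
    )
    for pair, r in res.reports.items():
        _write_csv(r.histogram(), out / f"overlay_hist_{pair}.csv", cfg)
        res.transforms[pair].to_json(out / f"transform_{pair}.json")
    (out / "overlay_qc.log").write_text("\n".join(res.log) + "\n")
    return res


# ---------------------------------------------------------------------------
# Recovery benchmark
# ---------------------------------------------------------------------------


def run_recovery_benchmark(
    cfg: RunConfig,
    k_values=(1, 2, 3, 4, 5, 6, 7, 8),
    diameter: float = 55.0,
    sigmas=(5.0,),
    n_endosomes: int = 50,
    write: bool = True,
) -> pd.DataFrame:
    """Sweep generator ground truth against pipeline estimates.

    For each (K domains, localization sigma) cell a scene of
    ``n_endosomes`` endosomes with exactly K domains of the given
    diameter is simulated and analyzed; the table reports recovered
    mean count and diameter with their biases.
    """
    rows = []
    for si, sigma in enumerate(sigmas):
        for k in k_values:
            spec = synth.recovery_sweep_spec(k, diameter)
            spec = dataclasses.replace(spec, n_endosomes=n_endosomes)
            cell_seed = int(cfg.seed) * 1000 + si * 100 + k
            truth = synth.generate_scene(spec, seed=cell_seed)
            model = synth.EmitterModel(
                sigma_loc={"egf": sigma, "tfn": sigma, "rab5": sigma}
            )
            tables = synth.simulate_localizations(truth, model, seed=cell_seed + 1)
            cell_cfg = dataclasses.replace(
                cfg, drift_mode="none", extent=(0.0, spec.field_size[0], 0.0, spec.field_size[1])
            )
            res = analyze_tables(tables, cell_cfg)
            true_mean = float(truth.domain_counts().mean())
            rows.append(
                {
                    "k_true": k,
                    "sigma_nm": sigma,
                    "diameter_true_nm": diameter,
                    "n_endosomes_true": spec.n_endosomes,
                    "n_endosomes_found": res.summary.n_endosomes,
                    "count_mean_true": true_mean,
                    "count_mean_recovered": res.summary.domain_count_mean,
                    "count_bias": res.summary.domain_count_mean - true_mean,
                    "diameter_mean_recovered": res.summary.diameter_mean,
                    "diameter_bias": res.summary.diameter_mean - diameter,
                }
            )
    df = pd.DataFrame(rows)
    if write:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_csv(df, out / "recovery_benchmark.csv", cfg)
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for sigma, sub in df.groupby("sigma_nm"):
            axes[0].plot(sub["k_true"], sub["count_mean_recovered"], "o-", label=f"sigma={sigma}")
            axes[1].plot(sub["k_true"], sub["diameter_mean_recovered"], "o-", label=f"sigma={sigma}")
        axes[0].plot(df["k_true"], df["k_true"], "k--", lw=1)
        axes[0].set_xlabel("true domains per endosome")
        axes[0].set_ylabel("recovered mean count")
        axes[1].axhline(diameter, color="k", ls="--", lw=1)
        axes[1].set_xlabel("true domains per endosome")
        axes[1].set_ylabel("recovered mean diameter (nm)")
        for ax in axes:
            ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "recovery_benchmark.png", dpi=110, metadata={"Software": None})
        plt.close(fig)
    return df
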