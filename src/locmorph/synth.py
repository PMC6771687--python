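"""Ground-truth scene and localization-stream simulator.

Emulates triple-channel SMLM acquisitions of early endosomes in thin
sections: endosomes are circles (limiting membrane) bearing disc-shaped
membrane nanodomains (the Rab5 channel), diffuse luminal cargo (the
EGF-like channel), membrane + tubule cargo (the Tfn-like channel),
rod-shaped broadband fiducials (bacteria surrogates, emitting in every
channel), uniform "cytosolic monomer" background localizations, linear
stage drift, and an EM-pixel reference image related to the SMLM frame
by a known transform.  Every simulated localization is traceable to a
structure id, and the generator is fully deterministic under a seed —
it is the ground-truth oracle for the analysis modules.

Blinking is reduced to what the downstream statistics see: each
emitter switches on once, at a uniformly random frame, for a
geometrically distributed number of consecutive frames (memoryless
on-time surrogate); per-frame localizations scatter isotropically
(Gaussian, per-channel sigma) about the emitter position.  Full
photoswitching kinetics (dark-state recovery, re-blinks) are out of
scope: localizations, not photophysics, are the unit under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loc_table import LocalizationTable
from .render import RenderedImage

CHANNELS = ("egf", "tfn", "rab5")

STRUCT_COLUMNS = [
    "id", "kind", "parent", "cx", "cy", "radius", "theta",
    "diameter", "length", "width", "x2", "y2",
]


class PackingError(RuntimeError):
    """Scene structures could not be placed without overlap."""


def _dist_spec_sample(rng: np.random.Generator, spec, size=None):
    """Sample from a small distribution spec: ("fixed", v),
    ("poisson", mean), ("uniform", lo, hi), ("normal", mean, sd)."""
    kind = spec[0]
    if kind == "fixed":
        return np.full(size, spec[1]) if size is not None else spec[1]
    if kind == "poisson":
        return rng.poisson(spec[1], size=size)
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size=size)
    if kind == "normal":
        return rng.normal(spec[1], spec[2], size=size)
    raise ValueError(f"unknown distribution spec {spec!r}")


@dataclass(frozen=True)
class SceneSpec:
    """Geometry of one synthetic field of view (all lengths nm).

    Defaults describe the regime the analysis targets: endosomes of
    150-400 nm radius carrying on average five ~55 nm membrane
    nanodomains, occasional tubules, a few micron-scale rod fiducials,
    sparse monomer background, and a slow linear drift.
    """

    field_size: tuple = (10_000.0, 10_000.0)
    n_endosomes: int = 12
    endosome_radius: tuple = (150.0, 400.0)
    domains_per_endosome: tuple = ("poisson", 5.0)
    min_domains: int = 1
    domain_diameter: tuple = ("fixed", 55.0)
    domain_gap: float = 40.0  # min edge-to-edge arc gap between domains
    tubules_per_endosome: tuple = ("poisson", 1.0)
    tubule_length: tuple = (200.0, 800.0)
    background_rate: float = 0.01  # localizations per um^2 per frame
    n_rods: int = 4
    rod_length: tuple = (1000.0, 3000.0)
    rod_width: float = 300.0
    margin: float = 600.0
    endosome_separation: float = 600.0  # min edge-to-edge clearance
    n_frames: int = 2000
    drift: tuple = (0.0, 0.0)  # nm per frame


@dataclass(frozen=True)
class EmitterModel:
    """Per-channel emitter statistics.

    Densities: domains and rods carry area densities (per nm^2),
    membranes and tubules carry contour densities (per nm).  Photon
    counts are lognormal per channel, parameterized by (median,
    sigma_log); medians sit comfortably above the standard per-dye
    amplitude thresholds (3000 / 1500 / 450 photons) so those act as
    plausible cut points on the simulated streams.  Localization error
    is isotropic Gaussian with per-channel sigma (default 10 nm).
    """

    domain_density: float = 0.02        # nm^-2, Rab5 channel
    lumen_density: float = 0.002        # nm^-2, EGF channel
    lumen_radius_fraction: float = 0.95  # luminal signal extent vs radius
    membrane_density: float = 0.5       # nm^-1, Tfn channel (dense,
    # continuous ring labeling)
    tubule_density: float = 0.5         # nm^-1, Tfn channel
    rod_density: float = 0.005          # nm^-2, every channel (dense,
    # quasi-continuous autofluorescence coverage)
    background_photon_factor: float = 1.0
    mean_on_frames: float = 3.0
    n_persistent_per_rod: int = 2       # always-on fiducial emitters
    photon_median: dict = field(
        default_factory=lambda: {"egf": 6000.0, "tfn": 3000.0, "rab5": 900.0}
    )
    photon_sigma_log: float = 0.5
    sigma_loc: dict = field(
        default_factory=lambda: {"egf": 10.0, "tfn": 10.0, "rab5": 10.0}
    )
    psf_fwhm_mean: float = 330.0
    psf_fwhm_sd: float = 40.0
    membrane_thickness_sigma: float = 10.0


@dataclass
class GroundTruth:
    """The generated scene: structure table plus true nuisance models."""

    structures: pd.DataFrame
    spec: SceneSpec
    seed: int
    drift: tuple = (0.0, 0.0)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.structures[self.structures["kind"] == kind]

    @property
    def endosomes(self) -> pd.DataFrame:
        return self.of_kind("endosome")

    @property
    def domains(self) -> pd.DataFrame:
        return self.of_kind("domain")

    @property
    def rods(self) -> pd.DataFrame:
        return self.of_kind("rod")

    def domain_counts(self) -> pd.Series:
        """True number of domains per endosome id."""
        counts = self.domains.groupby("parent").size()
        return counts.reindex(self.endosomes["id"], fill_value=0)

    def rod_landmarks(self) -> pd.DataFrame:
        """Exact rod landmark coordinates (nm, SMLM frame): centre of
        mass and the two axis endpoints per rod."""
        rows = []
        for r in self.rods.itertuples():
            dx, dy = math.cos(r.theta), math.sin(r.theta)
            h = r.length / 2.0
            rows.append((int(r.id), "center_of_mass", r.cx, r.cy))
            for s in (-1.0, 1.0):
                rows.append(
                    (int(r.id), "endpoint", r.cx + s * h * dx, r.cy + s * h * dy)
                )
        return pd.DataFrame(rows, columns=["fiducial_id", "kind", "x", "y"])

    def to_csv(self, path) -> None:
        self.structures.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------


def _place_nonoverlapping(
    rng, n, radii, field, margin, clearance, existing=(), max_tries=500
):
    """Rejection-place n discs of given radii; returns (n, 2) centres."""
    w, h = field
    centers = list(existing)
    placed = []
    for k in range(n):
        r = radii[k]
        lo_x, hi_x = margin + r, w - margin - r
        lo_y, hi_y = margin + r, h - margin - r
        if not (hi_x > lo_x and hi_y > lo_y):
            raise PackingError("field too small for structure radius + margin")
        for _ in range(max_tries):
            c = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])
            ok = all(
                np.hypot(*(c - pc)) >= r + pr + clearance for pc, pr in centers
            )
            if ok:
                centers.append((c, r))
                placed.append(c)
                break
        else:
            raise PackingError(
                f"could not place structure {k + 1}/{n} after {max_tries} tries"
            )
    return np.array(placed)


def _point_segment_dist(p, a, b) -> float:
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return float(np.hypot(*(p - (a + t * ab))))


def _segment_segment_dist(p1, p2, q1, q2) -> float:
    return min(
        _point_segment_dist(p1, q1, q2),
        _point_segment_dist(p2, q1, q2),
        _point_segment_dist(q1, p1, p2),
        _point_segment_dist(q2, p1, p2),
    )


def _place_domain_angles(rng, k, radius, diameters, gap, max_tries=200):
    """Angles of k non-overlapping arc discs on a circle of given radius."""
    arc = (np.asarray(diameters) + gap) / radius  # angular footprint
    if arc.sum() > 2 * np.pi:
        raise PackingError(
            f"{k} domains of mean diameter {np.mean(diameters):.0f} nm do not "
            f"fit on a circle of radius {radius:.0f} nm"
        )
    for _ in range(max_tries):
        ang = np.sort(rng.uniform(0, 2 * np.pi, size=k))
        gaps_ok = True
        for i in range(k):
            j = (i + 1) % k
            sep = (ang[j] - ang[i]) % (2 * np.pi)
            if sep < (arc[i] + arc[j]) / 2:
                gaps_ok = False
                break
        if gaps_ok:
            return ang
    # deterministic fallback: equal spacing with a random phase
    phase = rng.uniform(0, 2 * np.pi)
    return (phase + np.arange(k) * 2 * np.pi / k) % (2 * np.pi)


def generate_scene(spec: SceneSpec, seed: int) -> GroundTruth:
    """Generate a ground-truth scene deterministically from (spec, seed)."""
    rng = np.random.default_rng(seed)
    rows = []
    next_id = 0

    radii = rng.uniform(*spec.endosome_radius, size=spec.n_endosomes)
    centers = _place_nonoverlapping(
        rng, spec.n_endosomes, radii, spec.field_size, spec.margin,
        spec.endosome_separation,
    )
    endo_ids = []
    for k in range(spec.n_endosomes):
        rows.append(
            dict(id=next_id, kind="endosome", parent=-1, cx=centers[k, 0],
                 cy=centers[k, 1], radius=radii[k], theta=np.nan,
                 diameter=np.nan, length=np.nan, width=np.nan,
                 x2=np.nan, y2=np.nan)
        )
        endo_ids.append(next_id)
        next_id += 1

    for k, eid in enumerate(endo_ids):
        dspec = spec.domains_per_endosome
        if dspec[0] == "poisson_scaled":
            # larger endosomes carry more domains: Poisson mean scales
            # with radius, preserving the population mean
            lam = dspec[1] * radii[k] / np.mean(spec.endosome_radius)
            n_dom = int(rng.poisson(lam))
        else:
            n_dom = int(_dist_spec_sample(rng, dspec))
        n_dom = max(n_dom, spec.min_domains)
        diams = np.atleast_1d(
            _dist_spec_sample(rng, spec.domain_diameter, size=n_dom)
        ).astype(float)
        diams = np.clip(diams, 15.0, None)  # sub-15 nm domains are unresolvable
        angles = _place_domain_angles(rng, n_dom, radii[k], diams, spec.domain_gap)
        for a, d in zip(angles, diams):
            rows.append(
                dict(id=next_id, kind="domain", parent=eid,
                     cx=centers[k, 0] + radii[k] * math.cos(a),
                     cy=centers[k, 1] + radii[k] * math.sin(a),
                     radius=radii[k], theta=a, diameter=float(d),
                     length=np.nan, width=np.nan, x2=np.nan, y2=np.nan)
            )
            next_id += 1

        n_tub = int(_dist_spec_sample(rng, spec.tubules_per_endosome))
        for _ in range(n_tub):
            a = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(*spec.tubule_length)
            x1 = centers[k, 0] + radii[k] * math.cos(a)
            y1 = centers[k, 1] + radii[k] * math.sin(a)
            aa = a + rng.normal(0.0, 0.3)  # roughly radial
            rows.append(
                dict(id=next_id, kind="tubule", parent=eid, cx=x1, cy=y1,
                     radius=np.nan, theta=aa, diameter=np.nan, length=length,
                     width=np.nan, x2=x1 + length * math.cos(aa),
                     y2=y1 + length * math.sin(aa))
            )
            next_id += 1

    # rods: capsules kept clear of endosomes (and each other)
    rod_lengths = rng.uniform(*spec.rod_length, size=spec.n_rods)
    placed_rods = []  # (p1, p2, half_width)
    for k in range(spec.n_rods):
        length, hw = rod_lengths[k], spec.rod_width / 2.0
        for _ in range(500):
            theta = rng.uniform(0, np.pi)
            half = np.array([math.cos(theta), math.sin(theta)]) * length / 2.0
            reach = np.abs(half) + hw + spec.margin
            lo = reach
            hi = np.array(spec.field_size) - reach
            if not np.all(hi > lo):
                raise PackingError("field too small for a rod fiducial + margin")
            c = rng.uniform(lo, hi)
            p1, p2 = c - half, c + half
            ok = all(
                _point_segment_dist(centers[e], p1, p2)
                >= radii[e] + hw + 300.0
                for e in range(spec.n_endosomes)
            ) and all(
                _segment_segment_dist(p1, p2, q1, q2) >= hw + qhw + 200.0
                for q1, q2, qhw in placed_rods
            )
            if ok:
                placed_rods.append((p1, p2, hw))
                rows.append(
                    dict(id=next_id, kind="rod", parent=-1, cx=c[0], cy=c[1],
                         radius=np.nan, theta=theta, diameter=np.nan,
                         length=length, width=spec.rod_width,
                         x2=np.nan, y2=np.nan)
                )
                next_id += 1
                break
        else:
            raise PackingError(f"could not place rod {k + 1}/{spec.n_rods}")

    df = pd.DataFrame(rows, columns=STRUCT_COLUMNS)
    return GroundTruth(structures=df, spec=spec, seed=seed, drift=spec.drift)


# ---------------------------------------------------------------------------
# Emitter placement on structures
# ---------------------------------------------------------------------------


def _sample_disc(rng, n, cx, cy, radius):
    r = radius * np.sqrt(rng.uniform(size=n))
    a = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([cx + r * np.cos(a), cy + r * np.sin(a)])


def _sample_capsule(rng, n, cx, cy, theta, length, width):
    """Uniform points in a capsule of tip-to-tip ``length`` (rectangle
    of length - width plus semicircular end caps): rejection sampling
    in the axis-aligned frame, then rotation."""
    half_l, half_w = length / 2.0, width / 2.0
    body = max(half_l - half_w, 0.0)  # half-length of the straight part
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        m = (n - got) * 2 + 8
        u = rng.uniform(-half_l, half_l, size=m)
        v = rng.uniform(-half_w, half_w, size=m)
        ax = np.clip(u, -body, body)
        keep = (u - ax) ** 2 + v**2 <= half_w**2
        take = min(keep.sum(), n - got)
        sel = np.flatnonzero(keep)[:take]
        pts[got : got + take, 0] = u[sel]
        pts[got : got + take, 1] = v[sel]
        got += take
    c, s = math.cos(theta), math.sin(theta)
    return np.column_stack(
        [cx + c * pts[:, 0] - s * pts[:, 1], cy + s * pts[:, 0] + c * pts[:, 1]]
    )


def _channel_emitters(rng, truth: GroundTruth, model: EmitterModel, channel: str):
    """Emitter positions + owning structure ids for one channel."""
    pos, sid = [], []

    def add(p, i):
        if len(p):
            pos.append(p)
            sid.append(np.full(len(p), i, dtype=np.int64))

    if channel == "rab5":
        for d in truth.domains.itertuples():
            area = np.pi * (d.diameter / 2.0) ** 2
            n = rng.poisson(model.domain_density * area)
            add(_sample_disc(rng, n, d.cx, d.cy, d.diameter / 2.0), d.id)
    elif channel == "egf":
        # luminal cargo projects essentially to the membrane radius
        for e in truth.endosomes.itertuples():
            r_lum = model.lumen_radius_fraction * e.radius
            n = rng.poisson(model.lumen_density * np.pi * r_lum**2)
            add(_sample_disc(rng, n, e.cx, e.cy, r_lum), e.id)
    elif channel == "tfn":
        for e in truth.endosomes.itertuples():
            n = rng.poisson(model.membrane_density * 2 * np.pi * e.radius)
            a = rng.uniform(0, 2 * np.pi, size=n)
            rr = e.radius + rng.normal(0, model.membrane_thickness_sigma, size=n)
            add(
                np.column_stack([e.cx + rr * np.cos(a), e.cy + rr * np.sin(a)]),
                e.id,
            )
        for t in truth.of_kind("tubule").itertuples():
            n = rng.poisson(model.tubule_density * t.length)
            u = rng.uniform(size=n)
            px = t.cx + u * (t.x2 - t.cx) + rng.normal(0, 10.0, size=n)
            py = t.cy + u * (t.y2 - t.cy) + rng.normal(0, 10.0, size=n)
            add(np.column_stack([px, py]), t.id)
    else:
        raise ValueError(f"unknown channel {channel!r}")

    # broadband rods appear in every channel
    for r in truth.rods.itertuples():
        cap_area = r.length * r.width + np.pi * (r.width / 2.0) ** 2
        n = rng.poisson(model.rod_density * cap_area)
        add(_sample_capsule(rng, n, r.cx, r.cy, r.theta, r.length, r.width), r.id)

    if not pos:
        return np.empty((0, 2)), np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    pos = np.concatenate(pos)
    sid = np.concatenate(sid)

    # persistent (always-on) fiducial emitters on each rod
    pers_pos, pers_sid = [], []
    for r in truth.rods.itertuples():
        p = _sample_capsule(
            rng, model.n_persistent_per_rod, r.cx, r.cy, r.theta,
            r.length * 0.8, r.width * 0.5,
        )
        pers_pos.append(p)
        pers_sid.append(np.full(len(p), r.id, dtype=np.int64))
    if pers_pos:
        pos = np.concatenate([pos] + pers_pos)
        sid = np.concatenate([sid] + pers_sid)
        persistent = np.zeros(len(pos), dtype=bool)
        persistent[-sum(len(p) for p in pers_pos):] = True
    else:
        persistent = np.zeros(len(pos), dtype=bool)
    return pos, sid, persistent


def simulate_localizations(
    truth: GroundTruth, model: EmitterModel, seed: int
) -> dict[str, LocalizationTable]:
    """Simulate per-channel localization tables from a ground-truth scene.

    Each emitter turns on at a uniform random frame for a geometric
    number of consecutive frames (mean ``mean_on_frames``; persistent
    fiducial emitters span the whole acquisition); each on-frame
    yields one localization at the emitter position plus isotropic
    Gaussian error, a lognormal photon count and a Gaussian PSF FWHM.
    Uniform background localizations arrive Poisson-distributed at
    ``background_rate`` per um^2 per frame, and the scene's linear
    drift displaces every localization by drift * frame.  The owning
    structure id of each record (or -1 for background) is stored in
    each table's metadata under ``"structure_ids"``.
    """
    spec = truth.spec
    out: dict[str, LocalizationTable] = {}
    for ci, channel in enumerate(CHANNELS):
        rng = np.random.default_rng([seed, ci])
        pos, sid, persistent = _channel_emitters(rng, truth, model, channel)
        n_em = len(pos)
        if n_em:
            start = rng.integers(0, spec.n_frames, size=n_em)
            on = rng.geometric(1.0 / model.mean_on_frames, size=n_em)
            start[persistent] = 0
            on = np.where(persistent, spec.n_frames, on)
            on = np.minimum(on, spec.n_frames - start)
            frames = np.concatenate(
                [np.arange(s, s + o) for s, o in zip(start, on)]
            )
            rep = np.repeat(np.arange(n_em), on)
            xy = pos[rep] + rng.normal(
                0.0, model.sigma_loc[channel], size=(len(rep), 2)
            )
            struct = sid[rep]
        else:
            frames = np.empty(0, dtype=np.int64)
            xy = np.empty((0, 2))
            struct = np.empty(0, dtype=np.int64)

        # uniform monomer background
        area_um2 = spec.field_size[0] * spec.field_size[1] / 1e6
        n_bg = rng.poisson(spec.background_rate * area_um2 * spec.n_frames)
        if n_bg:
            bg_xy = np.column_stack(
                [
                    rng.uniform(0, spec.field_size[0], size=n_bg),
                    rng.uniform(0, spec.field_size[1], size=n_bg),
                ]
            )
            bg_frames = rng.integers(0, spec.n_frames, size=n_bg)
            frames = np.concatenate([frames, bg_frames])
            xy = np.vstack([xy, bg_xy])
            struct = np.concatenate([struct, np.full(n_bg, -1, dtype=np.int64)])

        n = len(frames)
        mu = math.log(model.photon_median[channel])
        photons = rng.lognormal(mu, model.photon_sigma_log, size=n)
        fwhm = np.clip(
            rng.normal(model.psf_fwhm_mean, model.psf_fwhm_sd, size=n), 50.0, None
        )
        # persistent fiducial emitters are bright and stably fitted
        # (strong broadband autofluorescence), so quality filters keep
        # their tracks intact
        if n_em and persistent.any():
            pmask = np.concatenate(
                [persistent[rep], np.zeros(n - len(rep), dtype=bool)]
            )
            photons[pmask] = rng.lognormal(
                mu + math.log(20.0), 0.2, size=int(pmask.sum())
            )
            fwhm[pmask] = np.clip(
                rng.normal(model.psf_fwhm_mean, 5.0, size=int(pmask.sum())), 50.0, None
            )

        # linear stage drift displaces the recorded positions
        vx, vy = truth.drift
        x = xy[:, 0] + vx * frames
        y = xy[:, 1] + vy * frames

        order = np.argsort(frames, kind="stable")
        df = pd.DataFrame(
            {
                "frame": frames[order],
                "x": x[order],
                "y": y[order],
                "photons": photons[order],
                "fwhm": fwhm[order],
            }
        )
        out[channel] = LocalizationTable(
            df,
            channel=channel,
            metadata={
                "structure_ids": struct[order],
                "n_frames": spec.n_frames,
                "true_drift": (vx, vy),
                "seed": seed,
            },
        )
    return out


def inject_drift(table: LocalizationTable, velocity: tuple) -> LocalizationTable:
    """Add linear drift to a table: x += vx*frame, y += vy*frame; the
    injected truth is recorded in metadata."""
    vx, vy = velocity
    if not (np.isfinite(vx) and np.isfinite(vy)):
        raise ValueError("drift velocity must be finite")
    df = table.records.copy()
    f = df["frame"].to_numpy(dtype=float)
    df["x"] = df["x"] + vx * f
    df["y"] = df["y"] + vy * f
    meta = dict(table.metadata)
    meta["injected_drift"] = (vx, vy)
    return LocalizationTable(df, table.channel, meta)


def simulate_track_field(
    n_emitters: int,
    track_length: int,
    sigma: float,
    spacing: float = 1000.0,
    seed: int = 0,
    photons: float = 5000.0,
    fwhm: float = 300.0,
) -> LocalizationTable:
    """A sparse grid of emitters, each localized in ``track_length``
    consecutive frames with isotropic Gaussian error sigma — the
    controlled input for the precision statistic."""
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_emitters)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    pos = (
        np.column_stack([gx.ravel(), gy.ravel()])[:n_emitters] * spacing
        + spacing / 2.0
    )
    rep = np.repeat(np.arange(n_emitters), track_length)
    frames = np.tile(np.arange(track_length), n_emitters)
    xy = pos[rep] + rng.normal(0.0, sigma, size=(len(rep), 2))
    df = pd.DataFrame(
        {
            "frame": frames,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "photons": photons,
            "fwhm": fwhm,
        }
    ).sort_values("frame", kind="stable").reset_index(drop=True)
    return LocalizationTable(df, channel="sim", metadata={"sigma": sigma})


# ---------------------------------------------------------------------------
# EM reference
# ---------------------------------------------------------------------------


def make_em_reference(
    truth: GroundTruth,
    transform,
    em_pixel_size: float = 20.0,
    sample_step: float | None = None,
) -> tuple[RenderedImage, pd.DataFrame]:
    """Rasterize the scene as an EM-overview-like silhouette image.

    ``transform`` maps SMLM nm coordinates to EM-frame nm coordinates
    (a fitted :class:`~locmorph.registration.TransformModel` or any
    callable on (n, 2) arrays).  Structures (endosome membranes and
    rod fiducials) are densely point-sampled in the SMLM frame, mapped,
    and histogrammed at ``em_pixel_size``.  Returns the image plus the
    exact landmark table: per rod, the transformed centre of mass and
    axis endpoints in both frames (columns x_smlm, y_smlm, x_em, y_em).
    """
    fn = transform.transform if hasattr(transform, "transform") else transform
    step = sample_step if sample_step is not None else em_pixel_size / 3.0
    pts = []
    for e in truth.endosomes.itertuples():
        n = max(int(2 * np.pi * e.radius / step), 16)
        a = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts.append(
            np.column_stack(
                [e.cx + e.radius * np.cos(a), e.cy + e.radius * np.sin(a)]
            )
        )
    for r in truth.rods.itertuples():
        nu = max(int(r.length / step), 2)
        nv = max(int(r.width / step), 2)
        u = np.linspace(-r.length / 2, r.length / 2, nu)
        v = np.linspace(-r.width / 2, r.width / 2, nv)
        uu, vv = np.meshgrid(u, v)
        body = max(r.length / 2 - r.width / 2, 0.0)
        inside = (uu - np.clip(uu, -body, body)) ** 2 + vv**2 <= (r.width / 2) ** 2
        uu, vv = uu[inside], vv[inside]
        c, s = math.cos(r.theta), math.sin(r.theta)
        pts.append(
            np.column_stack(
                [r.cx + c * uu - s * vv, r.cy + s * uu + c * vv]
            )
        )
    pts = np.concatenate(pts) if pts else np.empty((0, 2))
    em_pts = fn(pts)

    w, h = truth.spec.field_size
    corners = fn(np.array([[0, 0], [w, 0], [0, h], [w, h]], dtype=float))
    pad = 2 * em_pixel_size
    x0, y0 = corners.min(0) - pad
    x1, y1 = corners.max(0) + pad
    nx = int(np.ceil((x1 - x0) / em_pixel_size))
    ny = int(np.ceil((y1 - y0) / em_pixel_size))
    grid = np.zeros((ny, nx))
    jj = np.floor((em_pts[:, 0] - x0) / em_pixel_size).astype(int)
    ii = np.floor((em_pts[:, 1] - y0) / em_pixel_size).astype(int)
    ok = (jj >= 0) & (jj < nx) & (ii >= 0) & (ii < ny)
    np.add.at(grid, (ii[ok], jj[ok]), 1.0)
    image = RenderedImage(grid, em_pixel_size, origin=(float(x0), float(y0)))

    lm = truth.rod_landmarks().rename(columns={"x": "x_smlm", "y": "y_smlm"})
    em_lm = fn(lm[["x_smlm", "y_smlm"]].to_numpy())
    lm["x_em"] = em_lm[:, 0]
    lm["y_em"] = em_lm[:, 1]
    return image, lm


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def paper_like_preset(
    n_endosomes: int = 12, drift: tuple = (0.02, -0.01)
) -> tuple[SceneSpec, EmitterModel]:
    """The bundled reference regime: three channels, a dozen endosomes
    with on average five 55 nm Rab5 nanodomains each, rod fiducials,
    monomer background, and slow linear drift."""
    spec = SceneSpec(
        n_endosomes=n_endosomes,
        domains_per_endosome=("poisson_scaled", 5.0),
        domain_diameter=("fixed", 55.0),
        drift=drift,
    )
    return spec, EmitterModel()


def recovery_sweep_spec(k_domains: int, diameter: float = 55.0) -> SceneSpec:
    """One cell of the parameter-recovery benchmark: 50 endosomes each
    carrying exactly ``k_domains`` domains of the given diameter, on a
    larger field, without drift (the benchmark isolates morphometry)."""
    return SceneSpec(
        field_size=(20_000.0, 20_000.0),
        n_endosomes=50,
        endosome_radius=(250.0, 400.0),
        domains_per_endosome=("fixed", k_domains),
        domain_diameter=("fixed", diameter),
        tubules_per_endosome=("fixed", 0),
        n_rods=2,
        drift=(0.0, 0.0),
    )
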