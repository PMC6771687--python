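"""Fiducial landmarks, 2-D transform fitting, and overlay precision.

Channel-to-channel and SMLM-to-EM alignment is landmark based: rod
fiducials (bacteria visible in every channel and in the EM overview)
yield point landmarks either as intensity centres of mass (rods cut
along the short axis) or as the two endpoints along the principal axis
(rods cut lengthwise).  Transforms (similarity, affine, rigid
refinement, or regularized thin-plate spline) are least-squares fitted
to matched landmark pairs in nm.  Overlay precision is the Euclidean
distance between matched landmarks after alignment, reported both as
mean +- SD and median +- MAD, with leave-one-out evaluation by default
so the test fiducial never stabilizes its own fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import transform as sktf

from .morphometry import moment_axis_ratio
from .render import RenderedImage

MODEL_KINDS = ("similarity", "rigid", "affine", "thin_plate_spline")
MIN_MATCHES = {"similarity": 2, "rigid": 2, "affine": 3, "thin_plate_spline": 4}


@dataclass(frozen=True)
class PointMatch:
    """A matched landmark pair: reference-modality and moving-modality
    coordinates in nm."""

    p_ref: tuple
    p_mov: tuple
    kind: str = "center_of_mass"  # or "endpoint"
    fiducial_id: int = -1

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.p_ref)) or not np.all(np.isfinite(self.p_mov)):
            raise ValueError("landmark coordinates must be finite")


def matches_to_dataframe(matches: list[PointMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fiducial_id": m.fiducial_id,
                "kind": m.kind,
                "x_ref": m.p_ref[0],
                "y_ref": m.p_ref[1],
                "x_mov": m.p_mov[0],
                "y_mov": m.p_mov[1],
            }
            for m in matches
        ]
    )


def matches_from_dataframe(df: pd.DataFrame) -> list[PointMatch]:
    return [
        PointMatch(
            p_ref=(row.x_ref, row.y_ref),
            p_mov=(row.x_mov, row.y_mov),
            kind=getattr(row, "kind", "center_of_mass"),
            fiducial_id=int(getattr(row, "fiducial_id", -1)),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Landmark extraction
# ---------------------------------------------------------------------------


def fiducial_center_of_mass(image: RenderedImage, roi: tuple) -> tuple:
    """Intensity-weighted centre of mass inside a rectangular ROI.

    ``roi`` is (row_start, row_stop, col_start, col_stop) in pixels
    (half-open).  Returns (x, y) in nm using pixel-centre coordinates.
    """
    r0, r1, c0, c1 = roi
    ny, nx = image.shape
    if not (0 <= r0 < r1 <= ny and 0 <= c0 < c1 <= nx):
        raise ValueError("ROI must lie within the image")
    w = image.grid[r0:r1, c0:c1]
    s = w.sum()
    if s <= 0:
        raise ValueError("ROI has zero total intensity")
    rr, cc = np.mgrid[r0:r1, c0:c1]
    x = image.origin[0] + ((w * cc).sum() / s + 0.5) * image.pixel_size
    y = image.origin[1] + ((w * rr).sum() / s + 0.5) * image.pixel_size
    return (float(x), float(y))


def fiducial_endpoints(
    mask: np.ndarray,
    pixel_size: float,
    origin=(0.0, 0.0),
    min_elongation: float = 2.0,
) -> tuple:
    """Endpoints of a rod fiducial along its major principal axis.

    ``mask`` is a binary mask containing exactly one connected
    component.  The endpoints are the points *on* the major principal
    axis (second-moment eigenvector through the centroid) at the
    extreme signed projections of the component pixels — i.e. the
    reference points sit on the rod axis, so a flat or ragged end face
    cannot pull them sideways.  Returned in nm, ordered by smaller x
    first (tie: smaller y).  A component with major/minor elongation
    below ``min_elongation`` is rejected.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n != 1:
        raise ValueError(f"mask must contain exactly one component, found {n}")
    rr, cc = np.nonzero(mask)
    rr = rr.astype(float)
    cc = cc.astype(float)
    elong = moment_axis_ratio(rr, cc)
    if elong < min_elongation:
        raise ValueError(
            f"component elongation {elong:.2f} < {min_elongation}: not a rod"
        )
    r0, c0 = rr.mean(), cc.mean()
    cov = np.cov(np.stack([cc - c0, rr - r0]))
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]  # (dx, dy) of the major axis
    proj = (cc - c0) * axis[0] + (rr - r0) * axis[1]
    pts = []
    for p in (proj.min(), proj.max()):
        pts.append(
            (
                origin[0] + (c0 + p * axis[0] + 0.5) * pixel_size,
                origin[1] + (r0 + p * axis[1] + 0.5) * pixel_size,
            )
        )
    pts.sort(key=lambda p: (p[0], p[1]))
    return (pts[0], pts[1])


# ---------------------------------------------------------------------------
# Thin-plate spline with regularization
# ---------------------------------------------------------------------------


class ThinPlateSpline:
    """2-D thin-plate-spline mapping with bending-energy regularization.

    Solves the standard TPS system with kernel U(r) = r^2 log r and a
    regularization term lambda * I on the kernel block; lambda = 0
    interpolates the landmarks exactly, and lambda -> infinity
    approaches the affine least-squares fit (the affine part lies in
    the null space of the bending energy).
    """

    def __init__(self, src: np.ndarray, dst: np.ndarray, reg: float = 0.0):
        src = np.asarray(src, dtype=float)
        dst = np.asarray(dst, dtype=float)
        n = len(src)
        if n < 4:
            raise ValueError("thin-plate spline needs >= 4 landmarks")
        self.src = src
        self.reg = float(reg)
        K = self._kernel(src, src) + reg * np.eye(n)
        P = np.hstack([np.ones((n, 1)), src])
        A = np.zeros((n + 3, n + 3))
        A[:n, :n] = K
        A[:n, n:] = P
        A[n:, :n] = P.T
        b = np.zeros((n + 3, 2))
        b[:n] = dst
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"degenerate landmark geometry for TPS: {err}") from err
        self.w = sol[:n]  # kernel weights
        self.a = sol[n:]  # affine part (1, x, y)

    @staticmethod
    def _kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            k = 0.5 * d2 * np.log(d2)  # r^2 log r = d2 log(sqrt(d2))
        k[d2 == 0] = 0.0
        return k

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        K = self._kernel(pts, self.src)
        P = np.hstack([np.ones((len(pts), 1)), pts])
        return K @ self.w + P @ self.a

    @property
    def bending_energy(self) -> float:
        K = self._kernel(self.src, self.src)
        return float(np.trace(self.w.T @ K @ self.w))


# ---------------------------------------------------------------------------
# Transform fitting
# ---------------------------------------------------------------------------


@dataclass
class TransformModel:
    """A fitted 2-D point mapping with its landmarks and residuals."""

    model_kind: str
    _fn: object = field(repr=False)
    matches: list = field(default_factory=list, repr=False)
    rms_residual: float = np.nan
    parameters: dict = field(default_factory=dict)

    def transform(self, pts) -> np.ndarray:
        return self._fn(np.atleast_2d(np.asarray(pts, dtype=float)))

    def to_json(self, path) -> None:
        payload = {
            "model_kind": self.model_kind,
            "rms_residual_nm": self.rms_residual,
            "parameters": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.parameters.items()
            },
            "n_landmarks": len(self.matches),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _rigid_fit(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kabsch: rotation + translation, scale locked to 1."""
    mu_s, mu_d = src.mean(0), dst.mean(0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    t = mu_d - R @ mu_s
    return R, t


def fit_transform(
    matches: list[PointMatch], model_kind: str = "similarity", tps_reg: float = 0.0
) -> TransformModel:
    """Least-squares fit of a 2-D transform to matched landmarks.

    similarity / affine use the closed-form (Umeyama / normal-equation)
    estimators; "rigid" is the scale-locked Kabsch fit used for the
    automated refinement stage; thin_plate_spline solves the
    regularized radial-basis system (``tps_reg``; 0 interpolates).
    The RMS landmark residual in nm is stored on the model.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    if len(matches) < MIN_MATCHES[model_kind]:
        raise ValueError(
            f"{model_kind} needs >= {MIN_MATCHES[model_kind]} matches, got {len(matches)}"
        )
    src = np.array([m.p_mov for m in matches], dtype=float)
    dst = np.array([m.p_ref for m in matches], dtype=float)

    def _estimate(cls, what):
        if hasattr(cls, "from_estimate"):
            tf = cls.from_estimate(src, dst)
            ok = bool(tf)
        else:  # older scikit-image
            tf = cls()
            ok = tf.estimate(src, dst)
        if not ok or not np.all(np.isfinite(tf.params)):
            raise ValueError(f"degenerate landmark geometry for {what} fit")
        return tf

    params: dict = {}
    if model_kind == "similarity":
        tf = _estimate(sktf.SimilarityTransform, "similarity")
        if tf.scale <= 0:
            raise ValueError("similarity fit produced non-positive scale")
        fn = lambda p: tf(p)  # noqa: E731
        params = {
            "matrix": tf.params,
            "scale": float(tf.scale),
            "rotation_rad": float(tf.rotation),
            "translation": np.asarray(tf.translation),
        }
    elif model_kind == "affine":
        # ordinary least squares on homogeneous coordinates (the
        # default scikit-image affine estimator minimizes a normalized
        # total-least-squares criterion instead of the landmark
        # residual); collinear landmarks are rejected explicitly since
        # lstsq would silently return a rank-deficient solution
        sv = np.linalg.svd(src - src.mean(0), compute_uv=False)
        if sv[-1] <= 1e-9 * max(sv[0], 1.0):
            raise ValueError("collinear landmarks: affine fit is not conditioned")
        X = np.hstack([src, np.ones((len(src), 1))])
        beta, *_ = np.linalg.lstsq(X, dst, rcond=None)
        matrix = np.eye(3)
        matrix[:2, :2] = beta[:2].T
        matrix[:2, 2] = beta[2]
        fn = lambda p, b=beta: np.hstack([p, np.ones((len(p), 1))]) @ b  # noqa: E731
        params = {"matrix": matrix}
    elif model_kind == "rigid":
        R, t = _rigid_fit(src, dst)
        fn = lambda p, R=R, t=t: p @ R.T + t  # noqa: E731
        params = {"rotation": R, "translation": t, "scale": 1.0}
    else:
        tps = ThinPlateSpline(src, dst, reg=tps_reg)
        fn = tps
        params = {
            "reg": tps_reg,
            "bending_energy": tps.bending_energy,
            "kernel_weights": tps.w,
            "affine_part": tps.a,
        }

    resid = fn(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1)))) if len(src) else np.nan
    return TransformModel(
        model_kind=model_kind,
        _fn=fn,
        matches=list(matches),
        rms_residual=rms,
        parameters=params,
    )


def apply_transform(points_or_image, model: TransformModel, output_shape=None):
    """Map points exactly, or resample an image with bilinear interpolation.

    Points: (n, 2) nm array -> (n, 2) nm array.  Images: the moving
    :class:`RenderedImage` is warped onto the reference grid (inverse
    mapping through the fitted model; geometry of the input retained
    unless ``output_shape`` is given).  Image warping requires an
    invertible linear model (similarity/rigid/affine).
    """
    if isinstance(points_or_image, RenderedImage):
        img = points_or_image
        if model.model_kind == "thin_plate_spline":
            raise ValueError("image resampling supports linear models only")
        px, (ox, oy) = img.pixel_size, img.origin

        def inverse_px(coords):
            # skimage warp passes output (col, row) px coords; map output
            # (reference) nm -> input (moving) nm via the model inverse
            nm = coords * px + np.array([ox, oy]) + 0.5 * px
            if model.model_kind == "rigid":
                R = model.parameters["rotation"]
                t = model.parameters["translation"]
                src_nm = (nm - t) @ R
            else:
                m = np.asarray(model.parameters["matrix"])
                inv = np.linalg.inv(m)
                src_nm = (
                    np.hstack([nm, np.ones((len(nm), 1))]) @ inv.T
                )[:, :2]
            return (src_nm - np.array([ox, oy]) - 0.5 * px) / px

        shape = output_shape or img.shape
        warped = sktf.warp(
            img.grid, inverse_map=inverse_px, output_shape=shape, order=1,
            preserve_range=True,
        )
        return RenderedImage(np.clip(warped, 0, None), px, (ox, oy))
    return model.transform(points_or_image)


# ---------------------------------------------------------------------------
# Overlay precision
# ---------------------------------------------------------------------------


@dataclass
class OverlayPrecisionReport:
    """Residual landmark distances after alignment, nm."""

    distances: np.ndarray
    channel_pair: str = ""
    mode: str = "leave-one-out"

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if len(self.distances) == 0:
            raise ValueError("no distances to report")
        if (self.distances < 0).any():
            raise ValueError("distances must be >= 0")

    @property
    def n_fiducials(self) -> int:
        return len(self.distances)

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    @property
    def sd(self) -> float:
        return float(np.std(self.distances, ddof=1)) if len(self.distances) > 1 else 0.0

    @property
    def median(self) -> float:
        return float(np.median(self.distances))

    @property
    def mad(self) -> float:
        return float(np.median(np.abs(self.distances - self.median)))

    def summary(self) -> dict:
        return {
            "channel_pair": self.channel_pair,
            "mode": self.mode,
            "n_fiducials": self.n_fiducials,
            "mean_nm": self.mean,
            "sd_nm": self.sd,
            "median_nm": self.median,
            "mad_nm": self.mad,
        }

    def histogram(self, bin_width: float = 2.0) -> pd.DataFrame:
        top = max(self.distances.max() + bin_width, bin_width)
        edges = np.arange(0.0, top + bin_width, bin_width)
        counts, edges = np.histogram(self.distances, bins=edges)
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )


def overlay_precision(
    matches_after_alignment: list[PointMatch],
    channel_pair: str = "",
    mode: str = "held-out",
) -> OverlayPrecisionReport:
    """Overlay precision from already-aligned matches: the Euclidean
    distance between each reference and moving landmark.  The matches
    must come from fiducials not used to fit the alignment (or from
    leave-one-out evaluation, see :func:`leave_one_out_precision`)."""
    if not matches_after_alignment:
        raise ValueError("need at least one match")
    ref = np.array([m.p_ref for m in matches_after_alignment], dtype=float)
    mov = np.array([m.p_mov for m in matches_after_alignment], dtype=float)
    d = np.sqrt(((ref - mov) ** 2).sum(axis=1))
    return OverlayPrecisionReport(d, channel_pair=channel_pair, mode=mode)


def leave_one_out_precision(
    matches: list[PointMatch],
    model_kind: str = "similarity",
    channel_pair: str = "",
    tps_reg: float = 0.0,
) -> OverlayPrecisionReport:
    """Leave-one-out overlay precision: for each landmark, the transform
    is fitted to all other landmarks and the held-out moving point is
    mapped; its distance to the reference point is that fiducial's
    overlay error."""
    n = len(matches)
    if n < MIN_MATCHES[model_kind] + 1:
        raise ValueError(
            f"leave-one-out with {model_kind} needs >= {MIN_MATCHES[model_kind] + 1} matches"
        )
    d = np.empty(n)
    for i in range(n):
        rest = matches[:i] + matches[i + 1 :]
        model = fit_transform(rest, model_kind, tps_reg=tps_reg)
        mapped = model.transform([matches[i].p_mov])[0]
        d[i] = float(np.hypot(*(mapped - np.asarray(matches[i].p_ref))))
    return OverlayPrecisionReport(d, channel_pair=channel_pair, mode="leave-one-out")
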