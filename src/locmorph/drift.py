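"""Track linking, linear drift correction, and localization precision.

Localization precision is estimated from repeated localizations of the
same blinking emitter: localizations are linked into tracks by
mutual-nearest-neighbour matching between consecutive acquisition
frames, each track's spread about its mean coordinate gives a per-track
standard deviation, and the median of that distribution is reported as
the precision of the data set.  Lateral stage drift is modelled as a
linear function of the frame index and estimated from long tracks
(fiducials or persistent emitters) by length-weighted least squares.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .loc_table import LocalizationTable

#: Default linking radius: one camera pixel.
DEFAULT_LINK_RADIUS_NM = 104.0


@dataclass
class Track:
    """A chain of localizations of one emitter across consecutive frames.

    ``member_indices`` index into the source table's record rows;
    ``frames`` are strictly consecutive; ``coords`` is the (n, 2) array
    of member positions in nm.
    """

    member_indices: np.ndarray
    frames: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.member_indices = np.asarray(self.member_indices, dtype=np.int64)
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if len(self.frames) < 2:
            raise ValueError("a track needs at least 2 members")
        if not np.all(np.diff(self.frames) == 1):
            raise ValueError("track frames must be consecutive without gaps")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class DriftModel:
    """Linear lateral drift: displacement = velocity * (frame - frame0).

    Velocities are in nm per frame.  ``stderr`` holds the analytic
    least-squares standard errors of (vx, vy) when estimated from data.
    """

    vx: float
    vy: float
    frame0: int = 0
    method: str = "explicit"
    stderr: tuple = (np.nan, np.nan)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.vx) and np.isfinite(self.vy)):
            raise ValueError("drift velocities must be finite")

    def negated(self) -> "DriftModel":
        return DriftModel(-self.vx, -self.vy, self.frame0, self.method, self.stderr)


@dataclass
class PrecisionEstimate:
    """Per-track pooled standard deviations and their median.

    ``variant`` names whether per-axis variances were pooled
    (``"pooled-axis"``, default: sd = sqrt((var_x + var_y)/2) with
    unbiased per-axis variances) or Euclidean deviations from the track
    mean were used (``"euclidean"``).
    """

    per_track_sd: np.ndarray
    median_precision: float
    histogram: pd.DataFrame
    variant: str = "pooled-axis"
    n_tracks: int = 0

    def __post_init__(self) -> None:
        self.per_track_sd = np.asarray(self.per_track_sd, dtype=np.float64)
        self.n_tracks = len(self.per_track_sd)

    def histogram_to_csv(self, path) -> None:
        self.histogram.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------


def _mutual_nn_pairs(
    a_xy: np.ndarray, b_xy: np.ndarray, radius: float
) -> list[tuple[int, int]]:
    """Mutual nearest neighbours between two point sets within radius.

    Returns (i, j) local-index pairs where a[i]'s nearest b is b[j],
    b[j]'s nearest a is a[i], and their distance is <= radius.  Exact
    distance ties are resolved toward the lowest index (KD-tree query
    order), making the matching deterministic.
    """
    if len(a_xy) == 0 or len(b_xy) == 0:
        return []
    tree_a = cKDTree(a_xy)
    tree_b = cKDTree(b_xy)
    d_ab, j_ab = tree_b.query(a_xy, k=1)
    d_ba, i_ba = tree_a.query(b_xy, k=1)
    pairs = []
    for i in range(len(a_xy)):
        j = int(j_ab[i])
        if d_ab[i] <= radius and int(i_ba[j]) == i:
            pairs.append((i, j))
    return pairs


def link_consecutive(
    table: LocalizationTable, link_radius: float = DEFAULT_LINK_RADIUS_NM
) -> list[Track]:
    """Link localizations into tracks across consecutive frames.

    Greedy mutual-nearest-neighbour matching between frame f and f+1
    within ``link_radius`` (nm); chains are extended while links exist.
    Only tracks of length >= 2 are returned and every localization
    belongs to at most one track.  The matching is symmetric in time:
    reversing the frame order yields the same track memberships.
    """
    if link_radius <= 0:
        raise ValueError("link_radius must be > 0")
    if len(table) == 0:
        return []

    frames = table.frames
    xy = table.xy
    order = np.argsort(frames, kind="stable")
    # row indices grouped by frame
    by_frame: dict[int, np.ndarray] = {}
    for f in np.unique(frames):
        by_frame[int(f)] = np.flatnonzero(frames == f)

    # chain[i] = row index of the successor of row i (next frame), or -1
    nxt = np.full(len(table), -1, dtype=np.int64)
    has_pred = np.zeros(len(table), dtype=bool)

    fs = sorted(by_frame)
    for f in fs:
        if f + 1 not in by_frame:
            continue
        ia = by_frame[f]
        ib = by_frame[f + 1]
        for li, lj in _mutual_nn_pairs(xy[ia], xy[ib], link_radius):
            nxt[ia[li]] = ib[lj]
            has_pred[ib[lj]] = True

    tracks: list[Track] = []
    heads = np.flatnonzero((nxt >= 0) & ~has_pred)
    for h in heads:
        chain = [int(h)]
        while nxt[chain[-1]] >= 0:
            chain.append(int(nxt[chain[-1]]))
        idx = np.array(chain, dtype=np.int64)
        tracks.append(Track(idx, frames[idx], xy[idx]))
    return tracks


# ---------------------------------------------------------------------------
# Drift
# ---------------------------------------------------------------------------


class DriftEstimationError(RuntimeError):
    pass


def estimate_linear_drift(
    tracks: Sequence[Track], min_track_length: int = 100
) -> DriftModel:
    """Estimate a linear drift velocity from long tracks.

    For each track of length >= ``min_track_length`` the per-axis
    displacement-versus-frame slope is fitted by ordinary least
    squares; slopes are combined across tracks weighted by track
    length.  The analytic standard error of the combined slope
    (sigma_slope = sigma / sqrt(sum (f - mean f)^2), propagated through
    the weighting) is stored on the returned model.

    Raises
    ------
    DriftEstimationError
        If no track qualifies; supply an explicit :class:`DriftModel`
        in that case.
    """
    qual = [t for t in tracks if len(t) >= max(2, min_track_length)]
    if not qual:
        raise DriftEstimationError(
            f"no track of length >= {min_track_length}; supply an explicit "
            "DriftModel (vx, vy) instead"
        )
    slopes = np.empty((len(qual), 2))
    weights = np.empty(len(qual))
    var_slopes = np.empty((len(qual), 2))
    for k, t in enumerate(qual):
        f = t.frames.astype(float)
        fc = f - f.mean()
        sxx = float(np.sum(fc**2))
        for ax in range(2):
            y = t.coords[:, ax]
            beta = float(np.sum(fc * y) / sxx)
            slopes[k, ax] = beta
            resid = y - y.mean() - beta * fc
            dof = max(len(t) - 2, 1)
            var_slopes[k, ax] = float(np.sum(resid**2) / dof / sxx)
        weights[k] = len(t)

    # outlier rejection before the weighted least-squares combination:
    # long chains that hop between distinct nearby emitters carry wild
    # slopes; discard tracks whose slope deviates from the weighted
    # median by more than 5 robust scales (keeps everything when all
    # tracks are genuine fiducials)
    keep = np.ones(len(qual), dtype=bool)
    for ax in range(2):
        med = _weighted_median(slopes[:, ax], weights)
        mad = _weighted_median(np.abs(slopes[:, ax] - med), weights)
        if mad > 0:
            keep &= np.abs(slopes[:, ax] - med) <= 5 * 1.4826 * mad
    if not keep.any():
        keep[:] = True
    slopes, weights, var_slopes = slopes[keep], weights[keep], var_slopes[keep]

    w = weights / weights.sum()
    v = (w[:, None] * slopes).sum(axis=0)
    se = np.sqrt((w[:, None] ** 2 * var_slopes).sum(axis=0))
    return DriftModel(
        vx=float(v[0]),
        vy=float(v[1]),
        frame0=0,
        method=(
            f"track-lsq(min_len={min_track_length}, n_tracks={int(keep.sum())}"
            f"/{len(qual)})"
        ),
        stderr=(float(se[0]), float(se[1])),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    csum = np.cumsum(weights[order])
    idx = int(np.searchsorted(csum, 0.5 * csum[-1]))
    return float(values[order][min(idx, len(values) - 1)])


def apply_drift(table: LocalizationTable, model: DriftModel) -> LocalizationTable:
    """Subtract the modelled drift: x' = x - vx*(frame - frame0), same for y."""
    df = table.records.copy()
    dt = (df["frame"] - model.frame0).to_numpy(dtype=float)
    df["x"] = df["x"] - model.vx * dt
    df["y"] = df["y"] - model.vy * dt
    meta = copy.deepcopy(table.metadata)
    meta.setdefault("drift_corrections", []).append(
        {"vx": model.vx, "vy": model.vy, "frame0": model.frame0, "method": model.method}
    )
    return LocalizationTable(df, table.channel, meta)


# ---------------------------------------------------------------------------
# Precision
# ---------------------------------------------------------------------------


def estimate_precision(
    tracks: Sequence[Track],
    variant: str = "pooled-axis",
    bin_width: float = 1.0,
    max_bin: float | None = None,
    ddof: int = 1,
) -> PrecisionEstimate:
    """Localization precision from the per-track spread distribution.

    Per track: the unbiased sample variance of x and of y about the
    track mean, pooled per axis as sd = sqrt((var_x + var_y) / 2)
    (``variant="pooled-axis"``, default, a per-axis precision), or the
    root mean squared 2-D Euclidean deviation from the track mean with
    the same n-1 normalization (``variant="euclidean"``,
    sd = sqrt(var_x + var_y), larger by sqrt(2) for isotropic error).
    The median of the per-track values is reported as the precision;
    tracks from several fields of view may simply be concatenated
    before calling (pooling across tables).  ``ddof`` below is fixed at
    1 (unbiased); pass ``ddof=0`` for a divisor-n sensitivity check.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("estimate_precision needs at least one track")
    if variant not in ("pooled-axis", "euclidean"):
        raise ValueError("variant must be 'pooled-axis' or 'euclidean'")

    # vectorized over tracks via a flat frame with track ids
    ids = np.repeat(np.arange(len(tracks)), [len(t) for t in tracks])
    coords = np.concatenate([t.coords for t in tracks], axis=0)
    df = pd.DataFrame({"tid": ids, "x": coords[:, 0], "y": coords[:, 1]})
    g = df.groupby("tid")
    var = g[["x", "y"]].var(ddof=ddof)
    vsum = var["x"].to_numpy() + var["y"].to_numpy()
    sd = np.sqrt(vsum / 2.0) if variant == "pooled-axis" else np.sqrt(vsum)

    median = float(np.median(sd))
    top = max_bin if max_bin is not None else max(float(sd.max()) + bin_width, bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(sd, bins=edges)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    return PrecisionEstimate(
        per_track_sd=sd,
        median_precision=median,
        histogram=hist,
        variant=variant,
    )


def tracks_to_dataframe(tracks: Sequence[Track]) -> pd.DataFrame:
    """Flat track table (track_id, frame, x, y, record_index) for CSV export."""
    rows = []
    for tid, t in enumerate(tracks):
        for k in range(len(t)):
            rows.append(
                (tid, int(t.frames[k]), t.coords[k, 0], t.coords[k, 1], int(t.member_indices[k]))
            )
    return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "record_index"])
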