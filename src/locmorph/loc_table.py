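"""Single-molecule localization tables: data model, file I/O, record filtering.

A localization table is the pipeline's universal currency: one row per
fitted single-molecule detection with acquisition frame index, lateral
position in nanometres (camera frame, origin at the upper-left corner,
y increasing downward), fitted photon count (amplitude) and fitted PSF
full width at half maximum.  Tables are per color channel.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Mandatory columns, in native column order.
COLUMNS = ("frame", "x", "y", "photons", "fwhm")

#: Default optical camera pixel size in nm, used to convert pixel-unit
#: input files to the nm coordinates the pipeline works in.
DEFAULT_CAMERA_PIXEL_NM = 104.0

DIALECTS = ("csv", "whitespace")


class FormatError(ValueError):
    """A localization file does not conform to the declared dialect."""


@dataclass(frozen=True)
class FilterSpec:
    """Record-level quality filter.

    Parameters
    ----------
    fwhm_min, fwhm_max : float
        Closed PSF-width window in nm.  Detections whose fitted FWHM
        falls outside the window are discarded (out-of-focus or
        mis-fit events).  Typical window for thin sections is
        250-450 nm; for whole cells 250-650 nm.
    photon_min : float
        Minimum fitted amplitude in photons.  Standard per-dye values:
        3000 (AF647), 1500 (AF568), 450 (Dronpa / GFP).
    inclusive : bool
        If True (default) all boundaries are inclusive: kept records
        satisfy ``fwhm_min <= fwhm <= fwhm_max`` and
        ``photons >= photon_min``.  If False all comparisons are strict.
    """

    fwhm_min: float = 250.0
    fwhm_max: float = 450.0
    photon_min: float = 0.0
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not self.fwhm_min < self.fwhm_max:
            raise ValueError(
                f"fwhm_min ({self.fwhm_min}) must be < fwhm_max ({self.fwhm_max})"
            )
        if self.photon_min < 0:
            raise ValueError("photon_min must be >= 0")


@dataclass
class LocalizationTable:
    """An ordered collection of localizations for one color channel.

    Attributes
    ----------
    records : pandas.DataFrame
        Columns ``frame`` (int, 0-based), ``x``, ``y`` (nm), ``photons``,
        ``fwhm`` (nm).  Row order is meaningful (record index is the
        tie-break key in track linking).
    channel : str
        Channel label shared by every record.
    metadata : dict
        Acquisition parameters (camera pixel size nm, frame count, applied
        corrections, filter discard counts, ...).
    """

    records: pd.DataFrame
    channel: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
        df = df.loc[:, list(COLUMNS)].reset_index(drop=True)
        df["frame"] = df["frame"].astype(np.int64)
        for c in ("x", "y", "photons", "fwhm"):
            df[c] = df[c].astype(np.float64)
        self.records = df
        self._validate()

    def _validate(self) -> None:
        df = self.records
        if len(df) == 0:
            return
        if (df["frame"] < 0).any():
            raise ValueError("frame indices must be >= 0")
        if (df["photons"] <= 0).any():
            raise ValueError("photon counts must be > 0")
        if (df["fwhm"] <= 0).any():
            raise ValueError("FWHM values must be > 0")
        if not np.isfinite(df[["x", "y"]].to_numpy()).all():
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def frames(self) -> np.ndarray:
        return self.records["frame"].to_numpy()

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of positions in nm."""
        return self.records[["x", "y"]].to_numpy()

    def sort_by_frame(self) -> "LocalizationTable":
        """Stable sort by frame (record order within a frame preserved)."""
        df = self.records.sort_values("frame", kind="stable").reset_index(drop=True)
        return LocalizationTable(df, self.channel, copy.deepcopy(self.metadata))

    def copy(self) -> "LocalizationTable":
        return LocalizationTable(
            self.records.copy(), self.channel, copy.deepcopy(self.metadata)
        )

    def equals(self, other: "LocalizationTable") -> bool:
        return (
            self.channel == other.channel
            and len(self) == len(other)
            and bool(
                np.array_equal(self.records.to_numpy(), other.records.to_numpy())
            )
        )


def concat_tables(tables: Iterable[LocalizationTable]) -> LocalizationTable:
    """Concatenate tables of the same channel, preserving record order."""
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one table")
    channels = {t.channel for t in tables}
    if len(channels) > 1:
        raise ValueError(f"cannot concatenate across channels: {sorted(channels)}")
    df = pd.concat([t.records for t in tables], ignore_index=True)
    meta = dict(tables[0].metadata)
    return LocalizationTable(df, tables[0].channel, meta)


# ---------------------------------------------------------------------------
# File I/O
#
# Native dialect: comma-separated with a mandatory header line naming at
# least the five mandatory columns.  Headerless whitespace dialect: columns
# are positional (frame, x, y, photons, fwhm).  Gzip accepted by extension
# (pandas infers compression from the path).
# ---------------------------------------------------------------------------


def read_localizations(
    path,
    dialect: str = "csv",
    channel: str = "",
    coordinate_unit: str = "nm",
    camera_pixel_nm: float = DEFAULT_CAMERA_PIXEL_NM,
    frame_base: int = 0,
) -> LocalizationTable:
    """Read a localization table from a text file.

    Parameters
    ----------
    path : path-like
        Input file; ``.gz`` suffix triggers transparent decompression.
    dialect : {"csv", "whitespace"}
        "csv": comma-separated with header.  "whitespace": headerless,
        positional columns (frame, x, y, photons, fwhm).
    coordinate_unit : {"nm", "pixel"}
        Unit of x/y in the file.  Pixel-unit input is converted to nm
        with ``camera_pixel_nm`` and the conversion recorded in metadata.
    frame_base : {0, 1}
        Frame indexing convention of the file; 1-based input is
        normalized to the internal 0-based convention on read.
    """
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "csv":
        df = pd.read_csv(path)
        df.columns = [str(c).strip().lower() for c in df.columns]
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(
                f"{path}: missing mandatory column(s): {', '.join(missing)}"
            )
        df = df.loc[:, list(COLUMNS)]
    else:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
        if df.shape[1] < len(COLUMNS):
            raise FormatError(
                f"{path}: whitespace dialect needs {len(COLUMNS)} columns, "
                f"found {df.shape[1]}"
            )
        df = df.iloc[:, : len(COLUMNS)]
        df.columns = list(COLUMNS)

    bad = df[df.apply(lambda col: pd.to_numeric(col, errors="coerce")).isna().any(axis=1)]
    if len(bad):
        raise FormatError(f"{path}: non-numeric cell in row(s) {list(bad.index[:5])}")
    df = df.apply(pd.to_numeric)

    meta: dict = {"source": str(path), "dialect": dialect}
    if frame_base not in (0, 1):
        raise ValueError("frame_base must be 0 or 1")
    if frame_base == 1:
        df["frame"] = df["frame"] - 1
        meta["frame_base_normalized"] = "1-based input shifted to 0-based"
    if coordinate_unit == "pixel":
        df["x"] = df["x"] * camera_pixel_nm
        df["y"] = df["y"] * camera_pixel_nm
        meta["coordinate_conversion"] = f"pixel -> nm at {camera_pixel_nm} nm/px"
        meta["camera_pixel_nm"] = camera_pixel_nm
    elif coordinate_unit != "nm":
        raise ValueError("coordinate_unit must be 'nm' or 'pixel'")
    return LocalizationTable(df, channel=channel, metadata=meta)


def write_localizations(
    table: LocalizationTable,
    path,
    dialect: str = "csv",
    allow_empty: bool = False,
    float_format: str = "%.6f",
):
    """Write a localization table; lossless round-trip for the native CSV
    dialect at the serialized precision (default 6 decimals, i.e. well
    below 1e-3 nm)."""
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if len(table) == 0 and not allow_empty:
        raise ValueError("refusing to write empty table (pass allow_empty=True)")
    if dialect == "csv":
        table.records.to_csv(path, index=False, float_format=float_format)
    else:
        table.records.to_csv(
            path, index=False, header=False, sep=" ", float_format=float_format
        )
    return path


def filter_localizations(
    table: LocalizationTable, spec: FilterSpec
) -> LocalizationTable:
    """Apply PSF-width window and photon threshold to a table.

    Kept records satisfy ``fwhm_min <= fwhm <= fwhm_max`` and
    ``photons >= photon_min`` (strict comparisons if the spec is
    exclusive).  The number of records removed by each criterion is
    recorded in the result's metadata under ``"filter_discards"``.
    """
    df = table.records
    if spec.inclusive:
        ok_fwhm = (df["fwhm"] >= spec.fwhm_min) & (df["fwhm"] <= spec.fwhm_max)
        ok_phot = df["photons"] >= spec.photon_min
    else:
        ok_fwhm = (df["fwhm"] > spec.fwhm_min) & (df["fwhm"] < spec.fwhm_max)
        ok_phot = df["photons"] > spec.photon_min
    keep = ok_fwhm & ok_phot
    meta = copy.deepcopy(table.metadata)
    meta["filter_discards"] = {
        "fwhm": int((~ok_fwhm).sum()),
        "photons": int((~ok_phot).sum()),
        "total": int((~keep).sum()),
    }
    meta["filter_spec"] = {
        "fwhm_min": spec.fwhm_min,
        "fwhm_max": spec.fwhm_max,
        "photon_min": spec.photon_min,
        "inclusive": spec.inclusive,
    }
    return LocalizationTable(df[keep].reset_index(drop=True), table.channel, meta)
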