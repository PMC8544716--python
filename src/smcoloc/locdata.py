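"""Localization tables, cell ROIs and cell assignment.

A localization table is a :class:`pandas.DataFrame` with one row per detected
blink event and canonical columns ``x``, ``y``, ``z`` (nm), ``frame``
(non-negative int), ``channel`` (``"sRNA"`` or ``"mRNA"``) and, once assigned,
``cell_id`` (int, ``UNASSIGNED`` = -1). Coordinates are in nanometres
throughout; axes are right-handed and the astigmatism-derived z is taken at
face value.

Cell ROIs are supplied, not segmented: the pipeline starts downstream of cell
segmentation, and the synthetic generator emits ROIs together with its scenes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: cell_id value for localizations not inside any ROI
UNASSIGNED = -1

CHANNELS = ("sRNA", "mRNA")

#: default CSV header names, matching common localization-table exports
DEFAULT_DIALECT = {
    "x": "x [nm]",
    "y": "y [nm]",
    "z": "z [nm]",
    "frame": "frame",
    "channel": "channel",
}

COORD_COLS = ["x", "y", "z"]


class FormatError(ValueError):
    """A localization file does not have the expected structure."""


class ConfigurationError(ValueError):
    """Invalid analysis configuration (e.g. overlapping ROIs)."""


@dataclass(frozen=True)
class CellROI:
    """A cell region of interest: axis-aligned box or spherocylinder.

    A spherocylinder (the idealized rod-shaped bacterium) is a cylinder of
    length ``length`` and radius ``radius`` capped by hemispheres; ``axis`` is
    the unit vector of the cylinder axis and ``center`` its midpoint.
    A box is given by ``lo``/``hi`` corners. All lengths in nm.
    """

    cell_id: int
    shape: str  # "box" | "spherocylinder"
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    length: float = 0.0
    radius: float = 0.0
    lo: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hi: tuple[float, float, float] = (0.0, 0.0, 0.0)
    strain_label: str = ""

    def __post_init__(self):
        if self.shape not in ("box", "spherocylinder"):
            raise ConfigurationError(f"unknown ROI shape {self.shape!r}")
        if self.shape == "spherocylinder":
            if self.radius <= 0:
                raise ConfigurationError("spherocylinder radius must be > 0")
            if self.length < 0:
                raise ConfigurationError("spherocylinder length must be >= 0")
            n = float(np.linalg.norm(self.axis))
            if not np.isfinite(n) or n == 0:
                raise ConfigurationError("spherocylinder axis must be nonzero")

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        if self.shape == "box":
            return np.asarray(self.lo, float), np.asarray(self.hi, float)
        c = np.asarray(self.center, float)
        a = np.asarray(self.axis, float)
        a = a / np.linalg.norm(a)
        half = np.abs(a) * self.length / 2.0 + self.radius
        return c - half, c + half

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized containment test for an (n, 3) array of points."""
        pts = np.atleast_2d(np.asarray(points, float))
        if self.shape == "box":
            lo = np.asarray(self.lo, float)
            hi = np.asarray(self.hi, float)
            return np.all((pts >= lo) & (pts <= hi), axis=1)
        # distance from point to the axis segment <= radius
        c = np.asarray(self.center, float)
        a = np.asarray(self.axis, float)
        a = a / np.linalg.norm(a)
        half = self.length / 2.0
        rel = pts - c
        t = np.clip(rel @ a, -half, half)
        closest = c + t[:, None] * a
        d2 = np.sum((pts - closest) ** 2, axis=1)
        return d2 <= self.radius**2

    def volume(self) -> float:
        if self.shape == "box":
            lo = np.asarray(self.lo, float)
            hi = np.asarray(self.hi, float)
            return float(np.prod(hi - lo))
        return float(
            np.pi * self.radius**2 * self.length + 4.0 / 3.0 * np.pi * self.radius**3
        )

    def to_dict(self) -> dict:
        d = {"cell_id": self.cell_id, "shape": self.shape, "strain_label": self.strain_label}
        if self.shape == "box":
            d["lo"] = list(self.lo)
            d["hi"] = list(self.hi)
        else:
            d["center"] = list(self.center)
            d["axis"] = list(self.axis)
            d["length"] = self.length
            d["radius"] = self.radius
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CellROI":
        kw = dict(d)
        for key in ("center", "axis", "lo", "hi"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)


@dataclass
class FieldOfView:
    """One imaged field: a localization table plus its cell ROIs."""

    localizations: pd.DataFrame
    rois: list[CellROI] = field(default_factory=list)
    condition_label: str = ""

    def __post_init__(self):
        ids = {r.cell_id for r in self.rois}
        if len(ids) != len(self.rois):
            raise ConfigurationError("cell_ids must be unique within a field of view")
        if "cell_id" in self.localizations.columns and len(self.localizations):
            assigned = set(self.localizations["cell_id"].unique()) - {UNASSIGNED}
            missing = assigned - ids
            if missing:
                raise ConfigurationError(
                    f"localizations assigned to unknown cell_ids {sorted(missing)}"
                )


def make_table(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float],
    frame: Sequence[int] | int = 0,
    channel: Sequence[str] | str = "sRNA",
) -> pd.DataFrame:
    """Build a localization table from coordinate arrays."""
    n = len(x)
    frame = np.broadcast_to(np.asarray(frame), n)
    channel = np.broadcast_to(np.asarray(channel, object), n)
    df = pd.DataFrame(
        {
            "x": np.asarray(x, float),
            "y": np.asarray(y, float),
            "z": np.asarray(z, float),
            "frame": frame.astype(np.int64),
            "channel": channel,
        }
    )
    _validate(df)
    return df


def empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
            "z": pd.Series(dtype=float),
            "frame": pd.Series(dtype=np.int64),
            "channel": pd.Series(dtype=object),
        }
    )


def _validate(df: pd.DataFrame) -> None:
    if len(df) == 0:
        return
    coords = df[COORD_COLS].to_numpy(float)
    if not np.all(np.isfinite(coords)):
        bad = int(np.where(~np.isfinite(coords).all(axis=1))[0][0])
        raise FormatError(f"non-finite coordinate at row {bad}")
    if (df["frame"] < 0).any():
        raise FormatError("frame indices must be non-negative")


def read_localizations(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a localization CSV into a canonical table.

    ``dialect`` maps canonical names (``x``, ``y``, ``z``, ``frame``,
    ``channel``) to the column headers used in the file; unknown columns in the
    file are ignored. Units are taken as nm.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, dtype=str)
    missing = [v for v in dialect.values() if v not in raw.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    out = {}
    for canon, col in dialect.items():
        s = raw[col]
        if canon in ("x", "y", "z"):
            num = pd.to_numeric(s, errors="coerce")
            bad = num.isna() & s.notna()
            if bad.any():
                raise FormatError(
                    f"non-numeric coordinate in column {col!r} at row "
                    f"{int(np.where(bad)[0][0])}"
                )
            out[canon] = num.astype(float)
        elif canon == "frame":
            out[canon] = pd.to_numeric(s, errors="raise").astype(np.int64)
        else:
            out[canon] = s.astype(object)
    df = pd.DataFrame(out)
    if len(df) == 0:
        df = empty_table()
    _validate(df)
    return df


def write_localizations(df: pd.DataFrame, path, dialect: dict | None = None) -> None:
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    out = df[list(dialect.keys())].rename(columns=dialect)
    out.to_csv(path, index=False)


def read_rois(path) -> list[CellROI]:
    with open(path) as fh:
        records = json.load(fh)
    return [CellROI.from_dict(r) for r in records]


def write_rois(rois: Sequence[CellROI], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in rois], fh, indent=1)


def _boxes_overlap(a: CellROI, b: CellROI) -> bool:
    alo, ahi = a.bounding_box()
    blo, bhi = b.bounding_box()
    return bool(np.all(alo < bhi) and np.all(blo < ahi))


def assign_to_cells(locs: pd.DataFrame, rois: Sequence[CellROI]) -> pd.DataFrame:
    """Assign each localization the cell_id of the ROI that contains it.

    ROIs must be pairwise disjoint (checked on bounding boxes). Localizations
    inside no ROI get ``UNASSIGNED``. Coordinates are never modified.
    """
    rois = list(rois)
    for i in range(len(rois)):
        for j in range(i + 1, len(rois)):
            if _boxes_overlap(rois[i], rois[j]):
                raise ConfigurationError(
                    f"ROIs {rois[i].cell_id} and {rois[j].cell_id} overlap"
                )
    out = locs.copy()
    cell_id = np.full(len(out), UNASSIGNED, dtype=np.int64)
    if len(out):
        pts = out[COORD_COLS].to_numpy(float)
        for roi in rois:
            inside = roi.contains(pts)
            cell_id[inside] = roi.cell_id
    out["cell_id"] = cell_id
    return out
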