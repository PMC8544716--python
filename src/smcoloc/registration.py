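"""Chromatic-shift estimation and correction between the two dye channels.

Dual-labeled marker cells (the same transcripts stained with both dyes) give
matched centroid pairs across channels. Pairs are formed by mutual nearest
neighbour within a match radius; the shift is the component-wise median of the
displacements, which is robust to the occasional mismatched pair. The model is
translation-only: no field-dependent warp is fitted.

Convention: the estimated shift maps channel B (mRNA / Alexa 568) into the
channel A (sRNA / Alexa 647) frame; ``apply_shift`` subtracts the translation
from the named channel's coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .locdata import COORD_COLS

DEFAULT_MATCH_RADIUS = 200.0  # nm


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ChromaticShift:
    translation: tuple[float, float, float]  # nm, B - A
    n_pairs_used: int = 0
    residual_rms: float = 0.0

    def to_dict(self) -> dict:
        return {
            "translation": list(self.translation),
            "n_pairs_used": self.n_pairs_used,
            "residual_rms": self.residual_rms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChromaticShift":
        return cls(tuple(d["translation"]), d["n_pairs_used"], d["residual_rms"])


def _mutual_pairs(a: np.ndarray, b: np.ndarray, radius: float) -> np.ndarray:
    ta, tb = cKDTree(a), cKDTree(b)
    da, ia = tb.query(a, k=1, distance_upper_bound=radius)
    db, ib = ta.query(b, k=1, distance_upper_bound=radius)
    pairs = []
    for i in range(len(a)):
        j = ia[i]
        if j < len(b) and np.isfinite(da[i]) and ib[j] == i:
            pairs.append((i, j))
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def estimate_chromatic_shift(
    markers_a: np.ndarray,
    markers_b: np.ndarray,
    match_radius: float = DEFAULT_MATCH_RADIUS,
) -> ChromaticShift:
    """Estimate the B→A chromatic translation from marker centroids.

    Parameters are (n, 3) arrays of cluster centroids from the dual-labeled
    marker cells in each channel; ``match_radius`` (nm) bounds the mutual
    nearest-neighbour pairing.
    """
    a = np.atleast_2d(np.asarray(markers_a, float))
    b = np.atleast_2d(np.asarray(markers_b, float))
    if len(a) == 0 or len(b) == 0:
        raise RegistrationError("both marker centroid lists must be non-empty")
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    pairs = _mutual_pairs(a, b, match_radius)
    if len(pairs) == 0:
        raise RegistrationError(
            f"no mutual nearest-neighbour pairs within {match_radius} nm"
        )
    disp = b[pairs[:, 1]] - a[pairs[:, 0]]
    translation = np.median(disp, axis=0)
    resid = disp - translation
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return ChromaticShift(tuple(translation), n_pairs_used=len(pairs), residual_rms=rms)


def apply_shift(
    locs: pd.DataFrame, shift: ChromaticShift, channel: str = "mRNA"
) -> pd.DataFrame:
    """Subtract the translation from the named channel's coordinates only."""
    out = locs.copy()
    if len(out) == 0:
        return out
    mask = (out["channel"] == channel).to_numpy()
    t = np.asarray(shift.translation, float)
    coords = out.loc[mask, COORD_COLS].to_numpy(float) - t
    out.loc[mask, COORD_COLS] = coords
    return out
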