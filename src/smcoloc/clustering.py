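"""Density-based cluster analysis of 3D localizations.

A point is a *core* point iff the number of localizations within Euclidean 3D
distance ``eps`` of it — counting the point itself — is at least ``npt``.
Clusters are the connected components of core points under the eps-neighbour
relation; non-core points within eps of a core point join that core's cluster
(border points, ties broken toward the lowest-indexed core neighbour);
everything else is noise. With the defaults npt=2, eps=25 nm a blinking pair
forms a cluster and an isolated localization is discarded as noise.

The neighbour search uses a k-d tree but is exactly equivalent to the
all-pairs definition; distance is isotropic 3D Euclidean (no axial
down-weighting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .locdata import COORD_COLS, UNASSIGNED

#: cluster parameters reported for the original analysis
DEFAULT_EPS = 25.0
DEFAULT_NPT = 2


@dataclass(frozen=True)
class ClusterParams:
    eps: float = DEFAULT_EPS  # nm
    npt: int = DEFAULT_NPT

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.npt < 1:
            raise ValueError("npt must be >= 1")


@dataclass
class Cluster:
    member_indices: list[int]
    centroid: tuple[float, float, float]
    cell_id: int = UNASSIGNED
    channel: str = ""

    @property
    def n_spots(self) -> int:
        return len(self.member_indices)


def cluster_centroid(members: np.ndarray) -> np.ndarray:
    """Coordinate-wise arithmetic mean of an (n, 3) array of member positions."""
    members = np.atleast_2d(np.asarray(members, float))
    if members.shape[0] == 0:
        raise ValueError("centroid of zero members is undefined")
    return members.mean(axis=0)


def _labels(points: np.ndarray, eps: float, npt: int) -> np.ndarray:
    """Label array: cluster id >= 0 per point, -1 for noise."""
    n = len(points)
    labels = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return labels
    tree = cKDTree(points)
    neighbors = tree.query_ball_point(points, eps)
    core = np.array([len(nb) >= npt for nb in neighbors])

    # connected components of core points under the eps relation (union-find)
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in np.flatnonzero(core):
        for j in neighbors[i]:
            if core[j]:
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    root_to_label: dict[int, int] = {}
    for i in np.flatnonzero(core):
        r = find(i)
        if r not in root_to_label:
            root_to_label[r] = len(root_to_label)
        labels[i] = root_to_label[r]

    # border points: lowest-indexed core neighbour wins
    for i in np.flatnonzero(~core):
        core_nbs = [j for j in sorted(neighbors[i]) if core[j]]
        if core_nbs:
            labels[i] = labels[core_nbs[0]]
    return labels


def density_cluster(
    locs: pd.DataFrame, params: ClusterParams | None = None
) -> tuple[list[Cluster], list[int]]:
    """Cluster a single-cell, single-channel localization table.

    Returns ``(clusters, noise_row_indices)``; every input row index appears
    exactly once across the clusters and the noise list. Indices are 0-based
    positions in ``locs``.
    """
    params = params or ClusterParams()
    if len(locs) == 0:
        return [], []
    points = locs[COORD_COLS].to_numpy(float)
    labels = _labels(points, params.eps, params.npt)

    cell_id = UNASSIGNED
    if "cell_id" in locs.columns:
        ids = locs["cell_id"].unique()
        if len(ids) > 1:
            raise ValueError("density_cluster expects a single cell; split first")
        cell_id = int(ids[0])
    channel = ""
    if "channel" in locs.columns and len(locs):
        chs = locs["channel"].unique()
        if len(chs) > 1:
            raise ValueError("density_cluster expects a single channel; split first")
        channel = str(chs[0])

    clusters: list[Cluster] = []
    for lab in range(labels.max() + 1 if labels.size else 0):
        members = np.flatnonzero(labels == lab)
        clusters.append(
            Cluster(
                member_indices=members.tolist(),
                centroid=tuple(cluster_centroid(points[members])),
                cell_id=cell_id,
                channel=channel,
            )
        )
    noise = np.flatnonzero(labels == -1).tolist()
    return clusters, noise


def cluster_table(
    locs: pd.DataFrame, params: ClusterParams | None = None
) -> pd.DataFrame:
    """Cluster per (cell, channel) and return a flat cluster table.

    Unassigned localizations are skipped. Columns: cell_id, channel,
    cluster_id, n_spots, cx, cy, cz.
    """
    params = params or ClusterParams()
    rows = []
    if len(locs):
        df = locs if "cell_id" in locs.columns else locs.assign(cell_id=UNASSIGNED)
        for (cell, ch), sub in df.groupby(["cell_id", "channel"], sort=True):
            if cell == UNASSIGNED:
                continue
            clusters, _ = density_cluster(sub.reset_index(drop=True), params)
            for k, cl in enumerate(clusters):
                rows.append(
                    {
                        "cell_id": int(cell),
                        "channel": ch,
                        "cluster_id": k,
                        "n_spots": cl.n_spots,
                        "cx": cl.centroid[0],
                        "cy": cl.centroid[1],
                        "cz": cl.centroid[2],
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "channel", "cluster_id", "n_spots", "cx", "cy", "cz"],
    )
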