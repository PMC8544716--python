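"""Synthetic localization scenes and count matrices with known ground truth.

The scene generator is a statistical twin of two-color 3D single-molecule
imaging of rod-shaped bacteria:

* cells are spherocylinders placed on a non-overlapping grid;
* per cell, total sRNA and mRNA copies are Poisson; the bound-complex count
  follows the mass-action equilibrium (binomially realized);
* complexed molecules sit within an isotropic Gaussian pairing offset of each
  other, free molecules uniformly in the cell;
* each molecule emits NB(r, p) localizations (0 → undetected) displaced by
  Gaussian localization error, worse axially (σ_z ≥ σ_xy);
* nonspecific background localizations are Poisson per cell per channel;
* the mRNA channel is displaced by a chromatic shift, and dual-labeled marker
  cells (both channels at shared molecule positions) are emitted for
  registration.

Everything downstream of the generator can therefore be scored against exact
per-molecule truth. The count-matrix generator provides null and spiked
negative-binomial matrices for the MAPS statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .affinity import equilibrium_complex_count
from .locdata import CellROI, FieldOfView, empty_table
from .registration import ChromaticShift

# Cell geometry: a 2 µm x 0.8 µm rod, typical of exponential-phase E. coli.
DEFAULT_CELL_LENGTH = 2000.0  # nm, cylindrical part
DEFAULT_CELL_RADIUS = 400.0  # nm

# Localization precisions: σ_xy ≈ 8 nm lateral, σ_z ≈ 16 nm axial
# (≈ 20/40 nm FWHM resolution; astigmatism-based z is ~2x worse laterally).
DEFAULT_SIGMA_XY = 8.0
DEFAULT_SIGMA_Z = 16.0


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one simulated two-channel field of view."""

    n_cells: int = 100
    cell_length: float = DEFAULT_CELL_LENGTH  # nm
    cell_radius: float = DEFAULT_CELL_RADIUS  # nm
    mean_srna: float = 60.0  # S̄, Poisson mean copies per cell
    mean_mrna: float = 40.0  # M̄
    kd_v: float = 66.0  # K_D·V in copies (f = 0.40 at the means)
    sigma_pair: float = 20.0  # nm, RMS 3D separation of a bound pair
    spot_r: float = 10.0  # NB size of localizations per molecule
    spot_p: float = 0.5  # NB success probability (mean 10 spots)
    spots_fixed: int | None = None  # degenerate emitter: exactly N spots
    sigma_xy: float = DEFAULT_SIGMA_XY  # nm
    sigma_z: float = DEFAULT_SIGMA_Z  # nm
    background_rate: float = 2.0  # localizations per cell per channel
    chromatic_shift: tuple[float, float, float] = (60.0, -40.0, 25.0)  # nm
    n_marker_cells: int = 20
    marker_molecules: float = 30.0  # Poisson mean per marker cell
    seed: int = 0
    condition_label: str = ""

    def __post_init__(self):
        if min(self.n_cells, self.mean_srna, self.mean_mrna, self.kd_v,
               self.sigma_pair, self.background_rate, self.sigma_xy,
               self.sigma_z, self.spot_r) < 0:
            raise ValueError("rates, sizes and sigmas must be non-negative")
        if not (0 < self.spot_p < 1):
            raise ValueError("spot_p must be in (0, 1)")
        if self.sigma_z < self.sigma_xy:
            raise ValueError("axial precision cannot beat lateral (σ_z >= σ_xy)")
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be > 0")


@dataclass
class GroundTruth:
    """Exact per-cell and per-molecule truth for a simulated scene."""

    per_cell: pd.DataFrame  # cell_id, S, M, C, detected_srna, detected_mrna
    molecules: pd.DataFrame  # cell_id, channel, mol_id, x, y, z, bound, n_locs
    true_bound_fraction: float  # total C / total M
    shift: tuple[float, float, float]

    @property
    def detected_bound_fraction(self) -> float:
        """Bound fraction among complexes whose BOTH partners were detected."""
        mols = self.molecules
        bound = mols[mols["bound"] >= 0]
        det = bound.groupby(["cell_id", "bound"])["n_locs"].agg(
            lambda s: (s >= 2).all()
        )
        n_pairs_detected = int(det.sum())
        mrna_det = int(
            ((mols["channel"] == "mRNA") & (mols["n_locs"] >= 2)).sum()
        )
        return n_pairs_detected / mrna_det if mrna_det else 0.0


def _uniform_in_spherocylinder(
    n: int, length: float, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points in an x-axis-aligned spherocylinder centred at 0."""
    out = np.empty((0, 3))
    lo = np.array([-length / 2 - radius, -radius, -radius])
    hi = np.array([length / 2 + radius, radius, radius])
    while len(out) < n:
        batch = rng.uniform(lo, hi, size=(max(4 * (n - len(out)), 16), 3))
        ax = np.clip(batch[:, 0], -length / 2, length / 2)
        d2 = (batch[:, 0] - ax) ** 2 + batch[:, 1] ** 2 + batch[:, 2] ** 2
        out = np.vstack([out, batch[d2 <= radius**2]])
    return out[:n]


def _grid_centers(n: int, length: float, radius: float) -> np.ndarray:
    """Non-overlapping grid of cell centres with a safety margin."""
    pitch_x = length + 2 * radius + 400.0
    pitch_y = 2 * radius + 400.0
    ncol = int(np.ceil(np.sqrt(n)))
    centers = []
    for i in range(n):
        row, col = divmod(i, ncol)
        centers.append((col * pitch_x, row * pitch_y, 0.0))
    return np.asarray(centers)


def simulate_scene(config: SceneConfig) -> tuple[FieldOfView, GroundTruth]:
    """Simulate one field of view; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    L, R = config.cell_length, config.cell_radius
    total_cells = config.n_cells + config.n_marker_cells
    centers = _grid_centers(total_cells, L, R)

    rois: list[CellROI] = []
    loc_rows: list[pd.DataFrame] = []
    cell_rows = []
    mol_rows = []

    def emit_localizations(mol_pos: np.ndarray, channel: str, cell_id: int,
                           bound_ids: np.ndarray) -> np.ndarray:
        """Emit NB(r,p) localizations per molecule; returns per-molecule N."""
        n_mol = len(mol_pos)
        if config.spots_fixed is not None:
            n_locs = np.full(n_mol, config.spots_fixed, dtype=np.int64)
        else:
            n_locs = rng.negative_binomial(config.spot_r, config.spot_p, size=n_mol)
        for m in range(n_mol):
            mol_rows.append(
                (cell_id, channel, m, *mol_pos[m], int(bound_ids[m]), int(n_locs[m]))
            )
        if n_locs.sum() == 0:
            return n_locs
        reps = np.repeat(mol_pos, n_locs, axis=0)
        noise = rng.normal(
            0.0, [config.sigma_xy, config.sigma_xy, config.sigma_z],
            size=(len(reps), 3),
        )
        pts = reps + noise
        loc_rows.append(pd.DataFrame({
            "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
            "frame": np.arange(len(pts), dtype=np.int64),
            "channel": channel,
        }))
        return n_locs

    def emit_background(channel: str, center: np.ndarray) -> int:
        n_bg = rng.poisson(config.background_rate)
        if n_bg:
            pts = _uniform_in_spherocylinder(n_bg, L, R, rng) + center
            loc_rows.append(pd.DataFrame({
                "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
                "frame": np.arange(n_bg, dtype=np.int64),
                "channel": channel,
            }))
        return n_bg

    total_C = 0
    total_M = 0
    for cell_id in range(config.n_cells):
        center = centers[cell_id]
        rois.append(CellROI(
            cell_id=cell_id, shape="spherocylinder", center=tuple(center),
            axis=(1.0, 0.0, 0.0), length=L, radius=R, strain_label="condition",
        ))
        S = rng.poisson(config.mean_srna)
        M = rng.poisson(config.mean_mrna)
        mn = min(S, M)
        if mn > 0:
            c_star = equilibrium_complex_count(S, M, config.kd_v)
            C = int(rng.binomial(mn, c_star / mn))
        else:
            C = 0
        total_C += C
        total_M += M

        anchors = _uniform_in_spherocylinder(C, L, R, rng) + center
        srna_bound = anchors
        # sigma_pair is the RMS 3D separation of a bound pair, so the
        # per-axis standard deviation is sigma_pair / sqrt(3)
        mrna_bound = anchors + rng.normal(
            0.0, config.sigma_pair / np.sqrt(3.0), size=(C, 3))
        srna_free = _uniform_in_spherocylinder(S - C, L, R, rng) + center
        mrna_free = _uniform_in_spherocylinder(M - C, L, R, rng) + center

        srna_pos = np.vstack([srna_bound, srna_free])
        mrna_pos = np.vstack([mrna_bound, mrna_free])
        # bound id: complex index within the cell, -1 for free molecules
        srna_bid = np.concatenate([np.arange(C), -np.ones(S - C, int)])
        mrna_bid = np.concatenate([np.arange(C), -np.ones(M - C, int)])

        n_s = emit_localizations(srna_pos, "sRNA", cell_id, srna_bid)
        n_m = emit_localizations(mrna_pos, "mRNA", cell_id, mrna_bid)
        emit_background("sRNA", center)
        emit_background("mRNA", center)
        cell_rows.append({
            "cell_id": cell_id, "S": S, "M": M, "C": C,
            "detected_srna": int((n_s >= 2).sum()),
            "detected_mrna": int((n_m >= 2).sum()),
        })

    # marker cells: dual-labeled molecules, both channels at shared positions
    for j in range(config.n_marker_cells):
        cell_id = config.n_cells + j
        center = centers[cell_id]
        rois.append(CellROI(
            cell_id=cell_id, shape="spherocylinder", center=tuple(center),
            axis=(1.0, 0.0, 0.0), length=L, radius=R, strain_label="marker",
        ))
        n_mol = rng.poisson(config.marker_molecules)
        pos = _uniform_in_spherocylinder(n_mol, L, R, rng) + center
        bid = -np.ones(n_mol, int)
        emit_localizations(pos, "sRNA", cell_id, bid)
        emit_localizations(pos, "mRNA", cell_id, bid)
        emit_background("sRNA", center)
        emit_background("mRNA", center)

    locs = pd.concat(loc_rows, ignore_index=True) if loc_rows else empty_table()
    # chromatic displacement of the mRNA channel (undone by registration)
    shift = np.asarray(config.chromatic_shift, float)
    mask = (locs["channel"] == "mRNA").to_numpy() if len(locs) else np.array([], bool)
    if mask.any():
        locs.loc[mask, ["x", "y", "z"]] = (
            locs.loc[mask, ["x", "y", "z"]].to_numpy(float) + shift
        )

    fov = FieldOfView(localizations=locs, rois=rois,
                      condition_label=config.condition_label)
    truth = GroundTruth(
        per_cell=pd.DataFrame(
            cell_rows, columns=["cell_id", "S", "M", "C",
                                "detected_srna", "detected_mrna"],
        ),
        molecules=pd.DataFrame(
            mol_rows,
            columns=["cell_id", "channel", "mol_id", "x", "y", "z",
                     "bound", "n_locs"],
        ),
        true_bound_fraction=total_C / total_M if total_M else 0.0,
        shift=tuple(shift),
    )
    return fov, truth


def true_shift(config: SceneConfig) -> ChromaticShift:
    return ChromaticShift(tuple(config.chromatic_shift), n_pairs_used=0,
                          residual_rms=0.0)


def simulate_maps_counts(
    n_genes: int = 1000,
    n_reps_per_group: int = 2,
    baseline_mean: float = 100.0,
    dispersion: float = 0.05,
    spike_gene_count: int = 5,
    spike_fold: float = 8.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Simulate a MAPS count matrix with known spiked genes.

    Counts are negative binomial with the given dispersion (Poisson when
    dispersion = 0); the first ``spike_gene_count`` genes are multiplied by
    ``spike_fold`` in the tagged group. Transcript lengths are log-uniform in
    200–5,000 bp. Returns (counts DataFrame, lengths Series, truth Series of
    booleans flagging the spiked genes); sample columns are named
    ``tagged_1..`` / ``control_1..``.
    """
    if spike_gene_count and spike_fold <= 1:
        raise ValueError("spike_fold must be > 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    lengths = pd.Series(
        np.exp(rng.uniform(np.log(200.0), np.log(5000.0), size=n_genes)),
        index=genes, name="length_bp",
    ).round().astype(float)
    spiked = pd.Series(
        np.arange(n_genes) < spike_gene_count, index=genes, name="spiked")

    def draw(mean: np.ndarray) -> np.ndarray:
        if dispersion == 0:
            return rng.poisson(mean)
        size = 1.0 / dispersion
        return rng.negative_binomial(size, size / (size + mean))

    cols = {}
    mean_control = np.full(n_genes, baseline_mean)
    mean_tagged = mean_control * np.where(spiked.to_numpy(), spike_fold, 1.0)
    for rep in range(1, n_reps_per_group + 1):
        cols[f"tagged_{rep}"] = draw(mean_tagged)
    for rep in range(1, n_reps_per_group + 1):
        cols[f"control_{rep}"] = draw(mean_control)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    return counts, lengths, spiked
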