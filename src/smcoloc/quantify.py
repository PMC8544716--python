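"""Copy-number quantification from cluster spot counts.

Cells expressing the target at basal level contain so few RNAs that their
clusters can be taken as single molecules; the distribution of localization
spots per cluster in those cells calibrates a negative-binomial
single-molecule model N ~ NB(r, p),

    P(N = n) = C(n + r - 1, n) p^r (1 - p)^n,   E[N] = r (1 - p) / p,

whose k-fold convolution — NB(k·r, p), since the NB family is closed under
summation of iid copies — gives the reference matrix P(n | k copies). In an
induced cell where several RNAs can overlap into one cluster, the copy number
of a cluster with n spots is read off the matrix by maximum likelihood over k
(ties broken toward the smaller k, uniform prior; a posterior-mean rule is
available as an option). Per-cell copy numbers are then corrected by
subtracting the mean nonspecific background measured in a deletion strain
stained with the same probes, clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class UnderDispersionError(ValueError):
    """Sample variance <= mean: a negative binomial cannot be fitted.

    Consider a Poisson spot-count model instead (``poisson_fallback=True``).
    """


class SampleSizeError(ValueError):
    pass


class TruncationError(ValueError):
    pass


MIN_CALIBRATION_CLUSTERS = 30
DEFAULT_K_MAX = 50
COLUMN_MASS_TARGET = 0.999


@dataclass(frozen=True)
class SingleMoleculeModel:
    """Negative-binomial localizations-per-molecule model."""

    r: float
    p: float
    log_likelihood: float = float("nan")
    n_clusters: int = 0

    def __post_init__(self):
        if not (self.r > 0):
            raise ValueError("r must be > 0")
        if not (0 < self.p < 1):
            raise ValueError("p must be in (0, 1)")

    @property
    def mean(self) -> float:
        return self.r * (1 - self.p) / self.p

    @property
    def variance(self) -> float:
        return self.r * (1 - self.p) / self.p**2

    def pmf(self, n, k: int = 1) -> np.ndarray:
        """P(total spots = n) for k iid molecules: NB(k*r, p)."""
        return stats.nbinom.pmf(n, k * self.r, self.p)

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "p": self.p,
            "log_likelihood": self.log_likelihood,
            "n_clusters": self.n_clusters,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SingleMoleculeModel":
        return cls(d["r"], d["p"], d.get("log_likelihood", float("nan")),
                   d.get("n_clusters", 0))


def moment_init(counts: np.ndarray) -> tuple[float, float]:
    """Method-of-moments (r0, p0): p0 = mean/var, r0 = mean*p0/(1-p0).

    Uses the unbiased sample variance (ddof=1); overdispersion is required.
    """
    counts = np.asarray(counts, float)
    m = counts.mean()
    v = counts.var(ddof=1) if len(counts) > 1 else 0.0
    if v <= m:
        raise UnderDispersionError(
            f"sample variance {v:.4g} <= mean {m:.4g}; negative binomial "
            "requires overdispersion (consider a Poisson fallback)"
        )
    p0 = m / v
    r0 = m * p0 / (1 - p0)
    return r0, p0


class SpotCountModel:
    """Spots-per-cluster model for basal-expression calibration clusters.

    Parameters
    ----------
    counts : array-like of int
        Localization spot counts of clusters from basal-expression cells,
        each assumed to contain a single RNA molecule.

    Examples
    --------
    >>> res = SpotCountModel([3, 8, 5, 12, 6, 9, 4, 7] * 5).fit()
    >>> ref = res.reference_matrix(k_max=10)
    """

    def __init__(self, counts):
        self.counts = np.asarray(counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("spot counts must be non-negative")

    def fit(self, min_counts: int = MIN_CALIBRATION_CLUSTERS) -> "SpotCountResults":
        """Maximum-likelihood NB fit, initialized at method-of-moments."""
        counts = self.counts
        if len(counts) < min_counts:
            raise SampleSizeError(
                f"need >= {min_counts} calibration clusters, got {len(counts)}"
            )
        r0, p0 = moment_init(counts)

        def nll(theta):
            r, p = np.exp(theta[0]), 1 / (1 + np.exp(-theta[1]))
            return -np.sum(stats.nbinom.logpmf(counts, r, p))

        x0 = np.array([np.log(r0), np.log(p0 / (1 - p0))])
        opt = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10})
        r = float(np.exp(opt.x[0]))
        p = float(1 / (1 + np.exp(-opt.x[1])))
        model = SingleMoleculeModel(r, p, log_likelihood=-float(opt.fun),
                                    n_clusters=len(counts))
        return SpotCountResults(self, model, (r0, p0))


class SpotCountResults:
    """Fitted single-molecule spot-count model."""

    def __init__(self, model: SpotCountModel, smm: SingleMoleculeModel,
                 init: tuple[float, float]):
        self.model = model
        self.single_molecule = smm
        self.moment_init = init

    @property
    def r(self) -> float:
        return self.single_molecule.r

    @property
    def p(self) -> float:
        return self.single_molecule.p

    @property
    def llf(self) -> float:
        return self.single_molecule.log_likelihood

    def reference_matrix(self, k_max: int = DEFAULT_K_MAX,
                         n_max: int | None = None) -> "ReferenceMatrix":
        return build_reference_matrix(self.single_molecule, k_max=k_max, n_max=n_max)

    def summary(self) -> str:
        m = self.single_molecule
        lines = [
            "Single-molecule spot-count model (negative binomial)",
            "=" * 52,
            f"clusters used       {m.n_clusters:>10d}",
            f"size r              {m.r:>10.4f}",
            f"success prob p      {m.p:>10.4f}",
            f"mean spots/molecule {m.mean:>10.4f}",
            f"variance            {m.variance:>10.4f}",
            f"log-likelihood      {m.log_likelihood:>10.2f}",
            f"moment init (r0,p0) ({self.moment_init[0]:.4f}, {self.moment_init[1]:.4f})",
        ]
        return "\n".join(lines)


def fit_single_molecule_model(spot_counts) -> SingleMoleculeModel:
    """Functional wrapper: MLE negative-binomial fit of spots per molecule."""
    return SpotCountModel(spot_counts).fit().single_molecule


@dataclass(frozen=True)
class ReferenceMatrix:
    """P(n spots | k copies) for n in 0..n_max, k in 1..k_max.

    Column k is the k-fold convolution of the single-molecule pmf, equal in
    closed form to NB(k*r, p).
    """

    entries: np.ndarray  # shape (n_max + 1, k_max)
    r: float
    p: float

    @property
    def n_max(self) -> int:
        return self.entries.shape[0] - 1

    @property
    def k_max(self) -> int:
        return self.entries.shape[1]

    def pmf(self, n: int, k: int) -> float:
        if 0 <= n <= self.n_max and 1 <= k <= self.k_max:
            return float(self.entries[n, k - 1])
        # beyond the tabulated range fall back to the closed form
        return float(stats.nbinom.pmf(n, k * self.r, self.p))


def build_reference_matrix(
    model: SingleMoleculeModel, k_max: int = DEFAULT_K_MAX,
    n_max: int | None = None
) -> ReferenceMatrix:
    """Build the copy-number reference matrix by iterated convolution.

    When ``n_max`` is None it is grown automatically until every column holds
    at least ``COLUMN_MASS_TARGET`` probability mass; an explicit ``n_max``
    that fails that check raises :class:`TruncationError`.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    auto = n_max is None
    if auto:
        # start from the closed-form quantile of the widest column
        n_max = int(stats.nbinom.ppf(COLUMN_MASS_TARGET, k_max * model.r, model.p)) + 10
    while True:
        n = np.arange(n_max + 1)
        single = stats.nbinom.pmf(n, model.r, model.p)
        cols = np.empty((n_max + 1, k_max))
        col = single.copy()
        cols[:, 0] = col
        for k in range(1, k_max):
            col = np.convolve(col, single)[: n_max + 1]
            cols[:, k] = col
        mass = cols.sum(axis=0)
        if mass.min() >= COLUMN_MASS_TARGET:
            return ReferenceMatrix(entries=cols, r=model.r, p=model.p)
        if not auto:
            raise TruncationError(
                f"n_max={n_max} too small: column mass down to {mass.min():.6f} "
                f"< {COLUMN_MASS_TARGET}"
            )
        n_max *= 2


def estimate_copy_number(n_spots: int, ref: ReferenceMatrix) -> tuple[int, bool]:
    """ML copy number for a cluster of ``n_spots`` localizations.

    Returns ``(k_hat, saturated)``: the argmax of P(n_spots | k) over
    k = 1..k_max with ties broken toward smaller k; ``saturated`` flags
    k_hat == k_max. Spot counts beyond the tabulated n_max are handled with
    the closed-form pmf.
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    if n_spots <= ref.n_max:
        probs = ref.entries[n_spots, :]
    else:
        probs = stats.nbinom.pmf(n_spots, np.arange(1, ref.k_max + 1) * ref.r, ref.p)
    k_hat = int(np.argmax(probs)) + 1  # argmax returns the first (smallest) max
    return k_hat, k_hat == ref.k_max


def posterior_mean_copy_number(n_spots: int, ref: ReferenceMatrix) -> float:
    """Posterior-mean alternative under a uniform prior over k = 1..k_max."""
    if n_spots <= ref.n_max:
        probs = ref.entries[n_spots, :].astype(float)
    else:
        probs = stats.nbinom.pmf(n_spots, np.arange(1, ref.k_max + 1) * ref.r, ref.p)
    total = probs.sum()
    if total == 0:
        return float(ref.k_max)
    return float(np.dot(np.arange(1, ref.k_max + 1), probs) / total)


@dataclass(frozen=True)
class BackgroundModel:
    """Nonspecific-binding background from a deletion-strain control."""

    mean_background_copies_per_cell: float
    n_cells: int

    def __post_init__(self):
        if self.mean_background_copies_per_cell < 0:
            raise ValueError("background mean must be >= 0")

    @classmethod
    def from_copies(cls, copies_per_cell) -> "BackgroundModel":
        arr = np.asarray(copies_per_cell, float)
        return cls(float(arr.mean()), int(len(arr)))

    def to_dict(self) -> dict:
        return {
            "mean_background_copies_per_cell": self.mean_background_copies_per_cell,
            "n_cells": self.n_cells,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackgroundModel":
        return cls(d["mean_background_copies_per_cell"], d["n_cells"])


def correct_background(raw_copies_per_cell, background: BackgroundModel) -> np.ndarray:
    """Per-cell mean-background subtraction, clamped at zero."""
    raw = np.asarray(raw_copies_per_cell, float)
    return np.maximum(0.0, raw - background.mean_background_copies_per_cell)


def copies_per_cell(cluster_spot_counts_by_cell: dict, ref: ReferenceMatrix) -> dict:
    """Sum per-cluster ML copy numbers within each cell.

    ``cluster_spot_counts_by_cell`` maps cell_id -> iterable of cluster spot
    counts; returns cell_id -> integer raw copy number.
    """
    out = {}
    for cell, counts in cluster_spot_counts_by_cell.items():
        out[cell] = int(sum(estimate_copy_number(int(n), ref)[0] for n in counts))
    return out
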