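"""MAPS pull-down enrichment statistics, implemented from the definitions.

MAPS (MS2-affinity purification coupled with RNA sequencing) compares
gene-level read counts of RNAs co-purified with an MS2-tagged sRNA against an
untagged control. The statistics are:

* FPKM normalization: fpkm = count · 10⁹ / (length_bp · library_size).
* A dispersion-free exact test per gene. With zero dispersion the negative
  binomial reduces to Poisson; replicates are pooled per group after scaling
  counts to a common library size (the geometric mean of all library sizes,
  rounded to the nearest integer). Conditional on the pooled total
  T = y_A + y_B, y_A ~ Binomial(T, N_A/(N_A+N_B)) under H0; the two-sided
  p-value sums P(x) over all outcomes x with point probability ≤ that of the
  observation (minimum-likelihood method), capped at 1.
* Benjamini–Hochberg step-up FDR adjustment of the per-gene p-values.
* Enrichment: the ratio of group-mean FPKMs, with a pseudocount of 0.5
  fragments applied at the count level before FPKM (for the enrichment only,
  never for the test) so zero-count controls give finite volcano coordinates.
* Flags: 2× enrichment at q < 0.05 (the volcano thresholds) and the stricter
  "efficiently recovered" rule, fold change > 4 at q < 0.05.

The model/results surface follows statsmodels: build
:class:`MapsEnrichment` from a count matrix, call :meth:`~MapsEnrichment.fit`,
and read the per-gene table off the returned :class:`EnrichmentResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PSEUDOCOUNT = 0.5
Q_THRESHOLD = 0.05
ENRICH_2X = 2.0
RECOVERY_FOLD = 4.0

GROUPS = ("tagged", "control")


def compute_fpkm(count, length_bp, library_size):
    """Fragments per kilobase of transcript per million mapped fragments."""
    length_bp = np.asarray(length_bp, float)
    library_size = np.asarray(library_size, float)
    if np.any(length_bp <= 0):
        raise ValueError("length_bp must be > 0")
    if np.any(library_size <= 0):
        raise ValueError("library_size must be > 0")
    return np.asarray(count, float) * 1e9 / (length_bp * library_size)


def _pool_to_common_library(counts: np.ndarray, libs: np.ndarray,
                            common: float) -> int:
    """Scale each replicate's count to the common library size, round, sum."""
    scaled = np.rint(np.asarray(counts, float) * common / np.asarray(libs, float))
    return int(scaled.sum())


def exact_test_nodisp(counts_tagged, counts_control, lib_tagged, lib_control) -> float:
    """Two-sided dispersion-free exact test between two count groups.

    The zero-dispersion limit of the negative-binomial exact test: a
    conditional binomial test on the pooled, library-equalized group totals.
    """
    ct = np.atleast_1d(np.asarray(counts_tagged, float))
    cc = np.atleast_1d(np.asarray(counts_control, float))
    lt = np.atleast_1d(np.asarray(lib_tagged, float))
    lc = np.atleast_1d(np.asarray(lib_control, float))
    if (ct < 0).any() or (cc < 0).any():
        raise ValueError("counts must be non-negative")
    common = float(np.exp(np.mean(np.log(np.concatenate([lt, lc])))))
    y_a = _pool_to_common_library(ct, lt, common)
    y_b = _pool_to_common_library(cc, lc, common)
    total = y_a + y_b
    if total == 0:
        return 1.0
    prob = len(ct) / (len(ct) + len(cc))  # N_A/(N_A+N_B) with equalized libraries
    pmf = stats.binom.pmf(np.arange(total + 1), total, prob)
    p_obs = pmf[y_a]
    # sum outcomes no more likely than the observation; tolerance guards
    # against float noise deciding inclusion of the symmetric outcome
    p = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} ( p_(j) · m / j ), capped at 1.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class CountMatrix:
    """Gene-level counts with lengths and a two-group sample sheet.

    ``counts``: DataFrame indexed by gene, one column per sample;
    ``lengths``: Series of transcript lengths (bp) indexed by gene;
    ``groups``: sample -> "tagged" | "control";
    ``library_sizes``: sample -> mapped fragments (defaults to column sums).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    groups: dict
    library_sizes: dict | None = None

    def __post_init__(self):
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        bad = set(self.groups.values()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; use {GROUPS}")
        if self.library_sizes is None:
            self.library_sizes = {c: float(self.counts[c].sum())
                                  for c in self.counts.columns}
        for g in GROUPS:
            if g not in set(self.groups.values()):
                raise ValueError(f"need at least one {g!r} sample")

    def samples(self, group: str) -> list:
        return [s for s in self.counts.columns if self.groups[s] == group]

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        """Read a TSV count matrix (gene, length_bp, sample columns) plus a
        JSON sample sheet {sample: {"group": ..., "library_size": optional}}."""
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        if "length_bp" not in df.columns:
            raise ValueError("count matrix must contain a 'length_bp' column")
        lengths = df["length_bp"].astype(float)
        counts = df.drop(columns=["length_bp"])
        with open(samples_path) as fh:
            sheet = json.load(fh)
        groups = {s: rec["group"] for s, rec in sheet.items()}
        libs = {s: rec["library_size"] for s, rec in sheet.items()
                if "library_size" in rec}
        return cls(counts=counts, lengths=lengths, groups=groups,
                   library_sizes=libs or None)


class MapsEnrichment:
    """Per-gene MAPS enrichment model over a two-group count matrix."""

    def __init__(self, matrix: CountMatrix):
        self.matrix = matrix

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, lengths: pd.Series,
                       groups: dict, library_sizes: dict | None = None
                       ) -> "MapsEnrichment":
        return cls(CountMatrix(counts, lengths, groups, library_sizes))

    def fit(self) -> "EnrichmentResults":
        m = self.matrix
        tagged = m.samples("tagged")
        control = m.samples("control")
        libs_t = np.array([m.library_sizes[s] for s in tagged])
        libs_c = np.array([m.library_sizes[s] for s in control])

        genes, skipped = [], []
        for g in m.counts.index:
            if g in m.lengths.index and np.isfinite(m.lengths[g]) and m.lengths[g] > 0:
                genes.append(g)
            else:
                skipped.append(g)
        if skipped:
            import warnings

            warnings.warn(f"skipped {len(skipped)} gene(s) without a length")

        sub = m.counts.loc[genes]
        lengths = m.lengths.loc[genes].to_numpy(float)
        ct = sub[tagged].to_numpy(float)
        cc = sub[control].to_numpy(float)

        # group-mean FPKM with the count-level pseudocount (enrichment only)
        fpkm_t = compute_fpkm(ct + PSEUDOCOUNT, lengths[:, None], libs_t[None, :])
        fpkm_c = compute_fpkm(cc + PSEUDOCOUNT, lengths[:, None], libs_c[None, :])
        mean_t = fpkm_t.mean(axis=1)
        mean_c = fpkm_c.mean(axis=1)
        enrichment = mean_t / mean_c

        pvals = np.array([
            exact_test_nodisp(ct[i], cc[i], libs_t, libs_c)
            for i in range(len(genes))
        ])
        qvals = bh_adjust(pvals)

        table = pd.DataFrame(
            {
                "mean_fpkm_tagged": mean_t,
                "mean_fpkm_control": mean_c,
                "enrichment": enrichment,
                "log2_enrichment": np.log2(enrichment),
                "p_value": pvals,
                "q_value": qvals,
                "flag_2x": (enrichment >= ENRICH_2X) & (qvals < Q_THRESHOLD),
                "flag_recovered_4x": (enrichment > RECOVERY_FOLD)
                & (qvals < Q_THRESHOLD),
            },
            index=pd.Index(genes, name="gene"),
        )
        return EnrichmentResults(self, table, skipped)


class EnrichmentResults:
    """Fitted per-gene enrichment table with volcano coordinates."""

    def __init__(self, model: MapsEnrichment, table: pd.DataFrame, skipped: list):
        self.model = model
        self.table = table
        self.skipped_genes = skipped

    @property
    def n_significant_2x(self) -> int:
        return int(self.table["flag_2x"].sum())

    @property
    def n_recovered_4x(self) -> int:
        return int(self.table["flag_recovered_4x"].sum())

    def volcano_coordinates(self) -> pd.DataFrame:
        """log2 enrichment vs −log10 q-value, one row per gene."""
        return pd.DataFrame(
            {
                "log2_enrichment": self.table["log2_enrichment"],
                "neg_log10_q": -np.log10(self.table["q_value"].clip(lower=1e-300)),
            }
        )

    def volcano_plot(self, ax=None):
        """Scatter of the volcano coordinates with the 2× and q=0.05 lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xy = self.volcano_coordinates()
        ax.scatter(xy["log2_enrichment"], xy["neg_log10_q"], s=8, c="black")
        sig = self.table["flag_2x"]
        ax.scatter(xy.loc[sig, "log2_enrichment"], xy.loc[sig, "neg_log10_q"],
                   s=8, c="red")
        ax.axhline(-np.log10(Q_THRESHOLD), ls="--", lw=0.8, c="gray")
        ax.axvline(np.log2(ENRICH_2X), ls="--", lw=0.8, c="gray")
        ax.set_xlabel("log2 enrichment (tagged / control)")
        ax.set_ylabel("-log10 q-value")
        return ax

    def summary(self) -> str:
        t = self.table
        lines = [
            "MAPS enrichment (dispersion-free exact test, BH-adjusted)",
            "=" * 58,
            f"genes tested            {len(t):>8d}",
            f"skipped (no length)     {len(self.skipped_genes):>8d}",
            f"2x enriched, q<0.05     {self.n_significant_2x:>8d}",
            f"recovered (FC>4,q<0.05) {self.n_recovered_4x:>8d}",
            f"median enrichment       {t['enrichment'].median():>8.3f}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def enrichment_table(matrix: CountMatrix) -> pd.DataFrame:
    """Functional wrapper: per-gene enrichment records for a count matrix."""
    return MapsEnrichment(matrix).fit().table


def replicate_fpkm_correlation(matrix: CountMatrix, group: str = "tagged") -> float:
    """Pearson correlation of log FPKM between the first two replicates of a
    group — the replicate-consistency check run before testing."""
    samples = matrix.samples(group)
    if len(samples) < 2:
        raise ValueError(f"need >= 2 {group!r} replicates for a correlation")
    lengths = matrix.lengths.loc[matrix.counts.index].to_numpy(float)
    a = compute_fpkm(matrix.counts[samples[0]].to_numpy(float) + PSEUDOCOUNT,
                     lengths, matrix.library_sizes[samples[0]])
    b = compute_fpkm(matrix.counts[samples[1]].to_numpy(float) + PSEUDOCOUNT,
                     lengths, matrix.library_sizes[samples[1]])
    return float(np.corrcoef(np.log(a), np.log(b))[0, 1])
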