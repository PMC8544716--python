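# Methods

This note documents the models and procedures implemented in `smcoloc`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Overview

The imaging side of the package quantifies sRNA–mRNA interactions in bacteria
from two-channel 3D single-molecule localization data (smFISH imaged by
single-fluorophore super-resolution microscopy). A single RNA molecule appears
as a cluster of localizations — one per blink of its dye-labeled probes — so
the pipeline proceeds: chromatic registration → density clustering → copy
numbers via a calibrated spots-per-molecule model → colocalization at a
distance cutoff → an apparent equilibrium dissociation constant. The
sequencing side computes MAPS (MS2-affinity purification + RNA-seq) enrichment
statistics from a gene-level count matrix.

## Density clustering

A point is a core point iff at least `npt` localizations (counting itself) lie
within 3D Euclidean distance `eps`; clusters are connected components of core
points, with non-core neighbours attached as border points. Defaults are
`eps = 25 nm`, `npt = 2`: a blinking pair forms a cluster, an isolated blink
is discarded as noise. Counting the point itself and testing `>= npt` is
deliberate — the alternative (strictly more than two neighbours excluding
self) would discard genuine two-blink molecules entirely. Border points
adjacent to cores of two different clusters are assigned to the
lowest-indexed core neighbour for determinism; this is the only part of the
labeling that depends on row order. Distance is isotropic (no axial
down-weighting). A k-d tree accelerates the neighbour search but the result
is exactly the all-pairs definition, which the test suite verifies against a
brute-force neighbour-matrix oracle on a thousand random instances.

## Chromatic registration

Marker cells carry the same transcripts stained with both dyes, so their
cluster centroids appear in both channels at a common physical position plus
the chromatic shift. Centroids are paired by mutual nearest neighbour within
200 nm and the shift is the component-wise median of the displacements —
robust to occasional mispairing, and exact on noise-free scenes. The model is
translation-only; a field-dependent (affine or polynomial) warp is out of
scope. The convention is that the shift maps the mRNA channel into the sRNA
channel's frame.

## Spots-per-molecule calibration and copy numbers

Cells expressing the target at basal level contain few RNAs, so their
clusters are taken as single molecules. The spot counts of those clusters
calibrate a negative binomial N ~ NB(r, p) with pmf
P(N=n) = C(n+r−1, n) p^r (1−p)^n and mean r(1−p)/p, fitted by maximum
likelihood (Nelder–Mead on transformed parameters) initialized at the method
of moments (p0 = mean/variance with the unbiased sample variance,
r0 = mean·p0/(1−p0)). Under-dispersed input is rejected — a Poisson spot
model would be the appropriate fallback, and blinking data are essentially
always overdispersed.

Because the NB family is closed under summation, the spot count of a cluster
containing k molecules is NB(k·r, p). The reference matrix P(n | k) for
k = 1..50 is nevertheless built by iterated convolution of the single-molecule
pmf and checked against the closed form to 1e-10 — the convolution is the
definition, the closed form the oracle. `n_max` grows automatically until
every column holds ≥ 0.999 mass.

A cluster of n spots is assigned k̂ = argmax_k P(n | k), ties toward smaller
k, with a saturation flag at k = k_max and closed-form extrapolation beyond
the tabulated n. A posterior-mean read-out under a uniform prior is available
as an alternative. Per-cell raw copies are the sum of per-cluster k̂; the
nonspecific-binding background, measured as mean copies per cell in a
deletion-strain control stained with the same probes, is subtracted per cell
and clamped at zero.

**Known limitation — upward bias of the ML read-out.** For a cluster that
truly holds one molecule, k̂ ≥ 1 always, while a spot count in the upper tail
(n ≥ 15 under NB(10, 0.5)) is likelier under k = 2 and is read as two
molecules. The errors cannot cancel, so E[k̂ | k=1] = 1.152 under NB(10, 0.5)
— computable in closed form from the calibrated model — and per-cell copy
sums over mostly-single clusters run ~15% high. The bias shrinks as the
spot-count distribution narrows (larger r at fixed mean) and as clusters pool
more molecules, and it cancels in between-condition ratios such as the K_D
ratio, which is the package's main comparative output. The benchmark suite
measures this bias honestly rather than hiding it: the copy-number recovery
check reports the signed relative error.

## Colocalization

An mRNA cluster is colocalized iff its centroid lies within the cutoff
(default 50 nm, matching the axial resolution of astigmatism-based 3D
imaging) of at least one sRNA cluster centroid, in the registered frame. The
reported fraction is over all mRNA clusters, so it is bounded by 1;
centroid-to-centroid distance is used for determinism. Per-replicate
fractions support mean ± SD summaries across biological replicates.

Random colocalization is estimated either empirically (imaging a non-target
mRNA with the sRNA, the experimental negative control) or by a
complete-spatial-randomness model: for sRNA cluster density λ per nm³ the
unbounded-CSR colocalized fraction is the Poisson void-probability complement
1 − exp(−λ·(4/3)π·d³), and a Monte Carlo twin inside the actual cell geometry
accounts for boundary effects. The baseline is subtracted from the measured
fraction (floored at zero) before affinity estimation by default.

## Affinity

Binding is modeled as single-site mass action at equilibrium, S + M ⇌ SM.
With per-cell totals S (sRNA, background-corrected), M (mRNA), bound mRNA
fraction f, and cell volume V:

    K_D = (S − f·M)(1 − f) / (f·V).

V cancels in ratios between conditions with equal cell volume, so the default
V = 1 reports K_D in copies per cell volume; molar output is available given
V in liters. The forward model — the complex count at equilibrium, the
positive root of (S−C)(M−C) = K_D·V·C, evaluated in the cancellation-free
form 2SM/(b + √(b²−4SM)) — is shared with the simulator, and the
estimator inverts it exactly (round-trip identity at floating-point
precision). The ratio K_D(test)/K_D(reference) and its reciprocal, the
affinity fold-change, are the comparative outputs; the estimator is exposed
term-by-term because published analyses do not always state which terms
(sRNA abundance, mRNA abundance, bound fraction) entered a quoted ratio.

## MAPS enrichment

FPKM is count·10⁹/(length_bp · library size); library sizes default to column
sums. The per-gene test is the zero-dispersion limit of the negative-binomial
exact test: replicate counts are scaled to the geometric-mean common library
size, rounded, and pooled per group; conditional on the pooled total
T = y_A + y_B, y_A is Binomial(T, n_A/(n_A+n_B)) under the null, and the
two-sided p-value sums all outcomes with point probability ≤ the observed one
(minimum-likelihood method), capped at 1. Benjamini–Hochberg q-values use the
step-up rule q_(i) = min_{j≥i} p_(j)·m/j. Enrichment is the ratio of
group-mean FPKMs with a 0.5-fragment pseudocount applied at the count level —
for the enrichment only, never for the test — so zero-count controls give
finite volcano coordinates. Flags: 2× enrichment at q < 0.05 (volcano
thresholds) and the stricter recovery rule, fold change > 4 at q < 0.05.
These definitions are implemented directly rather than delegated to an
external package; the conditional binomial is cross-checked against an
independent exact two-sided binomial test, and BH against both the literal
definition and statsmodels.

## Synthetic data generator

The scene generator emulates the data-generating process the analyses assume:
spherocylindrical cells (2 µm × 0.8 µm, typical exponential-phase E. coli) on
a non-overlapping grid; Poisson totals S̄ = 60 sRNA and M̄ = 40 mRNA copies
per cell; complexes drawn binomially around the mass-action expectation with
K_D·V = 66 copies, giving a bound fraction of 0.40 at the means (the test
condition uses 3-fold fewer sRNA copies and K_D·V scaled by the study's
ratio); bound pairs separated by an isotropic Gaussian offset with RMS 3D
distance σ_pair = 20 nm (per-axis σ_pair/√3), so essentially all complexes
fall within the 50 nm cutoff after localization noise; NB(10, 0.5)
localizations per molecule (a molecule drawing 0 is undetected and recorded
as such in the truth tables); Gaussian localization error σ_xy = 8 nm,
σ_z = 16 nm — single-fluorophore precisions consistent with ~20 nm lateral
and ~40–50 nm axial FWHM resolution, at which the eps = 25 nm clustering
resolves one cluster per molecule (~1.04 clusters/molecule, 1.4% dropout, by
direct simulation of the forward model); 2 nonspecific background
localizations per cell per channel; a (60, −40, 25) nm chromatic displacement
of the mRNA channel; and dual-labeled marker cells sharing molecule positions
across channels.

What the generator does **not** emulate: frame-resolved blinking kinetics and
photobleaching, diffusion during acquisition, z-dependent detection
efficiency, optical PSF structure, cell segmentation errors, and spatially
structured expression (transcription foci, membrane association). Passing the
recovery benchmarks therefore demonstrates the correctness and calibration of
the analysis chain under its own statistical assumptions — not robustness to
every artifact of real microscopes. Likewise the count-matrix generator
(negative binomial with gene-independent dispersion, log-uniform lengths
200–5,000 bp, spiked fold changes in the tagged group) validates the test's
calibration and power, not robustness to compositional or batch effects.

## Numerical choices

* NB fitting: Nelder–Mead on (log r, logit p), tolerances 1e-8/1e-10;
  initialization at the method of moments.
* Equilibrium root: cancellation-free quadratic form (see above); residual
  |(S−C)(M−C) − K_D·V·C| ≤ 1e-6·max(1, S·M) enforced by tests.
* Exact test: rounding to the common library uses nearest-integer; outcome
  inclusion uses a 1 + 1e-12 relative tolerance on the observed pmf so float
  noise cannot drop the symmetric outcome.
* Degenerate inputs: empty localization tables cluster to (∅, ∅); an empty
  sRNA channel gives colocalization 0 with a warning; an empty mRNA channel
  is flagged as undefined; f = 0 raises (K_D unidentified); f·M > S clamps
  free sRNA at zero with a warning.
* Benchmark problem sizes (100–200 cells, 10,000 null genes, 1,000 clustering
  instances, 3 pipeline replicates) keep the full benchmark suite at a few
  minutes on one core while leaving Monte-Carlo error well inside each
  tolerance.

## Open design points

* ROI provenance: cell outlines are supplied (or generated), never segmented
  here; how the original per-cell statistics delineated cells is unknown.
* Clustering granularity: per cell per channel. Whether the original analysis
  clustered whole fields of view instead is unstated; per-cell clustering is
  the conservative choice given disjoint ROIs.
* Colocalization denominator: all mRNA clusters (so the percentage is bounded
  by 100%); an odds-style reading of "colocalized over non-colocalized" is
  possible but cannot produce the bounded percentages that are plotted.
* Background subtraction: pooled mean per cell, for determinism; a per-cell
  paired subtraction is not identifiable from a separate control strain.
* Copy-number read-out: ML argmax with ties toward smaller k (posterior mean
  available); see the bias discussion above.
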