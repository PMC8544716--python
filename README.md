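# smcoloc

Quantitative analysis of bacterial sRNA–mRNA interactions from two-channel 3D
single-molecule localization microscopy, plus MAPS pull-down enrichment
statistics.

Small regulatory RNAs (sRNAs) such as *E. coli* RyhB repress target mRNAs by
base-pairing, classically with help from the RNA chaperone Hfq. Two
complementary measurements probe this in vivo: super-resolution smFISH, where
each RNA appears as a cluster of single-fluorophore localizations, and MAPS
(MS2-affinity purification coupled with RNA-seq), where co-purifying RNAs are
detected as enrichment over an untagged control. `smcoloc` implements the
statistics of both, for microscopists and RNA biologists who have localization
tables or count matrices in hand:

* **Clustering** — density-based cluster analysis of 3D localizations
  (eps = 25 nm, npt = 2), exactly equivalent to the all-pairs definition.
* **Registration** — chromatic-shift correction between dye channels from
  dual-labeled marker cells (mutual nearest neighbours, median displacement).
* **Copy numbers** — a negative-binomial spots-per-molecule model NB(r, p) is
  calibrated on basal-expression cells and extended to a reference matrix
  P(n | k) = NB(k·r, p); cluster spot counts are inverted to molecule counts
  by maximum likelihood, and a deletion-strain background is subtracted.
* **Colocalization** — the fraction of mRNA clusters within a distance cutoff
  (50 nm) of any sRNA cluster, with an empirical negative-control or
  complete-spatial-randomness baseline, 1 − exp(−λ·(4/3)πd³).
* **Affinity** — the apparent dissociation constant from single-site mass
  action, K_D = (S − f·M)(1 − f)/(f·V), condition ratios and affinity
  fold-changes (a K_D ratio of 0.40 is a 2.5-fold affinity increase).
* **MAPS enrichment** — FPKM normalization, a dispersion-free exact test
  (conditional binomial on pooled, library-equalized counts, two-sided by
  minimum likelihood), Benjamini–Hochberg q-values, volcano coordinates, and
  the 2× / fold-change > 4 significance flags.
* **Synthetic data** — generators for localization scenes (rod-shaped cells,
  binding equilibrium, negative-binomial blinking, chromatic shift, marker
  cells) and count matrices, with exact ground truth for every stage.

See `docs/methods.md` for the models, assumptions and known limitations.

## Worked example

Simulate a two-condition study — a reference condition and a "test" condition
with 3-fold fewer sRNA copies and a true K_D at 40% of the reference — then
run the full pipeline:

```python
from pathlib import Path
from smcoloc import SceneConfig, simulate_scene
from smcoloc.locdata import write_localizations, write_rois
from smcoloc.pipeline import ConditionInput, PipelineConfig, run_pipeline

def write(cfg, d):
    fov, truth = simulate_scene(cfg)
    Path(d).mkdir(parents=True, exist_ok=True)
    write_localizations(fov.localizations, f"{d}/locs.csv")
    write_rois(fov.rois, f"{d}/rois.json")
    return ConditionInput(locs=f"{d}/locs.csv", rois=f"{d}/rois.json")

ref  = write(SceneConfig(n_cells=150, seed=11), "sim/ref")
test = write(SceneConfig(n_cells=150, mean_srna=20.0, kd_v=26.4, seed=12), "sim/test")
cal  = write(SceneConfig(n_cells=100, mean_srna=2.0, mean_mrna=0.0, kd_v=1e9, seed=13), "sim/cal")
bg   = write(SceneConfig(n_cells=100, mean_srna=0.0, mean_mrna=0.0, kd_v=1e9, seed=14), "sim/bg")

report = run_pipeline(PipelineConfig(
    conditions={"ref": ref, "test": test}, calibration=cal, background=bg,
    reference_condition="ref", out_dir="sim/out", seed=5))
for label, s in report.per_condition.items():
    print(f"{label}: S={s['mean_srna_copies']:.1f} M={s['mean_mrna_copies']:.1f} "
          f"f={s['colocalized_fraction']:.3f} K_D={s['kd']:.1f}")
print(report.kd_ratios)
```

Output:

```
ref: S=76.5 M=52.2 f=0.394 K_D=97.0
test: S=25.5 M=50.0 f=0.265 K_D=35.8
{'test': {'vs': 'ref', 'ratio': 0.36899239746352097, 'fold_affinity': 2.7100829363262458}}
```

`S` and `M` are background-corrected mean copies per cell (the
maximum-likelihood cluster read-out runs somewhat high; see the bias
discussion in `docs/methods.md` — it cancels in the ratio), `f` the
colocalized mRNA-cluster fraction at 50 nm, and the K_D ratio of 0.37
recovers the simulated 0.40, i.e. a ~2.7-fold affinity increase in the test
condition. Intermediate tables (clusters, copies, shifts, colocalization,
report) are written under `sim/out/`.

The same stages are available from the shell:

```bash
smcoloc simulate scene --seed 1 --out-dir sim/ref
smcoloc cluster --in sim/ref/locs.csv --rois sim/ref/rois.json --out clusters.tsv
smcoloc maps-test --counts counts.tsv --samples samples.json --out enrichment.tsv
smcoloc run --config pipeline.yaml
```

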