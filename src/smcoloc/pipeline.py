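"""End-to-end orchestration: calibrate → register → cluster → quantify →
colocalize → affinity.

The pipeline consumes localization CSVs plus ROI JSONs for each condition
(fields of view that include dual-labeled marker cells, tagged by the
``marker`` strain label), a basal-expression calibration input, and a
deletion-strain background input. Every stage writes its intermediate table
under the output directory, so any number in the report can be traced to a
stage output file; warnings raised along the way are collected in the report
rather than dropped.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .affinity import AffinityInput, estimate_kd, kd_ratio_and_fold, subtract_baseline
from .clustering import ClusterParams, cluster_table
from .colocalization import (
    DEFAULT_CUTOFF,
    colocalization_percentage,
    csr_baseline,
)
from .locdata import assign_to_cells, read_localizations, read_rois
from .quantify import (
    BackgroundModel,
    SpotCountModel,
    copies_per_cell,
    correct_background,
)
from .registration import estimate_chromatic_shift, apply_shift

MARKER_LABEL = "marker"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ConditionInput:
    locs: str
    rois: str


@dataclass
class PipelineConfig:
    conditions: dict  # label -> ConditionInput
    calibration: ConditionInput
    background: ConditionInput
    reference_condition: str
    out_dir: str
    eps: float = 25.0
    npt: int = 2
    cutoff: float = DEFAULT_CUTOFF
    volume: float = 1.0
    baseline_mode: str = "csr"  # csr | empirical | none
    negative_control: str | None = None  # condition label, empirical mode
    match_radius: float = 200.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        conditions = {
            label: ConditionInput(**rec) for label, rec in raw["conditions"].items()
        }
        return cls(
            conditions=conditions,
            calibration=ConditionInput(**raw["calibration"]),
            background=ConditionInput(**raw["background"]),
            reference_condition=raw["reference_condition"],
            out_dir=raw["out_dir"],
            eps=raw.get("eps", 25.0),
            npt=raw.get("npt", 2),
            cutoff=raw.get("cutoff", DEFAULT_CUTOFF),
            volume=raw.get("volume", 1.0),
            baseline_mode=raw.get("baseline", "csr"),
            negative_control=raw.get("negative_control"),
            match_radius=raw.get("match_radius", 200.0),
            seed=raw.get("seed", 0),
        )

    def validate(self) -> None:
        if self.baseline_mode not in ("csr", "empirical", "none"):
            raise PipelineError("config", f"unknown baseline mode {self.baseline_mode!r}")
        if self.baseline_mode == "empirical" and not self.negative_control:
            raise PipelineError("config", "empirical baseline needs negative_control")
        if self.reference_condition not in self.conditions:
            raise PipelineError(
                "config", f"reference condition {self.reference_condition!r} missing"
            )
        for label, inp in self._all_inputs():
            for path in (inp.locs, inp.rois):
                if not Path(path).exists():
                    raise PipelineError("config", f"{label}: no such file: {path}")

    def _all_inputs(self):
        yield from self.conditions.items()
        yield ("calibration", self.calibration)
        yield ("background", self.background)

    def content_hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in sorted(self.__dict__.items())}, default=str, sort_keys=True
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    per_condition: dict
    kd_ratios: dict
    provenance: dict
    warnings: list = dataclass_field(default_factory=list)
    timings: dict = dataclass_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_condition": self.per_condition,
            "kd_ratios": self.kd_ratios,
            "provenance": self.provenance,
            "warnings": self.warnings,
            "timings": self.timings,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=float)


def _load_and_cluster(inp: ConditionInput, params: ClusterParams,
                      shift=None) -> tuple[pd.DataFrame, list]:
    locs = read_localizations(inp.locs)
    rois = read_rois(inp.rois)
    if shift is not None:
        locs = apply_shift(locs, shift, channel="mRNA")
    assigned = assign_to_cells(locs, rois)
    return cluster_table(assigned, params), rois


def _marker_centroids(clusters: pd.DataFrame, rois: list, channel: str) -> np.ndarray:
    marker_ids = {r.cell_id for r in rois if r.strain_label == MARKER_LABEL}
    sub = clusters[(clusters["channel"] == channel)
                   & clusters["cell_id"].isin(marker_ids)]
    return sub[["cx", "cy", "cz"]].to_numpy(float)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages in order; idempotent given the seed."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = ClusterParams(eps=config.eps, npt=config.npt)
    collected: list[str] = []
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                self.ctx = warnings.catch_warnings(record=True)
                self.log = self.ctx.__enter__()
                warnings.simplefilter("always")
                return self

            def __exit__(self, exc_type, exc, tb):
                self.ctx.__exit__(exc_type, exc, tb)
                for w in self.log:
                    collected.append(f"{name}: {w.message}")
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
                return False

        return _T()

    # --- calibration: single-molecule spot-count model from basal cells
    with stage("calibrate"):
        cal_clusters, _ = _load_and_cluster(config.calibration, params)
        basal = cal_clusters[cal_clusters["channel"] == "sRNA"]
        results = SpotCountModel(basal["n_spots"].to_numpy()).fit()
        ref = results.reference_matrix()
        with open(out / "single_molecule_model.json", "w") as fh:
            json.dump(results.single_molecule.to_dict(), fh, indent=1)

    # --- background: deletion-strain nonspecific copies per cell
    with stage("background"):
        bg_clusters, bg_rois = _load_and_cluster(config.background, params)
        bg_sub = bg_clusters[bg_clusters["channel"] == "sRNA"]
        bg_ids = [r.cell_id for r in bg_rois if r.strain_label != MARKER_LABEL]
        by_cell = {c: bg_sub.loc[bg_sub["cell_id"] == c, "n_spots"].tolist()
                   for c in bg_ids}
        bg_copies = copies_per_cell(by_cell, ref)
        background = BackgroundModel.from_copies(list(bg_copies.values()))
        with open(out / "background.json", "w") as fh:
            json.dump(background.to_dict(), fh, indent=1)

    per_condition: dict[str, dict] = {}
    fractions: dict[str, float] = {}
    for label, inp in config.conditions.items():
        # --- registration from this condition's marker cells
        with stage(f"register[{label}]"):
            raw_locs = read_localizations(inp.locs)
            rois = read_rois(inp.rois)
            raw_clusters = cluster_table(assign_to_cells(raw_locs, rois), params)
            ma = _marker_centroids(raw_clusters, rois, "sRNA")
            mb = _marker_centroids(raw_clusters, rois, "mRNA")
            shift = estimate_chromatic_shift(ma, mb, config.match_radius)
            with open(out / f"shift_{label}.json", "w") as fh:
                json.dump(shift.to_dict(), fh, indent=1)

        # --- cluster the registered scene
        with stage(f"cluster[{label}]"):
            clusters, rois = _load_and_cluster(inp, params, shift=shift)
            marker_ids = {r.cell_id for r in rois if r.strain_label == MARKER_LABEL}
            clusters = clusters[~clusters["cell_id"].isin(marker_ids)]
            clusters.to_csv(out / f"clusters_{label}.tsv", sep="\t", index=False)

        # --- copy numbers, background-corrected on the sRNA channel
        with stage(f"quantify[{label}]"):
            cond_ids = sorted(r.cell_id for r in rois
                              if r.strain_label != MARKER_LABEL)
            copies = {}
            for channel in ("sRNA", "mRNA"):
                sub = clusters[clusters["channel"] == channel]
                by_cell = {c: sub.loc[sub["cell_id"] == c, "n_spots"].tolist()
                           for c in cond_ids}
                raw = np.array([copies_per_cell({c: by_cell[c]}, ref)[c]
                                for c in cond_ids], float)
                copies[channel] = raw
            corrected_s = correct_background(copies["sRNA"], background)
            copies_df = pd.DataFrame({
                "cell_id": cond_ids,
                "raw_srna": copies["sRNA"],
                "corrected_srna": corrected_s,
                "raw_mrna": copies["mRNA"],
            })
            copies_df.to_csv(out / f"copies_{label}.tsv", sep="\t", index=False)

        # --- colocalization
        with stage(f"colocalize[{label}]"):
            srna_cl = clusters[clusters["channel"] == "sRNA"]
            mrna_cl = clusters[clusters["channel"] == "mRNA"]
            coloc = colocalization_percentage(
                mrna_cl[["cx", "cy", "cz"]].to_numpy(float),
                srna_cl[["cx", "cy", "cz"]].to_numpy(float),
                cutoff=config.cutoff,
            )
            baseline_fraction = 0.0
            if config.baseline_mode == "csr":
                cond_rois = [r for r in rois if r.strain_label != MARKER_LABEL]
                mean_vol = float(np.mean([r.volume() for r in cond_rois]))
                lam = len(srna_cl) / (len(cond_ids) * mean_vol)
                base = csr_baseline(
                    n_mrna=max(int(round(len(mrna_cl) / len(cond_ids))), 1),
                    lam=lam, geometry=cond_rois[0], cutoff=config.cutoff,
                    n_draws=200, seed=config.seed,
                )
                baseline_fraction = base.mc_fraction
                coloc.baseline = base
            with open(out / f"coloc_{label}.json", "w") as fh:
                json.dump(coloc.to_dict(), fh, indent=1, default=float)

        per_condition[label] = {
            "n_cells": len(cond_ids),
            "mean_srna_copies": float(np.mean(corrected_s)),
            "sd_srna_copies": float(np.std(corrected_s, ddof=1)),
            "mean_mrna_copies": float(np.mean(copies["mRNA"])),
            "colocalized_fraction": coloc.fraction,
            "baseline_fraction": baseline_fraction,
            "n_mrna_clusters": coloc.n_mrna_clusters,
        }
        fractions[label] = subtract_baseline(coloc.fraction, baseline_fraction)

    # --- empirical baseline replaces the CSR one if requested
    if config.baseline_mode == "empirical":
        neg = per_condition[config.negative_control]["colocalized_fraction"]
        for label in config.conditions:
            per_condition[label]["baseline_fraction"] = neg
            fractions[label] = subtract_baseline(
                per_condition[label]["colocalized_fraction"], neg
            )

    # --- affinity: K_D per condition, ratio and fold vs the reference
    kd_ratios: dict[str, dict] = {}
    with stage("affinity"):
        kds = {}
        for label, summary in per_condition.items():
            if config.baseline_mode == "empirical" and label == config.negative_control:
                continue
            est = estimate_kd(AffinityInput(
                S=summary["mean_srna_copies"],
                M=summary["mean_mrna_copies"],
                f=fractions[label],
                V=config.volume,
                condition_label=label,
            ))
            kds[label] = est.kd
            per_condition[label]["kd"] = est.kd
        ref_kd = kds[config.reference_condition]
        for label, kd in kds.items():
            if label == config.reference_condition:
                continue
            ratio, fold = kd_ratio_and_fold(kd, ref_kd)
            kd_ratios[label] = {"vs": config.reference_condition,
                                "ratio": ratio, "fold_affinity": fold}

    report = PipelineReport(
        per_condition=per_condition,
        kd_ratios=kd_ratios,
        provenance={
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.content_hash(),
        },
        warnings=collected,
        timings=timings,
    )
    report.save(out / "report.json")
    return report
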