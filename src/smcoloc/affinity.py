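"""Apparent dissociation constants from copy numbers and bound fractions.

The sRNA:mRNA complex is modeled as single-site mass-action binding at
equilibrium, S + M ⇌ SM with dissociation constant

    K_D = [S]_free [M]_free / [SM].

With S total sRNA copies per cell, M total mRNA copies, f the bound fraction
of mRNA (the colocalization fraction, optionally baseline-subtracted) and V
the cell volume, the complex count is C = f·M and

    K_D = (S − f·M)(1 − f) / (f · V).

V cancels in condition ratios when cell volumes are equal, so the default
V = 1 reports K_D in copies-per-cell-volume units; passing V in liters and
``molar=True`` converts to molar via Avogadro's number. The forward model —
the bound-complex count at equilibrium given totals and K_D·V — is the
positive root of the binding quadratic and is shared with the simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

AVOGADRO = 6.02214076e23


class NoComplexError(ValueError):
    """Bound fraction is zero: K_D is unidentified (no complexes observed)."""


@dataclass(frozen=True)
class AffinityInput:
    S: float  # sRNA copies per cell, background-corrected
    M: float  # mRNA copies per cell
    f: float  # bound fraction of mRNA
    V: float = 1.0  # cell volume (consistent units across conditions)
    condition_label: str = ""

    def __post_init__(self):
        if self.S < 0 or self.M <= 0:
            raise ValueError("require S >= 0 and M > 0")
        if not (0 <= self.f < 1):
            raise ValueError("require 0 <= f < 1")
        if self.V <= 0:
            raise ValueError("require V > 0")


@dataclass(frozen=True)
class AffinityEstimate:
    kd: float  # copies per volume unit (or molar)
    condition_label: str = ""

    def __post_init__(self):
        if self.kd < 0:
            raise ValueError("kd must be >= 0")


def estimate_kd(inp: AffinityInput, molar: bool = False) -> AffinityEstimate:
    """K_D = (S − f·M)(1 − f)/(f·V) from a single condition's observables."""
    if inp.f == 0:
        raise NoComplexError("f = 0: no complexes, K_D unidentified")
    complexes = inp.f * inp.M
    s_free = inp.S - complexes
    if s_free < 0:
        warnings.warn(
            f"f*M = {complexes:.3g} exceeds S = {inp.S:.3g}; clamping free sRNA "
            "to 0 (K_D = 0). Check copy numbers and bound fraction."
        )
        s_free = 0.0
    kd = s_free * (1 - inp.f) / (inp.f * inp.V)
    if molar:
        kd /= AVOGADRO
    return AffinityEstimate(kd=kd, condition_label=inp.condition_label)


def kd_ratio_and_fold(
    kd_test: AffinityEstimate | float, kd_ref: AffinityEstimate | float
) -> tuple[float, float]:
    """Condition ratio K_D,test / K_D,ref and the affinity fold-change 1/ratio.

    A ratio below 1 means the test condition binds more tightly; e.g. a K_D
    ratio of 0.4 is a 2.5-fold higher affinity.
    """
    kt = kd_test.kd if isinstance(kd_test, AffinityEstimate) else float(kd_test)
    kr = kd_ref.kd if isinstance(kd_ref, AffinityEstimate) else float(kd_ref)
    if kr == 0:
        raise ZeroDivisionError("reference K_D is 0; ratio undefined")
    ratio = kt / kr
    return ratio, 1.0 / ratio


def equilibrium_complex_count(S: float, M: float, kd_v: float) -> float:
    """Bound complexes at equilibrium for totals S, M and K_D·V (copies).

    The positive root of (S − C)(M − C) = kd_v·C:
    C = ((S + M + kd_v) − sqrt((S + M + kd_v)² − 4 S M)) / 2, with
    0 ≤ C ≤ min(S, M). kd_v = 0 gives the infinite-affinity limit min(S, M).
    """
    if S < 0 or M < 0 or kd_v < 0:
        raise ValueError("S, M, kd_v must be non-negative")
    b = S + M + kd_v
    disc = b * b - 4.0 * S * M
    # 2SM/(b + sqrt(disc)) is the cancellation-free form of (b - sqrt(disc))/2
    denom = b + np.sqrt(max(disc, 0.0))
    c = 2.0 * S * M / denom if denom > 0 else 0.0
    return float(min(max(c, 0.0), min(S, M)))


def subtract_baseline(f: float, baseline: float) -> float:
    """Correct a colocalized fraction by the random baseline, floored at 0."""
    return max(0.0, f - baseline)
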