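"""Hakanson potential ecological risk index (RI) for heavy-metal soils.

The index sums per-metal risk factors Er_i = TF_i * C_i / C_bg,i, where C_i
is the measured concentration, C_bg,i the regional background and TF_i the
metal's toxicity factor (conventionally Pb = 5, Cd = 30).  Treatments are
designed by *inverse* use of the index: :func:`solve_additions` computes how
much of each metal to add to reach a target RI, the way graded L/M/H
microcosm levels (RI = 100/200/400) are constructed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MetalSpec",
    "RiskResult",
    "DEFAULT_TOXICITY_FACTORS",
    "DEFAULT_RISK_TARGETS",
    "contamination_factor",
    "risk_factor",
    "ecological_risk_index",
    "classify_risk",
    "solve_additions",
]

#: Conventional Hakanson toxicity factors for the two metals of the design.
DEFAULT_TOXICITY_FACTORS: dict[str, float] = {"Pb": 5.0, "Cd": 30.0}

#: Designed treatment targets: low, moderate and high ecological risk.
DEFAULT_RISK_TARGETS: dict[str, float] = {"L": 100.0, "M": 200.0, "H": 400.0}


@dataclass(frozen=True)
class MetalSpec:
    """One metal's concentration, background and toxicity factor (mg/kg)."""

    metal: str
    concentration: float
    background: float
    toxicity_factor: float

    def __post_init__(self) -> None:
        if self.background <= 0:
            raise ValueError(f"{self.metal}: background must be > 0")
        if self.concentration < 0:
            raise ValueError(f"{self.metal}: concentration must be >= 0")
        if self.toxicity_factor <= 0:
            raise ValueError(f"{self.metal}: toxicity factor must be > 0")


@dataclass(frozen=True)
class RiskResult:
    """Per-metal contamination/risk factors and the summed index."""

    contamination_factors: Mapping[str, float]
    risk_factors: Mapping[str, float]
    RI: float
    level: str

    def __post_init__(self) -> None:
        total = sum(self.risk_factors.values())
        if not np.isclose(total, self.RI, rtol=0, atol=1e-9 * max(1.0, abs(total))):
            raise ValueError(f"RI {self.RI} != sum of risk factors {total}")


def contamination_factor(concentration: float, background: float) -> float:
    """Cf = C / C_bg."""
    if background <= 0:
        raise ValueError(f"background must be > 0, got {background}")
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    return concentration / background


def risk_factor(cf: float, toxicity_factor: float) -> float:
    """Er = TF * Cf."""
    if cf < 0 or toxicity_factor < 0:
        raise ValueError("contamination and toxicity factors must be >= 0")
    return toxicity_factor * cf


def classify_risk(
    ri: float, level_targets: Mapping[str, float] | None = None
) -> str:
    """Label an RI by the nearest designed target (ties go to the lower one).

    Classification is against the designed treatment targets rather than
    published Hakanson band edges, because graded microcosm levels are
    named by their designed RI.
    """
    targets = dict(level_targets) if level_targets else dict(DEFAULT_RISK_TARGETS)
    if not targets:
        raise ValueError("level_targets must be non-empty")
    # sort by (distance, target value) so equidistant RIs take the lower target
    return min(targets.items(), key=lambda kv: (abs(ri - kv[1]), kv[1]))[0]


def ecological_risk_index(
    metal_specs: Sequence[MetalSpec],
    level_targets: Mapping[str, float] | None = None,
) -> RiskResult:
    """RI = sum_i TF_i * C_i / C_bg,i with a level label."""
    if not metal_specs:
        raise ValueError("need at least one metal")
    names = [m.metal for m in metal_specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate metals: {names}")
    cfs = {m.metal: contamination_factor(m.concentration, m.background) for m in metal_specs}
    ers = {m.metal: risk_factor(cfs[m.metal], m.toxicity_factor) for m in metal_specs}
    ri = float(sum(ers.values()))
    return RiskResult(cfs, ers, ri, classify_risk(ri, level_targets))


def solve_additions(
    target_ri: float,
    metal_specs: Sequence[MetalSpec],
    allocation: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Metal additions (mg/kg) that raise the current RI to ``target_ri``.

    ``allocation`` splits the *added risk* among metals (fractions summing
    to 1; default equal split).  Because RI is linear in concentration,
    added_i = allocation_i * (target - RI_current) * background_i / TF_i,
    and re-scoring the amended soil reproduces the target exactly.
    """
    current = ecological_risk_index(metal_specs)
    if target_ri < current.RI - 1e-12:
        raise ValueError(
            f"target RI {target_ri} is below the current RI {current.RI:.6g}"
        )
    metals = [m.metal for m in metal_specs]
    if allocation is None:
        allocation = {m: 1.0 / len(metals) for m in metals}
    if set(allocation) != set(metals):
        raise ValueError("allocation must cover exactly the given metals")
    alloc_sum = sum(allocation.values())
    if not np.isclose(alloc_sum, 1.0, atol=1e-9):
        raise ValueError(f"allocation fractions must sum to 1, got {alloc_sum}")
    delta = max(target_ri - current.RI, 0.0)
    return {
        m.metal: allocation[m.metal] * delta * m.background / m.toxicity_factor
        for m in metal_specs
    }
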