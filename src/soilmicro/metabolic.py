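"""Biolog plate metabolic profiling and HT-qPCR functional-gene abundance.

Community-level physiological profiling (CLPP) reads sole-carbon-source
utilisation off ECO (bacteria; 31 substrates in triplicate) and FF (fungi;
95 single-well substrates) plates: control-corrected optical densities give
the average well colour development (AWCD), per-substrate-group
intensities, and the functional diversity indices H' (Shannon-Wiener),
D (Simpson) and U (McIntosh).

Functional genes are quantified from high-throughput qPCR threshold cycles
(QMEC-style chip: 72 genes across the C, N, P and S cycles).  Genes whose
amplification efficiency falls outside 1.8-2.2 are discarded, and a CT of
31 is the detection limit: relative copy number = 10^((31 - CT) * 3/10),
zero at or beyond the limit.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import GroupComparison, group_compare
from .io_core import PlateReading

logger = logging.getLogger("soilmicro")

__all__ = [
    "SubstrateScheme",
    "PlateProfile",
    "GeneAbundance",
    "load_scheme",
    "load_gene_catalog",
    "correct_od",
    "awcd",
    "substrate_group_intensity",
    "functional_diversity",
    "efficiency_filter",
    "qmec_quantify",
    "cycle_summaries",
]


@dataclass(frozen=True)
class SubstrateScheme:
    """Well layout of one Biolog plate kind.

    ``wells`` maps each substrate to its replicate wells (three for ECO,
    one for FF); ``groups`` maps substrates to their biochemical group.
    """

    kind: str
    groups: Mapping[str, str]
    wells: Mapping[str, tuple[str, ...]]
    control_wells: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.groups) != set(self.wells):
            raise ValueError("groups and wells must cover the same substrates")

    @property
    def substrates(self) -> tuple[str, ...]:
        return tuple(self.wells)

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.groups.values():
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def wells_flat(self) -> list[str]:
        return [w for ws in self.wells.values() for w in ws]


def _read_packaged_csv(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("soilmicro.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def load_scheme(kind: str) -> SubstrateScheme:
    """Load the bundled ECO or FF substrate scheme."""
    kind = kind.upper()
    if kind not in ("ECO", "FF"):
        raise ValueError(f"unknown plate kind {kind!r}; expected 'ECO' or 'FF'")
    df = _read_packaged_csv(f"{kind.lower()}_scheme.csv")
    controls = tuple(df.loc[df["group"] == "control", "well"])
    sub = df[df["group"] != "control"]
    wells: dict[str, list[str]] = {}
    groups: dict[str, str] = {}
    for _, row in sub.iterrows():
        wells.setdefault(row["substrate"], []).append(row["well"])
        groups[row["substrate"]] = row["group"]
    return SubstrateScheme(
        kind=kind,
        groups=groups,
        wells={s: tuple(w) for s, w in wells.items()},
        control_wells=controls,
    )


def load_gene_catalog() -> dict[str, str]:
    """Bundled 72-gene catalog mapping gene name to cycle (C/N/P/S)."""
    df = _read_packaged_csv("gene_catalog.csv")
    return dict(zip(df["gene"], df["category"]))


# ---------------------------------------------------------------------------
# plate profiling


@dataclass(frozen=True)
class PlateProfile:
    """Control-corrected absorbances, substrate x timepoint."""

    kind: str
    substrates: tuple[str, ...]
    times: np.ndarray
    corrected: np.ndarray  # substrates x timepoints, floored at 0

    def at(self, time: float) -> np.ndarray:
        idx = np.where(np.isclose(self.times, time))[0]
        if idx.size == 0:
            raise ValueError(
                f"timepoint {time} h not recorded; available: {self.times.tolist()}"
            )
        return self.corrected[:, idx[0]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.corrected, index=list(self.substrates), columns=self.times
        )


def correct_od(
    reading: PlateReading, scheme: SubstrateScheme | None = None
) -> PlateProfile:
    """Subtract the mean control well from replicate-averaged absorbances.

    ECO triplicate wells are averaged before correction; negative corrected
    values are floored at zero.
    """
    if scheme is None:
        scheme = load_scheme(reading.kind)
    if scheme.kind != reading.kind:
        raise ValueError(
            f"scheme kind {scheme.kind} does not match plate kind {reading.kind}"
        )
    present = set(reading.wells)
    missing_controls = [w for w in scheme.control_wells if w not in present]
    if len(missing_controls) == len(scheme.control_wells):
        raise ValueError(f"no control wells ({scheme.control_wells}) in reading")
    control = np.mean(
        [reading.series(w) for w in scheme.control_wells if w in present], axis=0
    )
    rows = []
    for substrate in scheme.substrates:
        wells = [w for w in scheme.wells[substrate] if w in present]
        if not wells:
            raise ValueError(f"substrate {substrate!r}: no wells in reading")
        rows.append(np.mean([reading.series(w) for w in wells], axis=0) - control)
    corrected = np.maximum(np.array(rows), 0.0)
    return PlateProfile(reading.kind, scheme.substrates, reading.times, corrected)


def awcd(profile: PlateProfile, time: float = 168.0) -> float:
    """Average well colour development: mean corrected OD at ``time``."""
    return float(profile.at(time).mean())


def substrate_group_intensity(
    profile: PlateProfile, scheme: SubstrateScheme | None = None, time: float = 168.0
) -> dict[str, float]:
    """Mean corrected OD per biochemical substrate group at ``time``."""
    if scheme is None:
        scheme = load_scheme(profile.kind)
    if scheme.kind != profile.kind:
        raise ValueError(
            f"scheme kind {scheme.kind} does not match profile kind {profile.kind}"
        )
    values = profile.at(time)
    out: dict[str, list[float]] = {}
    for substrate, v in zip(profile.substrates, values):
        out.setdefault(scheme.groups[substrate], []).append(v)
    return {g: float(np.mean(v)) for g, v in out.items()}


def functional_diversity(profile: PlateProfile, time: float = 168.0) -> dict[str, float]:
    """Shannon-Wiener H', Simpson D and McIntosh U of the utilisation profile.

    With p_i the share of substrate i in total corrected colour:
    H' = -sum p_i ln p_i, D = 1 - sum p_i^2, U = sqrt(sum C_i^2).
    """
    c = profile.at(time)
    total = c.sum()
    if total <= 0:
        raise ValueError("all corrected absorbances are zero at this time")
    p = c[c > 0] / total
    return {
        "H": float(-np.sum(p * np.log(p))),
        "D": float(1.0 - np.sum(p**2)),
        "U": float(np.sqrt(np.sum(c**2))),
    }


# ---------------------------------------------------------------------------
# HT-qPCR gene quantification


@dataclass(frozen=True)
class GeneAbundance:
    """Relative copy numbers (gene x sample) with cycle categories."""

    copies: pd.DataFrame
    categories: Mapping[str, str]
    efficiencies: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if (self.copies < 0).any().any():
            raise ValueError("copy numbers must be >= 0")
        missing = set(self.copies.index) - set(self.categories)
        if missing:
            raise ValueError(f"genes without category: {sorted(missing)}")


def efficiency_filter(
    efficiencies: Mapping[str, float],
    efficiency_range: tuple[float, float] = (1.8, 2.2),
) -> list[str]:
    """Genes whose amplification efficiency lies within the window."""
    lo, hi = efficiency_range
    kept, dropped = [], []
    for gene, e in efficiencies.items():
        if e <= 0:
            raise ValueError(f"{gene}: efficiency must be positive, got {e}")
        (kept if lo <= e <= hi else dropped).append(gene)
    if dropped:
        logger.info(
            "efficiency filter removed %d genes outside [%g, %g]: %s",
            len(dropped), lo, hi, dropped,
        )
    return kept


def qmec_quantify(
    ct: pd.DataFrame,
    categories: Mapping[str, str],
    detection_ct: float = 31.0,
    efficiencies: Mapping[str, float] | None = None,
    efficiency_range: tuple[float, float] = (1.8, 2.2),
    scale_16s: Mapping[str, float] | None = None,
) -> GeneAbundance:
    """Relative copy numbers from threshold cycles.

    CT at or beyond the detection limit (or missing) means not detected
    (0 copies); otherwise copies = 10^((limit - CT) * 3/10), i.e. one
    ten-fold dilution per 10/3 cycles.  If ``efficiencies`` are given the
    window filter is applied first; ``scale_16s`` optionally multiplies
    each sample's copies by its 16S copy density for absolute abundance.
    """
    if efficiencies is not None:
        kept = efficiency_filter(efficiencies, efficiency_range)
        ct = ct.loc[[g for g in ct.index if g in kept]]
    copies = np.power(10.0, (detection_ct - ct) * 0.3)
    copies = copies.where(ct < detection_ct, 0.0).fillna(0.0)
    if scale_16s is not None:
        copies = copies.mul(pd.Series(scale_16s), axis=1)
    cats = {g: categories.get(g, "unknown") for g in copies.index}
    return GeneAbundance(copies, cats, efficiencies)


def cycle_summaries(
    abundance: GeneAbundance,
    groups: Sequence[str] | Mapping[str, str],
) -> dict[str, object]:
    """Per-category totals and group comparisons of gene abundance.

    Returns the per-sample total, the per-category x sample sums (which
    conserve the grand total exactly), and a :class:`GroupComparison`
    (letters from Holm-adjusted pairwise t-tests) for the total and each
    category.
    """
    copies = abundance.copies
    if isinstance(groups, Mapping):
        group_list = [groups[s] for s in copies.columns]
    else:
        group_list = list(groups)
    if len(group_list) != copies.shape[1]:
        raise ValueError("groups must match the sample columns")
    cat = pd.Series({g: abundance.categories[g] for g in copies.index})
    category_sums = copies.groupby(cat).sum()
    totals = copies.sum(axis=0)
    comparisons: dict[str, GroupComparison] = {}
    for name, values in [("total", totals), *category_sums.iterrows()]:
        try:
            comparisons[name] = group_compare(np.asarray(values), group_list)
        except ValueError as exc:  # e.g. a category with zero variance everywhere
            logger.warning("group comparison skipped for %s: %s", name, exc)
    return {
        "totals": totals,
        "category_sums": category_sums,
        "comparisons": comparisons,
    }
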