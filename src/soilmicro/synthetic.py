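"""Seeded generators for every input the pipeline consumes.

The generators emulate a graded heavy-metal microcosm study: four
treatment groups (CK control plus L/M/H at designed risk-index targets
100/200/400), 5-6 replicates each, bacterial activity declining and fungal
abundance rising with risk level, neutral vs environmentally filtered
community assembly, logistic Biolog colour development, and qPCR threshold
cycles around a detection limit of 31.  Every generator is a pure function
of its parameters and seed, and ground truth is recorded alongside each
dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import AbundanceTable, PlateReading, SampleMetadata, write_abundance_table, write_metadata, stage_rng
from .metabolic import load_gene_catalog, load_scheme
from .risk import DEFAULT_RISK_TARGETS, DEFAULT_TOXICITY_FACTORS, MetalSpec, ecological_risk_index, solve_additions

__all__ = [
    "ExperimentDesign",
    "lognormal_metacommunity",
    "simulate_neutral",
    "simulate_filtered",
    "simulate_plate",
    "write_plate",
    "simulate_experiment",
]

PLATE_TIMES = np.arange(0.0, 169.0, 24.0)  # 0..168 h, daily readings


def lognormal_metacommunity(
    n_taxa: int, sigma: float = 1.5, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Lognormal rank-abundance metacommunity (sums to 1).

    sigma controls evenness; the default gives both abundant (> 1%) and
    rare (< 1%) taxa at a few hundred taxa, as in real soil communities.
    """
    rng = rng or np.random.default_rng(0)
    x = np.sort(rng.lognormal(mean=0.0, sigma=sigma, size=n_taxa))[::-1]
    return x / x.sum()


def simulate_neutral(
    p: np.ndarray,
    m: float,
    N: int,
    n_samples: int,
    seed: int | np.random.Generator | None = None,
    sample_prefix: str = "S",
) -> AbundanceTable:
    """Sample communities from the Sloan neutral model.

    Per sample, taxon proportions are drawn from the model's stationary
    Beta(N m p_i, N m (1-p_i)) marginals, renormalised, and N reads drawn
    multinomially -- the exact sampling dual of the model's occurrence
    prediction.
    """
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-8) or np.any(p <= 0):
        raise ValueError("p must be positive and sum to 1")
    if m <= 0:
        raise ValueError("m must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.empty((n_samples, p.size), dtype=np.int64)
    for j in range(n_samples):
        x = rng.beta(N * m * p, N * m * (1.0 - p))
        x = x / x.sum()
        counts[j] = rng.multinomial(N, x)
    sample_ids = tuple(f"{sample_prefix}{j+1}" for j in range(n_samples))
    taxon_ids = tuple(f"OTU{i+1}" for i in range(p.size))
    return AbundanceTable(sample_ids, taxon_ids, counts)


def simulate_filtered(
    p: np.ndarray,
    gradient: float,
    niche_optima: np.ndarray,
    strength: float,
    N: int,
    n_samples: int,
    seed: int | np.random.Generator | None = None,
    noise_sigma: float = 0.3,
    sample_prefix: str = "S",
) -> AbundanceTable:
    """Sample communities under deterministic environmental filtering.

    Expected abundance of taxon i is p_i scaled by a Gaussian fitness
    kernel exp(-strength (gradient - optimum_i)^2) and renormalised;
    replicates get lognormal noise (sigma ``noise_sigma``) before N reads
    are drawn multinomially.  strength = 0 reduces to noisy sampling of p.
    """
    p = np.asarray(p, dtype=float)
    optima = np.asarray(niche_optima, dtype=float)
    if strength < 0:
        raise ValueError("strength must be >= 0")
    if optima.shape != p.shape:
        raise ValueError("niche_optima must match p")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fitness = np.exp(-strength * (gradient - optima) ** 2)
    expected = p * fitness
    expected = expected / expected.sum()
    counts = np.empty((n_samples, p.size), dtype=np.int64)
    for j in range(n_samples):
        w = expected * rng.lognormal(0.0, noise_sigma, size=p.size)
        counts[j] = rng.multinomial(N, w / w.sum())
    sample_ids = tuple(f"{sample_prefix}{j+1}" for j in range(n_samples))
    taxon_ids = tuple(f"OTU{i+1}" for i in range(p.size))
    return AbundanceTable(sample_ids, taxon_ids, counts)


# ---------------------------------------------------------------------------
# plates


def simulate_plate(
    kind: str,
    rate_multiplier: float = 1.0,
    times: np.ndarray | Sequence[float] = PLATE_TIMES,
    noise_sd: float = 0.01,
    seed: int | np.random.Generator | None = None,
) -> PlateReading:
    """Raw Biolog plate with logistic colour development.

    Each substrate develops as OD(t) = A / (1 + exp(-r (t - t0))) with
    amplitude, rate and midpoint drawn per substrate; the treatment's
    ``rate_multiplier`` scales every rate (0 gives a flat plate).  Control
    wells carry only the shared baseline drift; Gaussian noise is added to
    every well.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly ascending")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scheme = load_scheme(kind)
    substrates = scheme.substrates
    amplitude = rng.uniform(0.8, 2.0, size=len(substrates))
    rate = rng.uniform(0.04, 0.09, size=len(substrates)) * rate_multiplier
    midpoint = rng.uniform(48.0, 110.0, size=len(substrates))
    baseline = 0.05 + 0.0002 * times  # shared drift, removed by correction
    wells, rows = [], []
    # deterministic well order: scheme order, controls last
    for s_idx, substrate in enumerate(substrates):
        if rate_multiplier > 0:
            curve = amplitude[s_idx] / (1.0 + np.exp(-rate[s_idx] * (times - midpoint[s_idx])))
        else:
            curve = np.zeros_like(times)
        for w in scheme.wells[substrate]:
            wells.append(w)
            rows.append(baseline + curve + rng.normal(0.0, noise_sd, size=times.size))
    for w in scheme.control_wells:
        wells.append(w)
        rows.append(baseline + rng.normal(0.0, noise_sd, size=times.size))
    od = np.maximum(np.array(rows), 0.0)
    idx = sorted(range(len(wells)), key=lambda k: (wells[k][0], int(wells[k][1:])))
    return PlateReading(
        kind=scheme.kind,
        wells=tuple(wells[k] for k in idx),
        times=times,
        od=od[idx],
    )


def write_plate(reading: PlateReading, path: str | Path) -> None:
    """Write a raw plate CSV with a '# plate: KIND' header line."""
    with open(path, "w") as fh:
        fh.write(f"# plate: {reading.kind}\n")
        fh.write("well," + ",".join(f"{t:g}" for t in reading.times) + "\n")
        for w, row in zip(reading.wells, reading.od):
            fh.write(w + "," + ",".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# full experiment


@dataclass
class ExperimentDesign:
    """Study design: groups, effect sizes and per-group assembly regimes.

    Defaults emulate the reference design qualitatively: bacterial totals
    and metabolic rates decline with risk level while fungal totals rise;
    bacterial assembly is neutral in CK, filtered at L/M and neutral again
    (lower migration) at H; fungal assembly is filtered in CK and neutral
    under treatment.
    """

    replicates: Mapping[str, int] = field(
        default_factory=lambda: {"CK": 6, "L": 5, "M": 6, "H": 6}
    )
    n_bacteria: int = 300
    n_fungi: int = 150
    reads_per_sample: int = 2000
    metacommunity_sigma: float = 1.5
    # per-group assembly regime: ("neutral", m) or ("filtered", strength)
    bacteria_assembly: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: {
            "CK": ("neutral", 0.3),
            "L": ("filtered", 30.0),
            "M": ("filtered", 20.0),
            "H": ("neutral", 0.1),
        }
    )
    fungi_assembly: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: {
            "CK": ("filtered", 30.0),
            "L": ("neutral", 0.1),
            "M": ("neutral", 0.2),
            "H": ("neutral", 0.3),
        }
    )
    # total-abundance multipliers (drive qPCR copy totals)
    bacteria_abundance: Mapping[str, float] = field(
        default_factory=lambda: {"CK": 1.0, "L": 0.7, "M": 0.5, "H": 0.3}
    )
    fungi_abundance: Mapping[str, float] = field(
        default_factory=lambda: {"CK": 1.0, "L": 1.3, "M": 1.6, "H": 2.0}
    )
    # plate colour-development rate multipliers
    eco_rate: Mapping[str, float] = field(
        default_factory=lambda: {"CK": 1.0, "L": 0.8, "M": 0.6, "H": 0.45}
    )
    ff_rate: Mapping[str, float] = field(
        default_factory=lambda: {"CK": 1.0, "L": 0.95, "M": 0.9, "H": 0.5}
    )
    plate_noise_sd: float = 0.01
    # gene panel
    gene_base_log10_copies: tuple[float, float] = (4.0, 7.0)  # uniform range
    gene_abundance: Mapping[str, float] = field(
        default_factory=lambda: {"CK": 1.0, "L": 0.8, "M": 0.6, "H": 0.35}
    )
    gene_noise_sigma: float = 0.15
    efficiency_sd: float = 0.12
    # metals
    backgrounds: Mapping[str, float] = field(
        default_factory=lambda: {"Pb": 26.0, "Cd": 0.2}
    )
    risk_targets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_TARGETS)
    )
    # environmental gradient value per group (drives filtering)
    gradient: Mapping[str, float] = field(
        default_factory=lambda: {"CK": 0.0, "L": 1.0, "M": 2.0, "H": 4.0}
    )

    def __post_init__(self) -> None:
        if any(r < 3 for r in self.replicates.values()):
            raise ValueError("every group needs >= 3 replicates")
        for mapping in (self.bacteria_abundance, self.fungi_abundance):
            if any(v <= 0 for v in mapping.values()):
                raise ValueError("abundance multipliers must be > 0")


def _random_tree_newick(taxa: Sequence[str], rng: np.random.Generator) -> str:
    """Random bifurcating topology with exponential branch lengths."""
    nodes = [f"{t}:{rng.exponential(1.0):.6f}" for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.exponential(1.0):.6f}")
    inner = nodes[0].rsplit(":", 1)[0]
    return inner + ";"


def _group_table(
    domain: str,
    level: str,
    design: ExperimentDesign,
    p: np.ndarray,
    optima: np.ndarray,
    rng: np.random.Generator,
) -> AbundanceTable:
    regime, param = (
        design.bacteria_assembly[level] if domain == "bacteria" else design.fungi_assembly[level]
    )
    n_rep = design.replicates[level]
    prefix = f"{level}{'' if domain == 'bacteria' else ''}"
    if regime == "neutral":
        return simulate_neutral(
            p, param, design.reads_per_sample, n_rep, seed=rng, sample_prefix=prefix
        )
    if regime == "filtered":
        return simulate_filtered(
            p,
            design.gradient[level],
            optima,
            param,
            design.reads_per_sample,
            n_rep,
            seed=rng,
            sample_prefix=prefix,
        )
    raise ValueError(f"unknown assembly regime {regime!r}")


def _concat_tables(tables: Sequence[AbundanceTable]) -> AbundanceTable:
    taxa = tables[0].taxon_ids
    counts = np.vstack([t.counts for t in tables])
    sample_ids = tuple(s for t in tables for s in t.sample_ids)
    return AbundanceTable(sample_ids, taxa, counts)


def simulate_experiment(
    design: ExperimentDesign, seed: int, out_dir: str | Path
) -> dict:
    """Generate a full dataset directory plus ground truth.

    Writes otu_bacteria.tsv / otu_fungi.tsv, metadata.csv, newick trees,
    per-sample ECO and FF plate CSVs, a gene CT table with amplification
    efficiencies, and a metals CSV whose amendments hit the designed risk
    targets exactly; ground_truth.json records every generative parameter.
    """
    out = Path(out_dir)
    (out / "plates").mkdir(parents=True, exist_ok=True)
    levels = list(design.replicates)

    # --- communities -------------------------------------------------------
    tables: dict[str, AbundanceTable] = {}
    meta_rows: dict[str, tuple[str, int]] = {}
    for domain, n_taxa in (("bacteria", design.n_bacteria), ("fungi", design.n_fungi)):
        rng = stage_rng(seed, f"community/{domain}")
        p = lognormal_metacommunity(n_taxa, design.metacommunity_sigma, rng)
        optima = rng.uniform(0.0, 4.0, size=n_taxa)
        per_level = []
        for level in levels:
            t = _group_table(domain, level, design, p, optima, rng)
            ids = tuple(f"{level}{r+1}" for r in range(t.n_samples))
            per_level.append(AbundanceTable(ids, t.taxon_ids, t.counts))
            for r, sid in enumerate(ids):
                meta_rows[sid] = (level, r + 1)
        prefix = "B" if domain == "bacteria" else "F"
        merged = _concat_tables(per_level)
        merged = AbundanceTable(
            merged.sample_ids,
            tuple(f"{prefix}_{t}" for t in merged.taxon_ids),
            merged.counts,
            {f"{prefix}_{t}": f"d__{domain.capitalize()};otu__{t}" for t in merged.taxon_ids},
        )
        tables[domain] = merged
        write_abundance_table(merged, out / f"otu_{domain}.tsv")
        tree_rng = stage_rng(seed, f"tree/{domain}")
        (out / f"tree_{domain}.nwk").write_text(
            _random_tree_newick(merged.taxon_ids, tree_rng) + "\n"
        )

    metadata = SampleMetadata(
        levels={s: lv for s, (lv, _) in meta_rows.items()},
        replicates={s: r for s, (_, r) in meta_rows.items()},
    )
    write_metadata(metadata, out / "metadata.csv")
    sample_ids = list(metadata.levels)

    # --- plates ------------------------------------------------------------
    plate_rng = stage_rng(seed, "plates")
    for sid in sample_ids:
        level = metadata.levels[sid]
        for kind, rates in (("ECO", design.eco_rate), ("FF", design.ff_rate)):
            reading = simulate_plate(
                kind, rates[level], PLATE_TIMES, design.plate_noise_sd, seed=plate_rng
            )
            write_plate(reading, out / "plates" / f"{sid}_{kind}.csv")

    # --- genes -------------------------------------------------------------
    gene_rng = stage_rng(seed, "genes")
    catalog = load_gene_catalog()
    genes = list(catalog)
    lo, hi = design.gene_base_log10_copies
    base_log10 = gene_rng.uniform(lo, hi, size=len(genes))
    true_copies = pd.DataFrame(index=genes, columns=sample_ids, dtype=float)
    for sid in sample_ids:
        mult = design.gene_abundance[metadata.levels[sid]]
        noise = gene_rng.lognormal(0.0, design.gene_noise_sigma, size=len(genes))
        true_copies[sid] = 10.0**base_log10 * mult * noise
    ct = 31.0 - (10.0 / 3.0) * np.log10(true_copies)
    ct = ct.where(true_copies >= 1.0)  # below one copy: not detected
    ct = ct.where(ct < 31.0)  # at/beyond the detection limit: blank
    ct.round(4).to_csv(out / "genes_ct.csv", index_label="gene")
    eff = 2.0 + gene_rng.normal(0.0, design.efficiency_sd, size=len(genes))
    pd.DataFrame({"gene": genes, "efficiency": np.round(eff, 4)}).to_csv(
        out / "genes_efficiency.csv", index=False
    )

    # --- metals ------------------------------------------------------------
    tf = DEFAULT_TOXICITY_FACTORS
    base_specs = [
        MetalSpec(m, design.backgrounds[m], design.backgrounds[m], tf[m])
        for m in design.backgrounds
    ]
    alloc = {m: 1.0 / len(base_specs) for m in design.backgrounds}
    rows = []
    achieved: dict[str, float] = {}
    for level in levels:
        if level == "CK":
            specs = base_specs
        else:
            added = solve_additions(design.risk_targets[level], base_specs, alloc)
            specs = [
                MetalSpec(s.metal, s.concentration + added[s.metal], s.background, s.toxicity_factor)
                for s in base_specs
            ]
        achieved[level] = ecological_risk_index(specs).RI
        for s in specs:
            rows.append(
                {
                    "level": level,
                    "metal": s.metal,
                    "concentration": round(s.concentration, 9),
                    "background": s.background,
                    "toxicity_factor": s.toxicity_factor,
                }
            )
    pd.DataFrame(rows).to_csv(out / "metals.csv", index=False)

    # --- ground truth ------------------------------------------------------
    truth = {
        "seed": seed,
        "design": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in asdict(design).items()
        },
        "achieved_RI": achieved,
        "assembly": {
            "bacteria": {lv: list(design.bacteria_assembly[lv]) for lv in levels},
            "fungi": {lv: list(design.fungi_assembly[lv]) for lv in levels},
        },
        "plate_rates": {"ECO": dict(design.eco_rate), "FF": dict(design.ff_rate)},
        "gene_multipliers": dict(design.gene_abundance),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
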