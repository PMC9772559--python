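"""Core data containers, file readers/writers, configuration and seeding.

The central object is :class:`AbundanceTable`, a samples x taxa count matrix
with optional taxonomy strings, read from and written to plain TSV.  All
randomness in the pipeline flows from one master seed and is forked per
pipeline stage by stable stage names, so repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import skbio
import yaml

logger = logging.getLogger("soilmicro")

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "RunConfig",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "read_plate",
    "read_gene_ct",
    "read_metals",
    "stage_rng",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class AbundanceTable:
    """Samples x taxa count matrix with taxonomy labels.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample identifiers (rows).
    taxon_ids : sequence of str
        Unique taxon identifiers (columns).
    counts : ndarray of shape (n_samples, n_taxa)
        Non-negative integer read counts.
    taxonomy : mapping taxon_id -> lineage string, optional
        Rank-labelled lineage (e.g. ``d__Bacteria;p__Acidobacteria;...``).
    """

    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    counts: np.ndarray
    taxonomy: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError(f"counts must be 2-D, got shape {counts.shape}")
        if counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon ids")
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        unknown = set(self.taxonomy) - set(self.taxon_ids)
        if unknown:
            raise ValueError(f"taxonomy refers to unknown taxa: {sorted(unknown)[:5]}")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.taxon_ids)
        )

    def relative_abundance(self) -> np.ndarray:
        """Row-normalised counts; samples with zero total raise."""
        totals = self.counts.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            bad = [self.sample_ids[i] for i in np.where(totals[:, 0] == 0)[0]]
            raise ValueError(f"samples with zero total count: {bad}")
        return self.counts / totals

    def mean_relative_abundance(self) -> np.ndarray:
        """Per-taxon mean of within-sample relative abundances."""
        return self.relative_abundance().mean(axis=0)

    def select_taxa(self, taxa: Sequence[str]) -> "AbundanceTable":
        idx = [self.taxon_ids.index(t) for t in taxa]
        return AbundanceTable(
            self.sample_ids,
            tuple(taxa),
            self.counts[:, idx],
            {t: self.taxonomy[t] for t in taxa if t in self.taxonomy},
        )

    def select_samples(self, samples: Sequence[str]) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in samples]
        return AbundanceTable(
            tuple(samples), self.taxon_ids, self.counts[idx, :], dict(self.taxonomy)
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Treatment assignment of the microcosm samples.

    ``levels`` maps sample id to one of CK (control), L, M, H (graded
    ecological-risk treatments); ``replicates`` to the replicate number.
    """

    levels: Mapping[str, str]
    replicates: Mapping[str, int]

    VALID_LEVELS = ("CK", "L", "M", "H")

    def __post_init__(self) -> None:
        for sid, lev in self.levels.items():
            if lev not in self.VALID_LEVELS:
                raise ValueError(
                    f"sample {sid!r}: level {lev!r} not in {self.VALID_LEVELS}"
                )
        missing = set(self.levels) - set(self.replicates)
        if missing:
            raise ValueError(f"samples missing replicate numbers: {sorted(missing)}")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.levels)

    def group_of(self, sample_id: str) -> str:
        return self.levels[sample_id]

    def groups_for(self, sample_ids: Sequence[str]) -> list[str]:
        missing = [s for s in sample_ids if s not in self.levels]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        return [self.levels[s] for s in sample_ids]

    def samples_in(self, level: str) -> list[str]:
        return [s for s, g in self.levels.items() if g == level]


@dataclass
class RunConfig:
    """All tunable pipeline parameters plus the master seed.

    Every stochastic stage forks its generator from ``seed`` via a stable
    stage name, so stages are independently reproducible.
    """

    seed: int = 0
    # network stage
    corr_threshold_min: float = 0.30
    corr_threshold_max: float = 0.95
    corr_threshold_step: float = 0.01
    rmt_fallback_threshold: float = 0.80
    min_mean_relative_abundance: float = 0.0001
    robustness_fraction: float = 0.5
    robustness_iterations: int = 100
    taxon_gene_threshold: float = 0.6
    # diversity stage
    permanova_permutations: int = 999
    ace_rare_cutoff: int = 10
    abundant_fraction: float = 0.01
    # metabolic / genes stage
    awcd_time: float = 168.0
    detection_ct: float = 31.0
    efficiency_range: tuple[float, float] = (1.8, 2.2)
    # assembly stage
    n_null: int = 1000
    # risk stage
    risk_targets: Mapping[str, float] = field(
        default_factory=lambda: {"L": 100.0, "M": 200.0, "H": 400.0}
    )

    def __post_init__(self) -> None:
        if self.robustness_iterations <= 0 or self.permanova_permutations <= 0:
            raise ValueError("iteration/permutation counts must be positive")
        if self.n_null <= 0:
            raise ValueError("n_null must be positive")
        for name in ("robustness_fraction", "abundant_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            logger.warning("ignoring unknown config keys: %s", sorted(unknown))
        if "efficiency_range" in known:
            known["efficiency_range"] = tuple(known["efficiency_range"])
        return cls(**known)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Fork a generator for one pipeline stage from the master seed.

    The fork key is a CRC32 of the stage name, so adding a stage never
    perturbs the streams of existing ones.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(stage.encode()),))
    )


# ---------------------------------------------------------------------------
# abundance table I/O


def read_abundance_table(path: str | Path, format: str = "tsv") -> AbundanceTable:
    """Read a taxa x samples TSV into an :class:`AbundanceTable`.

    The first column holds taxon ids, the remaining columns samples; an
    optional last column named ``taxonomy`` holds lineage strings.
    """
    if format != "tsv":
        raise ValueError(f"unsupported format {format!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a taxon-id column plus >=1 sample column")
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged rows or missing cells")
    taxon_col = df.columns[0]
    taxonomy: dict[str, str] = {}
    if df.columns[-1].lower() == "taxonomy":
        taxonomy = dict(zip(df[taxon_col], df[df.columns[-1]]))
        df = df.iloc[:, :-1]
    taxa = df[taxon_col].tolist()
    sample_cols = list(df.columns[1:])
    try:
        counts = df[sample_cols].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer count ({exc})") from exc
    if np.any(counts < 0):
        i, j = np.argwhere(counts < 0)[0]
        raise ValueError(
            f"{path}: negative count at taxon {taxa[i]!r}, sample {sample_cols[j]!r}"
        )
    return AbundanceTable(tuple(sample_cols), tuple(taxa), counts.T, taxonomy)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write taxa x samples TSV; exact round-trip with the reader."""
    df = pd.DataFrame(
        table.counts.T, index=list(table.taxon_ids), columns=list(table.sample_ids)
    )
    df.index.name = "taxon_id"
    if table.taxonomy:
        df["taxonomy"] = [table.taxonomy.get(t, "") for t in table.taxon_ids]
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata CSV (columns sample_id, level, replicate)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "level": str, "replicate": int})
    required = {"sample_id", "level", "replicate"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dup}")
    return SampleMetadata(
        levels=dict(zip(df["sample_id"], df["level"])),
        replicates=dict(zip(df["sample_id"], df["replicate"])),
    )


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": list(metadata.levels),
            "level": list(metadata.levels.values()),
            "replicate": [metadata.replicates[s] for s in metadata.levels],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# tree I/O


def read_newick(path: str | Path) -> skbio.TreeNode:
    """Read a single rooted newick tree with branch lengths.

    Branches without a length are treated as zero-length, with a warning;
    the tree is returned as a scikit-bio ``TreeNode``.
    """
    # convert_underscores=False: OTU ids routinely contain underscores
    tree = skbio.TreeNode.read(str(path), format="newick", convert_underscores=False)
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        logger.warning(
            "%s: %d branches had no length; treated as 0", path, n_missing
        )
    return tree


# ---------------------------------------------------------------------------
# plate I/O


def read_plate(path: str | Path, kind: str | None = None) -> "PlateReading":
    """Read raw Biolog plate optical densities (well x timepoint CSV).

    The first column is the well label (A1..H12); the remaining column
    headers are reading times in hours, ascending.  The plate kind (ECO or
    FF) is taken from a ``# plate: KIND`` comment line if present, else from
    the ``kind`` argument.
    """
    from .metabolic import load_scheme  # deferred: metabolic imports io_core

    path = Path(path)
    header_kind = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "plate:" in first:
                header_kind = first.split("plate:")[1].strip().upper()
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    kind = (kind or header_kind or "").upper()
    if kind not in ("ECO", "FF"):
        raise ValueError(
            f"{path}: plate kind not declared; pass kind='ECO'|'FF' or add a "
            "'# plate: ECO' header line"
        )
    well_col = df.columns[0]
    wells = df[well_col].astype(str).tolist()
    scheme = load_scheme(kind)
    known = set(scheme.wells_flat()) | set(scheme.control_wells)
    unknown = [w for w in wells if w not in known]
    if unknown:
        raise ValueError(f"{path}: well labels not in the {kind} scheme: {unknown}")
    times = np.array([float(c) for c in df.columns[1:]])
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: timepoints must be strictly ascending, got {times}")
    values = df.iloc[:, 1:].astype(float).to_numpy()
    return PlateReading(kind=kind, wells=tuple(wells), times=times, od=values)


@dataclass(frozen=True)
class PlateReading:
    """Raw plate absorbances before control correction."""

    kind: str
    wells: tuple[str, ...]
    times: np.ndarray
    od: np.ndarray  # wells x timepoints

    def series(self, well: str) -> np.ndarray:
        return self.od[self.wells.index(well)]


# ---------------------------------------------------------------------------
# HT-qPCR I/O


def read_gene_ct(
    path: str | Path, catalog: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a gene x sample threshold-cycle (CT) table.

    Blank cells mean the gene was not detected in that sample and come back
    as NaN.  ``catalog`` maps gene name to its biogeochemical cycle (C, N,
    P or S); genes absent from the catalog are kept with category
    ``"unknown"`` and a warning.  The bundled QMEC-style catalog is used
    when none is given.
    """
    from .metabolic import load_gene_catalog

    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    ct = df.astype(float)
    if (ct.fillna(1.0) <= 0).any().any():
        raise ValueError(f"{path}: CT values must be positive or blank")
    if catalog is None:
        catalog = load_gene_catalog()
    categories = {}
    for gene in ct.index:
        if gene in catalog:
            categories[gene] = catalog[gene]
        else:
            logger.warning("gene %r not in catalog; category set to 'unknown'", gene)
            categories[gene] = "unknown"
    return ct, categories


def read_metals(path: str | Path) -> pd.DataFrame:
    """Read the metals CSV (metal, concentration, background, toxicity_factor
    and optionally a grouping column)."""
    df = pd.read_csv(path)
    required = {"metal", "concentration", "background", "toxicity_factor"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: metals table needs columns {sorted(required)}")
    return df
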