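"""Alpha and beta diversity of the microbial communities.

Covers the estimators used to compare graded-risk treatments: ACE richness,
Shannon entropy (nats), Faith's phylogenetic diversity on a rooted tree,
the abundant (>1%) vs rare (<1%) taxon partition, Bray-Curtis dissimilarity
with principal-coordinates analysis, a seeded permutation PERMANOVA, and
one-way ANOVA group comparison with a compact letter display.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import skbio
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .io_core import AbundanceTable

logger = logging.getLogger("soilmicro")

__all__ = [
    "AlphaResult",
    "OrdinationResult",
    "PermanovaResult",
    "GroupComparison",
    "ace_index",
    "shannon_index",
    "faith_pd",
    "alpha_diversity",
    "split_abundant_rare",
    "bray_curtis",
    "pcoa",
    "permanova",
    "group_compare",
]


@dataclass(frozen=True)
class AlphaResult:
    """Per-sample alpha diversity (ACE, Shannon in nats, Faith PD)."""

    sample_ids: tuple[str, ...]
    ace: np.ndarray
    shannon: np.ndarray
    pd: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"ACE": self.ace, "Shannon": self.shannon}
        if self.pd is not None:
            cols["PD"] = self.pd
        return pd.DataFrame(cols, index=list(self.sample_ids))


# ---------------------------------------------------------------------------
# alpha diversity


def ace_index(counts: Sequence[int] | np.ndarray, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator of richness (Chao & Lee).

    Taxa with count > ``rare_cutoff`` are "abundant" and enter as observed;
    the rare side is extrapolated from its sample coverage
    ``C_ace = 1 - F1/N_rare`` and coefficient of variation.  With no rare
    taxa the estimator reduces to observed richness; when every rare taxon
    is a singleton (C_ace = 0) it falls back to Chao1 with a warning.
    """
    c = np.asarray(counts, dtype=np.int64)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("cannot estimate richness for an all-zero sample")
    rare = c[c <= rare_cutoff]
    s_abund = int(np.sum(c > rare_cutoff))
    if rare.size == 0:
        return float(s_abund)
    s_rare = rare.size
    n_rare = int(rare.sum())
    f = np.bincount(rare, minlength=rare_cutoff + 1)  # f[i] = # taxa with count i
    f1 = int(f[1])
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        logger.warning("ACE coverage is 0 (all rare taxa singletons); using Chao1")
        return chao1_index(c)
    i = np.arange(1, rare_cutoff + 1)
    gamma2 = max(
        s_rare / c_ace * np.sum(i * (i - 1) * f[1:]) / (n_rare * (n_rare - 1)) - 1.0
        if n_rare > 1
        else 0.0,
        0.0,
    )
    return float(s_abund + s_rare / c_ace + f1 / c_ace * gamma2)


def chao1_index(counts: Sequence[int] | np.ndarray) -> float:
    """Chao1 richness: S_obs + F1(F1-1)/(2(F2+1))."""
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))
    return float(c.size + f1 * (f1 - 1) / (2 * (f2 + 1)))


def shannon_index(counts: Sequence[float] | np.ndarray) -> float:
    """Shannon entropy H = -sum p_i ln p_i, in nats."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = c / c.sum()
    return float(-np.sum(p * np.log(p)))


def faith_pd(present_taxa: set[str] | Sequence[str], tree: skbio.TreeNode) -> float:
    """Faith's phylogenetic diversity (rooted convention).

    Sum of branch lengths of the minimal subtree connecting the root to
    every present tip, i.e. the union of root-to-tip paths.
    """
    present = set(present_taxa)
    tips = {t.name for t in tree.tips()}
    missing = present - tips
    if missing:
        raise ValueError(f"taxa not found in tree: {sorted(missing)}")
    if not present:
        return 0.0
    total = 0.0
    for node in tree.postorder(include_self=False):
        node._pd_hit = (
            (node.name in present)
            if node.is_tip()
            else any(ch._pd_hit for ch in node.children)
        )
        if node._pd_hit:
            total += node.length or 0.0
    for node in tree.postorder(include_self=False):  # clean up annotation
        del node._pd_hit
    return float(total)


def alpha_diversity(
    table: AbundanceTable,
    tree: skbio.TreeNode | None = None,
    rare_cutoff: int = 10,
) -> AlphaResult:
    """ACE, Shannon and (if a tree is given) Faith PD for every sample."""
    ace = np.array([ace_index(row, rare_cutoff) for row in table.counts])
    shannon = np.array([shannon_index(row) for row in table.counts])
    pd_vals = None
    if tree is not None:
        pd_vals = np.array(
            [
                faith_pd(
                    {t for t, n in zip(table.taxon_ids, row) if n > 0}, tree
                )
                for row in table.counts
            ]
        )
    return AlphaResult(table.sample_ids, ace, shannon, pd_vals)


# ---------------------------------------------------------------------------
# abundant / rare partition


def split_abundant_rare(
    table: AbundanceTable, threshold: float = 0.01
) -> dict[str, list[str]]:
    """Partition taxa into abundant (mean relative abundance > 1%) and rare.

    The boundary itself (exactly 1%) is assigned to the rare side.
    """
    if table.n_taxa == 0 or table.n_samples == 0:
        raise ValueError("empty table")
    mean_ra = table.mean_relative_abundance()
    abundant = [t for t, p in zip(table.taxon_ids, mean_ra) if p > threshold]
    rare = [t for t, p in zip(table.taxon_ids, mean_ra) if p <= threshold]
    return {"abundant": abundant, "rare": rare}


# ---------------------------------------------------------------------------
# beta diversity


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity on counts (samples x samples)."""
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples")
    totals = table.counts.sum(axis=1)
    if np.any(totals == 0):
        bad = [table.sample_ids[i] for i in np.where(totals == 0)[0]]
        raise ValueError(f"samples with zero total count: {bad}")
    d = squareform(pdist(table.counts, metric="braycurtis"))
    return pd.DataFrame(d, index=list(table.sample_ids), columns=list(table.sample_ids))


@dataclass(frozen=True)
class OrdinationResult:
    """PCoA of a distance matrix; negative eigenvalues are reported as-is."""

    distances: pd.DataFrame
    coordinates: pd.DataFrame  # samples x axes (positive-eigenvalue axes)
    eigenvalues: np.ndarray  # all eigenvalues, descending (may be negative)
    explained: np.ndarray  # fractions over positive eigenvalues


def pcoa(distances: pd.DataFrame | np.ndarray, sample_ids: Sequence[str] | None = None) -> OrdinationResult:
    """Principal-coordinates analysis via Gower double-centering.

    Coordinates are returned for the positive-eigenvalue axes, ordered by
    descending eigenvalue; negative eigenvalues (non-Euclidean input) are
    reported, not silently dropped.  Explained-variance fractions are
    computed over the positive eigenvalues only.
    """
    if isinstance(distances, pd.DataFrame):
        ids = list(distances.index)
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(len(d))]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got {d.shape}")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(eigvals.max(), 0) * 1e-12
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    explained = eigvals[pos] / pos_sum if pos_sum > 0 else np.zeros(int(pos.sum()))
    dist_df = pd.DataFrame(d, index=ids, columns=ids)
    coord_df = pd.DataFrame(
        coords, index=ids, columns=[f"PCo{i+1}" for i in range(coords.shape[1])]
    )
    return OrdinationResult(dist_df, coord_df, eigvals, explained)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int | None


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(SS_among, SS_within) from squared distances and integer labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.where(labels == g)[0]
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss_total - ss_within, ss_within


def permanova(
    distances: pd.DataFrame | np.ndarray,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F statistic compares among- to within-group sums of squared
    distances; the p-value is ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``
    under free permutation of the group labels.
    """
    d = distances.to_numpy(dtype=float) if isinstance(distances, pd.DataFrame) else np.asarray(distances, dtype=float)
    labels = np.asarray(pd.factorize(np.asarray(groups))[0])
    if d.shape[0] != labels.size:
        raise ValueError("groups length must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need >= 2 groups")
    if np.any(counts < 2):
        raise ValueError("every group needs >= 2 samples")
    n, a = labels.size, uniq.size
    d2 = d**2

    def f_stat(lab: np.ndarray) -> float:
        ss_among, ss_within = _permanova_ss(d2, lab, uniq)
        if ss_within <= 0:
            return np.inf
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_obs = f_stat(labels)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        if f_stat(rng.permutation(labels)) >= f_obs:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    ss_among, ss_within = _permanova_ss(d2, labels, uniq)
    r2 = ss_among / (ss_among + ss_within) if (ss_among + ss_within) > 0 else 0.0
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations, seed)


# ---------------------------------------------------------------------------
# group comparison with compact letter display


@dataclass(frozen=True)
class GroupComparison:
    """Per-group summary with ANOVA p-value and significance letters."""

    summary: pd.DataFrame  # index group; columns mean, sd, n, letters
    anova_F: float
    anova_p: float
    pairwise_p: pd.DataFrame  # Holm-adjusted


def _compact_letters(
    group_names: Sequence[str],
    means: Mapping[str, float],
    significant: set[tuple[str, str]],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; 'a' goes to
    the highest-mean group by convention.
    """
    order = sorted(group_names, key=lambda g: -means[g])
    letter_sets: list[set[str]] = [set(order)]
    for i, j in significant:
        for s in list(letter_sets):
            if i in s and j in s:
                letter_sets.remove(s)
                letter_sets.extend([s - {i}, s - {j}])
        # absorb subsets
        letter_sets = [
            s
            for s in letter_sets
            if s and not any(s < t for t in letter_sets if t is not s)
        ]
        # deduplicate
        uniq: list[set[str]] = []
        for s in letter_sets:
            if s not in uniq:
                uniq.append(s)
        letter_sets = uniq
    # order letter sets by the best (highest-mean) member
    letter_sets.sort(key=lambda s: min(order.index(g) for g in s))
    letters: dict[str, str] = {g: "" for g in group_names}
    for k, s in enumerate(letter_sets):
        ch = chr(ord("a") + k)
        for g in order:
            if g in s:
                letters[g] += ch
    return letters


def group_compare(
    values: Sequence[float] | np.ndarray,
    groups: Sequence[str],
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA with Holm-adjusted pairwise t-tests and letters."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = list(pd.unique(groups))
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    by_group = {g: values[groups == g] for g in names}
    if all(np.var(v) == 0 for v in by_group.values()):
        raise ValueError("zero within-group variance in every group")
    f, p = stats.f_oneway(*[by_group[g] for g in names])
    pairs = list(itertools.combinations(names, 2))
    raw_p = [
        stats.ttest_ind(by_group[a], by_group[b]).pvalue for a, b in pairs
    ]
    adj_p = multipletests(raw_p, method="holm")[1]
    significant = {pair for pair, q in zip(pairs, adj_p) if q < alpha}
    significant |= {(b, a) for a, b in significant}
    means = {g: float(np.mean(by_group[g])) for g in names}
    letters = _compact_letters(names, means, significant)
    summary = pd.DataFrame(
        {
            "mean": [means[g] for g in names],
            "sd": [float(np.std(by_group[g], ddof=1)) for g in names],
            "n": [len(by_group[g]) for g in names],
            "letters": [letters[g] for g in names],
        },
        index=names,
    )
    pair_df = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for (a, b), q in zip(pairs, adj_p):
        pair_df.loc[a, b] = pair_df.loc[b, a] = q
    return GroupComparison(summary, float(f), float(p), pair_df)
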