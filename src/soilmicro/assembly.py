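"""Community-assembly inference: neutral model fit and stochasticity ratio.

The Sloan neutral community model (NCM) predicts how often a taxon should
occur across samples from its mean relative abundance alone, given a
migration rate m and community size N: detection frequency
``1 - BetaCDF(d; N m p, N m (1-p))`` with detection limit d.  Fitting m to
the observed occupancy-abundance cloud yields the migration estimate and a
goodness of fit R^2 that measures how far neutral dynamics alone explain
the community.

The modified stochasticity ratio (MST) compares observed pairwise
Bray-Curtis dissimilarity within a group to its expectation under a
randomisation null model that preserves each sample's richness and depth.
MST is 1 when observed dissimilarity equals the null expectation, 0 at
either extreme, and the 0.5 boundary separates stochastic (> 0.5) from
deterministic (< 0.5) assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform
from scipy.special import betaln

from .io_core import AbundanceTable

logger = logging.getLogger("soilmicro")

__all__ = [
    "NCMFit",
    "MSTResult",
    "ncm_predict",
    "ncm_detection_probability",
    "ncm_fit",
    "null_expected_dissimilarity",
    "mst_pair",
    "mst",
    "mst_by_group",
]


# ---------------------------------------------------------------------------
# Sloan neutral community model


def ncm_predict(
    p: float | np.ndarray, m: float, N: float, d: float
) -> float | np.ndarray:
    """Predicted occurrence frequency 1 - BetaCDF(d; N m p, N m (1-p))."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("mean relative abundances must lie in (0, 1)")
    if m <= 0:
        raise ValueError(f"migration rate must be > 0, got {m}")
    if N < 1:
        raise ValueError(f"community size must be >= 1, got {N}")
    if not 0 < d < 1:
        raise ValueError(f"detection limit must lie in (0, 1), got {d}")
    out = stats.beta.sf(d, N * m * p, N * m * (1.0 - p))
    return float(out) if out.ndim == 0 else out


def ncm_detection_probability(
    p: float | np.ndarray, m: float, N: float
) -> float | np.ndarray:
    """Exact probability of detecting a taxon in a sample of N reads.

    With the taxon's latent proportion x ~ Beta(N m p, N m (1-p)), a read
    sample of depth N misses it with probability E[(1-x)^N], so
    P(detect) = 1 - B(a, b+N) / B(a, b).  This is the finite-read
    (beta-binomial) counterpart of the sharp-threshold form in
    :func:`ncm_predict`; the two agree closely for an effective threshold
    near ln(2)/N, where the read sample detects with probability 1/2.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("mean relative abundances must lie in (0, 1)")
    if m <= 0 or N < 1:
        raise ValueError("require m > 0 and N >= 1")
    a = N * m * p
    b = N * m * (1.0 - p)
    n_reads = int(round(N))
    out = 1.0 - np.exp(betaln(a, b + n_reads) - betaln(a, b))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class NCMFit:
    """Fitted migration rate, goodness of fit and per-taxon partition."""

    m: float
    N: float
    R2: float
    detection: float
    detection_model: str
    taxa: pd.DataFrame  # p, observed_f, predicted_f, lower, upper, partition

    @property
    def Nm(self) -> float:
        return self.N * self.m


def _wilson_interval(p: np.ndarray, n: int, z: float = 1.959963984540054):
    """Wilson score interval for a binomial proportion."""
    denom = 1.0 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return np.clip(centre - half, 0, 1), np.clip(centre + half, 0, 1)


def ncm_fit(
    table: AbundanceTable,
    detection: float | None = None,
    detection_model: str = "reads",
) -> NCMFit:
    """Fit the neutral model to an occupancy-abundance cloud.

    p_i is each taxon's mean relative abundance, f_i the fraction of
    samples where it was detected; N is the mean sample depth.  The
    default ``detection_model='reads'`` predicts occupancy with the exact
    finite-read detection probability
    (:func:`ncm_detection_probability`); ``'threshold'`` uses the
    sharp-threshold form with limit ``detection`` (default one read in the
    average-depth sample, d = 1/N).  The migration rate minimises the
    squared occupancy residuals (log-grid scan refined by bounded
    optimisation); R^2 is computed about the mean observed frequency.
    Taxa are split into above / within / below the Wilson 95% band around
    the prediction.
    """
    if detection_model not in ("reads", "threshold"):
        raise ValueError("detection_model must be 'reads' or 'threshold'")
    counts = table.counts
    n_samples = table.n_samples
    N = float(counts.sum(axis=1).mean())
    if N < 1:
        raise ValueError("empty table")
    d = detection if detection is not None else 1.0 / N
    p = table.mean_relative_abundance()
    f = (counts > 0).mean(axis=0)
    use = (p > 0) & (p < 1)
    intermediate = np.sum((f > 0) & (f < 1) & use)
    if intermediate < 10:
        raise ValueError(
            f"need >= 10 taxa with intermediate occupancy, got {intermediate}"
        )
    p_use, f_use = p[use], f[use]

    def predict(m: float) -> np.ndarray:
        if detection_model == "reads":
            return ncm_detection_probability(p_use, m, N)
        return stats.beta.sf(d, N * m * p_use, N * m * (1 - p_use))

    def sse(log_m: float) -> float:
        return float(np.sum((f_use - predict(np.exp(log_m))) ** 2))

    grid = np.log(np.logspace(-5, 2, 120))
    best = grid[int(np.argmin([sse(g) for g in grid]))]
    step = grid[1] - grid[0]
    res = optimize.minimize_scalar(
        sse, bounds=(best - 2 * step, best + 2 * step), method="bounded"
    )
    m_hat = float(np.exp(res.x))
    pred = predict(m_hat)
    sst = float(np.sum((f_use - f_use.mean()) ** 2))
    r2 = 1.0 - res.fun / sst if sst > 0 else float("nan")
    lower, upper = _wilson_interval(pred, n_samples)
    partition = np.where(f_use > upper, "above", np.where(f_use < lower, "below", "within"))
    taxa_df = pd.DataFrame(
        {
            "p": p_use,
            "observed_f": f_use,
            "predicted_f": pred,
            "lower": lower,
            "upper": upper,
            "partition": partition,
        },
        index=[t for t, u in zip(table.taxon_ids, use) if u],
    )
    return NCMFit(
        m=m_hat, N=N, R2=float(r2), detection=d,
        detection_model=detection_model, taxa=taxa_df,
    )


# ---------------------------------------------------------------------------
# stochasticity ratio


def _null_draw(
    rng: np.random.Generator,
    richness: np.ndarray,
    depths: np.ndarray,
    occ_freq: np.ndarray,
    regional_p: np.ndarray,
) -> np.ndarray:
    """One null community matrix preserving per-sample richness and depth.

    Taxa are assigned to samples with probability proportional to their
    regional occurrence frequency; individuals beyond the one guaranteeing
    presence are filled proportionally to regional relative abundance.
    """
    n_taxa = occ_freq.size
    out = np.zeros((richness.size, n_taxa), dtype=np.int64)
    log_w = np.log(occ_freq)
    for j, (s, n) in enumerate(zip(richness, depths)):
        # weighted sample without replacement via the Gumbel-max trick
        keys = log_w + rng.gumbel(size=n_taxa)
        chosen = np.argpartition(keys, n_taxa - s)[n_taxa - s:]
        out[j, chosen] = 1
        remaining = n - s
        if remaining > 0:
            fill_p = regional_p[chosen]
            out[j, chosen] += rng.multinomial(remaining, fill_p / fill_p.sum())
    return out


def null_expected_dissimilarity(
    table: AbundanceTable,
    n_null: int = 1000,
    seed: int | None = None,
    regional: AbundanceTable | None = None,
) -> pd.DataFrame:
    """Expected pairwise Bray-Curtis under the proportional null model.

    ``table`` holds one group's samples.  Each draw reassembles every
    sample with its observed richness and read depth: taxa enter with
    probability proportional to their regional occurrence frequency and
    individuals are filled proportionally to regional relative abundance.
    ``regional`` defines that species pool (defaults to ``table`` itself;
    pass the whole multi-group dataset to measure a group against the
    study-wide pool, which is what separates selected communities from
    the null).  The expectation E_ij is the mean Bray-Curtis over draws.
    """
    if table.n_samples < 3:
        raise ValueError("need >= 3 samples in the group")
    if n_null < 2:
        raise ValueError("need >= 2 null draws")
    if n_null < 10:
        logger.warning("n_null = %d is very small; expectations will be noisy", n_null)
    pool = regional if regional is not None else table
    if pool.taxon_ids != table.taxon_ids:
        raise ValueError("regional pool must share the table's taxa")
    counts = table.counts
    richness = (counts > 0).sum(axis=1)
    depths = counts.sum(axis=1)
    occ_freq = (pool.counts > 0).mean(axis=0)
    regional_p = pool.counts.sum(axis=0) / pool.counts.sum()
    present = occ_freq > 0
    if present.sum() < richness.max():
        raise ValueError("regional pool has fewer taxa than a sample's richness")
    rng = np.random.default_rng(seed)
    acc = np.zeros((table.n_samples, table.n_samples))
    for _ in range(n_null):
        null = np.zeros_like(counts)
        null[:, present] = _null_draw(
            rng, richness, depths, occ_freq[present], regional_p[present]
        )
        acc += squareform(pdist(null, metric="braycurtis"))
    e = acc / n_null
    return pd.DataFrame(e, index=list(table.sample_ids), columns=list(table.sample_ids))


@dataclass(frozen=True)
class MSTResult:
    """Pairwise and mean stochasticity ratio for one group of samples."""

    pairwise: pd.DataFrame  # sample x sample, NaN on the diagonal
    mean: float
    classification: str  # 'stochastic' (> 0.5) or 'deterministic'
    n_null: int
    seed: int | None


def mst_pair(d: float, e: float, d_max: float = 1.0) -> float:
    """Stochasticity ratio for one sample pair.

    1 at the null fixed point (D = E), 0 at both extremes (D = 0 with
    E > 0, or D = d_max), linear in between; clamped to [0, 1].
    """
    if np.isclose(e, d_max):
        raise ValueError("null expectation equals d_max; ratio undefined")
    if d >= e:
        v = (d_max - d) / (d_max - e)
    else:
        v = d / e if e > 0 else float("nan")
    return float(np.clip(v, 0.0, 1.0))


def mst(
    table: AbundanceTable,
    n_null: int = 1000,
    seed: int | None = None,
    d_max: float = 1.0,
    regional: AbundanceTable | None = None,
) -> MSTResult:
    """Modified stochasticity ratio for one group.

    For each sample pair with observed dissimilarity D and null expectation
    E: MST = (d_max - D) / (d_max - E) when D >= E, else D / E, clamped to
    [0, 1].  MST is 1 when observation matches the null, 0 at either
    extreme; pairs with E = d_max are skipped with a warning.
    """
    obs = squareform(pdist(table.counts, metric="braycurtis"))
    e = null_expected_dissimilarity(
        table, n_null=n_null, seed=seed, regional=regional
    ).to_numpy()
    n = table.n_samples
    vals = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            d_ij, e_ij = obs[i, j], e[i, j]
            try:
                vals[i, j] = vals[j, i] = mst_pair(d_ij, e_ij, d_max)
            except ValueError:
                logger.warning(
                    "pair (%s, %s): null expectation equals d_max; skipped",
                    table.sample_ids[i], table.sample_ids[j],
                )
    mean = float(np.nanmean(vals[np.triu_indices(n, k=1)]))
    return MSTResult(
        pairwise=pd.DataFrame(vals, index=list(table.sample_ids), columns=list(table.sample_ids)),
        mean=mean,
        classification="stochastic" if mean > 0.5 else "deterministic",
        n_null=n_null,
        seed=seed,
    )


def mst_by_group(
    table: AbundanceTable,
    groups: Sequence[str],
    n_null: int = 1000,
    seed: int | None = None,
) -> dict[str, MSTResult]:
    """MST per treatment group against the study-wide species pool.

    Each group's null model draws from the occurrence frequencies and
    abundances of the *whole* table (all groups), so communities shaped
    by selection within a group register as deterministic relative to the
    shared pool.  Seeds are forked per group.
    """
    groups = np.asarray(groups)
    if groups.size != table.n_samples:
        raise ValueError("groups must match samples")
    out = {}
    for k, g in enumerate(pd.unique(groups)):
        samples = [s for s, lab in zip(table.sample_ids, groups) if lab == g]
        sub = table.select_samples(samples)
        sub_seed = None if seed is None else int(seed) + 1000 * (k + 1)
        out[str(g)] = mst(sub, n_null=n_null, seed=sub_seed, regional=table)
    return out
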