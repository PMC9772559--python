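# Methods

This note documents the models implemented in `soilmicro`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the package's known limitations.

## Risk index and treatment design

The Hakanson potential ecological risk index is linear in each metal's
concentration: Cf = C/C_bg, Er = TF·Cf, RI = Σ Er. Defaults use the
conventional toxicity factors Pb = 5 and Cd = 30 and backgrounds of
26 mg/kg (Pb) and 0.2 mg/kg (Cd), typical of uncontaminated agricultural
topsoil; all are configurable inputs. `solve_additions` inverts the index:
given an allocation of the *added risk* among metals (fractions summing
to 1), added_i = allocation_i · (RI_target − RI_current) · C_bg,i / TF_i.
Linearity makes the forward re-score exact, and the round trip is asserted
to 1e-9. Levels are classified by nearest designed target (100/200/400,
ties to the lower target) rather than by published band edges, because
graded microcosm treatments are named by their designed RI. Salt-mass
conversions (acetate/chloride hydrates) are out of scope; concentrations
are elemental.

## Diversity

ACE follows the Chao–Lee estimator with the rare/abundant cutoff at count
10: S_abund + S_rare/C_ace + (F1/C_ace)·γ², with coverage
C_ace = 1 − F1/N_rare and the rare-taxon coefficient of variation floored
at 0. With no rare taxa the estimator is the observed richness; when every
rare taxon is a singleton (C_ace = 0) it falls back to Chao1 with a logged
warning. Shannon entropy is reported in nats. Faith's PD uses the rooted
convention: the sum of branch lengths of the union of root-to-tip paths of
the present taxa. The abundant/rare split is by *mean* relative abundance
across samples (the per-sample alternative would let a taxon switch class
between samples), with the 1% boundary assigned to rare.

PCoA applies Gower double-centering and a symmetric eigendecomposition;
coordinates are returned for positive-eigenvalue axes only, but negative
eigenvalues (non-Euclidean Bray–Curtis input) are reported rather than
dropped, and explained fractions are normalised over the positive part of
the spectrum. PERMANOVA permutes labels freely (no strata) with
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm); it is implemented in-package so
the permutation stream is explicit and seeded, and its pseudo-F is
cross-checked against scikit-bio in the test suite. Type-I error at
α = 0.05 calibrates to 0.05–0.06 over 500 null datasets (99 permutations
each). Compact letters come from Holm-adjusted pairwise t-tests via the
standard insert-and-absorb algorithm, with 'a' assigned to the
highest-mean group.

## Metabolic profiling (CLPP)

The bundled ECO scheme is the standard 31-substrate layout in triplicate
with three water controls, grouped as carbohydrates 12, amino acids 6,
polymers 4, carboxylic acids 5, amines 2, phenolic compounds 2. The FF
scheme holds 95 single-well substrates in eight groups (29/20/10/4/5/10/
9/8). Substrate names and the group partition follow standard Biolog
documentation; group sizes are pinned to the published composition, and
the schemes are data files a user can replace. Replicate wells are
averaged before the mean control is subtracted; negative corrected values
are floored at zero, the common CLPP convention. AWCD is the mean
corrected OD over the plate's substrates at the reading of record (168 h
default). The functional indices use the corrected profile at that same
time: H′ = −Σ pᵢ ln pᵢ and D = 1 − Σ pᵢ² on proportions of corrected OD,
and McIntosh U = √(Σ Cᵢ²) on the raw corrected values. All indices are
computed at a single timepoint; kinetic curve fitting is out of scope.

## Functional genes

Genes with amplification efficiency outside [1.8, 2.2] are discarded
before quantification. The CT detection limit is 31; below it, relative
copy number is 10^((31 − CT)·3/10), i.e. one ten-fold dilution per 10/3
cycles, and a CT at or beyond the limit (or a blank cell) is zero. An
optional per-sample 16S copy density converts relative to absolute
abundance. The bundled 72-gene catalog (36 C, 22 N, 9 P, 5 S) is a
representative panel in the style of high-throughput biogeochemical-cycle
chips; it is an input file, not a claim about any particular chip's primer
list. Category sums conserve the per-sample grand total exactly.

## Co-occurrence networks

Taxa are filtered at mean relative abundance > 0.01% (strict inequality),
then correlated with Pearson on log₁₀ relative abundances, replacing zeros
by half the smallest positive relative abundance in the table. The
similarity threshold is chosen by a random-matrix-theory scan
(0.30–0.95, step 0.01): at each candidate the sub-threshold entries are
zeroed, the eigenvalue spectrum is unfolded by a degree-5 polynomial fit
to the empirical spectral CDF, and the nearest-neighbour spacing
distribution is tested (χ², equal-probability bins) against the Poisson
form e^(−s); the smallest Poisson-consistent threshold wins, with a
configurable fallback of 0.80 when the scan is exhausted or the spectrum
is too degenerate to unfold. The χ² test has modest power at small node
counts, so thresholds on small matrices should be read as order-of-
magnitude choices.

Modules come from greedy modularity maximisation on the unweighted graph.
Community detection and every downstream iteration are canonically ordered
(communities by size then smallest member), so runs are byte-identical
across processes regardless of Python's hash randomisation. Topology:
avgCC is the mean local clustering coefficient; GD the mean unweighted
shortest path over connected pairs (logged note when the graph is
disconnected); modularity is unweighted. Zi–Pi uses the classical
Guimerà–Amaral cutoffs (Zi ≥ 2.5, Pi ≥ 0.62) to flag hubs, connectors and
keystones; modules with zero within-degree variance assign Zi = 0.
Robustness removes ⌊0.5·n⌋ random nodes per iteration, prunes secondary
extinctions (zero-degree survivors), and reports the mean ± sd surviving
fraction over 100 iterations — exactly 0.5 with zero variance on a
complete graph. Vulnerability is the maximal relative loss of global
efficiency (mean inverse shortest path over ordered pairs) over
single-node deletions, computed via sparse BFS; all of these match
brute-force recomputation on every ≤ 12-node graph in the test suite.
Taxon–gene networks correlate log₁₀ taxon relative abundances against
log₁₀ gene copies and by default keep only positive edges.

## Community assembly

`ncm_predict` implements the Sloan neutral expectation: a taxon with mean
relative abundance p is detected with frequency
1 − BetaCDF(d; N m p, N m (1 − p)). For fitting, the package defaults to
the *exact finite-read* detection probability: with the latent proportion
x ~ Beta(N m p, N m (1−p)), a sample of N reads misses the taxon with
probability E[(1−x)^N], so P(detect) = 1 − B(a, b+N)/B(a, b). The sharp
threshold d = 1/N is a smoothed-step approximation of this quantity whose
half-detection point actually sits near ln2/N, and fitting with it biases
m upward by ~25% on read-sampled data; the exact form removes the bias
(~2% median error in recovery tests) and is the package's default
(`detection_model="reads"`; the threshold form remains available). m is
fitted by least squares on occupancy (log-grid scan refined by bounded
scalar optimisation), R² is computed about the mean observed frequency,
and taxa are partitioned against Wilson 95% bands around the prediction.

MST compares observed pairwise Bray–Curtis D to its expectation E under a
proportional null model that preserves each sample's richness and read
depth: taxa enter a null sample with probability proportional to their
occurrence frequency in the **regional pool**, and reads are filled
proportionally to regional relative abundance (weighted sampling without
replacement via the Gumbel-max trick). The regional pool defaults to the
group itself but should be the whole multi-group dataset when comparing
treatment levels (`mst_by_group` does this): a selected community judged
only against its own pool has its dominance structure baked into the null
and cannot register as deterministic. Per pair,
MST = (1−D)/(1−E) if D ≥ E else D/E, clamped to [0,1]; the group value is
the pair mean and > 0.5 reads as stochastic. Note a known property: a
*single* observation drawn from the null itself scores slightly below 1
(≈ 0.85–0.95), because the formula peaks exactly at D = E and any
draw-to-draw fluctuation pushes it down; classification at the 0.5
boundary is unaffected, and planted regimes separate cleanly (neutral
≈ 0.9, strongly filtered ≈ 0.33 in the acceptance runs).

## Synthetic data

The generators emulate the study design the pipeline targets: four groups
(CK plus L/M/H at RI 100/200/400, designed through `solve_additions` so
the metals file re-scores exactly), 6/5/6/6 replicates, bacterial totals
and plate rates declining with risk while fungal totals rise, and
per-group assembly regimes (bacteria: neutral at CK and H, filtered at L
and M; fungi mirrored) so the stochasticity analysis has planted ground
truth. The metacommunity is a lognormal rank-abundance curve (σ = 1.5,
300 bacterial and 150 fungal taxa) giving both >1% and <1% taxa; samples
carry 2000 reads. Neutral sampling draws Beta(N m p, N m (1−p)) marginals,
renormalises and resamples N reads multinomially — the sampling dual of
the finite-read detection prediction (occupancy RMSD < 0.03 at 200
samples). Filtering scales expected abundances by a Gaussian fitness
kernel exp(−strength·(gradient − optimum)²) with lognormal replicate
noise. Plates develop logistically, OD(t) = A/(1+exp(−r(t−t₀))), with
per-substrate parameters, treatment-scaled rates, shared baseline drift
and Gaussian noise; CT values are 31 − (10/3)·log₁₀(copies) blanked at
the detection limit; trees are random bifurcating topologies with
exponential branch lengths (sufficient for PD, not a real phylogeny).

What passing tests show — and do not. The generators produce
compositional count data with realistic rank-abundance structure, planted
group effects and known assembly regimes, so they validate estimator
correctness, calibration and discrimination. They do not emulate
sequencing error, chimeras, taxonomy, phylogenetic signal in niche
optima, temporal autocorrelation, or compositional coupling between the
gene panel and the OTU tables; conclusions about real communities still
require the real data.

## Reproducibility and problem sizes

All randomness forks from one master seed by stable stage names (CRC32
spawn keys), so adding a stage never perturbs another's stream, and
repeated runs are byte-identical (verified across processes and hash
seeds). Default problem sizes keep the full pipeline fast at desk scale —
the bundled experiment (23 samples, 450 taxa, 46 plates, 72 genes) runs
end to end in well under a minute, with the stochasticity null at 100
draws in tests and 1000 in the pipeline default — while remaining large
enough for the calibration and recovery guarantees quoted above.

## Limitations

- The RMT threshold test is a goodness-of-fit heuristic; on dense or small
  correlation matrices it can accept the lowest scanned threshold.
- Robustness is unweighted (secondary extinction = zero degree); an
  abundance-weighted variant would need per-node abundances.
- The NCM fit assumes a single metacommunity and equal detection across
  taxa; group-wise fits on 5–6 replicates estimate occupancy coarsely and
  can be skipped when fewer than 10 taxa have intermediate occupancy.
- MST absolute values depend on the null-model variant (richness- and
  depth-preserving proportional assignment here); comparisons should keep
  the variant fixed.
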