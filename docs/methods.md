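# Methods

This note records the models implemented in `adhesomics`, the choices
made where the published procedure left details open, what the synthetic
generators do and do not emulate, and the package's known limitations.

## Proteomics chain

The chain is fixed: replication filter → (log2 if the input is declared
linear-scale) → global normalisation → pass-1 imputation → pass-2
imputation → testing. Stages never reorder rows.

**Replication filter.** A protein is kept if observed in at least
`min_present` (default 2) replicates of *at least one* group. An error
is raised only if `min_present` exceeds every group's size (the rule
would be unsatisfiable); in unbalanced designs a group smaller than
`min_present` simply cannot qualify rows on its own.

**Robust linear regression normalisation.** The reference profile is the
row-wise median of observed values. Each sample is regressed on the
reference over co-observed rows with an iteratively reweighted Huber fit
(tuning constant 1.345, ≤50 iterations, tolerance 1e-8, via statsmodels
RLM), and the fitted systematic deviation is subtracted:
`normalised = raw − (fitted − reference)`. The original tool's exact
robust-fit flavour is not public, so the fit family and tuning constant
are exposed as parameters. The often-quoted property that normalisation
leaves the median profile unchanged holds exactly for shift-type
distortions (and is tested there); for general affine distortions it
holds only approximately.

**Two-pass imputation.** Pass 1 targets intensities censored below the
detection floor: only rows with *zero* observations in some group have
that group's cells set to the minimum observed value of each sample
column. The alternative reading ("local minimum across a replicate" as a
windowed minimum) was considered and not adopted; the column minimum is
the simplest faithful interpretation and is what the per-sample
detection-floor argument supports. Pass 2 is single-imputation
predictive mean matching by chained equations over sample columns:
regress the column on all others using its observed rows, perturb the
coefficients by a draw from their estimated sampling distribution,
predict all rows, and copy the observed value of one of the 5 donors
with nearest prediction (uniform, seeded); 10 sweeps. Every imputed
value is therefore an observed value of its own column — asserted in
tests.

**Testing.** Per-protein two-sided t-test with the Student/Welch variant
chosen by a two-sided F-test on the variance ratio at α = 0.05 (the
published analysis states the gate but not its level; 0.05 is the
conventional default and is configurable). BH correction across rows;
calls require q < 0.05 *and* |log2 FC| ≥ 1.

**Known limitation (measured).** Under strong intensity-dependent
censoring (80% missingness below the 25% column quantile) with three
replicates, end-to-end recall/precision of planted effects plateaus
around 0.6–0.9: PMM donors are drawn from censoring-biased observed
values, which attenuates estimated effects and inflates within-group
variance, and minimum imputation turns chance present/absent patterns
into confident calls. These are properties of the published two-pass
design, not of this implementation; the end-to-end MNAR check therefore
asserts the estimator-bias bound (|bias| < 0.2 on planted log2 FCs),
while calling accuracy is asserted in the random-missingness regime.

## Node scoring and active modules

The beta-uniform mixture density f(p) = λ + (1−λ) a p^(a−1) (0 < a < 1)
is fitted by bounded L-BFGS-B from six starts; the uniform-only model
(log-likelihood 0) is a tested lower bound. The FDR-to-threshold map and
the score s(p) = (a−1)(ln p − ln τ) follow the standard signal–noise
decomposition; nodes without a p-value default to the score of p = 0.5
(configurable), keeping them usable as connectors.

The MWCS→PCST transform shifts scores by w⁻ = min(0, min score) so
profits are non-negative and every edge costs −w⁻; for trees the two
objectives differ by a constant, so optima coincide (tested by
exhaustion on small graphs).

The exact solver enumerates every connected induced subgraph once
(rooted at its minimum node, growing through permitted neighbours) and
is capped at 20 nodes; ties break toward the lexicographically smallest
node list. An integer-linear-programming formulation (binary node/edge
indicators, flow-based connectivity) would scale further but is not
needed at the scales this package targets; the enumerator is the oracle.
The heuristic contracts adjacent positive nodes into super-nodes, grows
a module from a seed super-node by repeatedly attaching the super-node
with the best net gain via its cheapest connector path (node cost
max(0, −s), re-priced after each attachment so shared connectors are
paid once), prunes negative dangling leaves, and keeps the best result
over all seed super-nodes (≤25 seeds). On 100 random ≤12-node instances
it matches the exact optimum on all 100.

**Benchmark calibration.** With planted-signal p-values from
Beta(0.2, 1) and scoring at 5% FDR, a planted node's *expected* score is
negative ((a−1)(E[ln p] − ln τ) < 0 because τ ≈ 0.002–0.003 while
E[ln p] = −5), and about 37% of planted members (those with p > 0.1)
are individually indistinguishable from noise. No score-consistent
solver can then place ≥80% of planted members in the maximal-scoring
subgraph; recovery at that level requires stronger signal (e.g.
Beta(0.05, 1), under which the heuristic recovers ≥85% with no
extraneous nodes in the seeded test).

## Community detection

One Louvain engine serves both objectives. Node sweep order is ascending
id, shuffled once per level when a seed is given; a node moves to the
candidate community (neighbouring communities plus an empty one, the
latter mattering for high-γ CPM) with the largest positive gain, ties
breaking toward the smallest community id. Aggregation tracks original
node counts so the CPM size penalty stays exact. Identical seed and
input give identical partitions; negative edge weights are rejected.

Quality functions are evaluated on the original graph: modularity
Q = Σ_c [w_c/m − (d_c/2m)²] and CPM H(γ) = Σ_c [w_c − γ n_c(n_c−1)/2].
On ≤8-node fixtures both match exhaustive partition search.

Surprise is computed on the *binary* topology (the standard
hypergeometric formulation): S = −ln P(X ≥ m_int) for X hypergeometric
over M = N(N−1)/2 node pairs, M_int intra-community pairs, m edges —
log-gamma arithmetic throughout. The γ scan (default grid: 25 points
log-spaced on [0.01, 2]) returns the Surprise-maximising CPM partition,
ties to the smaller γ.

Edge weights from abundance: Spearman ρ + 1 for modularity (range
[0, 2]); max(ρ, 0) for CPM, because the local-move gain rules assume
non-negative weights and the treatment of anti-correlated neighbours is
not specified in the published analysis. Edges with an endpoint lacking
a profile get the neutral weight (1 or 0 respectively).

Hub cartography follows the within-module-degree/participation
convention (z ≥ 2.5; connector hubs P ∈ (0.30, 0.75], kinless hubs
P > 0.75), computed on unweighted degrees; the published analysis names
the hub classes but not its thresholds.

## DamID profiling

Windows: one per GATC motif, centred at motif start + 2 and extended
±250 bp (clipped at chromosome ends), so each motif yields one 500-bp
window; GATC is its own reverse complement, so a forward scan suffices.
Reads are start positions; a start position landing in k overlapping
windows increments all k. RPM normalisation divides by total mapped
reads; the log2 ratio adds a pseudo-value of 0.5 RPM to both numerator
and denominator (zero handling is not specified in the published
analysis).

**Peak FDR.** Candidate thresholds are ratio quantiles from 75% to 100%
in steps of 0.0005 (deduplicated to distinct exceedance sets); peaks are
runs of ≥2 consecutive same-chromosome windows above threshold. The null
is 15 seeded uniform permutations of the ratio values across windows —
preserving the marginal distribution, destroying autocorrelation. A
run's score is its summed exceedance Σ(ratio − t); its FDR is
min(1, mean null count of runs scoring ≥ s / observed count of runs
scoring ≥ s), i.e. null peaks *as good or better* are compared with
observed ones. Comparing raw per-threshold peak *counts* cannot work at
small scale: a single broad planted domain yields one observed run
against a null of many short fragments, so the count ratio never drops
below the target; score-ranked counting is what makes broad domains with
permutation-unreachable scores callable. Because the threshold scan
gives the best observed run many chances against only 15 permutations,
calling is additionally gated on track-level significance: at each
threshold each of the 16 arrangements (observed + permutations) gets a
margin — its best run score minus the best of the others, normalised by
the mean run score there — and the observed arrangement must hold the
strictly largest scan-maximum margin. All arrangements are treated
identically, so on an exchangeable (signal-free) track the gate opens
with probability 1/16 ≈ 6%, which bounds the whole-track false-call
rate; measured: 6/100 seeded null tracks report any peak. Runs are
reported at the smallest threshold passing FDR < 5%; overlapping
reported runs merge, keeping the lowest FDR. The permutation null is a
conservative–optimistic trade-off: it ignores genuine autocorrelation
in real tracks, so peak boundaries on strongly autocorrelated data
should be read with that in mind.

## Imaging metrics

Linear normalisation maps each channel onto [0, 1500]; it is exact and
idempotent, and errors on constant (zero-dynamic-range) input. The
automatic threshold maximises between-class variance over a 256-bin
histogram of the observed range (the commercial imaging software does
not disclose its algorithm; this is the standard choice and matches
scikit-image's implementation, which serves as the test oracle).
Manders coefficients are intensity-weighted co-occurrence fractions
using per-channel thresholds computed on the masked images; the region
mask ("nuclear membrane") zeroes excluded voxels in both channels, and
its complement gives the cytoplasmic variant. An all-zero or constant
channel after masking yields NaN.

## Synthetic data

The generators are pure functions of their arguments including the seed.
Defaults encode the study conditions used throughout the tests:

* LFQ matrices: 2000 proteins, 3 replicates per group, baseline log2
  intensity N(25, 2), replicate noise SD 0.3 (a typical log2 replicate
  spread for label-free data), 10% differential at ±2 log2 units,
  censoring probability 0.8 below the 25% column quantile plus 2%
  missing completely at random. Censoring is probabilistic rather than a
  hard truncation so pass-2 imputation has signal to exploit.
* Interaction graphs: Barabási–Albert backbone (degree-heterogeneous,
  connected) with a BFS-grown planted connected module densified to at
  least twice the background edge density. The real analysis used a
  curated interaction database; emulating its exact degree structure is
  out of scope.
* DamID: a 100-kb chromosome with GATC motifs planted every ~200 bp
  (background occurrences are mutated away so motif count is
  controlled), two planted lamina-associated intervals covering 20% of
  the chromosome at 4-fold sampling enrichment, 2×10⁵ reads per
  condition. Reads are start positions only; read length, mappability
  and GC structure are not modelled.
* Voxel pairs: equal-size foreground supports sharing an exact number of
  voxels, constant foreground intensity, plus a spherical-shell
  "membrane" mask. No point-spread function or noise model.

Passing tests on these generators demonstrates correctness of the
computational machinery under controlled conditions; they do not
demonstrate robustness to the messier failure modes of real data
(batch effects, peptide-level artefacts, mappability bias, optical
aberrations).

## Numerical choices

Hypergeometric tails, and hence Surprise, are summed in log space with
log-gamma binomials (stable for ~2×10⁴-identifier universes). BUM
fitting clamps p ≤ 0 to the smallest positive double with a warning and
rejects p > 1. Solver and partition tie-breaks are lexicographic on
sorted node ids / smallest community id, making every result
deterministic for a fixed seed. Quantile thresholds in peak calling are
deduplicated by exceedance set, which changes nothing statistically and
bounds the scan cost by the number of windows.
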