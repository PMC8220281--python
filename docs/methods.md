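# Methods

`statescape` characterizes the dynamics of short multichannel
electrophysiological segments along two complementary embeddings: a
continuous *embedded point cloud* (EPC) summarized by persistent
homology, and discrete per-channel *ordinal partition networks* (OPNs)
summarized by information-theoretic and graph measures. This note
records the models, the parameters that matter, the numerical choices,
and what the synthetic surrogates do and do not establish.

## Signal conditioning

A segment is a C x T matrix `M` of voltages at sampling rate `fs`. The
chain is: band limiting, mains notching, edge trimming, global z-score —
in that order.

- **Filters.** All filters are windowed-sinc (Hamming) FIRs applied
  forwards and backwards (`filtfilt`), so the cascade has exactly zero
  phase; tests assert the time-reversal symmetry this implies. The
  low-pass transition bandwidth is `max(0.25 * edge, 2 Hz)`. Mains
  notches are placed at the base frequency and all harmonics up to a
  ceiling (default 50, 100, ..., 250 Hz), each +/-2 Hz wide with a 4 Hz
  transition; the wider transition keeps the notch FIRs short enough
  (~825 taps at 1 kHz) that their edge transients die inside the 50 ms
  trim window while still attenuating a centred mains tone by >40 dB
  after two passes.
- **High-pass.** A genuine 0.1 Hz FIR high-pass needs a transition band
  below 0.1 Hz and therefore ~10^5 taps — longer than a 10 s segment.
  When the requested cutoff is unrealizable the chain substitutes DC
  (mean) removal and records which path ran in the segment history.
- **Trim.** 50 ms are dropped from each end (filter transients); at
  1 kHz this maps T = 10000 to 9900.
- **Z-score.** One mean and one SD over the whole C x T matrix, so
  relative inter-channel amplitudes survive; per-channel scaling would
  erase the spatial pattern that the EPC is meant to capture.

## Embedded point cloud and persistent homology

Each column of the conditioned matrix is a point in C-dimensional state
space; the T points, in recording order, are the EPC. Consecutive-state
cosine dissimilarity (`1 - cos`, in [0, 2]) is a state-space velocity;
its mean is reported per segment.

The Vietoris-Rips filtration runs on the pairwise cosine dissimilarity
matrix. H0 is computed by a union-find over edges sorted by length; H1
by column reduction of the triangle boundary matrix over GF(2), columns
held as integer bitmasks. Numerical determinism comes from lexicographic
tie-breaking: edges by (length, i, j), triangles by (max-edge length,
i, j, k). Conventions:

- zero-persistence H1 pairs are dropped (standard); all H0 merges are
  kept, so finite H0 intervals + surviving components = n points;
- the filtration is truncated at 1.1x the connectivity radius (capped at
  2 for cosine dissimilarity) unless a radius is given: the cycles of
  interest close before full connectivity, and truncation bounds the
  triangle count. Cycles still open at truncation are reported with
  death = max radius and a `truncated` flag, and are excluded from
  `max_persistence` (their true death is unknown) but counted in
  `n_cycles`;
- scalar summaries per diagram: `max_persistence` (longest-lived closed
  cycle), `n_cycles` (total H1 intervals), `max_cycles` (peak of the H1
  Betti curve on a shared 100-point radius grid).

Exact Rips persistence on a full 9900-point cloud is not feasible (the
simplex count explodes super-exponentially), so long recordings are
subsampled to 100 maxmin (farthest-point) landmarks before the
filtration; the landmark set is deterministic given the starting index.
A guard refuses clouds above 600 points unless raised explicitly. The
implementation is verified exactly — H0 and H1, 100 random clouds —
against an independent full-boundary-matrix GF(2) reduction in the test
suite.

## Ordinal partition networks

Each channel is delay-embedded (dimension `d`, lag `tau`); each window
maps to its argsort permutation, ties broken toward the earlier window
position (stable sort) so quantized signals symbolize deterministically.
Distinct permutations are nodes; consecutive-window transitions are
weighted directed edges, self-loops included (overlapping windows
commonly repeat a symbol; dropping self-loops is available but changes
the entropy measures and is logged). Node visit counts and normalized
out-transition distributions `W_i` are retained.

Parameter policy:

- `tau` per channel: the first zero crossing of the biased sample
  autocorrelation, located by linear interpolation between the last
  positive and first non-positive lag and rounded to the nearest lag.
  The interpolation matters: the raw "first lag with acf <= 0" rule
  systematically overshoots analytic crossings (a period-100 sinusoid
  crosses at lag 25.0, but finite-sample bias keeps acf[25] marginally
  positive). Capped (with a warning) at T/4 when no crossing exists.
- `d` shared across channels: per channel, the candidate in {3..7}
  maximizing the variance of the OPN total-degree distribution; the
  dataset-wide mode (ties to the smaller d) is used everywhere so that
  networks are comparable. The pipeline default fixes d = 5 — the mode
  this rule selects on broadband recordings — which also bounds the
  repertoire at 5! = 120 nodes.

## Scalar dynamical measures

With N nodes and out-distributions `W_i` (bits throughout):

    Det = (log2 N - <H(W_i)>) / log2 N
    Deg = (log2 N - H(<W_i>)) / log2 N

`<.>` is the unweighted mean over nodes with outgoing transitions
(maximum-entropy intervention convention; visit-weighted averaging is
available and logged). Terminal nodes — at most the last observed
symbol — have no defined out-distribution and are excluded, with the
count logged. Det is 1 iff every state has a unique successor; Deg is 0
when the averaged out-distribution is uniform. Single-node networks make
both undefined (log2 1 = 0) and return NaN with a warning rather than a
silent 0. Both formulas are cross-checked against an independent
dict-based evaluation and a hand-computed 3-node example.

**Permutation entropy** is the unnormalized Shannon entropy of the
symbol frequencies; for iid noise at d = 3 it approaches log2 6 bits.

**Map-equation modularity.** Communities are found by minimizing the
two-level map equation for a random walker following the edge weights
with 15% uniform teleportation (nodes without out-edges teleport with
probability 1); the walker's stationary distribution comes from power
iteration to 1e-14. The search is greedy: incremental single-node moves
(O(1) codelength deltas from per-module flow aggregates) alternated with
pairwise module merges, over 4 seeded random restart orders, keeping the
best codelength; the all-in-one partition is always compared as a
baseline, which is the optimum for unstructured flows such as a single
directed cycle. Exhaustive enumeration over all partitions of graphs
with up to 8 nodes confirms the greedy optimum is global on the test
fixtures. The reported scalar is Newman's directed weighted modularity Q
of the resulting partition on the raw edge counts (the partition's
codelength is also exported): a partition-quality number in [0, 1) is
what a "modularity" column calls for, while the codelength is the
quantity the search optimizes.

**Largest Lyapunov exponent** (Rosenstein): delay-embed, find each
point's nearest neighbour outside a Theiler window (default
`lag * (m - 1)`), track the mean log distance of the paired trajectories
forward, and fit a line over steps 1-10; the slope is the exponent in
nats per sample. The pipeline embeds with unit lag for this estimator
(m = d, lag = 1): the exponent is reported per sample, and unit-lag
embedding keeps the divergence of fast broadband signals resolvable
within the fit range, whereas embedding at the (often large) ordinal lag
tau lets the divergence curve saturate between consecutive steps and
degrades the slope into noise. The estimator recovers ln 2 within 10%
on the r = 4 logistic map and |lambda| < 0.01 on a sinusoid.

## Statistics

Group differences use the Kruskal-Wallis rank ANOVA (tie-corrected H,
chi-squared approximation) with pairwise two-sided Mann-Whitney U post
hoc tests (exact null for tie-free samples with n <= 20, tie-corrected
normal approximation otherwise), via scipy. No multiple-comparison
correction is applied by default (a Holm option exists). Aggregation
reports mean, sample SD (0 with an n = 1 flag), group size, and missing
counts — missing values are counted, never silently dropped. TDA
summaries aggregate at segment level, OPN measures at channel level.

## Synthetic regimes: what they emulate and what they do not

`gen_regime` produces C-channel, 10 s surrogates in three regimes whose
*relative* structure mimics awake / intermediate / sedated cortical
recordings:

- **rich** (awake-like): per channel, an independent broadband chaotic
  source — a fully chaotic logistic orbit smoothed with a 5-sample Hann
  window, which spreads the map's divergence over a few samples —
  weakly mixed (coupling 0.1) with one shared chaotic source, plus 0.2
  units of 1/f noise and `noise_scale` (default 0.1) white noise;
- **poor** (sedated-like): a single shared 2 Hz oscillation with slow
  (0.3 Hz, 20%) amplitude modulation, projected to all channels with
  gains U(0.5, 1.5), plus white noise. With zero noise the matrix is
  exactly rank 1;
- **intermediate**: the 50/50 per-channel mixture of the two.

All sources are standardized before mixing; every generator takes an
explicit seed and is bit-reproducible. These choices make the regime
ordering an emergent property the pipeline must recover — across seeds,
`rich > intermediate > poor` for node count, edge count, permutation
entropy, H1 cycle count and Lyapunov exponent, and the reverse for
determinism and modularity — the qualitative signature reported for
awake vs. anaesthetized cortex. The surrogates are **not** biophysical:
no pharmacokinetics, no spatial electrode geometry, no realistic
spectra beyond the broadband/1-f vs. slow-oscillation contrast, no
non-stationarity across the segment. Passing the ordering tests shows
the pipeline resolves this qualitative axis at desk scale; it does not
certify the absolute values a particular recording system would give.

## Problem sizes and defaults

Tests and the acceptance script run the study at desk scale: 8 channels,
250 Hz, 10 s, 20 seeds per regime (the generator's own defaults are 16
channels at 250 Hz; 1000 Hz remains available via the spec objects), EPC
landmarked to 100 points, map-equation search with 4 restarts. The
regime-ordering property is additionally checked per seed at the
generator default C = 16, where the per-seed strict ordering of node
count, permutation entropy and H1 cycles holds in >= 90% of draws.

## Known limitations

- H1 only; voids (H2) and persistence-diagram metrics (bottleneck,
  Wasserstein) are out of scope — comparisons use Betti curves and the
  three scalar summaries.
- Landmarking preserves large-scale cycles but undercounts fine-scale
  ones; cycle counts are comparable only across runs with the same
  landmark budget.
- The map-equation search is greedy and seeded; global optimality is
  verified only on small fixtures. Restarts make inversions rare but
  possible on large degenerate networks.
- OPNs are univariate by construction; joint multichannel OPNs are not
  attempted.
- Det/Deg are normalized ratios and reported dimensionless; entropy
  quantities are in bits, the Lyapunov exponent in nats per sample.
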