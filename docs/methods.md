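# Methods

This note documents the models, conventions and numerical choices behind
`mupool`, in the order data flow through the pipeline.

## Data model

Discharge times are stored as integer sample indices at the recording
rate (2048 Hz default). Seconds-to-sample conversion rounds half up, so
CSV round trips are bit-stable. Within one participant/muscle group a
unit present in any trial must be present in all trials (the
matched-unit contract of tracked decompositions); loading enforces this,
with `allow_unmatched=True` downgrading to a warning for exploratory
work. Inter-spike-interval QC flags intervals strictly below 20 ms or
strictly above 250 ms (boundary values pass); flagging never edits data —
spike editing is a manual, out-of-scope step.

The deposit reader accepts MATLAB containers (v7 via scipy.io, v7.3/HDF5
via h5py) through an explicit layout mapping, because the internal
variable naming of published deposits varies and should be confirmed
against the actual files rather than guessed. MATLAB-style 1-based pulse
indices are converted via the layout's `index_base`.

## Synthetic motor-neuron pool

The generator reproduces the statistical structure the analyses assume,
not motoneuron biophysics. Per unit *i*, the instantaneous rate is

    r_i(t) = R_i · (1 + g_c,i · s_i(t) + g_n,i · η_i(t)),   floored at 0.5 pps,

where `s_i` is the unit's mix of one or two shared inputs (zero-mean,
unit-variance white noise low-pass filtered at 2.5 Hz, 4th-order
zero-phase Butterworth), `η_i` an independent noise of the same
bandwidth, and mixing rows are L2-normalized so `g_c` is the effective
common gain. Discharges come from an inhomogeneous renewal process via
time rescaling: unit-mean Gaussian thresholds with SD equal to the
target ISI CoV (truncated at 0.1; intervals under 20 ms rejected). With
zero CoV and constant rate this degenerates to a deterministic clock —
a useful exactness oracle. Force is the cumulative spike train convolved
with a second-order critically damped twitch h(t) = A·(t/T)·e^(1−t/T),
rescaled so the plateau mean equals the requested %MVC, plus white
measurement noise. Trials share one target trajectory (ramp at
5 %MVC/s, 30-s stochastic plateau at 10 %MVC with oscillations low-pass
filtered at 1.5 Hz); shared-input realizations are fresh per trial
unless `frozen_input=True`, which replays one realization across trials
as a positive control for consistency analyses (discharge noise stays
fresh). The analysis window is the last 25 s of the plateau, excluding
the first 5 s where units may not yet fire tonically.

Default conditions (chosen once, then frozen): 10 units, mean rates
spread over 8–15 pps, ISI CoV 0.10, common gain 0.18, noise gain 0.04,
twitch time-to-peak 0.13 s, force noise SD 0.05 %MVC. Under these
settings the plateau force CoV averages ≈ 9.6% (SD ≈ 1.7 across
realizations), the smoothed-rate matrix has KMO ≈ 0.96, and PCA assigns
≈ 75% of variance to the first component. The twitch time-to-peak sits
in the slower half of the physiological tibialis-anterior range; at
90 ms the same gains would put force CoV near 11%, outside the regime
the generator is meant to emulate. Note the generator is open-loop:
there is no visual-feedback correction, so slow (< 0.75 Hz) drive
fluctuations pass into force untracked, and per-realization force CoV
scatters more than it would for a human tracking a target.

What passing recovery tests does and does not show: the generator
produces exactly the covariance structure the methods assume (shared
band-limited drive + independent noise), so recovery there demonstrates
correctness of the machinery, not validity of the physiological
assumptions; real data add rate-dependent nonlinearities, recruitment
and derecruitment, tracking behavior, and decomposition errors that the
model deliberately omits.

## Preprocessing

Fixed order, enforced by flags on the matrix object: binarize → smooth →
high-pass → standardize. Smoothing convolves each binary train
("same" alignment, zero padding) with a 400-ms Hanning window normalized
to unit time-integral, so intermediate outputs are in pulses/s; the
kernel's −3 dB cutoff is ≈ 1.8 Hz (closed form ≈ 0.72/T). Any kernel
scaling is annihilated by the final z-scoring. Detrending is a 3rd-order
Butterworth high-pass at 0.75 Hz applied forward–backward: the protocol
fixes order and cutoff but not phase handling, and zero-phase filtering
preserves the temporal alignment the cross-correlation analyses depend
on. The first/last 200 ms of the window are kept (the 25-s window
already excludes transients).

Trial selection filters force at 15 Hz (3rd-order, zero-phase),
linearly detrends force and target (the protocol does not state whether
detrending is linear or mean-only; linear is used and configurable), and
picks the earliest consecutive triplet with minimal mean RMSE. Force CoV
is SD of the detrended filtered force over its pre-detrend mean.

## Linear branch

KMO follows the anti-image formulation: partial correlations from the
inverse correlation matrix, KMO = Σr²/(Σr² + Σp²) off-diagonal, with
0.70 as the factorability criterion. Parallel analysis builds surrogates
by permuting each column's time samples independently (destroying
cross-correlation, preserving marginals), collects PCA eigenvalues over
1,000 repetitions, and retains components whose observed eigenvalues
exceed the per-rank 97.5th percentile. A joint-row-shuffle alternative
is available behind a flag for sensitivity analysis. Because the
smoothed rates are band-limited near 1.8 Hz, surrogate loops may run on
anti-aliased decimated matrices (pipeline default 64 Hz; `None`
reproduces the full-rate computation) — the correlation matrix, and
hence the eigenstructure, is essentially unchanged while the loop cost
drops by the decimation factor.

PCA eigendecomposes the correlation matrix (columns are standardized, so
covariance = correlation); loadings are orthonormal eigenvectors and
variance shares are eigenvalue percentages. FA uses principal-axis
factoring with squared-multiple-correlation initial communalities
(maximum-likelihood extraction via scikit-learn is a config option);
no rotation is applied anywhere. Headline variance shares always follow
the PCA convention; FA communalities are exported for completeness.
Component signs are fixed so each score correlates positively (at its
peak lag) with the mean smoothed rate across units — defined even when
force was not recorded. Two components are extracted by default.

Cross-correlations linearly detrend both series and scan lags in
±2 s — wide enough for electromechanical delay, narrow enough to avoid
spurious peaks on 25-s records; the signed r at the lag maximizing |r|
is reported (zero-lag-only is a config option; whether the reference
statistic is peak-over-lags or zero-lag is not stated). Positive lag
means the second series trails the first. Trial consistency splits
scores into non-overlapping 5-s windows (trailing remainder discarded),
takes the peak correlation per window and averages signed peaks per
trial pair and component.

## Network-information branch

Gaussian-copula MI maps each series through rank/(n+1) and the inverse
normal CDF and applies MI = −½·ln(1 − ρ²), with |ρ| clipped to
1 − 10⁻¹² (duplicated signals hit a finite ceiling instead of ∞). The
estimator is exactly invariant under strictly monotone transforms and
symmetric by construction; at n = 5000 its bias against the Gaussian
closed form is below 0.01 nats. MI matrices are computed on decimated
signals by default (64 Hz) to trim serial-correlation-driven estimator
inflation; factor-1 decimation reproduces the naive estimate.

The percolation rule is isolated behind one function so alternatives can
be swapped: candidate thresholds are the unique edge weights, and the
threshold is the largest weight at which the ≥-threshold subgraph keeps
every node that has any edge in a single connected component. If no
candidate is spanning (the weighted graph is disconnected from the
start) the fallback picks the candidate maximizing giant-component size
minus isolated-node count, preferring the larger threshold on ties.
Both the rule and the fallback are verified against an independent
brute-force scan on random graphs.

Overlapping communities follow the hierarchical link-clustering
construction: similarity between links sharing a node is the Jaccard
index of the inclusive neighborhoods of their non-shared endpoints
(unweighted by default; non-adjacent link pairs sit at maximal
distance), single-linkage clustering, cut at maximum partition density
D = (2/M)·Σ_c m_c(m_c − n_c + 1)/((n_c − 2)(n_c − 1)). A node belongs to
every community any of its links belongs to. "First component" means
the largest community by member count, ties broken by summed
intra-community edge weight (the ordering convention is otherwise
unspecified); isolated nodes belong to no community but count in the
denominator of the first-component fraction. Density is
2|E|/(n(n − 1)).

## Pipeline, determinism and problem sizes

`RunConfig` defaults equal the protocol values (400 ms, 0.75 Hz, 15 Hz,
1,000 repetitions, 95% CI, 2 components, 5-s windows). Trial selection
runs only when force and target exist for ≥ 3 trials; otherwise the
provided trials are taken as already selected (discharge-time-only
deposits contain the selected trials only). Groups with fewer than two
matched units are skipped with a logged reason. Per-trial surrogate
seeds are derived by hashing (seed, participant, muscle, trial), so runs
are deterministic given the config seed and invariant to group
ordering. Exported bundles are plain CSV plus JSON provenance
(config hash, seed, package versions); a hash-keyed cache directory
reuses results for unchanged configs.

Monte-Carlo suites use 8–20 seeds per claim with 25-s, 10-unit trials —
large enough that dominance statistics (component 1 vs component 2)
are stable, small enough for a routine test run; the acceptance script
averages 5 replicate cohorts (15 trials) for pipeline quantities and 10
independent realizations for force CoV. Recovery assertions are stated
on Monte-Carlo means (e.g. mean PC1-truth correlation > 0.8) because
individual realizations scatter by roughly ±0.05 around them.

## Known limitations

- The generator omits recruitment/derecruitment, rate-dependent ISI
  variability, motoneuron nonlinearities (e.g. persistent inward
  currents) and feedback tracking; it is a test harness for the
  analysis machinery, and no synthetic number is a substitute for the
  experimental result.
- The percolation rule for "significant associations" is one defensible
  reading of a modified percolation analysis; the exact published
  variant is not fully specified, which is why the rule is pluggable.
- Factor-analysis scores use the regression method; other estimators
  (Bartlett) would differ by a component-wise scaling, which the
  correlation-based statistics ignore.
- KMO and PCA operate on sample correlation matrices of strongly
  autocorrelated signals; their effective sample size is far below r,
  so per-trial values fluctuate more than iid intuition suggests.
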