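# Methods

`rqadetect` classifies short single-channel EEG windows into healthy,
interictal and ictal states from the nonlinear-dynamics signature of the
signal.  The chain is: delay embedding → thresholded recurrence plot →
twelve recurrence-quantification measures per 1.475 s block →
mutual-information (mRMR) feature selection → feed-forward neural
network, evaluated by repeated random sub-sampling.  This note records
the model, the parameter choices and their rationale, the numerical
conventions, and what the synthetic data can and cannot show.

## Phase-space reconstruction

A scalar series (u_1, …, u_N) is embedded as
x_t = (u_t, u_{t+τ}, …, u_{t+(m−1)τ}), giving N − (m−1)τ points in m
dimensions.

**Delay τ** is the first local minimum of the average mutual information
(AMI) between u_t and u_{t+k}.  The AMI estimator is a plug-in
two-dimensional histogram with equal-width bins shared across lags
(⌈√N⌉ bins capped at 32 by default), in nats.  Because the plug-in
estimate of a flat AMI basin is jagged, curves of ≥ 16 lags are smoothed
with a centered 3-point moving average before minimum-picking; without
this, sampling jitter produces shallow dips well before the true
minimum (for a noisy period-64 sinusoid the raw rule scatters over lags
4–14, the smoothed rule concentrates on 15–17, the quarter period).
Short curves are scanned raw.  If no local minimum exists the delay
falls back to the first lag with AMI < AMI(0)/e, then to the largest lag.
A plateau followed by a rise counts as a minimum, located where the
curve turns up.

**Dimension m** uses Cao's criterion: E(m) is the mean ratio of
(m+1)- to m-dimensional Chebyshev distances to each point's
m-dimensional nearest neighbor (ties to the smallest index; reference
points with a zero nearest-neighbor distance are skipped), and
E1(m) = E(m+1)/E(m).  The selected m is the smallest with
|E1(m) − 1| < 0.05 (configurable), falling back to the largest probed m
for stochastic signals whose E1 never saturates — that fallback is the
expected behavior for noise, not an error.  E2 (the analogous statistic
on the extra coordinate alone) is exposed for determinism screening:
E2 ≈ 1 at every m marks an uncorrelated stochastic series.

Known limitation: for strongly chaotic *maps* (e.g. the logistic map)
the AMI decays to its floor without a meaningful minimum, so the
AMI-selected delay can be large and the subsequent Cao estimate
inflated.  The classical recommendation for maps is τ = 1, which the
config supports (`embedding.mode: global` with fixed `tau`/`m`); the
validation suite probes the map at τ = 1 accordingly.  EEG blocks behave
like noisy flows, where the AMI rule is appropriate.

## Recurrence plot

R_ij = Θ(ε − ‖x_i − x_j‖) with the Euclidean norm; a distance exactly
equal to ε counts as recurrent.  ε is calibrated per block to a target
recurrence rate (default 10%) as the corresponding rank quantile of the
off-diagonal pairwise-distance distribution.  Fixed-rate calibration
makes the line-structure measures comparable across windows of differing
amplitude — essential here because the classes differ hugely in
amplitude, and amplitude should be allowed to matter only through
dynamics, not through threshold coverage.  A fixed ε as a fraction of
the trajectory extent is available (`recurrence.epsilon_mode:
fixed_eps`).  No Theiler window is applied beyond excluding the line of
identity (LOI) from diagonal measures.  Lines touching the border count
at their visible length; off-LOI diagonal lines are counted once per
triangle of the symmetric matrix.

## The twelve measures

With P(l) and P(v) the diagonal/vertical run-length histograms
(l_min = v_min = 2 by default):

| measure | definition | reads as |
|---|---|---|
| RR | Σ R_ij / N² (LOI included) | recurrence probability |
| DET | Σ_{l≥l_min} l·P(l) / Σ_{l≥1} l·P(l) | determinism |
| L | Σ_{l≥l_min} l·P(l) / Σ_{l≥l_min} P(l) | mean prediction time |
| Lmax | longest diagonal | inverse divergence rate |
| ENTR | Shannon entropy of p(l), l ≥ l_min (nats) | diagonal complexity |
| LAM | Σ_{v≥v_min} v·P(v) / Σ_{v≥1} v·P(v) | laminarity |
| TT | Σ_{v≥v_min} v·P(v) / Σ_{v≥v_min} P(v) | trapping time |
| Vmax | longest vertical | longest laminar phase |
| T1 | mean first-type recurrence time | neighborhood revisit rate |
| T2 | mean second-type recurrence time | true return period |
| RPDE | normalized entropy of the T2 density | aperiodicity in [0, 1] |
| Trans | trace(A³) / Σ_i k_i(k_i−1), A = R − I | network regularity |

Recurrence times aggregate over **all** reference points: row i of the
membership matrix flags which trajectory points lie inside the
neighborhood of x_i; first-type times are index gaps between
consecutive members (so sojourn points, where the trajectory lingers,
contribute gaps of 1), second-type times are gaps between entries from
outside (the series start counts as an entry when inside).  Aggregating
over all reference points rather than one arbitrary point trades a
small positive bias for a large variance reduction on 256-sample
blocks.

RPDE is −Σ P(t) ln P(t) / ln T_max over the second-type times, with
T_max the largest observed (or capped) time: 0 when all return periods
are equal, 1 for a flat period density.

**Close-return radius for the time measures.**  T1/T2/RPDE use their own
neighborhood, calibrated by default to a 2% return rate rather than the
recurrence plot's 10%.  Return-time statistics want sparse,
well-separated return events: at a 10% return probability the entry-gap
distribution of white noise is geometric with normalized entropy ≈ 0.65,
flattening the periodic-vs-aperiodic contrast that RPDE exists to
measure, while at 2% uniform noise scores ≈ 0.76 and a sinusoid ≈ 0.1.
`rqa.rpde_radius_mode: matrix_eps` reuses the plot's ε instead, and
`fixed` takes a literal radius.

Zero-denominator cases (empty histograms, empty time sets) return 0 and
set a quality flag on the feature vector instead of raising: a block
must never silently vanish from a feature table.  A constant block is a
defined degenerate case (all points coincide: RR = 1, Trans = 1,
RPDE = 0, flag `degenerate`).

## Feature selection

Features are discretized into equal-frequency (quantile) bins — default
3, scale-invariant so no prior standardization is needed — and mutual
information is the plug-in estimate on the contingency table, in nats,
clamped at 0.  Greedy forward mRMR maximizes
J(f) = I(f; c) − β Σ_{s∈S} I(f; s) with β = 1/|S| by default (the
mean-redundancy "MID" scheme); β = 0 reduces to pure relevance ranking.
Ties break toward the earlier column.  Five features are selected by
default.

Selection runs **inside each training split** by default
(`mrmr.scope: train`), so the reported accuracies carry no selection
leakage; `scope: global` reproduces the simpler select-once-on-all-data
protocol.

## Classification protocol

Per repeat: a uniformly random 60/5/35 train/validation/test split
(redrawn with an incremented sub-seed, at most 10 times, if any class is
absent from train or test), features z-scored with training-split
statistics, then a feed-forward network with one hidden layer of 20
logistic units and a softmax-style output over the classes, trained by
Adam (learning rate 0.01, minibatch ≤ 200, ≤ 200 epochs).  Early
stopping monitors the **validation log-loss** with patience 20 and
restores the best-epoch weights; accuracy saturates almost instantly on
a 5% validation split and would stop training long before the decision
boundary is sharp, whereas the log-loss keeps improving.  Test accuracy
is plain percent correct; 20 repeats are summarized as mean ± sample SD.
Class imbalance (e.g. 6400 vs 1600 in the nonseizure-vs-seizure case) is
left as-is — plain accuracy, no rebalancing — which a deployment-grade
detector would revisit.

The whole run is deterministic given the master seeds: data generation,
splits, network initialization and the selection trace all derive from
explicit generators.

## The surrogate dataset

The generator emulates the public five-subset recording layout (100
segments per subset, 4097 samples ≈ 23.6 s at 173.61 Hz) with
class-dependent dynamics, in arbitrary amplitude units:

* **A, B (healthy):** weakly colored Gaussian noise (AR(1), a = 0.55 /
  0.62) — irregular broadband activity;
* **C, D (interictal):** strongly colored noise (a = 0.90 / 0.92) with
  Poisson-placed Gaussian-envelope spike transients (0.6 / 1.0 per
  second, ~3× background amplitude) — smoother background with sporadic
  epileptiform discharges;
* **E (ictal):** a 3.5 Hz oscillation with a weak second harmonic,
  slow amplitude modulation (0.3 Hz, depth 0.4), random phase, and a
  small broadband floor — the abrupt rhythmic, high-amplitude regime.

These choices mirror the qualitative electrophysiology (interictal
activity is less rhythmic and lower-amplitude; ictal activity is
abruptly rhythmic and synchronized) and make the classes separable in
recurrence measures by construction, with the coloring gap between
a ≈ 0.6 and a ≈ 0.9 providing the healthy/interictal margin.  They are
**not** physiological EEG: no 1/f spectrum, no alpha/beta rhythms, no
eye-blink or muscle artifacts, no channel montage, no recording drift.
Consequently the ≥ 99% surrogate accuracies validate the pipeline's
mechanics — feature informativeness, selection behavior, protocol
plumbing — and not clinical performance; real recordings are noisier
and the published accuracies on them depend on threshold choices that
are not recoverable.  The `run` pipeline accepts a local directory of
the original ASCII recordings for users who have them.

## Problem sizes used in validation

The validation suite and the acceptance script run the full recording
geometry (5 × 100 segments → 8000 feature vectors) for the end-to-end
classification checks; measure-level oracle checks use ≥ 200 randomized
recurrence structures up to N = 64; dynamics-signature checks average
50 blocks of 1024 samples per fixture class.

## Known limitations

* AMI-based delay selection is inappropriate for strongly chaotic maps
  (see above); use a fixed τ = 1 for map-like data.
* T1/T2 aggregation over all reference points, and the 2% close-return
  rate, are conventions; other software may use a single reference
  point or the plot's ε, shifting absolute values (orderings between
  dynamics classes are robust).
* Per-block ε calibration makes RR ≈ its target by construction, so RR
  carries little between-block information under `fixed_rr`; it becomes
  informative under `fixed_eps`.
* The evaluation's feature standardization and the trainer (Adam with
  log-loss early stopping) are implementation choices; the contract is
  the architecture, the 60/5/35 × 20 protocol and determinism, not the
  specific optimizer.
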