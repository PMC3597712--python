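# Methods

## The model

`eegstates` quantifies *dynamical* non-stationarity of a single-channel signal:
variation over time in the parameters of a (generally non-linear) dynamical
model underlying the signal, as opposed to variation in stochastic moments.
The signal is assumed piecewise quasi-stationary — a concatenation of stretches
during which one dynamical regime holds.

Each channel of an epoch is divided into half-overlapping windows.  Within a
window the one-step dynamics are approximated by a polynomial map over a delay
embedding,

    x[t] = F(x[t-tau], x[t-2*tau], ..., x[t-m*tau]) + e[t],

with `F` a full polynomial of total degree ≤ `p` in the `m` lagged values,
fitted by least squares (ridge-stabilised normal equations).  The window's
fingerprint is its coefficient vector; two windows are compared by the
Euclidean distance between fingerprints.  Windows are clustered by two-stage
affinity propagation; temporally adjacent windows in one cluster are glued
into quasi-stationary segments.  A channel/epoch is summarised by

* **n** — the number of distinct states (clusters) visited, and
* **L** — the mean glued-segment duration (seconds),

two complementary measures: with the repertoire fixed, faster alternation
shortens L; the repertoire can grow without L changing.

Group/condition structure in the per-channel measures is tested with
mean-centered and contrast PLS (SVD of the group × condition cell means,
centered by the grand column mean, or of the covariance between a-priori
orthogonal contrasts and the cell means), permutation tests that reassign
conditions within subjects, and bootstrap ratios (loading / bootstrap SE,
participants resampled within cells, |BSR| ≥ 2 ≈ 95% criterion, resampled
loadings sign-aligned to the original).  Associations with relative spectral
power (Welch, Hann windows, 50% overlap, per-channel band normalisation) are
measured by first-order partial correlations between one measure and power,
controlling the other measure, pooled across subjects and conditions.

## Parameter defaults and why

| parameter | default | rationale |
|---|---|---|
| window length | 0.7 s | long enough for ≥ 3 cycles of theta-and-above rhythms; short enough that several windows fit inside a 1.5–2 s quasi-stationary segment |
| overlap | 0.5 | half-overlapping windows |
| embedding dimension `m` | 2 | the smallest setting distinguishing damped-oscillator (second-order) regimes |
| polynomial order `p` | 1 | see "Why a linear default map" below; `p` is config-exposed and higher orders are fully supported and tested |
| embedding delay `tau` | ≈ fs/40 samples | places consecutive lags about a quarter period of the 10–20 Hz rhythms apart (the standard autocorrelation-time heuristic); at high sampling rates neighbouring samples are nearly collinear and carry almost no dynamical information |
| analysis rate | 128 Hz | channels sampled faster are decimated by an integer stride; dynamics of interest live well below 64 Hz and white observation noise stays white under decimation |
| per-window z-scoring | on | the intercept and amplitude-dependent coefficients otherwise dominate the Euclidean distance with offset/amplitude noise that says nothing about the dynamics |
| ridge | 1e-8 | numerically invisible on well-posed fits; guards near-collinear monomials and flat windows |
| AP damping / max_iter / conv window | 0.9 / 1000 / 50 | determinism and convergence margin |
| stage-1 preference | median off-diagonal similarity | the classic affinity-propagation heuristic |
| stage-2 preference | −(4 · r_k · (S̄/size_k)^0.25)², r_k = median member→exemplar distance | see below |
| n_perm / n_boot | 500 / 500 | stable p-values and SEs at the cohort sizes used |
| BSR threshold | 2.0 | ≈ 95% confidence criterion |
| spectral window | 2 s, Hann, 50% overlap | 0.5 Hz resolution on 10–20 s epochs |

### Why a linear default map

With observation noise, least-squares fits of near-unit-root autoregressive
dynamics suffer strong errors-in-variables attenuation: at a 256 Hz sampling
rate, 10% amplitude noise shrinks the one-step AR coefficients of a 6 Hz and
an 11 Hz oscillator onto nearly the same point, destroying the contrast the
distance is supposed to measure.  Two remedies are built into the defaults:
the delay embedding (which moves the regression away from the unit root) and
window z-scoring (which removes offset/amplitude nuisance from the
fingerprint).  Under those, the linear (`p=1`) coefficients carry essentially
all of the between-regime contrast for oscillatory regimes, while cubic
monomials add many high-variance coefficients that dilute the Euclidean
distance; measured window-label recovery on two-regime signals drops from
~85–95% at `p=1` to near zero at `p=3`.  Deterministic nonlinear maps (e.g.
the logistic map) are still recovered exactly when fitted with `p≥2`, which
the test suite exercises.

A practical constraint follows from the embedding: two oscillatory regimes
whose frequencies satisfy `f2 ≈ fs/tau − f1` have nearly equal lag-`tau`
autocorrelations and become indistinguishable in coefficient space (aliasing
of the embedded representation).  With the defaults the usable band is
roughly 1–21 Hz at a 128 Hz analysis rate; the synthetic palettes respect it.

### The two-stage clustering

Stage 1 is plain affinity propagation (message passing implemented in this
package, with the standard final medoid-refinement pass and a seeded 1e-10
jitter to break exact ties) at the median-similarity preference.  This
typically over-partitions: windows from one regime form several lumps because
windows within one dwell share data and finite-sample bias.  Stage 2
re-clusters the stage-1 exemplars.  Its job is to absorb clusters that are
close *on the scale of their own within-cluster spread* while never merging
genuinely distant clusters, and to prefer exemplars that unified many
windows.  The preference of exemplar `k` is

    pref_k = −( c · r_k · (S̄ / size_k)^γ )²,    c = 4, γ = 0.25,

where `r_k` is the median coefficient distance of cluster `k`'s members to
their exemplar (singletons fall back to the global median window→exemplar
distance) and `S̄` the mean cluster size.  In affinity propagation an
exemplar stays a cluster centre iff its preference exceeds its best
alternative similarity, so this rule merges exemplar `j` into `k` roughly
when their distance is below `c` within-radii — a local criterion — while the
size term hands larger clusters preferences closer to zero, suppressing small
clusters born of noisy coefficient fluctuations.  A global threshold derived
from the median exemplar similarity (the simplest alternative rule) fails
whenever between-cluster separations are heterogeneous; the radius rule
handles both tight, well-separated
configurations (where it reproduces the exhaustive-search optimum exactly)
and the lumpy geometry of real fits.  Windows are finally assigned to the
most similar surviving exemplar (inheritance of the stage-1 exemplar's label
is available as a config option).

Degenerate inputs: a single window or an all-zero distance matrix returns one
cluster; a stage 1 that yields a single exemplar skips stage 2; message
passing that never stabilises returns the best-net-similarity assignment seen
with `converged=False` and a warning.  Ties everywhere break toward the
lowest index; all randomness is seeded.

## The synthetic cohort generator

The generator emulates exactly what the pipeline measures: piecewise
quasi-stationary multichannel signals with a known number of regimes K and
known dwell times.  Regimes are damped AR(2) oscillators at distinct centre
frequencies (deterministic polynomial maps are available for exact
single-channel tests); AR state carries across switches so transitions are
continuous; dwell is fixed (test default) or exponential; regimes cycle
deterministically or in random order.  Observation noise is white Gaussian.
Cohorts implement the two effect modes: K varying with an age-group/visit
covariate on focal channels, dwell varying globally, with longitudinal
(subject-in-every-visit) or between-subject designs.  A separate coupled
cohort ties a 3.5 Hz component's amplitude to the switch rate on all channels
and a 10 Hz component's amplitude to K on the focal channels, for the
spectral-association checks.

What the generator does **not** emulate: volume-conduction topographies
beyond an optional uniform mixing knob, 1/f background spectra, eye-blink or
muscle artifacts, non-stationary amplitude drift, or realistic electrode
geometry.  Passing recovery tests on this generator therefore demonstrates
that the estimator chain is correct and directionally sensitive under its own
model assumptions — not that effect sizes on real EEG would match.

## Problem sizes used in the validation scenarios

Scenario sizes are chosen so every scenario runs in minutes on one CPU:
two-regime recovery uses a single 30 s channel at 256 Hz; the clustering
oracle uses 50 instances of ≤ 8 points (exhaustive search is exact there);
the null calibration uses 200 cohorts of 12 subjects × 2 conditions × 8
channels with 4 s epochs and 200 permutations; the age-effect cohort uses 12
subjects × 3 visits × 2 conditions × 2 × 12 s epochs × 8 channels; the
coupled cohort 20 subjects × 2 conditions × 3 × 16 s epochs × 6 channels.

## Known limitations

* Two-regime recovery at 10% noise has a residual ~5–15% failure rate across
  signal realisations (an extra cluster from per-dwell coefficient lumps, or
  ambiguity of the ~35% of windows that straddle a switch); the reproduction
  script reports the median over five replicate signals.
* The estimated number of states compresses toward 2–3 as true K grows at
  these epoch lengths (few dwells per regime per epoch); group *trends* in K
  are recovered reliably, absolute K is not.
* Estimated n and L are mechanically anti-correlated within a channel (more
  states ⇒ shorter glued runs), which is why the partial-correlation analysis
  controls the other measure.
* The permutation count uses the plain exceedance proportion, so `p = 0` is
  reportable; with 500 permutations the resolution is 0.002.
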