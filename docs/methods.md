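# Methods

This note documents the models, numerical choices and known limitations
behind each part of the pipeline, in the order data flows through it.

## Acoustic parameters

Each vocalization is summarized by five parameters, chosen because they
separate call types in phocid repertoires:

| parameter | unit | procedure |
|---|---|---|
| duration | s | annotation interval length, end − start (half-open interval) |
| spectral center of gravity (CoG) | Hz | power-weighted mean frequency of a single whole-call spectrum |
| dominant frequency | Hz | center of the highest-power spectral bin; ties go to the lowest bin |
| percentage voiced | % of frames | framed autocorrelation pitch analysis, search range 50–400 Hz |
| median harmonicity (HNR) | dB | median frame-wise 10·log₁₀(r/(1−r)), minimum pitch 50 Hz |

**Spectrum.** One rFFT of the whole call, no framing or windowing; this is
the conventional single-spectrum procedure for short calls. Optional
zero-padding to a 5-smooth length refines the bin grid (the bin width is
`rate / n_fft` and is exposed on the `Spectrum` object); per-bin powers are
normalized so that total spectral power equals mean squared amplitude
(Parseval, asserted to 1 × 10⁻⁶ relative in the tests). CoG uses the
weight |S(f)|^p with p = 2 (power weighting, the common default;
configurable).

**Pitch and voicing.** Frames span three periods of the pitch floor
(60 ms at the default 50 Hz floor) with a hop of 0.75/floor. Per frame the
normalized cross-correlation r(τ) = Σx_t x_{t+τ} / √(e₀(τ)e₁(τ)) is
maximized over lags in [rate/ceiling, rate/floor]. A frame is voiced when
the best r exceeds 0.45 (voicing threshold) and the frame peak exceeds
0.03 of the global peak (silence threshold) — the classical two-threshold
rule. Every candidate peak is parabolically refined *before* candidate
selection: the true period is generally a fractional lag, and comparing
unrefined integer-lag peaks systematically favours period multiples
(octave errors). Among refined peaks within 0.02 of the maximum, the
smallest lag wins, again to suppress subharmonic choices. Synthetic
signals with known f0 inside the search range are recovered within 2%.

One behaviour worth knowing: a pure tone *above* the 400 Hz ceiling is
still reported voiced, at the subharmonic that falls inside the search
range — its autocorrelation is exactly 1 at every multiple of the period,
so any autocorrelation tracker does this. Voicing percentages are only
meaningful for signals whose periodicity lies in band.

**Harmonicity.** Same correlation machinery with a 2/min_pitch window
(40 ms at the 50 Hz default), lag range [rate/600, rate/min_pitch], and
HNR = 10·log₁₀(r/(1−r)) per frame, r clipped away from {0, 1}. A noiseless
harmonic signal scores > 20 dB; an equal-power harmonic/noise mix scores
≈ 0 dB (r ≈ 0.5); white noise scores well below 0.

The backend is a protocol (`PitchBackend`), so an external phonetics
engine can be substituted to cross-validate voicing and harmonicity; the
shipped implementation is the native one described above, and exact
numerical agreement with any particular third-party engine is not a goal.

**Intensity.** `scale_intensity` equalizes RMS to a target level in dB SPL
re 20 µPa (default 70 dB), warning when the scaled peak would clip PCM
full scale. Equal intensity removes loudness as a discrimination cue.

## Stimulus selection

**Mutual information.** Parameters are ranked by the plug-in MI (in bits)
between an equal-frequency 16-bin discretization of the parameter and the
type label. Equal-frequency binning makes the estimator invariant under
strictly monotone transformations of the parameter; ranking ties break
alphabetically. The plug-in estimator has the usual positive bias of order
(bins − 1)/(2N ln 2), which is why an uninformative parameter at N ≈ 200
shows ~0.05–0.15 bits rather than exactly zero; rankings are unaffected.

**Equal-percentile threshold.** For a parameter where the upper class has
the larger mean, p_eq solves Q_lower(p) = Q_upper(1 − p) with
linear-interpolation (type 7) empirical quantiles. Type 7 makes both sides
continuous and the difference monotone, so bisection (to |Δp| < 10⁻⁹)
finds the unique crossing whenever the supports overlap; with disjoint
supports p_eq = 1 and the threshold is the gap midpoint. Filtering keeps
upper-class calls strictly above and lower-class calls strictly below the
threshold (values exactly at it are dropped), leaving the retained classes
linearly separable on that parameter. `select_stimulus_pool` applies the
top-2 MI parameters conjunctively — the two-parameter shaded-region
picture — a choice that is deliberate but configurable via
`top_k_parameters`, since applying thresholds per-parameter independently
is equally defensible.

## Session design

**Duration pairing.** Stimuli enter pools as cross-type pairs with
|Δduration| < 0.01 s so duration cannot cue the type. Feasibility is
decided exactly (maximum bipartite matching on the tolerance graph, via
scipy); infeasible requests report the exact maximum. The sampler itself
is random-order greedy with restarts: exact uniform sampling over
matchings is intractable (#P-hard counting), and on the loosely
constrained instances the protocol produces, greedy-with-restarts reaches
every feasible completion with comparable probability.

**Gellermann orders.** The presentation order of the two types is
constrained by four classical rules, each individually toggleable with
configurable thresholds: equal counts; no run longer than 3; per-type
counts in each half differing by ≤ 1; alternation fraction within
[0.4, 0.6]. Together they defeat position habits and win-stay/lose-shift
strategies. Orders are drawn by rejection sampling from uniform balanced
permutations, which is exactly uniform over the passing set (verified by
chi-square against full enumeration at length 10, where 78 of 1024
sequences pass).

**Experiments.** Session composition follows the three-experiment
protocol: experiment 1 replays the fixed 20 trained stimuli (10 per type);
experiment 2 draws 5+5 trained plus 10+10 novel per session, novel
stimuli reusable across sessions but never within one; experiment 3 draws
10+10 entirely novel stimuli without replacement globally, so no stimulus
is ever heard twice. The novel-stimulus pool size is a config parameter
(`novel_pool_size`, default 100). Repeat-after-error trials are runtime
events recorded in logs, never part of a plan.

## Criterion statistics

The learning criterion is read as *each* of `run_required` consecutive
sessions at or above the threshold (not a mean over sessions), with the
per-session pass count c = ⌈threshold·n⌉: 16/20 and 24/30 at the 80%
default. Under guessing (p = ½) the session pass probability is the exact
rational binomial tail — 6196/2²⁰ for 20 trials, 768212/2³⁰ for 30 —
computed in integer arithmetic; for other rational p the computation stays
in `fractions.Fraction`.

The p-value for reaching the criterion within H sessions is the
first-passage probability of a success run, computed by dynamic
programming over the current run length (states 0…run−1 plus absorption).
The DP is linear in H and exact to float precision; it agrees to 10⁻¹²
with exhaustive enumeration over all 2^H session-outcome sequences up to
H = 16, and with the closed forms q⁴ (H = 4) and q⁴(2 − q) (H = 5).
Session proportions exclude terminated sessions and repeat-flagged trials
by default (both toggleable); the threshold comparison uses a 10⁻¹²
tolerance so that 80% of 20 trials is not lost to float rounding.

The exact binomial test (two-sided via the small-probability method),
Fisher's exact test (sample odds ratio ad/bc, hypergeometric two-sided p)
and the Mann-Whitney U test (exact enumeration for combined n ≤ 20
without ties, tie-corrected continuity-corrected normal otherwise; U
reported for the first sample, U₁ + U₂ = n₁n₂) are provided through
scipy's implementations behind the module surface, each validated in the
tests against an independent enumeration oracle. Tests default to
two-sided.

## Response analysis

The pre/post battery reports, per vocal type and parameter, stage medians
and the Mann-Whitney comparison; per parameter, a two-way (type × stage)
ANOVA sum-of-squares table; and per stage, a PCA. ANOVA uses Type-II sums
of squares (each main effect adjusted for the other but not for the
interaction) — the usual choice when the question is the relative size of
main effects in an unbalanced design — configurable to Type I/III, with
the interaction term includable by flag. PCA standardizes each parameter
to zero mean and unit variance first (correlation-matrix PCA), because the
parameters carry incommensurate units; constant columns are dropped and
named.

## Synthetic data

The generator emulates the two things the analysis needs from real data:
two call types whose parameter distributions overlap partially, and
trial-level behaviour from responders of known competence.

A call is an additive harmonic stack (partial amplitudes following a
spectral tilt in dB/octave) plus white noise, with a 10 ms raised-cosine
onset/offset ramp and 50 ms of surrounding silence so interval slicing is
exercised. Durations are log-normal (positive, right-skewed, like real
call durations); f0 is normal, clipped into the tracker's range. Each of
the five parameters is steerable by one knob: duration by the log-normal
median, CoG monotonically by tilt, dominant frequency by f0 and tilt,
percentage voiced by the voiced fraction of the call, HNR monotonically by
the noise power fraction. Noisiness and voiced fraction get per-call
jitter (log-normal and normal respectively), as in real repertoires where
recording conditions and call quality vary — without that jitter HNR and
voicing would separate the types with implausible, near-deterministic
precision.

The default type pair places the planted contrast on CoG (tilts −2.5 vs
−7.0 dB/octave, spread 1.2) with a mild voicing difference (90% vs 86%)
and near-matched noisiness: at repertoire sizes of 60 + 45 this yields
CoG equal-percentile thresholds around p_eq ≈ 0.87–0.98 — genuine overlap,
exercised by the selection machinery — with CoG carrying the highest MI.
The post-stage variant shortens durations by a factor 0.55 and leaves the
spectrum untouched, planting a stage effect on duration only.

Responder agents: `chance` (p = ½ per trial, the null model), `expert`
(fixed p_correct), `logistic_learner` (p rises along a logistic curve in
the session index — a harness device for generating plausible learning
curves, not a claim about real learning dynamics), and `biased` (answers
type 1 with fixed probability regardless of stimulus).
`simulate_chance_sessions` is the vectorized per-session collapse of the
chance model, used for 10⁵-replicate Monte-Carlo validation of the exact
statistics. One global seed fans out via `numpy.random.SeedSequence`.

What passing tests on this material do **not** show: that the acoustic
backend matches any particular phonetics engine on real recordings; that
real repertoires are as well-behaved as the log-normal/normal synthetic
ones (no background transients, no overlapping callers, no recording-chain
coloration); or that the published data-dependent values (specific
thresholds in Hz, U statistics, SS tables) are reproduced — those require
the original recordings.

## Problem sizes

The shipped test suite works at desk scale, chosen to keep a full run in
minutes on one CPU: repertoires of 60 + 45 calls at 16 kHz for the
selection and recovery tests (100 seeded replicates for the
planted-effect recovery rate), exhaustive enumeration up to 2¹⁶ outcome
sequences and 2¹⁰ Gellermann sequences, and 10⁵ Monte-Carlo replicates
for the chance-model checks.
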