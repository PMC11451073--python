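# vocalearn

Computational machinery for two-alternative vocal usage / comprehension
playback experiments, of the kind used to test whether an animal (here:
harbor seals answering playbacks of their own call types) has learned to
match a heard vocal type with the corresponding vocal response.

The package covers the whole desk side of such a study, end to end and
without any recordings:

- **`io_formats`** — PCM WAV audio, Praat TextGrid interval annotations
  (long and short dialects, UTF-8/UTF-16), CSV trial/session logs with
  recomputed correctness flags, and session-plan playlists.
- **`acoustics`** — the five call parameters used to tell vocal types
  apart: duration, spectral center of gravity (CoG), dominant frequency,
  percentage of voiced frames (pitch search 50–400 Hz), and median
  harmonics-to-noise ratio (HNR), plus RMS intensity normalization.
  Voicing and harmonicity use a framed normalized-autocorrelation analysis
  behind a pluggable backend protocol.
- **`stimulus_selection`** — ranking parameters by binned mutual
  information with the type label, and the equal-percentile overlap
  threshold: the percentile *p*<sub>eq</sub> solving
  *Q*<sub>lower</sub>(*p*) = *Q*<sub>upper</sub>(1 − *p*), whose common
  quantile value is the cutoff that leaves only clearly distinguishable
  stimuli in the pool.
- **`session_design`** — duration-matched type pairs (paired stimuli
  differ by < 0.01 s), the pool rules of the three experiments (fixed
  trained set; trained + resampled novel; entirely novel, consumed once),
  and Gellermann-valid pseudorandom presentation orders (balanced counts,
  runs ≤ 3, balanced halves, alternation rate in [0.4, 0.6]).
- **`criterion_stats`** — the headline statistic. The learning criterion
  (LC) is a run rule: four consecutive sessions each with ≥ 80% correct.
  Under random guessing a session passes with probability
  *q* = P(Bin(*n*, ½) ≥ ⌈0.8 *n*⌉), exactly 6196/2²⁰ ≈ 0.0059 for
  20-trial sessions, and the p-value for reaching the LC within *H*
  sessions is the first-passage probability of a 4-success run in *H*
  Bernoulli(*q*) trials, computed by an exact dynamic program over
  run-length states. Exact binomial and Fisher tests round out the
  behavioural statistics.
- **`response_analysis`** — pre/post comparison of response acoustics:
  Mann-Whitney tests per type and parameter, a two-way (type × stage)
  ANOVA sum-of-squares decomposition, and correlation-matrix PCA.
- **`synthetic_data`** — harmonic-stack-plus-noise call synthesis with
  independently steerable parameters and partially overlapping type
  distributions, and simulated responders (chance / expert / logistic
  learner / side-biased) that exercise the full pipeline.

## Worked example

How surprising is it that a guessing animal reaches the learning criterion
within five 20-trial sessions?

```sh
$ vocalearn lc-prob --horizon 5
{"min_correct": 16, "session_success_probability": 0.005908966064453125,
 "lc_first_passage_probability": 2.4310336146197683e-09}
```

A single session needs ≥ 16/20 correct, which guessing achieves with
probability 0.0059; stringing four such sessions together within five has
probability 2.4 × 10⁻⁹ — far below any conventional significance level, so
an animal that does it has learned the task. The 30-trial variant
(criterion 24/30) within six sessions:

```sh
$ vocalearn lc-prob --n-trials 30 --horizon 6
{"min_correct": 24, "session_success_probability": 0.000715453177690506,
 "lc_first_passage_probability": 7.85667752743441e-13}
```

The same numbers are available in Python, along with the rest of the
pipeline:

```python
from vocalearn import CriterionSpec, lc_first_passage_probability
from vocalearn.synthetic_data import default_type_specs, generate_repertoire
from vocalearn.stimulus_selection import select_stimulus_pool

lc_first_passage_probability(CriterionSpec(), horizon=5)  # 2.43e-09

spec1, spec2 = default_type_specs()
repertoire, _ = generate_repertoire(spec1, spec2, n1=60, n2=45, seed=42)
pool, thresholds = select_stimulus_pool(repertoire)
thresholds[0].parameter, round(thresholds[0].p_eq, 3)  # ('cog', 0.959)
```

A Gellermann presentation order for a 20-trial session:

```sh
$ vocalearn gellermann --n-trials 20 --seed 7
21112221211221121221
```

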