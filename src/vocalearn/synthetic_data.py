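"""Synthetic vocalizations and simulated responders.

No recordings ship with the package, so everything the pipeline consumes can
be generated here: (a) two-type synthetic "repertoires" — harmonic-stack-
plus-noise calls whose five acoustic parameters are independently steerable
and whose type distributions partially overlap, the regime the selection
threshold is designed for; (b) trial-level behavioural logs from
parameterized responder agents ranging from pure chance (the null model of
the criterion statistics) to expert performance.

One global seed fans out through ``numpy.random.SeedSequence.spawn``, so any
sub-result is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from . import acoustics
from .io_formats import AnnotatedInterval, ExperimentLog, SessionRecord, TrialResult, Waveform
from .session_design import PoolEntry, SessionPlan, StimulusPool, build_session
from .stimulus_selection import LabeledFeatureSet

__all__ = [
    "VocalTypeSpec",
    "AgentSpec",
    "default_type_specs",
    "shifted_stage_spec",
    "synthesize_vocalization",
    "generate_repertoire",
    "make_stimulus_pool",
    "simulate_agent_responses",
    "simulate_experiment",
    "simulate_chance_sessions",
]


@dataclass(frozen=True)
class VocalTypeSpec:
    """Distributional recipe for one vocal type.

    Durations are log-normal (positive and right-skewed, like call
    durations); the fundamental is normal, clipped into the pitch-tracker
    range; spectral tilt (dB/octave across partials) steers the spectral
    center of gravity; the voiced fraction steers percentage voiced; the
    noise power fraction steers harmonicity.
    """

    duration_median: float = 0.5  # s
    duration_sigma_log: float = 0.25  # sd of log duration
    f0_mean: float = 180.0  # Hz
    f0_sd: float = 12.0
    n_partials: int = 24
    spectral_tilt: float = -4.0  # dB/octave across partials
    spectral_tilt_sd: float = 1.0
    voiced_fraction_pct: float = 90.0  # mean % of the call that is harmonic
    voiced_fraction_sd: float = 5.0  # per-call spread of the voiced fraction (pct points)
    noise_mix: float = 0.1  # median noise power fraction in (0, 1)
    noise_mix_log_sd: float = 0.35  # per-call log-normal jitter of the noise mix
    amplitude: float = 0.3  # peak amplitude target
    rate: int = 16000  # Hz


@dataclass(frozen=True)
class AgentSpec:
    """Behavioural model for a simulated responder.

    chance: correct with probability 0.5 on every trial (the null model);
    expert: correct with probability ``p_correct``; logistic_learner: the
    per-trial correct probability follows a logistic curve in the session
    index, 0.5 + (p_max - 0.5) / (1 + exp(-(t - t0)/tau)); biased: responds
    type 1 with probability ``beta`` regardless of the stimulus.
    """

    model: Literal["chance", "expert", "logistic_learner", "biased"] = "chance"
    p_correct: float = 0.5
    p_max: float = 0.95
    t0: float = 5.0
    tau: float = 2.0
    beta: float = 0.5

    def correct_probability(self, session_index: int) -> float | None:
        if self.model == "chance":
            return 0.5
        if self.model == "expert":
            return self.p_correct
        if self.model == "logistic_learner":
            return 0.5 + (self.p_max - 0.5) / (1.0 + np.exp(-(session_index - self.t0) / self.tau))
        return None  # biased: depends on the stimulus type


def default_type_specs() -> tuple[VocalTypeSpec, VocalTypeSpec]:
    """Two overlapping vocal types in the study's regime.

    Type 1 carries a shallow spectral tilt (high CoG), type 2 a steep one
    (low CoG); the tilt gap and its spread are set so that the CoG
    distributions overlap in roughly the published band (equal-percentile
    threshold around 0.9-1.0 at repertoire sizes of a few hundred calls).
    """
    type1 = VocalTypeSpec(
        duration_median=0.55, f0_mean=185.0, spectral_tilt=-2.5, spectral_tilt_sd=1.2,
        voiced_fraction_pct=90.0, noise_mix=0.12,
    )
    type2 = VocalTypeSpec(
        duration_median=0.60, f0_mean=185.0, spectral_tilt=-7.0, spectral_tilt_sd=1.2,
        voiced_fraction_pct=86.0, noise_mix=0.13,
    )
    return type1, type2


def shifted_stage_spec(spec: VocalTypeSpec, duration_factor: float = 0.55) -> VocalTypeSpec:
    """A post-stage variant of a type spec: same spectrum, shorter calls.

    Mirrors the duration drop observed in experimental responses while
    leaving the spectral parameters untouched.
    """
    return replace(spec, duration_median=spec.duration_median * duration_factor)


# --------------------------------------------------------------------------
# Signal synthesis
# --------------------------------------------------------------------------

_PAD_S = 0.05  # silence padding around each call so interval slicing is exercised
_RAMP_S = 0.01  # attack/decay ramp


def synthesize_vocalization(
    spec: VocalTypeSpec, seed: int | np.random.Generator
) -> tuple[Waveform, AnnotatedInterval]:
    """One synthetic call: harmonic stack plus noise, embedded in silence.

    The first ``voiced_fraction_pct`` of the call is a harmonic stack with
    per-partial amplitudes following the spectral tilt; the remainder is
    noise only.  Broadband noise at the requested power fraction overlays
    the whole call.  A 10 ms raised-cosine ramp shapes onset and offset.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    duration = float(np.exp(np.log(spec.duration_median) + spec.duration_sigma_log * rng.standard_normal()))
    duration = max(duration, 0.08)
    f0 = float(np.clip(rng.normal(spec.f0_mean, spec.f0_sd), 55.0, 395.0))
    tilt = float(rng.normal(spec.spectral_tilt, spec.spectral_tilt_sd))
    rate = spec.rate
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    nyquist = rate / 2.0
    ks = np.arange(1, spec.n_partials + 1)
    ks = ks[ks * f0 < 0.95 * nyquist]
    amps = 10.0 ** (tilt * np.log2(ks) / 20.0)
    phases = rng.uniform(0, 2 * np.pi, size=ks.size)
    harmonic = (amps[None, :] * np.sin(2 * np.pi * ks[None, :] * f0 * t[:, None] + phases)).sum(axis=1)
    voiced_pct = float(np.clip(rng.normal(spec.voiced_fraction_pct, spec.voiced_fraction_sd), 0.0, 100.0))
    n_voiced = int(round(n * voiced_pct / 100.0))
    harmonic[n_voiced:] = 0.0

    noise = rng.standard_normal(n)
    p_h = float(np.mean(harmonic**2))
    # per-call noisiness jitter: real calls vary in how clean they are
    mix = float(np.clip(spec.noise_mix * np.exp(rng.normal(0.0, spec.noise_mix_log_sd)), 1e-9, 0.97))
    p_target_noise = mix / max(1.0 - mix, 1e-9) * max(p_h, 1e-12)
    noise *= np.sqrt(p_target_noise / np.mean(noise**2))
    x = harmonic + noise

    ramp = min(int(_RAMP_S * rate), n // 2)
    if ramp > 0:
        win = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        x[:ramp] *= win
        x[-ramp:] *= win[::-1]
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= spec.amplitude / peak

    pad = int(_PAD_S * rate)
    samples = np.concatenate([np.zeros(pad), x, np.zeros(pad)])
    iv = AnnotatedInterval(start=pad / rate, end=(pad + n) / rate, label="call")
    return Waveform(samples, rate), iv


def generate_repertoire(
    spec1: VocalTypeSpec,
    spec2: VocalTypeSpec,
    n1: int,
    n2: int,
    seed: int,
    keep_audio: bool = False,
) -> tuple[LabeledFeatureSet, list[tuple[Waveform, AnnotatedInterval]]]:
    """A labelled two-type repertoire with features extracted by the acoustics module.

    Returns the LabeledFeatureSet (ids v1-0001...) and, when ``keep_audio``,
    the raw (Waveform, interval) pairs in row order.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 calls per type")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(n1 + n2)
    rows = []
    audio = []
    for i, (vtype, spec) in enumerate([(1, spec1)] * n1 + [(2, spec2)] * n2):
        w, iv = synthesize_vocalization(spec, np.random.default_rng(streams[i]))
        fv = acoustics.extract_features(w, iv)
        rows.append({"id": f"v{vtype}-{i:04d}", "type": vtype, **fv.as_dict()})
        if keep_audio:
            audio.append((w, iv))
    return LabeledFeatureSet(pd.DataFrame(rows)), audio


def make_stimulus_pool(
    fs: LabeledFeatureSet,
    n_trained_per_type: int = 10,
    n_novel2_per_type: int = 50,
    n_novel3_per_type: int = 40,
    seed: int = 0,
) -> StimulusPool:
    """Partition a repertoire into the trained / novel / more-novel pools.

    Assignments are disjoint random draws per type, so the experiment-3 pool
    is disjoint from everything else, as the protocol requires.
    """
    rng = np.random.default_rng(seed)
    entries: list[PoolEntry] = []
    for vtype in fs.types:
        sub = fs.table[fs.table["type"] == vtype]
        need = n_trained_per_type + n_novel2_per_type + n_novel3_per_type
        if len(sub) < need:
            raise ValueError(
                f"type {vtype}: need {need} calls for the three pools, have {len(sub)}"
            )
        picked = sub.iloc[rng.permutation(len(sub))[:need]]
        origins = (
            ["trained"] * n_trained_per_type
            + ["novel_exp2"] * n_novel2_per_type
            + ["novel_exp3"] * n_novel3_per_type
        )
        for (_, row), origin in zip(picked.iterrows(), origins):
            entries.append(
                PoolEntry(id=str(row["id"]), type=int(vtype), duration=float(row["duration"]), origin=origin)
            )
    return StimulusPool(entries)


# --------------------------------------------------------------------------
# Simulated responders
# --------------------------------------------------------------------------


def simulate_agent_responses(
    plan: SessionPlan,
    agent: AgentSpec,
    session_index: int,
    seed: int | np.random.Generator,
    session_id: int | None = None,
) -> SessionRecord:
    """Play one session plan against an agent and record trial results."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    trials = []
    for i, (_sid, stype) in enumerate(plan.trials, start=1):
        if agent.model == "biased":
            response = 1 if rng.random() < agent.beta else 2
        else:
            p = agent.correct_probability(session_index)
            response = stype if rng.random() < p else (3 - stype)
        trials.append(
            TrialResult(
                trial_index=i,
                stimulus_type=stype,
                response_type=response,
                correct=response == stype,
            )
        )
    return SessionRecord(
        session_id=session_id if session_id is not None else session_index,
        trials=trials,
        experiment=str(plan.experiment),
    )


def simulate_experiment(
    exp: int,
    pool: StimulusPool,
    agent: AgentSpec,
    n_sessions_max: int,
    seed: int,
    spec=None,
) -> ExperimentLog:
    """Run sessions against an agent until the LC is attained or the horizon ends."""
    from .criterion_stats import CriterionSpec, detect_learning_criterion
    from .session_design import TRIALS_PER_SESSION

    if spec is None:
        spec = CriterionSpec(n_trials=TRIALS_PER_SESSION[exp])
    root = np.random.SeedSequence(seed)
    sessions: list[SessionRecord] = []
    for s in range(1, n_sessions_max + 1):
        child = root.spawn(1)[0]
        plan_seed, resp_seed = child.spawn(2)
        plan = build_session(exp, pool, seed=int(plan_seed.generate_state(1)[0] % 2**31))
        sessions.append(
            simulate_agent_responses(
                plan, agent, session_index=s, seed=np.random.default_rng(resp_seed)
            )
        )
        result = detect_learning_criterion(ExperimentLog(list(sessions)), spec)
        if result.lc_session is not None:
            break
    return ExperimentLog(sessions)


def simulate_chance_sessions(
    n_trials: int, n_sessions: int, n_replicates: int, seed: int, p: float = 0.5
) -> np.ndarray:
    """Per-session correct counts for chance responders, vectorized.

    Returns an (n_replicates, n_sessions) integer array of correct-response
    counts; each count is the sum of ``n_trials`` independent Bernoulli(p)
    trials, exactly the trial-level chance model collapsed per session.
    Used for large Monte-Carlo validation of the exact statistics.
    """
    rng = np.random.default_rng(seed)
    return rng.binomial(n_trials, p, size=(n_replicates, n_sessions))
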