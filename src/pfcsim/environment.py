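"""Generative process: trial conditions, stimulus emission, and trial loops.

The environment mirrors the agent's generative model of the task: a cue
identifying the attentional rule, an empty delay, simultaneous visual and
auditory stimuli of which only the cued modality carries the target, and
feedback contingent on the committed choice.  The unattended (distractor)
stimulus can be drawn independently of the target (matching the agent's
uniform likelihood for that modality), forced incongruent (the stimuli
always conflict, as when both options are presented and only one modality
is task-relevant), or forced congruent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .engine import (
    BeliefState,
    EngineSettings,
    expected_free_energy,
    free_energy,
    init_beliefs,
    one_hot,
    policy_posterior,
    select_action,
    state_update,
)
from .model import CHOICES, GenerativeModel, RULES, TARGETS

__all__ = [
    "TrialCondition",
    "EpochRecord",
    "TrialRecord",
    "SessionSummary",
    "sample_condition",
    "emit_outcomes",
    "run_trial",
    "run_session",
    "DISTRACTOR_MODES",
]

DISTRACTOR_MODES = ("incongruent", "independent", "congruent")


@dataclass(frozen=True)
class TrialCondition:
    """True rule and target of one trial."""

    rule: int
    target: int
    seed: int | None = None

    @property
    def rule_label(self) -> str:
        return RULES[self.rule]

    @property
    def target_label(self) -> str:
        return TARGETS[self.target]


@dataclass
class EpochRecord:
    """Everything the agent saw, believed, and did in one observation epoch."""

    t: int
    observations: list[np.ndarray]
    F: np.ndarray
    G: np.ndarray
    posterior: np.ndarray
    action: int | None
    s: list[np.ndarray]  # per factor: (n_policies, T, dim), post-update copy


@dataclass
class TrialRecord:
    """Full log of one perception-action trial."""

    condition: TrialCondition
    epochs: list[EpochRecord] = field(default_factory=list)
    beliefs: BeliefState | None = None
    choice_states: list[int] = field(default_factory=list)
    congruent: bool | None = None
    feedback: int | None = None  # outcome level index in the feedback modality
    correct: bool | None = None
    n_iter: int = 0

    @property
    def final_choice(self) -> int:
        return self.choice_states[-1]

    @property
    def final_choice_label(self) -> str:
        return CHOICES[self.final_choice]


@dataclass
class SessionSummary:
    """Aggregate outcomes of a batch of independent trials."""

    n_trials: int
    accuracy: float
    per_condition_accuracy: dict[str, float]
    mean_policy_entropy: float
    seed: int
    lesion: str = "none"
    trials: list[TrialRecord] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "accuracy": self.accuracy,
            "per_condition_accuracy": self.per_condition_accuracy,
            "mean_policy_entropy": self.mean_policy_entropy,
            "seed": self.seed,
            "lesion": self.lesion,
        }


def sample_condition(rng: np.random.Generator) -> TrialCondition:
    """Draw rule and target independently and uniformly."""
    return TrialCondition(rule=int(rng.integers(2)), target=int(rng.integers(2)))


def emit_outcomes(
    condition: TrialCondition,
    choice_state: int,
    tau: int,
    rng: np.random.Generator | None = None,
    distractor: str = "incongruent",
) -> list[np.ndarray]:
    """One-hot outcomes per modality (cue, vision, audition, feedback) at tau.

    tau=1: the cue reflects the true rule.  tau=2: silence.  tau=3: the
    attended modality shows the target; the other modality shows a
    distractor per ``distractor`` mode.  tau=4: feedback is correct iff the
    choice state matches the target (no-choice counts as incorrect).
    """
    if tau not in (1, 2, 3, 4):
        raise ValueError(f"emit_outcomes: tau={tau} outside 1..4")
    if distractor not in DISTRACTOR_MODES:
        raise ValueError(f"emit_outcomes: unknown distractor mode {distractor!r}")
    NULL = 2
    cue = vis = aud = fb = NULL
    if tau == 1:
        cue = condition.rule
    elif tau == 3:
        if distractor == "independent":
            if rng is None:
                raise ValueError("emit_outcomes: independent distractor needs an rng")
            dis = int(rng.integers(2))
        elif distractor == "incongruent":
            dis = 1 - condition.target
        else:
            dis = condition.target
        if condition.rule == 0:  # attend-vision
            vis, aud = condition.target, dis
        else:
            aud, vis = condition.target, dis
    elif tau == 4:
        fb = 0 if choice_state == condition.target + 1 else 1
    return [one_hot(cue, 3), one_hot(vis, 3), one_hot(aud, 3), one_hot(fb, 3)]


def run_trial(
    model: GenerativeModel,
    settings: EngineSettings | None = None,
    condition: TrialCondition | None = None,
    rng: np.random.Generator | None = None,
    distractor: str = "incongruent",
    record_trace: bool = True,
) -> TrialRecord:
    """Run one full perception-action trial.

    Each epoch t = 1..T: emit outcomes from the true states, update beliefs
    under every policy, evaluate F and G, form the policy posterior, and (for
    t < T) select and execute an action on the choice state.
    """
    settings = settings or EngineSettings()
    rng = rng or np.random.default_rng(0)
    condition = condition or sample_condition(rng)
    T = model.T
    n_pi = model.n_policies

    record = TrialRecord(condition=condition, n_iter=settings.n_iter)
    beliefs = init_beliefs(model)
    record.beliefs = beliefs
    observations: list[list[np.ndarray]] = []
    choice_state = 0  # no-choice
    record.choice_states.append(choice_state)

    for t in range(1, T + 1):
        obs_t = emit_outcomes(condition, choice_state, t, rng, distractor)
        observations.append(obs_t)
        if t == 3:
            att, una = (1, 2) if condition.rule == 0 else (2, 1)
            record.congruent = bool(
                np.argmax(obs_t[att]) == np.argmax(obs_t[una])
            )
        state_update(
            model, beliefs, observations, t, settings, record_trace=record_trace
        )
        F = np.array(
            [free_energy(model, beliefs, observations, t, pi, settings) for pi in range(n_pi)]
        )
        G = np.array(
            [expected_free_energy(model, beliefs, pi, t, settings) for pi in range(n_pi)]
        )
        post = policy_posterior(F, G, settings)
        action = None
        if t < T:
            action = select_action(post, model.policies, t, model.n_actions)
            # the true choice state moves deterministically under the action
            col = model.B[model.controlled_factor][action][:, choice_state]
            choice_state = int(np.argmax(col))
            record.choice_states.append(choice_state)
        record.epochs.append(
            EpochRecord(
                t=t,
                observations=obs_t,
                F=F,
                G=G,
                posterior=post,
                action=action,
                s=[sn.copy() for sn in beliefs.s],
            )
        )

    record.feedback = int(np.argmax(observations[-1][3]))
    record.correct = record.feedback == 0
    return record


def _policy_entropy(posterior: np.ndarray) -> float:
    p = posterior[posterior > 0]
    return float(-(p * np.log(p)).sum())


def run_session(
    model: GenerativeModel,
    settings: EngineSettings | None = None,
    n_trials: int = 64,
    seed: int = 0,
    distractor: str = "incongruent",
    record_trace: bool = False,
    keep_trials: bool = True,
) -> SessionSummary:
    """Run ``n_trials`` independent trials and summarize performance.

    A master seed spawns independent substreams for the trial conditions and
    for every trial's stimulus noise, so each component is reproducible on
    its own.
    """
    if n_trials < 1:
        raise ValueError("run_session: n_trials must be >= 1")
    settings = settings or EngineSettings()
    ss = np.random.SeedSequence(seed)
    cond_stream, *trial_streams = ss.spawn(n_trials + 1)
    cond_rng = np.random.default_rng(cond_stream)

    trials: list[TrialRecord] = []
    hits: dict[str, list[bool]] = {}
    entropies = []
    n_correct = 0
    for k in range(n_trials):
        condition = sample_condition(cond_rng)
        rec = run_trial(
            model,
            settings,
            condition,
            np.random.default_rng(trial_streams[k]),
            distractor,
            record_trace=record_trace,
        )
        n_correct += bool(rec.correct)
        key = f"{condition.rule_label}/{condition.target_label}"
        hits.setdefault(key, []).append(bool(rec.correct))
        # entropy of the policy posterior at the post-stimulus epoch
        entropies.append(_policy_entropy(rec.epochs[2].posterior))
        if keep_trials:
            trials.append(rec)

    return SessionSummary(
        n_trials=n_trials,
        accuracy=n_correct / n_trials,
        per_condition_accuracy={k: float(np.mean(v)) for k, v in sorted(hits.items())},
        mean_policy_entropy=float(np.mean(entropies)),
        seed=seed,
        trials=trials,
    )
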