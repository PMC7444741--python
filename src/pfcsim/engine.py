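"""Variational message passing, free energies, and policy selection.

Perception is cast as a gradient-flow on variational free energy: for every
policy, each hidden-state factor and represented time step carries a
"depolarization" vector ``v`` whose softmax ``s`` is the posterior
expectation (read out as a firing rate).  Each update sweep combines three
messages -- a forward message from beliefs about the previous step (through
the transition model), a backward message from beliefs about the next step,
and a likelihood message from observed outcomes contextualized by the other
factors' beliefs -- into a prediction error that increments ``v``.

Action selection scores each candidate policy by its variational free energy
``F`` (evidence accrued so far) plus expected free energy ``G`` (risk of
predicted outcomes relative to preferences, plus ambiguity of the likelihood
mapping); the policy posterior is a softmax of ``-(F + G)`` and actions take
the most probable next move under that posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import xlogy

from .model import GenerativeModel

__all__ = [
    "EngineSettings",
    "BeliefState",
    "TraceFrame",
    "NumericError",
    "softmax_normalize",
    "safe_log",
    "one_hot",
    "likelihood_message",
    "init_beliefs",
    "state_update",
    "predict_outcomes",
    "free_energy",
    "expected_free_energy",
    "likelihood_entropy",
    "policy_posterior",
    "select_action",
]


class NumericError(ArithmeticError):
    """Raised when belief updating diverges or receives non-finite input."""


@dataclass(frozen=True)
class EngineSettings:
    """Numerical settings of the belief-update scheme.

    Parameters
    ----------
    n_iter :
        Update sweeps per observation epoch.
    kappa :
        Step size of the depolarization increment, in (0, 1].
    log_floor :
        Additive floor inside every log of a probability; default ``e**-16``.
    gamma :
        Precision (inverse temperature) of the policy softmax.
    message_mode :
        ``"half-averaged"`` weights the forward and backward messages by 1/2
        (the marginal-message-passing convention); ``"full-sum"`` uses unit
        weights.
    policy_value :
        ``"posterior"`` scores policies by -(F+G); ``"prior"`` by -G only.
    """

    n_iter: int = 16
    kappa: float = 1.0 / 3.0
    log_floor: float = float(np.exp(-16.0))
    gamma: float = 1.0
    message_mode: str = "full-sum"
    policy_value: str = "posterior"

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0 < self.kappa <= 1:
            raise ValueError("kappa must lie in (0, 1]")
        if not self.log_floor > 0:
            raise ValueError("log_floor must be positive")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if self.message_mode not in ("full-sum", "half-averaged"):
            raise ValueError(f"unknown message_mode {self.message_mode!r}")
        if self.policy_value not in ("posterior", "prior"):
            raise ValueError(f"unknown policy_value {self.policy_value!r}")

    @property
    def message_weight(self) -> float:
        return 1.0 if self.message_mode == "full-sum" else 0.5


def softmax_normalize(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Stable softmax: exp(v - max) renormalized to sum to one."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise NumericError("softmax_normalize: non-finite input")
    e = np.exp(v - v.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def safe_log(p: np.ndarray, log_floor: float = float(np.exp(-16.0))) -> np.ndarray:
    """ln(p + floor) for probabilities; raises on negative entries."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("safe_log: negative entries")
    return np.log(p + log_floor)


def one_hot(index: int, n: int) -> np.ndarray:
    o = np.zeros(n)
    o[index] = 1.0
    return o


def _contract_others(arr: np.ndarray, svecs: Sequence[np.ndarray], keep: int) -> np.ndarray:
    """Contract every state axis of ``arr`` except ``keep`` with the beliefs."""
    others = [m for m in range(len(svecs)) if m != keep]
    arr = np.transpose(arr, [keep] + others)
    for m in reversed(others):
        arr = arr @ svecs[m]
    return arr


def _contract_all(arr: np.ndarray, svecs: Sequence[np.ndarray]) -> float:
    for m in range(len(svecs) - 1, -1, -1):
        arr = arr @ svecs[m]
    return float(arr)


def likelihood_message(
    model: GenerativeModel,
    observations: Sequence[np.ndarray],
    s_tau: Sequence[np.ndarray],
    n: int,
    tau: int,
    settings: EngineSettings | None = None,
) -> np.ndarray:
    """Sensory evidence for factor ``n`` at time ``tau``, gated by context.

    Sums, over modalities, the log-likelihood array contracted with the
    observed outcome and with the concurrent beliefs about every other
    factor.  It is through this contraction that (for example) beliefs about
    the attentional rule control the gain of each stimulus modality's input
    to the target representation.

    ``tau`` is 1-based; ``observations[g]`` must be one-hot.
    """
    settings = settings or EngineSettings()
    msg = np.zeros(model.factors[n].n)
    for g, obs in enumerate(observations):
        obs = np.asarray(obs, dtype=float)
        if obs.shape != (model.modalities[g].n,) or not (
            np.isclose(obs.sum(), 1.0) and set(np.unique(obs)) <= {0.0, 1.0}
        ):
            raise ValueError(f"likelihood_message: outcome for modality {g} not one-hot")
        lnA = safe_log(model.A[g][tau - 1], settings.log_floor)
        arr = np.tensordot(obs, lnA, axes=(0, 0))  # over outcome axis
        msg += _contract_others(arr, s_tau, keep=n)
    return msg


@dataclass
class TraceFrame:
    """Belief snapshot after one update sweep (for electrophysiology)."""

    epoch: int
    iteration: int
    s: list[np.ndarray]  # per factor: (n_policies, T, dim)
    v: list[np.ndarray]
    F: np.ndarray | None = None  # per-policy free energy at this sweep
    G: np.ndarray | None = None  # per-policy expected free energy at this sweep


@dataclass
class BeliefState:
    """Per-policy posterior expectations ``s`` and depolarizations ``v``.

    ``s[n][pi, tau, i]`` is the expectation that factor ``n`` occupies level
    ``i`` at (1-based) time ``tau + 1``, conditioned on policy ``pi``;
    ``v`` holds the pre-softmax potentials, ``s = softmax(v)`` per vector,
    and ``eps`` the most recent prediction errors (message minus potential).
    The full sweep-resolved history is kept in ``trace``.
    """

    s: list[np.ndarray]
    v: list[np.ndarray]
    eps: list[np.ndarray] | None = None
    trace: list[TraceFrame] = field(default_factory=list)
    # reported (never silently accepted) increases of the policy-averaged
    # free energy across sweeps within an epoch: (epoch, iteration, increase)
    descent_violations: list[tuple[int, int, float]] = field(default_factory=list)

    def policy_beliefs(self, pi: int) -> list[np.ndarray]:
        return [sn[pi] for sn in self.s]


def init_beliefs(model: GenerativeModel) -> BeliefState:
    """Uniform beliefs (v = 0) for every policy, factor, and time step."""
    s, v, eps = [], [], []
    for f in model.factors:
        v.append(np.zeros((model.n_policies, model.T, f.n)))
        s.append(np.full((model.n_policies, model.T, f.n), 1.0 / f.n))
        eps.append(np.zeros((model.n_policies, model.T, f.n)))
    return BeliefState(s=s, v=v, eps=eps)


def _policy_action(model: GenerativeModel, pi: int, tau: int) -> list[int]:
    """Per-factor action index for the transition tau -> tau+1 (1-based)."""
    acts = [0] * len(model.factors)
    acts[model.controlled_factor] = int(model.policies[pi, tau - 1])
    return acts


def state_update(
    model: GenerativeModel,
    beliefs: BeliefState,
    observations: Sequence[Sequence[np.ndarray]],
    t: int,
    settings: EngineSettings | None = None,
    epoch: int | None = None,
    record_trace: bool = True,
) -> BeliefState:
    """Run ``n_iter`` update sweeps given observations up to epoch ``t``.

    ``observations[k]`` holds the one-hot outcomes of epoch ``k+1``.  Beliefs
    persist across calls (warm start), so within-trial traces concatenate
    into a continuous time series.  Modifies and returns ``beliefs``.
    """
    settings = settings or EngineSettings()
    if len(observations) < t:
        raise ValueError("state_update: fewer observation epochs than t")
    w = settings.message_weight
    lam = settings.log_floor
    kappa = settings.kappa
    T = model.T
    N = len(model.factors)
    cf = model.controlled_factor
    epoch = t if epoch is None else epoch

    # the observed log-likelihood summed over modalities is constant within
    # the epoch; precompute one state-space array per observed time step
    SL = _observed_loglik(model, observations, t, lam)
    lnD = [np.log(model.D[n] + lam) for n in range(N)]

    s, v = beliefs.s, beliefs.v
    for it in range(settings.n_iter):
        for pi in range(model.n_policies):
            for tau in range(1, T + 1):
                s_tau = [sn[pi, tau - 1] for sn in s]
                for n in range(N):
                    if tau == 1:
                        fwd = lnD[n]
                    else:
                        u = model.policies[pi, tau - 2] if n == cf else 0
                        fwd = np.log(model.B[n][u] @ s[n][pi, tau - 2] + lam)
                    if tau < T:
                        u = model.policies[pi, tau - 1] if n == cf else 0
                        msg = w * (fwd + np.log(model.B[n][u].T @ s[n][pi, tau] + lam))
                    else:
                        msg = w * fwd
                    if tau <= t:
                        msg = msg + _contract_others(SL[tau - 1], s_tau, n)
                    eps = msg - v[n][pi, tau - 1]
                    if np.any(np.abs(eps) > 1e6):
                        raise NumericError(
                            f"state_update diverged (|eps| > 1e6) with {settings}"
                        )
                    if beliefs.eps is not None:
                        beliefs.eps[n][pi, tau - 1] = eps
                    vn = v[n][pi, tau - 1] + kappa * eps
                    v[n][pi, tau - 1] = vn
                    e = np.exp(vn - vn.max())
                    new_s = e / e.sum()
                    s[n][pi, tau - 1] = new_s
                    s_tau[n] = new_s
        if record_trace:
            F = np.array(
                [
                    _free_energy_given_loglik(model, beliefs, SL, t, pi, lam)
                    for pi in range(model.n_policies)
                ]
            )
            G = np.array(
                [
                    expected_free_energy(model, beliefs, pi, t, settings)
                    for pi in range(model.n_policies)
                ]
            )
            frame = TraceFrame(
                epoch=epoch,
                iteration=it + 1,
                s=[sn.copy() for sn in beliefs.s],
                v=[vn.copy() for vn in beliefs.v],
                F=F,
                G=G,
            )
            prev = beliefs.trace[-1] if beliefs.trace else None
            if prev is not None and prev.epoch == epoch:
                post = policy_posterior(F, G, settings)
                increase = float(post @ F) - float(post @ prev.F)
                if increase > 1e-6:
                    beliefs.descent_violations.append((epoch, it + 1, increase))
            beliefs.trace.append(frame)
    return beliefs


def _observed_loglik(
    model: GenerativeModel,
    observations: Sequence[Sequence[np.ndarray]],
    t: int,
    lam: float,
) -> list[np.ndarray]:
    """Per observed time step: sum over modalities of obs-contracted ln A."""
    SL = []
    for tau in range(1, t + 1):
        acc = np.zeros(model.state_dims)
        for g, obs in enumerate(observations[tau - 1]):
            obs = np.asarray(obs, dtype=float)
            if obs.shape != (model.modalities[g].n,) or not (
                np.isclose(obs.sum(), 1.0) and set(np.unique(obs)) <= {0.0, 1.0}
            ):
                raise ValueError(
                    f"state_update: outcome for modality {g} at tau={tau} not one-hot"
                )
            acc += np.log(model.A[g][tau - 1][int(np.argmax(obs))] + lam)
        SL.append(acc)
    return SL


def _free_energy_given_loglik(
    model: GenerativeModel,
    beliefs: BeliefState,
    SL: Sequence[np.ndarray],
    t: int,
    pi: int,
    lam: float,
) -> float:
    F = 0.0
    cf = model.controlled_factor
    for tau in range(1, model.T + 1):
        s_tau = [sn[pi, tau - 1] for sn in beliefs.s]
        for n in range(len(model.factors)):
            sv = s_tau[n]
            if tau == 1:
                fwd = np.log(model.D[n] + lam)
            else:
                u = model.policies[pi, tau - 2] if n == cf else 0
                fwd = np.log(model.B[n][u] @ beliefs.s[n][pi, tau - 2] + lam)
            F += float(sv @ (np.log(sv + lam) - fwd))
        if tau <= t:
            F -= _contract_all(SL[tau - 1], s_tau)
    return F


def predict_outcomes(
    model: GenerativeModel, beliefs: BeliefState, pi: int
) -> list[np.ndarray]:
    """Predicted outcome distributions o[g][tau] under policy ``pi``."""
    out = []
    for g, m in enumerate(model.modalities):
        o = np.zeros((model.T, m.n))
        for tau in range(1, model.T + 1):
            s_tau = [sn[pi, tau - 1] for sn in beliefs.s]
            arr = model.A[g][tau - 1]
            for ax in range(len(s_tau) - 1, -1, -1):
                arr = np.tensordot(arr, s_tau[ax], axes=(ax + 1, 0))
            o[tau - 1] = arr
        out.append(o)
    return out


def free_energy(
    model: GenerativeModel,
    beliefs: BeliefState,
    observations: Sequence[Sequence[np.ndarray]],
    t: int,
    pi: int,
    settings: EngineSettings | None = None,
) -> float:
    """Variational free energy of policy ``pi`` given outcomes up to ``t``.

    Complexity: KL-like divergence of each time step's beliefs from the
    forward (prior) message.  Accuracy: expected log-likelihood of every
    observed outcome under the current beliefs.
    """
    settings = settings or EngineSettings()
    lam = settings.log_floor
    SL = _observed_loglik(model, observations, t, lam)
    return _free_energy_given_loglik(model, beliefs, SL, t, pi, lam)


def likelihood_entropy(model: GenerativeModel, g: int, tau: int) -> np.ndarray:
    """Negative-entropy vector H over joint states for modality g at tau.

    ``H_i = sum_j A[j|i] ln A[j|i]`` (<= 0; exactly 0 where the outcome is
    deterministic).  Exact zeros use the 0 ln 0 = 0 convention.
    """
    A = model.A[g][tau - 1]
    return xlogy(A, A).sum(axis=0)


def expected_free_energy(
    model: GenerativeModel,
    beliefs: BeliefState,
    pi: int,
    t: int,
    settings: EngineSettings | None = None,
    predicted: Sequence[np.ndarray] | None = None,
) -> float:
    """Expected free energy G of policy ``pi`` over future steps t+1..T.

    Risk is the divergence of predicted outcomes from the log-preferences C;
    ambiguity is the expected entropy of the likelihood mapping under the
    predicted states.  Both are accumulated over every modality and future
    time step.
    """
    settings = settings or EngineSettings()
    lam = settings.log_floor
    if predicted is None:
        predicted = predict_outcomes(model, beliefs, pi)
    G = 0.0
    for tau in range(t + 1, model.T + 1):
        s_tau = [sn[pi, tau - 1] for sn in beliefs.s]
        for g in range(len(model.modalities)):
            o = predicted[g][tau - 1]
            G += float(o @ (safe_log(o, lam) - model.C[g][tau - 1]))
            H = likelihood_entropy(model, g, tau)
            G -= _contract_all(H, s_tau)
    return G


def policy_posterior(
    F: np.ndarray,
    G: np.ndarray,
    settings: EngineSettings | None = None,
) -> np.ndarray:
    """Softmax policy posterior from free energies: softmax(-gamma (F + G))."""
    settings = settings or EngineSettings()
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    if settings.policy_value == "prior":
        value = -G
    else:
        value = -(F + G)
    return softmax_normalize(settings.gamma * value)


def frame_posterior(frame: TraceFrame, settings: EngineSettings | None = None) -> np.ndarray:
    """Policy posterior implied by one trace frame's free energies."""
    if frame.F is None or frame.G is None:
        raise ValueError("frame_posterior: frame carries no free energies")
    return policy_posterior(frame.F, frame.G, settings)


def select_action(
    posterior: np.ndarray, policies: np.ndarray, t: int, n_actions: int
) -> int:
    """Most probable action at step ``t`` (1-based) under the policy posterior.

    Marginalizes the posterior over policies prescribing each action; exact
    ties resolve to the lowest action index.
    """
    if not 1 <= t <= policies.shape[1]:
        raise ValueError(f"select_action: t={t} outside 1..{policies.shape[1]}")
    mass = np.zeros(n_actions)
    for pi, p in enumerate(posterior):
        mass[int(policies[pi, t - 1])] += p
    return int(np.argmax(mass))
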