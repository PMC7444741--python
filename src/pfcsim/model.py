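"""Generative-model data structures and the delay-period attention task.

The agent's world model is a discrete partially observed Markov decision
process factorized into

* hidden-state *factors* (rule, target, choice), each a categorical variable,
* outcome *modalities* (cue, vision, audition, feedback), each with a
  designated "null" (uninformative) level,
* ``A`` — a per-modality, per-time likelihood mapping joint hidden states to
  outcome distributions,
* ``B`` — per-factor, per-action column-stochastic transition matrices,
* ``C`` — per-modality log-preferences over outcomes at each time step,
* ``D`` — per-factor initial-state priors, and
* a set of candidate policies (action sequences on the choice factor).

The time dependence of the likelihood is stored as one array per time step;
this is equivalent to conditioning on a deterministic clock state and keeps
the joint state space small.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FactorSpec",
    "ModalitySpec",
    "TaskParams",
    "GenerativeModel",
    "ValidationReport",
    "ConfigurationError",
    "build_policy_set",
    "build_task_model",
    "validate_model",
    "model_to_json",
    "model_from_json",
]

STOCH_TOL = 1e-9

# canonical level orderings for the default task
RULES = ("attend-vision", "attend-audition")
TARGETS = ("blue", "green")
CHOICES = ("no-choice", "blue", "green")
ACTIONS = ("stay", "pick-blue", "pick-green")


class ConfigurationError(ValueError):
    """Raised when a model or task configuration is structurally invalid."""


@dataclass(frozen=True)
class FactorSpec:
    """One categorical hidden-state factor."""

    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 2:
            raise ConfigurationError(f"factor {self.name!r}: needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ConfigurationError(f"factor {self.name!r}: duplicate level labels")

    @property
    def n(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class ModalitySpec:
    """One categorical outcome modality; exactly one level is the null outcome."""

    name: str
    levels: tuple[str, ...]
    null_level: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 2:
            raise ConfigurationError(f"modality {self.name!r}: needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ConfigurationError(f"modality {self.name!r}: duplicate level labels")
        if self.null_level not in self.levels:
            raise ConfigurationError(
                f"modality {self.name!r}: null level {self.null_level!r} not in levels"
            )

    @property
    def n(self) -> int:
        return len(self.levels)

    @property
    def null_index(self) -> int:
        return self.levels.index(self.null_level)


@dataclass(frozen=True)
class TaskParams:
    """Parameters of the default delay-period attention task.

    Parameters
    ----------
    preference :
        Log-preference magnitude c (nats) for correct feedback at the final
        step; incorrect feedback carries -c.  Must be positive.
    policy_mode :
        ``"terminal-choice"`` (three policies: hold until the post-delay step,
        then stay / pick-blue / pick-green) or ``"full-tree"`` (all action
        sequences).
    cue_precision, attended_precision :
        Probability mass the cue (resp. attended-stimulus) likelihood places
        on the correct outcome; 1.0 gives the identity mappings of the
        default task.
    """

    preference: float = 3.0
    policy_mode: str = "terminal-choice"
    cue_precision: float = 1.0
    attended_precision: float = 1.0

    def __post_init__(self) -> None:
        if not self.preference > 0:
            raise ConfigurationError("preference: must be > 0")
        for name in ("cue_precision", "attended_precision"):
            val = getattr(self, name)
            if not 0.5 < val <= 1.0:
                raise ConfigurationError(f"{name}: must lie in (0.5, 1]")


@dataclass
class GenerativeModel:
    """A discrete-state generative model.

    Attributes
    ----------
    A : list of ndarray
        Per modality ``g``: array of shape ``(T, n_outcomes_g, *state_dims)``;
        ``A[g][t-1, o, i1, .., iN] = P(o_t = o | s_t = (i1..iN))``.
    B : list of ndarray
        Per factor ``n``: array of shape ``(n_actions_n, dim_n, dim_n)`` with
        column-stochastic matrices ``B[n][u, i, j] = P(next=i | cur=j, u)``.
        Only the controlled factor has more than one action.
    C : list of ndarray
        Per modality: ``(T, n_outcomes_g)`` log-preferences (unnormalized
        natural-log prior over outcomes).
    D : list of ndarray
        Per factor: initial-state prior.
    policies : ndarray
        ``(n_policies, T-1)`` action indices on the controlled factor.
    """

    factors: list[FactorSpec]
    modalities: list[ModalitySpec]
    A: list[np.ndarray]
    B: list[np.ndarray]
    C: list[np.ndarray]
    D: list[np.ndarray]
    policies: np.ndarray
    T: int
    controlled_factor: int

    @property
    def state_dims(self) -> tuple[int, ...]:
        return tuple(f.n for f in self.factors)

    @property
    def n_policies(self) -> int:
        return self.policies.shape[0]

    @property
    def n_actions(self) -> int:
        return self.B[self.controlled_factor].shape[0]

    def factor_index(self, name: str) -> int:
        for i, f in enumerate(self.factors):
            if f.name == name:
                return i
        raise KeyError(name)

    def modality_index(self, name: str) -> int:
        for i, m in enumerate(self.modalities):
            if m.name == name:
                return i
        raise KeyError(name)

    def copy(self) -> "GenerativeModel":
        return copy.deepcopy(self)


def build_policy_set(mode: str, T: int) -> np.ndarray:
    """Enumerate candidate action sequences on the choice factor.

    ``terminal-choice`` holds "stay" until the final transition, where the
    agent may stay or commit to either option (3 policies).  ``full-tree``
    enumerates every action sequence of length T-1 (3**(T-1) policies).
    """
    if T < 2:
        raise ConfigurationError("T: horizon must be >= 2")
    n_act = len(ACTIONS)
    if mode == "terminal-choice":
        pols = np.zeros((n_act, T - 1), dtype=np.intp)
        pols[:, -1] = np.arange(n_act)
        return pols
    if mode == "full-tree":
        grids = np.meshgrid(*([np.arange(n_act)] * (T - 1)), indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1).astype(np.intp)
    raise ConfigurationError(f"policy_mode: unknown mode {mode!r}")


def build_task_model(params: TaskParams | None = None) -> GenerativeModel:
    """Build the generative model of the rule-cued cross-modal attention task.

    Trial structure (T=4): a cue identifying the attentional rule, a delay
    with no informative input, simultaneous visual and auditory stimuli of
    which only the rule-cued modality reflects the target, and feedback that
    is "correct" iff the committed choice matches the target (failing to
    choose counts as incorrect).
    """
    params = params or TaskParams()
    T = 4
    c = float(params.preference)

    factors = [
        FactorSpec("rule", RULES),
        FactorSpec("target", TARGETS),
        FactorSpec("choice", CHOICES),
    ]
    modalities = [
        ModalitySpec("cue", ("brown-noise", "blue-noise", "null"), "null"),
        ModalitySpec("vision", ("blue", "green", "null"), "null"),
        ModalitySpec("audition", ("blue", "green", "null"), "null"),
        ModalitySpec("feedback", ("correct", "incorrect", "null"), "null"),
    ]
    dims = (2, 2, 3)

    A = [np.zeros((T, m.n) + dims) for m in modalities]
    CUE, VIS, AUD, FB = range(4)
    NULL = 2  # null index in every modality here

    # t=1: cue is the (precision-weighted) image of the rule; everything else null
    p = params.cue_precision
    for r in range(2):
        A[CUE][0, :, r, :, :] = 0.0
        A[CUE][0, r, r, :, :] = p
        A[CUE][0, 1 - r, r, :, :] = 1.0 - p
    for g in (VIS, AUD, FB):
        A[g][0, NULL] = 1.0

    # t=2: delay — every modality null regardless of state
    for g in range(4):
        A[g][1, NULL] = 1.0

    # t=3: attended modality maps the target identically (precision q);
    # unattended modality is uniform over its two stimulus levels
    q = params.attended_precision
    for r, attended in ((0, VIS), (1, AUD)):
        unattended = AUD if attended == VIS else VIS
        for tgt in range(2):
            A[attended][2, tgt, r, tgt, :] = q
            A[attended][2, 1 - tgt, r, tgt, :] = 1.0 - q
        A[unattended][2, 0, r, :, :] = 0.5
        A[unattended][2, 1, r, :, :] = 0.5
    A[CUE][2, NULL] = 1.0
    A[FB][2, NULL] = 1.0

    # t=4: feedback deterministic on choice == target; no-choice is incorrect
    for tgt in range(2):
        for ch in range(3):
            correct = ch == tgt + 1  # choice levels: no-choice, blue, green
            A[FB][3, 0 if correct else 1, :, tgt, ch] = 1.0
    A[CUE][3, NULL] = 1.0
    A[VIS][3, NULL] = 1.0
    A[AUD][3, NULL] = 1.0

    # transitions: identity for rule and target; choice controlled
    B = [np.eye(2)[None], np.eye(2)[None], np.zeros((3, 3, 3))]
    B[2][0] = np.eye(3)  # stay
    for u, picked in ((1, 1), (2, 2)):
        B[2][u, picked, 0] = 1.0        # no-choice -> picked
        B[2][u, 1, 1] = 1.0             # picked levels are absorbing
        B[2][u, 2, 2] = 1.0

    # log-preferences: only feedback at the final step is non-uniform
    C = [np.zeros((T, m.n)) for m in modalities]
    C[FB][3] = np.array([c, -c, 0.0])

    D = [np.full(2, 0.5), np.full(2, 0.5), np.array([1.0, 0.0, 0.0])]

    policies = build_policy_set(params.policy_mode, T)
    return GenerativeModel(
        factors=factors,
        modalities=modalities,
        A=A,
        B=B,
        C=C,
        D=D,
        policies=policies,
        T=T,
        controlled_factor=2,
    )


@dataclass
class ValidationReport:
    """Outcome of checking a model's structural invariants."""

    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def validate_model(model: GenerativeModel) -> ValidationReport:
    """Check every structural invariant of a generative model.

    Report-only: returns a list of human-readable failure descriptions with
    array coordinates; an empty list means the model is well formed.
    """
    rep = ValidationReport()
    dims = model.state_dims
    T = model.T

    for g, (m, Ag) in enumerate(zip(model.modalities, model.A)):
        want = (T, m.n) + dims
        if Ag.shape != want:
            rep.failures.append(f"A[{m.name}]: shape {Ag.shape}, expected {want}")
            continue
        if np.any(Ag < -STOCH_TOL) or np.any(Ag > 1 + STOCH_TOL):
            rep.failures.append(f"A[{m.name}]: entries outside [0, 1]")
        sums = Ag.sum(axis=1)
        bad = np.argwhere(np.abs(sums - 1.0) > STOCH_TOL)
        for idx in bad[:20]:
            t, *state = idx
            rep.failures.append(
                f"A[{m.name}]: outcome distribution at tau={t + 1}, "
                f"state={tuple(int(i) for i in state)} sums to {sums[tuple(idx)]:.6g}"
            )

    for n, (f, Bn) in enumerate(zip(model.factors, model.B)):
        if Bn.shape[1:] != (f.n, f.n):
            rep.failures.append(f"B[{f.name}]: non-square shape {Bn.shape}")
            continue
        if n != model.controlled_factor and Bn.shape[0] != 1:
            rep.failures.append(f"B[{f.name}]: uncontrolled factor has multiple actions")
        colsums = Bn.sum(axis=1)
        bad = np.argwhere(np.abs(colsums - 1.0) > STOCH_TOL)
        for u, j in bad[:20]:
            rep.failures.append(
                f"B[{f.name}]: column j={int(j)} under action {int(u)} "
                f"sums to {colsums[u, j]:.6g}"
            )

    fb = _feedback_index(model)
    for g, (m, Cg) in enumerate(zip(model.modalities, model.C)):
        if Cg.shape != (T, m.n):
            rep.failures.append(f"C[{m.name}]: shape {Cg.shape}, expected {(T, m.n)}")
            continue
        if not np.all(np.isfinite(Cg)):
            rep.failures.append(f"C[{m.name}]: non-finite entries")
        for t in range(T):
            must_be_uniform = g != fb or t != T - 1
            if must_be_uniform and np.ptp(Cg[t]) > STOCH_TOL:
                rep.failures.append(
                    f"C[{m.name}]: non-uniform preferences at tau={t + 1}"
                )

    for f, Dn in zip(model.factors, model.D):
        if Dn.shape != (f.n,):
            rep.failures.append(f"D[{f.name}]: shape {Dn.shape}, expected {(f.n,)}")
            continue
        if np.any(Dn < -STOCH_TOL):
            rep.failures.append(f"D[{f.name}]: negative entries")
        if abs(Dn.sum() - 1.0) > STOCH_TOL:
            rep.failures.append(f"D[{f.name}]: sums to {Dn.sum():.6g}")

    pols = model.policies
    if pols.size == 0:
        rep.failures.append("policies: empty policy set")
    else:
        if pols.shape[1] != T - 1:
            rep.failures.append(f"policies: length {pols.shape[1]}, expected {T - 1}")
        n_act = model.B[model.controlled_factor].shape[0]
        if np.any(pols < 0) or np.any(pols >= n_act):
            rep.failures.append("policies: action index out of range")
    return rep


def _feedback_index(model: GenerativeModel) -> int:
    try:
        return model.modality_index("feedback")
    except KeyError:
        return len(model.modalities) - 1


# --------------------------------------------------------------------------
# serialization


def model_to_json(model: GenerativeModel) -> str:
    """Serialize a model to a JSON document (row-major nested lists)."""
    doc = {
        "T": model.T,
        "controlled_factor": model.controlled_factor,
        "factors": [{"name": f.name, "levels": list(f.levels)} for f in model.factors],
        "modalities": [
            {"name": m.name, "levels": list(m.levels), "null_level": m.null_level}
            for m in model.modalities
        ],
        "A": [a.tolist() for a in model.A],
        "B": [b.tolist() for b in model.B],
        "C": [c.tolist() for c in model.C],
        "D": [d.tolist() for d in model.D],
        "policies": model.policies.tolist(),
    }
    return json.dumps(doc)


def model_from_json(text: str) -> GenerativeModel:
    """Inverse of :func:`model_to_json`; the round trip is lossless."""
    doc = json.loads(text)
    return GenerativeModel(
        factors=[FactorSpec(f["name"], tuple(f["levels"])) for f in doc["factors"]],
        modalities=[
            ModalitySpec(m["name"], tuple(m["levels"]), m["null_level"])
            for m in doc["modalities"]
        ],
        A=[np.asarray(a, dtype=float) for a in doc["A"]],
        B=[np.asarray(b, dtype=float) for b in doc["B"]],
        C=[np.asarray(c, dtype=float) for c in doc["C"]],
        D=[np.asarray(d, dtype=float) for d in doc["D"]],
        policies=np.asarray(doc["policies"], dtype=np.intp),
        T=int(doc["T"]),
        controlled_factor=int(doc["controlled_factor"]),
    )
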