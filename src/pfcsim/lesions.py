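"""In-silico prefrontal lesions: graded perturbations of the generative model.

A lesion is a convex mixture of the relevant probability arrays toward the
uniform distribution, giving a graded severity axis whose endpoint
(severity 1) reproduces the canonical manipulations:

* ``lateral`` -- flatten the rule-factor transitions, disconnecting the
  recurrent coupling that carries the rule through the delay (lateral
  prefrontal damage: delay-period activity collapses, chance performance).
* ``medial`` -- flatten the feedback likelihood, disconnecting interoceptive
  feedback from the choice (medial prefrontal damage: rule and target
  inference are spared but the policy posterior stays flat).
* ``extrinsic-rule-cue`` -- flatten the cue likelihood at the first step,
  rendering rule and cue conditionally independent (an extrinsic
  disconnection producing a lateral-like deficit).
* ``flat-preferences`` -- scale the feedback log-preferences toward zero (an
  alternative route to the medial phenotype).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import EngineSettings
from .environment import run_session
from .model import ConfigurationError, GenerativeModel

__all__ = ["LesionConfig", "LESION_KINDS", "apply_lesion", "lesion_battery"]

LESION_KINDS = ("none", "lateral", "medial", "extrinsic-rule-cue", "flat-preferences")


@dataclass(frozen=True)
class LesionConfig:
    """A named perturbation of the generative model."""

    kind: str = "none"
    severity: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ConfigurationError(
                f"lesion kind {self.kind!r} not in {LESION_KINDS}"
            )
        if not 0.0 <= self.severity <= 1.0:
            raise ConfigurationError("lesion severity must lie in [0, 1]")


def _mix_to_uniform(arr: np.ndarray, axis: int, severity: float) -> np.ndarray:
    """(1-severity)*arr + severity*uniform along the distribution axis."""
    uniform = np.full_like(arr, 1.0 / arr.shape[axis])
    return (1.0 - severity) * arr + severity * uniform


def apply_lesion(model: GenerativeModel, config: LesionConfig) -> GenerativeModel:
    """Return a lesioned deep copy of ``model``; stochasticity is preserved."""
    out = model.copy()
    sev = config.severity
    if config.kind == "none":
        return out
    if config.kind == "lateral":
        n = out.factor_index("rule")
        out.B[n] = _mix_to_uniform(out.B[n], axis=1, severity=sev)
    elif config.kind == "medial":
        g = out.modality_index("feedback")
        out.A[g] = _mix_to_uniform(out.A[g], axis=1, severity=sev)
    elif config.kind == "extrinsic-rule-cue":
        g = out.modality_index("cue")
        out.A[g][0] = _mix_to_uniform(out.A[g][0], axis=0, severity=sev)
    elif config.kind == "flat-preferences":
        g = out.modality_index("feedback")
        out.C[g] = (1.0 - sev) * out.C[g]
    return out


def _delay_rule_concentration(rec) -> float:
    """Max rule belief about the present during the delay epoch (t=2, tau=2)."""
    s = rec.epochs[1].s[0]  # rule factor: (n_policies, T, 2)
    bma = rec.epochs[1].posterior @ s[:, 1, :]
    return float(bma.max())


def _target_concentration(rec) -> float:
    """Max target belief about the present at the post-stimulus epoch (t=3)."""
    s = rec.epochs[2].s[1]
    bma = rec.epochs[2].posterior @ s[:, 2, :]
    return float(bma.max())


def lesion_battery(
    model: GenerativeModel,
    settings: EngineSettings | None = None,
    n_trials: int = 50,
    seed: int = 0,
    kinds: tuple[str, ...] = ("none", "lateral", "medial"),
    distractor: str = "incongruent",
) -> pd.DataFrame:
    """Run one session per lesion kind (severity 1) and compare summaries.

    Columns: accuracy, mean delay-period rule-belief concentration, mean
    target concentration after the stimuli, and mean policy-posterior
    entropy at the post-stimulus epoch.
    """
    if n_trials < 50:
        raise ValueError("lesion_battery: needs n_trials >= 50 per arm")
    settings = settings or EngineSettings()
    rows = []
    for kind in kinds:
        lesioned = apply_lesion(model, LesionConfig(kind=kind, severity=1.0))
        summary = run_session(
            lesioned,
            settings,
            n_trials=n_trials,
            seed=seed,
            distractor=distractor,
            keep_trials=True,
        )
        rows.append(
            {
                "lesion": kind,
                "n_trials": n_trials,
                "accuracy": summary.accuracy,
                "delay_rule_concentration": float(
                    np.mean([_delay_rule_concentration(r) for r in summary.trials])
                ),
                "target_concentration": float(
                    np.mean([_target_concentration(r) for r in summary.trials])
                ),
                "policy_entropy": summary.mean_policy_entropy,
            }
        )
    return pd.DataFrame(rows).set_index("lesion")
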