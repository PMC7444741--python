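"""Aggregate session summaries into a single report document."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .environment import SessionSummary

__all__ = ["Report", "summary_report"]


@dataclass
class Report:
    """Human-readable text plus the underlying machine-readable table."""

    text: str
    table: pd.DataFrame

    def to_json(self) -> str:
        return self.table.to_json(orient="records")


def summary_report(summaries: list[SessionSummary]) -> Report:
    """Aggregate one or more session summaries into a report.

    Rows are sessions (labelled by lesion kind and seed); columns carry
    accuracy, per-condition accuracy spread, and mean policy entropy.
    """
    if not summaries:
        raise ValueError("summary_report: needs at least one session summary")
    rows = []
    for s in summaries:
        acc = s.per_condition_accuracy.values()
        rows.append(
            {
                "lesion": s.lesion,
                "seed": s.seed,
                "n_trials": s.n_trials,
                "accuracy": s.accuracy,
                "min_condition_accuracy": min(acc) if acc else float("nan"),
                "max_condition_accuracy": max(acc) if acc else float("nan"),
                "mean_policy_entropy": s.mean_policy_entropy,
            }
        )
    table = pd.DataFrame(rows)
    lines = ["session report", "=" * 14]
    for row in rows:
        lines.append(
            f"lesion={row['lesion']} seed={row['seed']}: "
            f"accuracy {row['accuracy']:.3f} over {row['n_trials']} trials, "
            f"mean policy entropy {row['mean_policy_entropy']:.3f}"
        )
    return Report(text="\n".join(lines), table=table)
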