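"""Copeland social-choice ranking of models over multi-task benchmarks.

Each pair of models holds a contest: whoever beats the other on
strictly more tasks wins it (per-task direction aware — for error
metrics lower is better).  A model's Copeland score is its pairwise
wins minus losses; ranking by descending score picks the model that
dominates the most rivals and is dominated by the fewest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ContestOutcome(Enum):
    A_WINS = "a_wins"
    B_WINS = "b_wins"
    DRAW = "draw"


@dataclass
class ScoreMatrix:
    """Models x tasks performance values with per-task direction."""

    models: list[str]
    tasks: list[str]
    scores: np.ndarray
    higher_is_better: list[bool]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        M, T = len(self.models), len(self.tasks)
        if M < 2:
            raise ValueError("need at least 2 models to rank")
        if T < 1:
            raise ValueError("need at least 1 task")
        if len(set(self.models)) != M:
            raise ValueError("model names must be unique")
        if self.scores.shape != (M, T):
            raise ValueError(f"scores shape {self.scores.shape} != ({M}, {T})")
        if len(self.higher_is_better) != T:
            raise ValueError("higher_is_better must have one entry per task")
        if not np.isfinite(self.scores).all():
            bad = [
                f"({self.models[i]}, {self.tasks[j]})"
                for i, j in zip(*np.nonzero(~np.isfinite(self.scores)))
            ]
            raise ValueError(f"missing or non-finite cells: {', '.join(bad)}")

    @classmethod
    def from_csv(
        cls, path: str | Path, higher_is_better: Mapping[str, bool] | Sequence[bool]
    ) -> "ScoreMatrix":
        """Load a CSV whose first column is the model name and whose header
        row names the tasks; direction comes from a sidecar mapping."""
        df = pd.read_csv(path, index_col=0)
        tasks = [str(t) for t in df.columns]
        if isinstance(higher_is_better, Mapping):
            missing = [t for t in tasks if t not in higher_is_better]
            if missing:
                raise ValueError(f"no direction given for tasks: {missing}")
            directions = [bool(higher_is_better[t]) for t in tasks]
        else:
            directions = [bool(b) for b in higher_is_better]
        return cls(
            models=[str(m) for m in df.index],
            tasks=tasks,
            scores=df.to_numpy(dtype=float),
            higher_is_better=directions,
        )


def pairwise_contest(
    a_scores: Sequence[float],
    b_scores: Sequence[float],
    higher_is_better: Sequence[bool],
) -> ContestOutcome:
    """Majority contest over tasks: tied tasks count for neither side."""
    a = np.asarray(a_scores, dtype=float)
    b = np.asarray(b_scores, dtype=float)
    if a.shape != b.shape or len(higher_is_better) != a.shape[0]:
        raise ValueError("score vectors and direction vector must share one length")
    sign = np.where(np.asarray(higher_is_better, dtype=bool), 1.0, -1.0)
    diff = (a - b) * sign
    a_task_wins = int((diff > 0).sum())
    b_task_wins = int((diff < 0).sum())
    if a_task_wins > b_task_wins:
        return ContestOutcome.A_WINS
    if b_task_wins > a_task_wins:
        return ContestOutcome.B_WINS
    return ContestOutcome.DRAW


@dataclass
class CopelandResult:
    copeland_scores: dict[str, int]
    ranking: list[str]
    tie_groups: list[list[str]]
    variant: str
    tie_break: str = "mean task-rank, then lexicographic name"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "copeland_scores": self.copeland_scores,
            "ranking": self.ranking,
            "tie_groups": self.tie_groups,
            "variant": self.variant,
            "tie_break": self.tie_break,
        }

    def to_text(self) -> str:
        """Rank-table rendering (rank, model, Copeland score)."""
        lines = ["Rank  Copeland  Model", "----  --------  -----"]
        for pos, name in enumerate(self.ranking, start=1):
            lines.append(f"{pos:>4}  {self.copeland_scores[name]:>8}  {name}")
        return "\n".join(lines)


def _mean_task_ranks(matrix: ScoreMatrix) -> np.ndarray:
    """Average of per-task competition-free (average-tie) ranks, direction
    aware: rank 1 = best on that task.  Used only as a tie-break."""
    M, T = matrix.scores.shape
    ranks = np.empty((M, T))
    for j in range(T):
        col = matrix.scores[:, j]
        keyed = -col if matrix.higher_is_better[j] else col
        ranks[:, j] = stats.rankdata(keyed, method="average")
    return ranks.mean(axis=1)


def copeland_ranking(matrix: ScoreMatrix, variant: str = "wins_minus_losses") -> CopelandResult:
    """Copeland scores and a total-order ranking.

    ``variant='wins_minus_losses'`` (the classical rule, default) scores
    each model as pairwise wins minus losses with draws contributing 0;
    ``variant='wins_only'`` counts wins alone.  Ties on the Copeland
    score are broken by mean per-task rank, then model name, and the tie
    groups are reported explicitly.
    """
    if variant not in ("wins_minus_losses", "wins_only"):
        raise ValueError(f"unknown Copeland variant {variant!r}")
    M = len(matrix.models)
    wins = np.zeros(M, dtype=int)
    losses = np.zeros(M, dtype=int)
    for i in range(M):
        for j in range(i + 1, M):
            outcome = pairwise_contest(
                matrix.scores[i], matrix.scores[j], matrix.higher_is_better
            )
            if outcome is ContestOutcome.A_WINS:
                wins[i] += 1
                losses[j] += 1
            elif outcome is ContestOutcome.B_WINS:
                wins[j] += 1
                losses[i] += 1
    scores = wins - losses if variant == "wins_minus_losses" else wins

    mean_ranks = _mean_task_ranks(matrix)
    order = sorted(
        range(M), key=lambda i: (-scores[i], mean_ranks[i], matrix.models[i])
    )
    ranking = [matrix.models[i] for i in order]

    tie_groups: list[list[str]] = []
    by_score: dict[int, list[str]] = {}
    for i in order:
        by_score.setdefault(int(scores[i]), []).append(matrix.models[i])
    for s, group in by_score.items():
        if len(group) > 1:
            tie_groups.append(group)

    return CopelandResult(
        copeland_scores={matrix.models[i]: int(scores[i]) for i in range(M)},
        ranking=ranking,
        tie_groups=tie_groups,
        variant=variant,
    )
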