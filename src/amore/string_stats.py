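"""Surface-level perturbation statistics for augmented SMILES.

How much does each augmentation disturb the *string*, irrespective of
chemistry?  The central quantity is the Levenshtein ratio — edit
distance between original and augmented string divided by the original
length — summarized per augmentation kind, plus a Spearman utility for
correlating per-item quality scores with retrieval metrics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .augment import AugmentedPair


def levenshtein_distance(a: Sequence, b: Sequence) -> int:
    """Minimal number of insertions, deletions and substitutions turning
    ``a`` into ``b`` (unit costs), by dynamic programming.

    Accepts strings or any token sequences, so the same routine serves
    character-level and token-level analyses.
    """
    if len(a) < len(b):  # iterate over the longer side, vectorize the shorter
        a, b = b, a
    if not b:
        return len(a)
    if isinstance(a, str) and isinstance(b, str):
        b_arr = np.frombuffer(b.encode("utf-32-le"), dtype=np.uint32)
        a_sym: Iterable = (ord(c) for c in a)
    else:
        vocab = {tok: i for i, tok in enumerate(dict.fromkeys(list(a) + list(b)))}
        b_arr = np.array([vocab[t] for t in b], dtype=np.int64)
        a_sym = (vocab[t] for t in a)

    m = len(b)
    offsets = np.arange(1, m + 1)
    prev = np.arange(m + 1)
    for i, sym in enumerate(a_sym, start=1):
        cur = np.empty(m + 1, dtype=prev.dtype)
        cur[0] = i
        # deletion / substitution terms are row-parallel
        cur[1:] = np.minimum(prev[1:] + 1, prev[:-1] + (b_arr != sym))
        # insertion term chains along the row: cur[j] <= cur[j-1] + 1,
        # folded in via a running minimum of (value - position)
        shifted = np.minimum.accumulate(cur - np.arange(m + 1))
        np.minimum(cur, shifted + np.arange(m + 1), out=cur)
        prev = cur
    return int(prev[-1])


def levenshtein_ratio(pair: AugmentedPair) -> float:
    """Edit distance from original to augmented string, over the original
    length — the per-pair surface-perturbation measure."""
    original = pair.original.smiles
    if len(original) == 0:
        raise ValueError(f"record {pair.original.id} has an empty original SMILES")
    return levenshtein_distance(original, pair.augmented_smiles) / len(original)


def _mean_std(values: Sequence[float], ddof: int = 0) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=ddof))


@dataclass
class KindStats:
    kind: str
    n: int
    length_mean: float
    length_std: float
    ratio_mean: float
    ratio_std: float
    token_length_mean: float | None = None
    token_length_std: float | None = None
    token_ratio_mean: float | None = None
    token_ratio_std: float | None = None

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "n": self.n,
            "length_mean": self.length_mean,
            "length_std": self.length_std,
            "ratio_mean": self.ratio_mean,
            "ratio_std": self.ratio_std,
        }
        if self.token_length_mean is not None:
            d.update(
                token_length_mean=self.token_length_mean,
                token_length_std=self.token_length_std,
                token_ratio_mean=self.token_ratio_mean,
                token_ratio_std=self.token_ratio_std,
            )
        return d


@dataclass
class StringStatsReport:
    """Per-kind length and Levenshtein-ratio summaries.

    The ``no_augmentation`` row describes the original strings (ratio 0
    by definition).  Standard deviations are population (÷n) by default;
    pass ``ddof=1`` to the builder for the sample convention.
    """

    rows: dict[str, KindStats]
    ddof: int = 0
    tokenizer: str | None = None

    def to_dict(self) -> dict:
        return {
            "std_convention": "population" if self.ddof == 0 else "sample",
            "tokenizer": self.tokenizer,
            "rows": {k: v.to_dict() for k, v in self.rows.items()},
        }


def dataset_string_report(
    pairs_by_kind: Mapping[str, Sequence[AugmentedPair]],
    tokenizer: Callable[[str], Sequence] | None = None,
    ddof: int = 0,
) -> StringStatsReport:
    """Summarize string lengths and Levenshtein ratios per augmentation kind.

    Token-level columns are filled only when a tokenizer is supplied
    (the character-level analysis is the canonical path).
    """
    rows: dict[str, KindStats] = {}
    originals_seen: list[str] = []
    for kind, pairs in pairs_by_kind.items():
        if not pairs:
            raise ValueError(f"no pairs for kind {kind!r}")
        key = kind.value if hasattr(kind, "value") else str(kind)
        lengths = [len(p.augmented_smiles) for p in pairs]
        ratios = [levenshtein_ratio(p) for p in pairs]
        lm, ls = _mean_std(lengths, ddof)
        rm, rs = _mean_std(ratios, ddof)
        row = KindStats(key, len(pairs), lm, ls, rm, rs)
        if tokenizer is not None:
            toks_orig = [list(tokenizer(p.original.smiles)) for p in pairs]
            toks_aug = [list(tokenizer(p.augmented_smiles)) for p in pairs]
            tl, tls = _mean_std([len(t) for t in toks_aug], ddof)
            tr, trs = _mean_std(
                [
                    levenshtein_distance(o, a) / len(o)
                    for o, a in zip(toks_orig, toks_aug)
                ],
                ddof,
            )
            row.token_length_mean, row.token_length_std = tl, tls
            row.token_ratio_mean, row.token_ratio_std = tr, trs
        rows[key] = row
        originals_seen = [p.original.smiles for p in pairs]

    if originals_seen:
        lm, ls = _mean_std([len(s) for s in originals_seen], ddof)
        base = KindStats("no_augmentation", len(originals_seen), lm, ls, 0.0, 0.0)
        if tokenizer is not None:
            tl, tls = _mean_std([len(list(tokenizer(s))) for s in originals_seen], ddof)
            base.token_length_mean, base.token_length_std = tl, tls
            base.token_ratio_mean, base.token_ratio_std = 0.0, 0.0
        rows["no_augmentation"] = base

    return StringStatsReport(
        rows=rows,
        ddof=ddof,
        tokenizer=getattr(tokenizer, "__name__", None) if tokenizer else None,
    )


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str

    def to_dict(self) -> dict:
        return {"rho": self.rho, "p_value": self.p_value, "n": self.n, "method": self.method}


_EXACT_PERMUTATION_MAX_N = 10


def _rank_with_ties(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _pearson_on_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value is computed by full permutation enumeration
    for n <= 10 and by the large-sample t approximation otherwise; the
    method used is recorded in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"inputs must be equal-length vectors, got {x.shape}, {y.shape}")
    n = x.shape[0]
    if n < 3:
        raise ValueError("Spearman correlation requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant input vector")

    rx, ry = _rank_with_ties(x), _rank_with_ties(y)
    rho = _pearson_on_ranks(rx, ry)

    if n <= _EXACT_PERMUTATION_MAX_N:
        target = abs(rho) - 1e-12
        rxc = rx - rx.mean()
        sy = math.sqrt(((ry - ry.mean()) ** 2).sum())
        denom = math.sqrt((rxc @ rxc)) * sy
        hits = total = 0
        perms = itertools.permutations(ry)
        while True:  # chunked so n=10 (3.6M permutations) stays tractable
            chunk = np.array(list(itertools.islice(perms, 100_000)))
            if chunk.size == 0:
                break
            rhos = (chunk - ry.mean()) @ rxc / denom
            hits += int((np.abs(rhos) >= target).sum())
            total += chunk.shape[0]
        return CorrelationResult(rho, hits / total, n, "exact permutation")

    res = stats.spearmanr(x, y)
    return CorrelationResult(rho, float(res.pvalue), n, "large-sample approximation")
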