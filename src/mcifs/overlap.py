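"""Cross-method rank comparison and hypergeometric list-overlap enrichment.

Two ranked gene lists drawn from a universe of N features share x items; the
upper-tail hypergeometric probability of an overlap at least that large,

    p = sum_{j=x}^{min(a,b)} C(a, j) C(N-a, b-j) / C(N, b),

is the pairwise case of the exact multi-set intersection test.  Fold
enrichment is x / (a*b/N), the observed overlap over its expectation under
independent draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError
from .mcfs import FeatureRanking

__all__ = [
    "RankComparison",
    "IntersectionResult",
    "compare_ranks",
    "hypergeom_overlap",
    "upper_tail_probabilities",
]


@dataclass
class RankComparison:
    """Per-method ranks of the key features, in their source (MCFS) order."""

    table: pd.DataFrame  # columns: feature_id, <method ranks...>, best_method, best_rank

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def compare_ranks(
    key: list[str] | FeatureRanking,
    others: dict[str, FeatureRanking],
    k: int | None = None,
) -> RankComparison:
    """Look up the rank of each key feature in every other ranking.

    ``key`` is either an explicit feature list (already ordered) or a full
    ranking whose top ``k`` is taken.  All rankings must cover every key
    feature (they are total by construction).
    """
    if isinstance(key, FeatureRanking):
        features = key.top(k if k is not None else len(key))
    else:
        features = list(key)
    methods = sorted(others.keys())
    rows = []
    for f in features:
        ranks = {}
        for m in methods:
            try:
                ranks[m] = others[m].rank_of(f)
            except KeyError:
                raise ValidationError(f"feature {f!r} missing from ranking {m!r}") from None
        best_rank = min(ranks.values())
        best_method = min(m for m in methods if ranks[m] == best_rank)
        rows.append({"feature_id": f, **ranks, "best_method": best_method, "best_rank": best_rank})
    return RankComparison(pd.DataFrame(rows))


@dataclass(frozen=True)
class IntersectionResult:
    """Overlap of two lists of sizes a, b from a universe of N features."""

    universe: int
    a: int
    b: int
    overlap: int
    p: float
    fold: float


def upper_tail_probabilities(N: int, a: int, b: int) -> np.ndarray:
    """P(overlap >= x) for every x in 0..min(a,b), in log space.

    Entry x is the suffix log-sum-exp of the hypergeometric log-pmf from x
    upwards; entry 0 is exactly 1.
    """
    if not (0 <= a <= N and 0 <= b <= N):
        raise ValidationError(f"need 0 <= a,b <= N, got N={N}, a={a}, b={b}")
    m = min(a, b)
    js = np.arange(m + 1)
    with np.errstate(divide="ignore"):
        logpmf = hypergeom.logpmf(js, N, a, b)
    suffix = np.logaddexp.accumulate(logpmf[::-1])[::-1]
    p = np.exp(suffix)
    p[0] = 1.0
    return np.clip(p, 0.0, 1.0)


def hypergeom_overlap(N: int, a: int, b: int, x: int) -> IntersectionResult:
    """Upper-tail hypergeometric probability of an overlap >= x."""
    tail = upper_tail_probabilities(N, a, b)
    if not 0 <= x <= min(a, b):
        raise ValidationError(f"need 0 <= x <= min(a,b)={min(a, b)}, got x={x}")
    p = float(tail[x])
    expected = a * b / N if N > 0 else float("nan")
    fold = x / expected if expected > 0 else float("nan")
    return IntersectionResult(N, a, b, x, p, fold)
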