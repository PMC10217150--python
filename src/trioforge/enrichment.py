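"""Gene-set enrichment: hypergeometric/binomial tails, BH adjustment,
rank-deviation z-scores and the combined ranking score.

The combined score follows the published combination ``c = z * ln(p)``:
``p`` is the term's upper-tail overlap p-value and ``z`` the standardized
deviation of the term's observed rank from its expected rank under
repeated random queries of the same size (negative z = better than
expected), so for an enriched term the score is positive and larger is
stronger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id} has no members")


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P[X >= k] for drawing n genes from a universe of N with
    K marked; exact via the survival function, stable in log space.

    k = overlap, K = term size, n = query size, N = universe size.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def binomial_p(k: int, n: int, q: float) -> float:
    """Upper-tail P[X >= k] under Binomial(n, q) (q = K/N approximation)."""
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k} n={n}")
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, q))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment; input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def combined_score(p_value: float, z_score: float) -> float:
    """The enrichment ranking score ``c = z * ln(p)``.

    For a better-than-expected rank (z <= 0) and p < 1 the score is
    non-negative; p = 1 gives 0 regardless of z.
    """
    if not (0.0 < p_value <= 1.0):
        raise ValueError(f"p_value must lie in (0, 1], got {p_value}")
    return z_score * math.log(p_value)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT library: term, description, then member genes (tabs)."""
    sets: list[GeneSet] = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line needs term, description and >= 1 gene: {line[:80]!r}")
        term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if term in seen:
            raise ValueError(f"duplicate term id in GMT: {term}")
        seen.add(term)
        sets.append(GeneSet(term_id=term, term_name=desc or term, members=frozenset(genes)))
    return sets


def _rank_terms(pvals: np.ndarray) -> np.ndarray:
    """Ranks (1 = smallest p), average ranks for ties."""
    return stats.rankdata(pvals, method="average")


def enrich(
    query: Iterable[str],
    library: Sequence[GeneSet],
    universe: Optional[Iterable[str]] = None,
    n_background_queries: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query gene list against a library.

    Per term: upper-tail hypergeometric p for the query/term overlap, BH
    adjustment across the library, a z-score from the deviation of the
    term's observed p-rank from its rank distribution under
    ``n_background_queries`` random same-size queries, and the combined
    score ``z * ln(p)``. Sorted by ascending p, ties by term id.
    """
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query gene list")
    if not library:
        raise ValueError("empty gene-set library")
    if universe is None:
        uni = set().union(*(gs.members for gs in library)) | query_set
    else:
        uni = set(universe)
        stray = query_set - uni
        if stray:
            raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    N = len(uni)
    n = len(query_set & uni)
    members = [gs.members & uni for gs in library]

    pvals = np.array([
        hypergeometric_p(len(query_set & m), len(m), n, N) if m else 1.0
        for m in members
    ])
    obs_rank = _rank_terms(pvals)

    rng = np.random.default_rng(seed)
    uni_list = sorted(uni)
    bg_ranks = np.empty((n_background_queries, len(library)))
    for b in range(n_background_queries):
        bg = set(rng.choice(uni_list, size=n, replace=False))
        bg_p = np.array([
            hypergeometric_p(len(bg & m), len(m), n, N) if m else 1.0
            for m in members
        ])
        bg_ranks[b] = _rank_terms(bg_p)
    mu = bg_ranks.mean(axis=0)
    sd = bg_ranks.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    z = (obs_rank - mu) / sd

    padj = bh_adjust(list(pvals))
    rows = pd.DataFrame({
        "term_id": [gs.term_id for gs in library],
        "term_name": [gs.term_name for gs in library],
        "overlap": [len(query_set & m) for m in members],
        "set_size": [len(m) for m in members],
        "p_value": pvals,
        "p_adjusted": padj,
        "z_score": z,
        "combined_score": [combined_score(p, zi) if p > 0 else float("inf")
                           for p, zi in zip(pvals, z)],
    })
    return rows.sort_values(["p_value", "term_id"]).reset_index(drop=True)
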