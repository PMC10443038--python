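"""Levenshtein-distance diversity selection.

To turn a combinatorially enumerated domain set into a panel of discrete
points in sequence space, the most mutually different fraction (typically
1%) is retained.  Two documented selection methods are offered:

``greedy_maximin``
    Maximin subset selection.  Small instances (at most ``EXACT_SEARCH_LIMIT``
    candidate subsets) are solved exactly by enumeration; larger ones use
    farthest-point greedy — start from a seeded pick, then repeatedly add
    the candidate whose minimum Levenshtein distance to the already-selected
    set is largest (ties broken lexicographically).  The greedy objective is
    guaranteed to be at least half the exact optimum.

``mean_distance_rank``
    Rank candidates by mean pairwise distance to the whole input (estimated
    on a seeded subsample for very large inputs) and keep the top fraction.

Distances are unit-cost edit distances computed with edlib.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import edlib
import numpy as np

Method = Literal["greedy_maximin", "mean_distance_rank"]

#: Maximum number of candidate subsets for exact maximin search.
EXACT_SEARCH_LIMIT = 20_000


def levenshtein(a: str, b: str) -> int:
    """Standard unit-cost edit distance (insert/delete/substitute)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass(frozen=True)
class DiversitySelection:
    """Result of a diversity down-selection."""

    selected: tuple[str, ...]
    method: Method
    fraction: float
    seed: int

    def __len__(self) -> int:
        return len(self.selected)


def _exact_maximin(domains: Sequence[str], k: int) -> list[str]:
    """Brute-force maximin subset: maximise the minimum pairwise distance.

    Feasible only for small instances; ties resolved to the lexicographically
    smallest sorted subset, so the result is deterministic and seed-free.
    """
    pool = sorted(domains)
    dist = {
        (a, b): levenshtein(a, b) for i, a in enumerate(pool) for b in pool[i + 1 :]
    }
    best_obj, best_subset = -1, None
    for subset in itertools.combinations(pool, k):
        obj = min(dist[pair] for pair in itertools.combinations(subset, 2))
        if obj > best_obj:
            best_obj, best_subset = obj, subset
    return list(best_subset)


def _greedy_maximin(domains: Sequence[str], k: int, rng: np.random.Generator) -> list[str]:
    pool = list(domains)
    first = int(rng.integers(0, len(pool)))
    selected = [pool.pop(first)]
    # min distance of every remaining candidate to the selected set
    min_dist = np.array([levenshtein(selected[0], d) for d in pool])
    while len(selected) < k:
        best = np.max(min_dist)
        tied = [i for i in np.flatnonzero(min_dist == best)]
        pick = min(tied, key=lambda i: pool[i])  # lexicographic tie-break
        chosen = pool[pick]
        selected.append(chosen)
        pool.pop(pick)
        min_dist = np.delete(min_dist, pick)
        if pool:
            new = np.array([levenshtein(chosen, d) for d in pool])
            min_dist = np.minimum(min_dist, new)
    return selected


def _mean_distance_rank(
    domains: Sequence[str], k: int, rng: np.random.Generator, subsample: int | None
) -> list[str]:
    if subsample is not None and subsample < len(domains):
        ref_idx = rng.choice(len(domains), size=subsample, replace=False)
        reference = [domains[i] for i in sorted(ref_idx)]
    else:
        reference = list(domains)
    means = [
        (-(sum(levenshtein(d, r) for r in reference) / len(reference)), d) for d in domains
    ]
    means.sort()  # most-distant first, lexicographic on ties
    return [d for _, d in means[:k]]


def select_most_different(
    domains: Sequence[str],
    fraction: float,
    method: Method = "greedy_maximin",
    seed: int = 0,
    subsample: int | None = None,
) -> DiversitySelection:
    """Keep the ``floor(fraction * len(domains))`` most mutually different strings.

    Parameters
    ----------
    domains : candidate strings (e.g. one enumerated domain region).
    fraction : fraction to retain, in (0, 1]; 0.01 reproduces the published
        24 / 3542 / 14 per-region panel sizes.
    method : selection algorithm (see module docstring).
    seed : seeds the first greedy pick / the mean-distance subsample.
    subsample : optional reference subsample size for ``mean_distance_rank``.
    """
    if not domains:
        raise ValueError("empty domain list")
    if not 0 < fraction <= 1:
        raise ValueError(f"invalid fraction {fraction}")
    k = math.floor(fraction * len(domains))
    if k == 0:
        raise ValueError("fraction retains zero domains")
    rng = np.random.default_rng(seed)
    if method == "greedy_maximin":
        if k >= 2 and math.comb(len(domains), k) <= EXACT_SEARCH_LIMIT:
            # small instances are solved exactly; greedy is the scalable fallback
            selected = _exact_maximin(domains, k)
        else:
            selected = _greedy_maximin(domains, k, rng)
    elif method == "mean_distance_rank":
        selected = _mean_distance_rank(domains, k, rng, subsample)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DiversitySelection(tuple(selected), method, fraction, seed)


def retained_count(n_domains: int, fraction: float = 0.01) -> int:
    """Selection size for a domain set of *n_domains* (floor of the retained fraction)."""
    if not 0 < fraction <= 1:
        raise ValueError(f"invalid fraction {fraction}")
    return math.floor(fraction * n_domains)
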