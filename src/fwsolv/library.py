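"""Combinatorial virtual-library enumeration and Free-Wilson scoring.

From the per-site substituent pools observed in a training series, the full
combinatorial library has prod(|pool_s|) members; subtracting the observed
combinations gives the count of *unexplored* derivatives.  Counting is pure
arithmetic (O(1) memory); enumeration is a lazy generator that never
materializes the library, so paper-scale spaces (tens of millions of
combinations) stream safely.

Each candidate's predicted pIC50 is the model intercept plus the per-site
coefficients of its substituents; candidates below a potency threshold are
filtered out on the fly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import prod
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from fwsolv.freewilson import FWModel
from fwsolv.rgroups import CoreScaffold, RGroupAssignment, attach_groups

logger = logging.getLogger(__name__)

__all__ = [
    "SubstituentPools",
    "EnumeratedCandidate",
    "EnumerationStats",
    "pools_from_assignments",
    "observed_combinations",
    "count_library",
    "enumerate_and_score",
    "candidates_to_dataframe",
]


@dataclass(frozen=True)
class SubstituentPools:
    """Ordered, unique per-site substituent lists observed in training."""

    pools: Mapping[int, tuple[str, ...]]

    def __post_init__(self) -> None:
        for site, pool in self.pools.items():
            if not pool:
                raise ValueError(f"empty substituent pool at site R{site}")
            if len(set(pool)) != len(pool):
                raise ValueError(f"duplicate substituents in pool at site R{site}")

    @property
    def sites(self) -> tuple[int, ...]:
        return tuple(sorted(self.pools))

    def sizes(self) -> dict[int, int]:
        return {s: len(self.pools[s]) for s in self.sites}

    def total_combinations(self) -> int:
        return prod(len(self.pools[s]) for s in self.sites)


@dataclass(frozen=True)
class EnumeratedCandidate:
    """One unexplored combination with its assembled structure and prediction."""

    groups: Mapping[int, str]
    assembled_smiles: str | None
    predicted_pic50: float


@dataclass
class EnumerationStats:
    """Tallies accumulated while streaming (invalid assemblies, yields, ...)."""

    n_examined: int = 0
    n_observed_skipped: int = 0
    n_invalid_chemistry: int = 0
    n_below_threshold: int = 0
    n_yielded: int = 0


def pools_from_assignments(
    assignments: Iterable[RGroupAssignment],
) -> SubstituentPools:
    """Per-site pools of unique substituents, in first-seen order."""
    pools: dict[int, list[str]] = {}
    for a in assignments:
        if not a.matched:
            continue
        for site, sub in a.groups.items():
            pool = pools.setdefault(site, [])
            if sub not in pool:
                pool.append(sub)
    if not pools:
        raise ValueError("no matched assignments; pools would be empty")
    return SubstituentPools({s: tuple(p) for s, p in pools.items()})


def observed_combinations(
    assignments: Iterable[RGroupAssignment],
) -> set[tuple[str, ...]]:
    """The set of (site-ordered) substituent tuples present in training."""
    out = set()
    for a in assignments:
        if a.matched:
            out.add(tuple(a.groups[s] for s in sorted(a.groups)))
    return out


def count_library(
    pools: SubstituentPools,
    observed: set[tuple[str, ...]] | Sequence[tuple[str, ...]] = (),
    include_observed: bool = False,
) -> int:
    """Number of (unexplored) combinations, without materializing anything.

    ``prod(|pool_s|)`` minus the observed combinations (unless
    ``include_observed``).  Observed tuples must be drawn from the pools.
    """
    total = pools.total_combinations()
    if include_observed:
        return total
    observed = set(observed)
    for combo in observed:
        for site, sub in zip(pools.sites, combo):
            if sub not in pools.pools[site]:
                raise ValueError(
                    f"observed combination uses {sub!r} at R{site}, absent from the pool"
                )
    return total - len(observed)


def enumerate_and_score(
    pools: SubstituentPools,
    model: FWModel,
    min_pic50: float = float("-inf"),
    limit: int | None = None,
    observed: set[tuple[str, ...]] | Sequence[tuple[str, ...]] = (),
    scaffold: CoreScaffold | None = None,
    seed: int | None = None,
    stats: EnumerationStats | None = None,
) -> Iterator[EnumeratedCandidate]:
    """Lazily yield unexplored combinations predicted at or above ``min_pic50``.

    Enumeration order is lexicographic over pool indices (deterministic);
    with ``seed`` given, combinations are instead drawn uniformly at random
    without replacement — useful for exporting a random high-scoring subset
    of a space too large to exhaust.  When a ``scaffold`` is supplied, each
    combination is assembled into a full molecule; combinations producing
    invalid chemistry are skipped and tallied in ``stats``, never yielded.
    An empty stream (threshold above everything) is not an error.
    """
    observed = set(observed)
    stats = stats if stats is not None else EnumerationStats()
    sites = pools.sites
    # per-site coefficient lookup; unseen pairs cannot occur since pools come
    # from the training assignments, but guard anyway
    coef = {}
    for site in sites:
        for sub in pools.pools[site]:
            if (site, sub) not in model.coefficients:
                raise ValueError(
                    f"model has no coefficient for {sub!r} at R{site}; "
                    "pools must come from the training series"
                )
            coef[(site, sub)] = model.coefficients[(site, sub)]

    if seed is None:
        index_iter: Iterator[tuple[int, ...]] = itertools.product(
            *(range(len(pools.pools[s])) for s in sites)
        )
    else:
        index_iter = _random_index_stream(pools, seed)

    n_yielded = 0
    for idx in index_iter:
        stats.n_examined += 1
        combo = tuple(pools.pools[s][i] for s, i in zip(sites, idx))
        if combo in observed:
            stats.n_observed_skipped += 1
            continue
        pred = model.intercept + sum(coef[(s, g)] for s, g in zip(sites, combo))
        if pred < min_pic50:
            stats.n_below_threshold += 1
            continue
        groups = dict(zip(sites, combo))
        smiles = None
        if scaffold is not None:
            smiles = attach_groups(scaffold, groups)
            if smiles is None:
                stats.n_invalid_chemistry += 1
                logger.debug("invalid assembly for %r", groups)
                continue
        stats.n_yielded += 1
        yield EnumeratedCandidate(
            groups=groups, assembled_smiles=smiles, predicted_pic50=pred
        )
        n_yielded += 1
        if limit is not None and n_yielded >= limit:
            return


def _random_index_stream(
    pools: SubstituentPools, seed: int
) -> Iterator[tuple[int, ...]]:
    """Uniform draws without replacement over the index space (seeded).

    For small spaces a shuffled exhaustive list; for large ones, rejection
    sampling with a seen-set (callers cap with ``limit``, so memory stays
    bounded by the number of draws, not the space).
    """
    rng = np.random.default_rng(seed)
    sizes = [len(pools.pools[s]) for s in pools.sites]
    total = prod(sizes)
    if total <= 100_000:
        order = rng.permutation(total)
        for flat in order:
            yield tuple(np.unravel_index(int(flat), sizes))
    else:
        seen: set[int] = set()
        while len(seen) < total:
            flat = int(rng.integers(total))
            if flat in seen:
                continue
            seen.add(flat)
            yield tuple(np.unravel_index(flat, sizes))


def candidates_to_dataframe(
    candidates: Iterable[EnumeratedCandidate], site_labels: Mapping[int, str] | None = None
) -> pd.DataFrame:
    """Tabulate candidates: id, per-site substituents, assembled SMILES, prediction."""
    rows = []
    for i, cand in enumerate(candidates):
        row: dict = {"candidate_id": f"VL{i + 1:06d}"}
        for site in sorted(cand.groups):
            label = site_labels.get(site, f"R{site}") if site_labels else f"R{site}"
            row[label] = cand.groups[site]
        row["assembled_smiles"] = cand.assembled_smiles
        row["predicted_pic50"] = cand.predicted_pic50
        rows.append(row)
    return pd.DataFrame(rows)
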