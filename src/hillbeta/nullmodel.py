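"""Generalized Raup-Crick null model over the Hill dissimilarity continuum.

The null model asks whether the observed dissimilarity between two samples
could be explained by random assembly from a regional taxon pool. For each
randomization, null counterparts of *both* samples are assembled
independently, each preserving its template's observed richness (number of
detected taxa) and read depth:

1. taxa are drawn without replacement from the pool, with selection
   probability proportional to either the number of pool samples in which
   the taxon occurs (``scheme="frequency"``, the default) or its summed
   read count over the pool (``scheme="abundance"``);
2. every selected taxon is seeded with one read, and the remaining
   ``depth - richness`` reads are distributed multinomially over the
   selected taxa with probabilities proportional to their pool-wide read
   totals (renormalized over the selected taxa).

The dissimilarity between the two null assemblies is computed with the same
index and diversity order as the observed pair, giving a null distribution.
The Raup-Crick index of order q is the fraction of randomizations at least
as similar as observed, counting ties as half:

    qRC = (n_less + 0.5 * n_equal) / N_TOT

qRC near 0 means the pair is more similar than random assembly predicts
(homogenizing processes); near 1, more dissimilar (divergent selection);
near 0.5, indistinguishable from random assembly. An optional rescaling
maps qRC onto [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import hill
from .hill import pair_dissimilarity, resolve_index
from .io_tables import CountTable, ValidationError

logger = logging.getLogger(__name__)

#: |qd_exp - qd_obs| at or below this counts as a tie in the qRC numerator.
#: At q=0 dissimilarities take few discrete values, so ties are real and
#: frequent; a strict float equality would undercount them.
TIE_TOL = 1e-10

#: default number of randomizations.
DEFAULT_ITERATIONS = 199

SCHEMES = ("frequency", "abundance")


@dataclass
class RegionalPool:
    """Taxon pool from which null samples are assembled.

    ``frequency`` is the number of pool samples in which each taxon occurs;
    ``total_reads`` is its summed read count over the pool. Taxa absent
    from every pool sample are excluded.
    """

    taxon_ids: list[str]
    frequency: np.ndarray
    total_reads: np.ndarray
    pool_sample_ids: list[str]

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=np.int64)
        self.total_reads = np.asarray(self.total_reads, dtype=np.int64)
        n = len(self.taxon_ids)
        if self.frequency.shape != (n,) or self.total_reads.shape != (n,):
            raise ValidationError("pool arrays do not match taxon list")
        if n == 0:
            raise ValidationError("regional pool is empty")
        m = len(self.pool_sample_ids)
        if (self.frequency < 1).any() or (self.frequency > m).any():
            raise ValidationError("occurrence frequencies outside [1, n_pool_samples]")
        if (self.total_reads < self.frequency).any():
            raise ValidationError("pool read totals below occurrence frequencies")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)


@dataclass
class NullModelResult:
    """Observed dissimilarity, null distribution, and qRC for one pair."""

    pair: tuple[str, str]
    q: float
    index_name: str
    observed: float
    null_values: np.ndarray
    rc: float
    n_less: int
    n_equal: int
    iterations: int
    seed: int | None = None


@dataclass
class RaupCrickProfile:
    """Per-q mean/sd of qRC over a set of sample pairs."""

    q_grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    pair_count: int
    #: per-pair qRC values, shape (pair_count, len(q_grid))
    rc_values: np.ndarray
    pairs: list[tuple[str, str]]
    index_name: str
    iterations: int
    seed: int | None = None


def build_pool(
    table: CountTable, pool_sample_ids: Sequence[str] | None = None
) -> RegionalPool:
    """Tally occurrence frequencies and read totals over the pool samples.

    By default the pool is every sample in the table; pass
    ``pool_sample_ids`` to restrict it (e.g. to one reactor or habitat).
    """
    ids = list(pool_sample_ids) if pool_sample_ids is not None else table.sample_ids
    if not ids:
        raise ValidationError("regional pool has no samples")
    missing = [s for s in ids if s not in set(table.sample_ids)]
    if missing:
        raise ValidationError(f"pool references unknown sample(s): {missing}")
    sub = table.counts[ids]
    depths = sub.sum(axis=0)
    empty = depths[depths == 0]
    if len(empty):
        raise ValidationError(f"pool sample {empty.index[0]!r} has zero reads")
    totals = sub.sum(axis=1).to_numpy()
    keep = totals > 0
    return RegionalPool(
        taxon_ids=[t for t, k in zip(table.taxon_ids, keep) if k],
        frequency=(sub.to_numpy() > 0).sum(axis=1)[keep],
        total_reads=totals[keep],
        pool_sample_ids=ids,
    )


def _selection_weights(pool: RegionalPool, scheme: str) -> np.ndarray:
    if scheme == "frequency":
        w = pool.frequency.astype(float)
    elif scheme == "abundance":
        w = pool.total_reads.astype(float)
    else:
        raise ValidationError(f"unknown randomization scheme {scheme!r}; use {SCHEMES}")
    return w / w.sum()


def _randomize_indices(
    pool: RegionalPool,
    richness: int,
    depth: int,
    scheme: str,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble one null sample; returns (pool indices, read counts)."""
    if richness < 1:
        raise ValidationError("target richness must be >= 1")
    if richness > pool.n_taxa:
        raise ValidationError(
            f"target richness {richness} exceeds pool size {pool.n_taxa}"
        )
    if depth < richness:
        raise ValidationError(
            f"depth {depth} is below richness {richness}; every selected taxon "
            "needs at least one read"
        )
    p = _selection_weights(pool, scheme) if weights is None else weights
    idx = rng.choice(pool.n_taxa, size=richness, replace=False, p=p)
    reads = np.ones(richness, dtype=np.int64)
    extra = depth - richness
    if extra > 0:
        pr = pool.total_reads[idx].astype(float)
        reads += rng.multinomial(extra, pr / pr.sum())
    return idx, reads


def randomize_sample(
    pool: RegionalPool,
    richness: int,
    depth: int,
    scheme: str = "frequency",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> dict[str, int]:
    """Assemble one null sample with the given richness and read depth."""
    rng = _resolve_rng(rng, seed)
    idx, reads = _randomize_indices(pool, richness, depth, scheme, rng)
    return {pool.taxon_ids[i]: int(r) for i, r in zip(idx, reads)}


def _resolve_rng(
    rng: np.random.Generator | None, seed: int | None
) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def raup_crick_multi(
    table: CountTable,
    pair: tuple[str, str],
    q_values: Sequence[float],
    index_name: str = hill.LOCAL,
    pool_sample_ids: Sequence[str] | None = None,
    iterations: int = DEFAULT_ITERATIONS,
    scheme: str = "frequency",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[NullModelResult]:
    """qRC for one sample pair at several diversity orders.

    One shared set of null assemblies is generated per iteration and reused
    across the whole q list; because the assembly draws do not depend on q,
    this is identical to recomputing each order separately with the same
    seed. Results are deterministic given a seed.
    """
    index = resolve_index(index_name)
    if iterations < 1:
        raise ValidationError("need at least one randomization")
    qv = [float(q) for q in q_values]
    if not qv:
        raise ValidationError("empty diversity-order list")
    for q in qv:
        if q < 0:
            raise ValidationError(f"diversity order must be >= 0, got {q}")
    s1, s2 = pair
    c1, c2 = table.column(s1), table.column(s2)
    d1, d2 = int(c1.sum()), int(c2.sum())
    if d1 == 0 or d2 == 0:
        raise ValidationError(f"pair ({s1!r}, {s2!r}) contains a zero-read sample")
    r1, r2 = int((c1 > 0).sum()), int((c2 > 0).sum())

    observed = [pair_dissimilarity(c1 / d1, c2 / d2, index, q) for q in qv]

    pool = build_pool(table, pool_sample_ids)
    weights = _selection_weights(pool, scheme)
    rng = _resolve_rng(rng, seed)

    T = pool.n_taxa
    null = np.empty((iterations, len(qv)))
    for it in range(iterations):
        i1, n1 = _randomize_indices(pool, r1, d1, scheme, rng, weights)
        i2, n2 = _randomize_indices(pool, r2, d2, scheme, rng, weights)
        v1 = np.zeros(T)
        v1[i1] = n1 / d1
        v2 = np.zeros(T)
        v2[i2] = n2 / d2
        for k, q in enumerate(qv):
            null[it, k] = pair_dissimilarity(v1, v2, index, q)

    results = []
    for k, q in enumerate(qv):
        diffs = null[:, k] - observed[k]
        n_equal = int(np.sum(np.abs(diffs) <= TIE_TOL))
        n_less = int(np.sum(diffs < -TIE_TOL))
        rc = (n_less + 0.5 * n_equal) / iterations
        results.append(
            NullModelResult(
                pair=(s1, s2),
                q=q,
                index_name=index,
                observed=observed[k],
                null_values=null[:, k].copy(),
                rc=rc,
                n_less=n_less,
                n_equal=n_equal,
                iterations=iterations,
                seed=seed,
            )
        )
    return results


def raup_crick(
    table: CountTable,
    pair: tuple[str, str],
    q: float,
    index_name: str = hill.LOCAL,
    pool_sample_ids: Sequence[str] | None = None,
    iterations: int = DEFAULT_ITERATIONS,
    scheme: str = "frequency",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> NullModelResult:
    """qRC for one sample pair at a single diversity order."""
    return raup_crick_multi(
        table, pair, [q], index_name, pool_sample_ids, iterations, scheme, rng, seed
    )[0]


def rescale_rc(rc: float) -> float:
    """Map a qRC value from [0, 1] onto [-1, 1] via 2 * (rc - 0.5)."""
    if not 0.0 <= rc <= 1.0:
        raise ValidationError(f"qRC must be in [0, 1], got {rc}")
    return 2.0 * (rc - 0.5)


def rc_profile(
    table: CountTable,
    pairs: Sequence[tuple[str, str]],
    q_grid: Sequence[float] | None = None,
    index_name: str = hill.LOCAL,
    pool_sample_ids: Sequence[str] | None = None,
    iterations: int = DEFAULT_ITERATIONS,
    scheme: str = "frequency",
    seed: int | None = None,
) -> RaupCrickProfile:
    """Per-q mean/sd of qRC over a set of pairs.

    Each pair gets an independent random stream spawned from ``seed``, so
    results for one pair do not change when other pairs are added or
    removed.
    """
    if not pairs:
        raise ValidationError("empty pair list")
    grid = hill.DEFAULT_Q_GRID if q_grid is None else np.asarray(list(q_grid), float)
    if grid.size == 0:
        raise ValidationError("empty diversity-order grid")
    streams = np.random.SeedSequence(seed).spawn(len(pairs))
    rc_values = np.empty((len(pairs), grid.size))
    for r, (pair, stream) in enumerate(zip(pairs, streams)):
        results = raup_crick_multi(
            table,
            pair,
            list(grid),
            index_name,
            pool_sample_ids,
            iterations,
            scheme,
            rng=np.random.default_rng(stream),
        )
        rc_values[r] = [res.rc for res in results]
    return RaupCrickProfile(
        q_grid=grid,
        mean=rc_values.mean(axis=0),
        sd=rc_values.std(axis=0),
        pair_count=len(pairs),
        rc_values=rc_values,
        pairs=[tuple(p) for p in pairs],
        index_name=resolve_index(index_name),
        iterations=iterations,
        seed=seed,
    )
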