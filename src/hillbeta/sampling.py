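"""Rarefaction and sequencing-depth simulation.

Rarefaction subsamples each sample's reads *without replacement* to a
common depth, which puts all samples on an equal sampling-effort footing
before incidence-sensitive indices are computed. It is a single draw with
a stored seed, not an average over draws.

The depth simulation emulates the effect of sequencing depth on replicate
dissimilarity: replicate samples are drawn *with replacement*
(multinomially) from a fixed true relative-abundance distribution, so any
dissimilarity between replicates is pure sampling noise — the true
dissimilarity is zero. Comparing the mean replicate dissimilarity across a
ladder of depths shows how undersampling inflates incidence-based (low-q)
dissimilarity long after abundance-based (high-q) dissimilarity has
converged.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import hill
from .fixtures import make_replicate_tables
from .hill import DissimilarityProfile, dissimilarity_profile
from .io_tables import CountTable, RelativeAbundance, ValidationError

logger = logging.getLogger(__name__)

#: default ladder of sequencing depths for the simulation.
DEFAULT_DEPTHS = (10_000, 30_000, 100_000, 300_000, 1_000_000)


@dataclass
class DepthSimulationResult:
    """Replicate dissimilarity and taxon detection along a depth ladder."""

    depths: list[int]
    replicates: int
    #: per-depth array of detected-taxon counts, one entry per replicate
    detected: dict[int, np.ndarray]
    #: per-depth dissimilarity profile over all replicate pairs
    profiles: dict[int, DissimilarityProfile]
    seed: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for depth in self.depths:
            prof = self.profiles[depth]
            det = self.detected[depth]
            for q, m, s in zip(prof.q_grid, prof.mean, prof.sd):
                rows.append(
                    {
                        "depth": depth,
                        "q": q,
                        "mean": m,
                        "sd": s,
                        "n_pairs": prof.pair_count,
                        "mean_detected": det.mean(),
                        "sd_detected": det.std(),
                    }
                )
        return pd.DataFrame(rows)


def rarefy(
    table: CountTable,
    depth: int | str = "min",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> CountTable:
    """Rarefy every sample to a common depth without replacement.

    ``depth="min"`` resolves to the smallest sample depth. Each column is a
    multivariate-hypergeometric draw from its own reads, so no cell ever
    exceeds its original count and every column sums exactly to ``depth``.
    Taxa reduced to zero everywhere are pruned (and recorded on the result).
    """
    depths = table.depths
    if isinstance(depth, str):
        if depth != "min":
            raise ValidationError(f"depth must be an integer or 'min', got {depth!r}")
        target = int(depths.min())
    else:
        target = int(depth)
    if target < 1:
        raise ValidationError(f"rarefaction depth must be >= 1, got {target}")
    shallow = depths[depths < target]
    if len(shallow):
        raise ValidationError(
            f"sample {shallow.index[0]!r} has only {int(shallow.iloc[0])} reads, "
            f"below the rarefaction depth {target}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    new_cols = {}
    for s in table.sample_ids:
        col = table.column(s)
        if col.sum() == target:
            new_cols[s] = col.copy()
        else:
            new_cols[s] = rng.multivariate_hypergeometric(col, target)
    counts = pd.DataFrame(new_cols, index=table.taxon_ids)
    return CountTable(counts, sequences=table.sequences)


def simulate_depth(
    truth: RelativeAbundance,
    depths: Sequence[int] = DEFAULT_DEPTHS,
    replicates: int = 6,
    q_grid: Sequence[float] = (0.0, 1.0, 2.0),
    index_name: str = hill.LOCAL,
    seed: int | None = None,
) -> DepthSimulationResult:
    """Replicate-dissimilarity simulation across sequencing depths.

    For each depth, ``replicates`` samples are drawn multinomially from
    ``truth``; the per-depth output is the number of detected taxa per
    replicate and the dissimilarity profile over all replicate pairs.
    Each depth gets an independent stream spawned from ``seed``.
    """
    depths = [int(d) for d in depths]
    if not depths or min(depths) < 1:
        raise ValidationError("depths must be positive integers")
    if replicates < 2:
        raise ValidationError("need at least 2 replicates per depth")
    streams = np.random.SeedSequence(seed).spawn(len(depths))
    detected: dict[int, np.ndarray] = {}
    profiles: dict[int, DissimilarityProfile] = {}
    for depth, stream in zip(depths, streams):
        table = make_replicate_tables(
            truth, replicates, depth, rng=np.random.default_rng(stream)
        )
        detected[depth] = table.richness.to_numpy()
        pairs = list(itertools.combinations(table.sample_ids, 2))
        profiles[depth] = dissimilarity_profile(table, pairs, q_grid, index_name)
    return DepthSimulationResult(
        depths=depths,
        replicates=replicates,
        detected=detected,
        profiles=profiles,
        seed=seed,
    )
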