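"""Consensus merging of count tables from different denoising pipelines.

Denoisers (DADA2, Deblur, UNOISE, ...) infer exact amplicon sequence
variants, so a true ASV found by one pipeline should also be found by
another, whereas error sequences tend to be pipeline-specific. The
consensus algorithm exploits this: it identifies the taxa detected in
*all* supplied count tables, computes for each table the fraction of its
reads carried by that shared set, retains the table with the highest
fraction, subsets it to the shared taxa, and returns the subset as the
consensus table. Counts therefore come from exactly one input table; no
abundance reconciliation across tables is attempted.

Matching modes
--------------
``exact``
    sequences equal after uppercasing (default; the conservative reading
    of "detected in all tables").
``subsequence``
    one sequence contained in the other, which tolerates pipelines that
    trim reads to different lengths.
``edit_distance``
    Levenshtein distance at most ``max_distance`` (via edlib).
``identifier``
    match on taxon ids instead of sequences; only for tables that already
    share an id space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import edlib

from .io_tables import CountTable, ValidationError

logger = logging.getLogger(__name__)

MODES = ("exact", "subsequence", "edit_distance", "identifier")


@dataclass
class ConsensusResult:
    """Outcome of a consensus merge.

    ``shared_taxa`` holds one taxon id per input table for every matched
    group; ``per_table_fraction`` maps table id to the fraction of its
    reads on the shared set.
    """

    shared_taxa: list[tuple[str, ...]]
    per_table_fraction: dict[str, float]
    retained_table_id: str
    consensus: CountTable


class _TableView:
    """Pre-indexed view of one input table for matching."""

    def __init__(self, table: CountTable, table_id: str, mode: str):
        self.table = table
        self.table_id = table_id
        self.reads = table.counts.sum(axis=1)
        if mode == "identifier":
            self.sequences = None
            self.by_seq = None
            return
        if table.sequences is None or set(table.sequences) != set(table.taxon_ids):
            missing = (
                sorted(set(table.taxon_ids) - set(table.sequences or {}))[:5]
            )
            raise ValidationError(
                f"table {table_id!r} lacks sequences for matching "
                f"(e.g. {missing}); attach sequences or use mode='identifier'"
            )
        self.sequences = table.sequences
        self.by_seq: dict[str, str] = {}
        for taxon in table.taxon_ids:
            seq = self.sequences[taxon]
            if seq in self.by_seq:
                # identical sequences within one table: keep the more abundant
                prev = self.by_seq[seq]
                if self.reads[taxon] > self.reads[prev]:
                    self.by_seq[seq] = taxon
                logger.warning(
                    "table %s: duplicate sequence for %r and %r; keeping the "
                    "more abundant",
                    table_id,
                    prev,
                    taxon,
                )
            else:
                self.by_seq[seq] = taxon


def _find_match(
    query_id: str,
    query_seq: str | None,
    view: _TableView,
    mode: str,
    max_distance: int,
) -> str | None:
    if mode == "identifier":
        return query_id if query_id in set(view.table.taxon_ids) else None
    if mode == "exact":
        return view.by_seq.get(query_seq)
    # tolerant modes: collect candidates as (distance, -reads, taxon)
    candidates: list[tuple[int, float, str]] = []
    for taxon in view.table.taxon_ids:
        seq = view.sequences[taxon]
        if mode == "subsequence":
            if query_seq in seq or seq in query_seq:
                candidates.append((abs(len(seq) - len(query_seq)), -float(view.reads[taxon]), taxon))
        else:  # edit_distance
            res = edlib.align(query_seq, seq, task="distance", k=max_distance)
            if res["editDistance"] != -1:
                candidates.append((res["editDistance"], -float(view.reads[taxon]), taxon))
    if not candidates:
        return None
    candidates.sort()
    if len(candidates) > 1:
        logger.info(
            "ambiguous match for %r in table %s resolved to %r "
            "(minimal distance, then read count)",
            query_id,
            view.table_id,
            candidates[0][2],
        )
    return candidates[0][2]


def match_taxa(
    tables: Sequence[CountTable],
    mode: str = "exact",
    max_distance: int = 0,
    table_ids: Sequence[str] | None = None,
) -> list[tuple[str, ...]]:
    """Group taxa detected in every input table.

    Returns one tuple per group with exactly one taxon id per table (in
    input-table order). A group exists only if a match is found in *every*
    table; the shared set is the intersection over all tables, not a union
    of pairwise matches.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown matching mode {mode!r}; use {MODES}")
    if len(tables) < 2:
        raise ValidationError("need at least 2 tables for a consensus")
    if max_distance < 0:
        raise ValidationError("max_distance must be >= 0")
    ids = list(table_ids) if table_ids else [f"table_{k + 1}" for k in range(len(tables))]
    views = [_TableView(t, i, mode) for t, i in zip(tables, ids)]

    groups: list[tuple[str, ...]] = []
    used: list[set[str]] = [set() for _ in views[1:]]
    for taxon in tables[0].taxon_ids:
        seq = views[0].sequences[taxon] if mode != "identifier" else None
        members = [taxon]
        for view, taken in zip(views[1:], used):
            hit = _find_match(taxon, seq, view, mode, max_distance)
            if hit is None or hit in taken:
                break
            members.append(hit)
        else:
            for taken, member in zip(used, members[1:]):
                taken.add(member)
            groups.append(tuple(members))
    return groups


def consensus_table(
    tables: Sequence[CountTable],
    mode: str = "exact",
    max_distance: int = 0,
    table_ids: Sequence[str] | None = None,
) -> ConsensusResult:
    """Merge count tables into a consensus restricted to shared taxa.

    Read fractions are computed on the raw (pre-rarefaction) counts. Ties
    on the fraction retain the table with fewer taxa, then the first by
    input order; both events are logged.
    """
    ids = list(table_ids) if table_ids else [f"table_{k + 1}" for k in range(len(tables))]
    if len(set(ids)) != len(ids):
        raise ValidationError("table ids must be unique")
    groups = match_taxa(tables, mode=mode, max_distance=max_distance, table_ids=ids)
    if not groups:
        raise ValidationError("no taxa are shared by all tables; consensus is empty")

    fractions: dict[str, float] = {}
    for j, (table, tid) in enumerate(zip(tables, ids)):
        member_ids = [g[j] for g in groups]
        shared_reads = table.counts.loc[member_ids].to_numpy().sum()
        total_reads = table.counts.to_numpy().sum()
        fractions[tid] = shared_reads / total_reads

    best = max(fractions.values())
    tied = [k for k, (t, tid) in enumerate(zip(tables, ids)) if fractions[tid] == best]
    if len(tied) > 1:
        tied.sort(key=lambda k: (tables[k].shape[0], k))
        logger.info(
            "read-fraction tie between %s; retaining %s (fewer taxa, then input order)",
            [ids[k] for k in tied],
            ids[tied[0]],
        )
    winner = tied[0]

    member_ids = list(dict.fromkeys(g[winner] for g in groups))
    consensus = tables[winner].subset_taxa(member_ids)
    return ConsensusResult(
        shared_taxa=groups,
        per_table_fraction=fractions,
        retained_table_id=ids[winner],
        consensus=consensus,
    )
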