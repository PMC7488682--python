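"""Count-table I/O and the core in-memory data model.

The central container is :class:`CountTable`: a taxa-by-samples matrix of
non-negative integer read counts, optionally carrying representative
nucleotide sequences keyed by taxon id. All downstream analyses (Hill
diversity, null models, consensus merging, rarefaction) consume this type.

On-disk contract
----------------
Count tables are UTF-8 TSV files with a header row
``taxon_id<TAB><sample1><TAB><sample2>...``; each subsequent row is a taxon
id followed by integer read counts. Representative sequences travel as
FASTA with record ids matching the taxon ids, and sample metadata as a
two-column TSV ``sample_id<TAB>category``.

Counts must be integers: rarefaction and the null model are defined on
reads, so real-valued tables are rejected rather than rounded. Taxon rows
that are zero in every sample carry no information for any index computed
here; they are pruned at construction time and the pruning is recorded on
the object and in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Characters allowed in representative sequences (case-insensitive on input).
SEQUENCE_ALPHABET = frozenset("ACGTUN")

#: Header columns that are dropped (with a warning) rather than parsed as samples.
_TAXONOMY_COLUMNS = frozenset({"taxonomy", "classification", "lineage"})


class FormatError(ValueError):
    """An input file does not conform to the expected on-disk layout."""


class ValidationError(ValueError):
    """Parsed or constructed data violate a count-table invariant."""


@dataclass
class CountTable:
    """Taxa x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    counts:
        DataFrame with taxon ids as the index and sample ids as columns.
        Values must be non-negative and integral (integer-valued floats are
        accepted and cast). All-zero taxon rows are pruned on construction
        and listed in :attr:`pruned_taxa`.
    sequences:
        Optional map ``taxon_id -> nucleotide sequence``. Keys must be taxon
        ids of the table; sequences are uppercased and restricted to the
        alphabet ``ACGTUN``.
    """

    counts: pd.DataFrame
    sequences: dict[str, str] | None = None
    pruned_taxa: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        df = self.counts
        if not isinstance(df, pd.DataFrame):
            raise ValidationError("counts must be a pandas DataFrame")
        if df.shape[1] == 0:
            raise ValidationError("count table has no sample columns")
        if df.shape[0] == 0:
            raise ValidationError("count table has no taxon rows")
        idx = df.index.astype(str)
        cols = df.columns.astype(str)
        if idx.has_duplicates:
            dupes = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicate taxon ids: {dupes}")
        if cols.has_duplicates:
            dupes = sorted(set(cols[cols.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dupes}")

        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("count table contains non-numeric cells")
        if np.isnan(values.astype(float)).any():
            raise ValidationError("count table contains NaN cells")
        if (values < 0).any():
            raise ValidationError("count table contains negative counts")
        if not np.all(np.equal(np.mod(values, 1), 0)):
            raise ValidationError(
                "count table contains non-integer counts; counts are reads "
                "and are not rounded"
            )

        df = pd.DataFrame(
            values.astype(np.int64), index=idx, columns=cols, copy=False
        )

        if self.sequences is not None:
            checked: dict[str, str] = {}
            known = set(df.index)
            for taxon, seq in self.sequences.items():
                if taxon not in known:
                    raise ValidationError(
                        f"sequence key {taxon!r} is not a taxon id of the table"
                    )
                checked[taxon] = _validate_sequence(taxon, seq)
            self.sequences = checked

        zero = df.sum(axis=1) == 0
        if zero.any():
            dropped = tuple(df.index[zero])
            logger.info(
                "pruned %d all-zero taxon row(s): %s",
                len(dropped),
                ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
            )
            df = df.loc[~zero]
            if df.shape[0] == 0:
                raise ValidationError("count table is empty after pruning")
            self.pruned_taxa = tuple(self.pruned_taxa) + dropped
            if self.sequences is not None:
                self.sequences = {
                    t: s for t, s in self.sequences.items() if t in set(df.index)
                }
        self.counts = df

    # -- basic introspection -------------------------------------------------

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=0)

    @property
    def richness(self) -> pd.Series:
        """Number of detected (count > 0) taxa per sample."""
        return (self.counts > 0).sum(axis=0)

    def column(self, sample_id: str) -> np.ndarray:
        """Counts for one sample as an integer vector in taxon order."""
        if sample_id not in self.counts.columns:
            raise ValidationError(f"unknown sample id: {sample_id!r}")
        return self.counts[sample_id].to_numpy()

    # -- derived tables ------------------------------------------------------

    def subset_samples(self, sample_ids: list[str]) -> "CountTable":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"unknown sample id(s): {missing}")
        return CountTable(self.counts[list(sample_ids)].copy(), sequences=self.sequences)

    def subset_taxa(self, taxon_ids: list[str]) -> "CountTable":
        missing = [t for t in taxon_ids if t not in self.counts.index]
        if missing:
            raise ValidationError(f"unknown taxon id(s): {missing}")
        seqs = None
        if self.sequences is not None:
            seqs = {t: self.sequences[t] for t in taxon_ids if t in self.sequences}
        return CountTable(self.counts.loc[list(taxon_ids)].copy(), sequences=seqs)

    def copy(self) -> "CountTable":
        seqs = dict(self.sequences) if self.sequences is not None else None
        return CountTable(self.counts.copy(), sequences=seqs)


@dataclass
class RelativeAbundance:
    """Relative abundances p_i of the taxa in a single community.

    The vector must be non-negative and sum to 1 within 1e-12.
    """

    taxon_ids: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1:
            raise ValidationError("relative abundances must be a 1-D vector")
        if len(self.taxon_ids) != p.size:
            raise ValidationError("taxon_ids and p have different lengths")
        if (p < 0).any():
            raise ValidationError("relative abundances must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError(
                f"relative abundances sum to {p.sum()!r}, expected 1"
            )
        self.p = p


def _validate_sequence(taxon: str, seq: str) -> str:
    s = str(seq).upper()
    bad = set(s) - SEQUENCE_ALPHABET
    if bad:
        raise ValidationError(
            f"sequence for {taxon!r} contains illegal character(s): {sorted(bad)}"
        )
    if not s:
        raise ValidationError(f"sequence for {taxon!r} is empty")
    return s


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, transpose: bool = False) -> CountTable:
    """Read a TSV count table (taxa as rows, samples as columns).

    Set ``transpose=True`` only for files stored samples-as-rows; the
    orientation is never guessed silently.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty file or blank header")
    cols = header.rstrip("\r\n").split("\t")
    if len(cols) < 2:
        raise FormatError(
            f"{path}: header must contain a taxon-id column and at least one sample"
        )
    sample_cols = cols[1:]
    seen: set[str] = set()
    for c in sample_cols:
        if c in seen:
            raise ValidationError(f"{path}: duplicate sample column {c!r}")
        seen.add(c)

    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:  # pragma: no cover - header check first
        raise FormatError(f"{path}: empty file") from exc

    tax_cols = [c for c in df.columns if c.lower() in _TAXONOMY_COLUMNS]
    if tax_cols:
        logger.warning("%s: ignoring taxonomy column(s) %s", path, tax_cols)
        df = df.drop(columns=tax_cols)
        if df.shape[1] == 0:
            raise FormatError(f"{path}: no sample columns after dropping taxonomy")

    if df.isna().any().any():
        raise ValidationError(f"{path}: table contains empty cells")
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric cell in count table: {exc}") from exc

    numeric.index = numeric.index.astype(str)
    if transpose:
        numeric = numeric.T
    return CountTable(numeric)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count table as TSV; round-trips bit-exactly via the reader."""
    table.counts.to_csv(path, sep="\t", index_label="taxon_id")


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA of representative sequences into ``{id: SEQ}``.

    Sequences are uppercased; duplicate record ids and characters outside
    ``ACGTUN`` are rejected.
    """
    path = Path(path)
    records: dict[str, str] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        if rec.id in records:
            raise ValidationError(f"{path}: duplicate FASTA record id {rec.id!r}")
        records[rec.id] = _validate_sequence(rec.id, str(rec.seq))
    if n == 0:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def attach_sequences(table: CountTable, sequences: dict[str, str]) -> CountTable:
    """Return a copy of *table* with matching sequences attached.

    Sequence ids not present in the table are warned about and left
    unattached (returned tables keep only matching keys).
    """
    known = set(table.taxon_ids)
    matched = {t: s for t, s in sequences.items() if t in known}
    orphans = sorted(set(sequences) - known)
    if orphans:
        logger.warning(
            "%d sequence record(s) have no matching taxon and were not attached: %s",
            len(orphans),
            ", ".join(orphans[:10]) + ("..." if len(orphans) > 10 else ""),
        )
    return CountTable(table.counts.copy(), sequences=matched)


def read_metadata(
    path: str | Path,
    table: CountTable | None = None,
    column: str | None = None,
) -> dict[str, str]:
    """Read sample metadata (``sample_id -> category``) from a TSV.

    The first column holds sample ids. ``column`` selects the category
    column by name; by default the second column is used. When *table* is
    given, every metadata sample id must exist in it.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty metadata file") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: metadata needs sample-id and category columns")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids in metadata")
    if column is not None:
        if column not in df.columns:
            raise ValidationError(f"{path}: no metadata column named {column!r}")
        cats = df[column].astype(str)
    else:
        cats = df.iloc[:, 1].astype(str)
    meta = dict(zip(ids, cats))
    if table is not None:
        unknown = sorted(set(meta) - set(table.sample_ids))
        if unknown:
            raise ValidationError(
                f"{path}: metadata references unknown sample(s): {unknown}"
            )
    return meta


def to_relative_abundance(table: CountTable, sample_id: str) -> RelativeAbundance:
    """Normalize one sample column to relative abundances p_i."""
    col = table.column(sample_id)
    total = col.sum()
    if total == 0:
        raise ValidationError(
            f"sample {sample_id!r} has zero reads and cannot be normalized"
        )
    return RelativeAbundance(table.taxon_ids, col / total)


# ---------------------------------------------------------------------------
# sample-pair helpers (used by profiles, null models and the CLI)
# ---------------------------------------------------------------------------

def pairs_within(metadata: dict[str, str], category: str) -> list[tuple[str, str]]:
    """All unordered sample pairs inside one metadata category."""
    members = [s for s, c in metadata.items() if c == category]
    if len(members) < 2:
        raise ValidationError(
            f"category {category!r} has {len(members)} sample(s); need >= 2"
        )
    return [
        (members[i], members[j])
        for i in range(len(members))
        for j in range(i + 1, len(members))
    ]


def pairs_between(
    metadata: dict[str, str], category_a: str, category_b: str
) -> list[tuple[str, str]]:
    """All cross pairs between two metadata categories."""
    a = [s for s, c in metadata.items() if c == category_a]
    b = [s for s, c in metadata.items() if c == category_b]
    if not a or not b:
        missing = category_a if not a else category_b
        raise ValidationError(f"category {missing!r} has no samples")
    return [(x, y) for x in a for y in b]
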