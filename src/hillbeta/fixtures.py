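"""Synthetic community generators used for testing and demonstrations.

Two kinds of data are produced:

* a structured toy count table of eight samples (S0-S7) whose sharing
  pattern isolates how abundance weighting shapes dissimilarity: samples
  S0-S3 each hold 2 abundant, 4 intermediate, and 8 rare taxa (richness
  14) and share prescribed numbers of taxa per abundance class with S0 at
  identical relative abundances; S4 shares all of S0's taxa but with a
  different abundance distribution; S5-S7 are two-taxon samples whose taxa
  coincide with S0's abundant, intermediate, and rare classes respectively;
* parametric long-tailed communities (lognormal rank-abundance curves) and
  multinomial replicate tables drawn from them, emulating replicate
  amplicon libraries sequenced from one underlying community.

The structured table is verified by a self-check of every class size and
sharing count before it is returned.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_tables import CountTable, RelativeAbundance, ValidationError

logger = logging.getLogger(__name__)

#: default per-taxon relative abundances for the (abundant, intermediate,
#: rare) classes; constrained by 2a + 4i + 8r = 1 and a > i > r > 0.
DEFAULT_SCHEME = (0.25, 0.075, 0.025)

#: abundance scheme used for S4 (same taxa as S0, different distribution).
DEFAULT_ALT_SCHEME = (0.2, 0.1, 0.025)

DEFAULT_DEPTH = 1000


def _check_scheme(scheme: tuple[float, float, float]) -> tuple[float, float, float]:
    a, i, r = (float(x) for x in scheme)
    if not (a > i > r > 0):
        raise ValidationError(f"class abundances must satisfy a > i > r > 0, got {scheme}")
    total = 2 * a + 4 * i + 8 * r
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"class abundances must satisfy 2a + 4i + 8r = 1, got {total}")
    return a, i, r


def _to_counts(fraction: float, depth: int) -> int:
    x = fraction * depth
    if abs(x - round(x)) > 1e-9:
        raise ValidationError(
            f"abundance {fraction} times depth {depth} is not an integer read "
            "count; pick a compatible depth"
        )
    return int(round(x))


def make_structured_table(
    abundance_scheme: tuple[float, float, float] = DEFAULT_SCHEME,
    alt_scheme: tuple[float, float, float] = DEFAULT_ALT_SCHEME,
    depth: int = DEFAULT_DEPTH,
) -> CountTable:
    """Build the eight-sample structured toy table S0-S7.

    Sharing pattern with S0 (class counts abundant/intermediate/rare):
    S1 shares 1/2/4, S2 shares 0/2/4, S3 shares 1/4/1, S4 shares all 14
    taxa (different abundance distribution), and S5/S6/S7 are two-taxon
    samples drawn from S0's abundant/intermediate/rare classes. Within
    S0-S3 every shared taxon has identical relative abundance in both
    members of a pair. Taxa of S1-S3 that are not shared with S0 are
    unique to their sample; S5-S7 split their reads equally between their
    two taxa.
    """
    a, i, r = _check_scheme(abundance_scheme)
    a2, i2, r2 = _check_scheme(alt_scheme)
    if depth % 2:
        raise ValidationError("depth must be even (S5-S7 split reads equally)")
    ca, ci, cr = (_to_counts(x, depth) for x in (a, i, r))
    ca2, ci2, cr2 = (_to_counts(x, depth) for x in (a2, i2, r2))
    half = depth // 2

    A = [f"A{k}" for k in range(1, 3)]           # S0 abundant
    I = [f"I{k}" for k in range(1, 5)]           # S0 intermediate
    R = [f"R{k}" for k in range(1, 9)]           # S0 rare
    s1u = [f"S1u{k}" for k in range(1, 8)]       # 1 abundant, 2 interm., 4 rare
    s2u = [f"S2u{k}" for k in range(1, 9)]       # 2 abundant, 2 interm., 4 rare
    s3u = [f"S3u{k}" for k in range(1, 9)]       # 1 abundant, 7 rare
    taxa = A + I + R + s1u + s2u + s3u

    cols: dict[str, dict[str, int]] = {}
    cols["S0"] = {**{t: ca for t in A}, **{t: ci for t in I}, **{t: cr for t in R}}
    cols["S1"] = {
        "A1": ca, "S1u1": ca,
        "I1": ci, "I2": ci, "S1u2": ci, "S1u3": ci,
        **{t: cr for t in ["R1", "R2", "R3", "R4", "S1u4", "S1u5", "S1u6", "S1u7"]},
    }
    cols["S2"] = {
        "S2u1": ca, "S2u2": ca,
        "I3": ci, "I4": ci, "S2u3": ci, "S2u4": ci,
        **{t: cr for t in ["R5", "R6", "R7", "R8", "S2u5", "S2u6", "S2u7", "S2u8"]},
    }
    cols["S3"] = {
        "A1": ca, "S3u1": ca,
        **{t: ci for t in I},
        **{t: cr for t in ["R1", "S3u2", "S3u3", "S3u4", "S3u5", "S3u6", "S3u7", "S3u8"]},
    }
    cols["S4"] = {**{t: ca2 for t in A}, **{t: ci2 for t in I}, **{t: cr2 for t in R}}
    cols["S5"] = {"A1": half, "A2": half}
    cols["S6"] = {"I1": half, "I2": half}
    cols["S7"] = {"R1": half, "R2": half}

    counts = pd.DataFrame(0, index=taxa, columns=list(cols), dtype=np.int64)
    for sample, row in cols.items():
        for taxon, c in row.items():
            counts.loc[taxon, sample] = c
    table = CountTable(counts)
    _verify_structured(table, (ca, ci, cr))
    return table


def _verify_structured(table: CountTable, class_counts: tuple[int, int, int]) -> None:
    """Assert every class size and sharing count before serving the table."""
    ca, ci, cr = class_counts
    df = table.counts

    def classes(sample: str) -> dict[int, set[str]]:
        col = df[sample]
        return {c: set(col.index[col == c]) for c in (ca, ci, cr)}

    for s in ("S0", "S1", "S2", "S3"):
        by = classes(s)
        sizes = (len(by[ca]), len(by[ci]), len(by[cr]))
        assert sizes == (2, 4, 8), f"{s}: class sizes {sizes} != (2, 4, 8)"
        assert int((df[s] > 0).sum()) == 14, f"{s}: richness != 14"
    for s in ("S5", "S6", "S7"):
        assert int((df[s] > 0).sum()) == 2, f"{s}: richness != 2"

    s0 = classes("S0")
    expected_sharing = {"S1": (1, 2, 4), "S2": (0, 2, 4), "S3": (1, 4, 1)}
    for s, (na, ni, nr) in expected_sharing.items():
        by = classes(s)
        got = (len(s0[ca] & by[ca]), len(s0[ci] & by[ci]), len(s0[cr] & by[cr]))
        assert got == (na, ni, nr), f"S0-{s}: shared class counts {got} != {(na, ni, nr)}"
        # shared taxa must have identical relative abundance in both samples
        shared = set(df.index[(df["S0"] > 0) & (df[s] > 0)])
        assert (df.loc[sorted(shared), "S0"] == df.loc[sorted(shared), s]).all()

    s4 = set(df.index[df["S4"] > 0])
    assert s4 == set(df.index[df["S0"] > 0]), "S4 must share all 14 taxa with S0"
    assert {t for t in df.index[df["S5"] > 0]} <= s0[ca]
    assert {t for t in df.index[df["S6"] > 0]} <= s0[ci]
    assert {t for t in df.index[df["S7"] > 0]} <= s0[cr]


def make_lognormal_community(
    S: int, sigma: float, seed: int | None = None
) -> RelativeAbundance:
    """Long-tailed (lognormal rank-abundance) community of S taxa.

    ``sigma`` is the log-scale standard deviation: 0 gives a uniform
    community; larger values give lower evenness. Deterministic per seed.
    """
    if S < 1:
        raise ValidationError(f"need at least 1 taxon, got {S}")
    if sigma < 0:
        raise ValidationError(f"sigma must be >= 0, got {sigma}")
    ids = [f"ASV{k + 1:05d}" for k in range(S)]
    if sigma == 0:
        return RelativeAbundance(ids, np.full(S, 1.0 / S))
    rng = np.random.default_rng(seed)
    x = np.sort(rng.lognormal(mean=0.0, sigma=sigma, size=S))[::-1]
    return RelativeAbundance(ids, x / x.sum())


def make_replicate_tables(
    truth: RelativeAbundance,
    n: int,
    depth: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    prefix: str = "rep",
) -> CountTable:
    """``n`` multinomial replicate samples of ``depth`` reads from ``truth``.

    Models resampling of sequencing libraries from one fixed community
    (sampling with replacement); taxa never drawn in any replicate are
    pruned from the returned table, mirroring real count tables that only
    list detected taxa.
    """
    if n < 1:
        raise ValidationError(f"need at least 1 replicate, got {n}")
    if depth < 1:
        raise ValidationError(f"depth must be >= 1, got {depth}")
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = rng.multinomial(depth, truth.p, size=n)  # n x taxa
    counts = pd.DataFrame(
        draws.T, index=truth.taxon_ids, columns=[f"{prefix}{k + 1}" for k in range(n)]
    )
    return CountTable(counts)


def make_random_table(
    n_taxa: int = 12,
    n_samples: int = 4,
    depth: int = 200,
    concentration: float = 0.6,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CountTable:
    """Random sparse count table for property tests and demos.

    Each sample draws its composition from a symmetric Dirichlet with the
    given concentration (values < 1 produce realistic sparse, uneven
    columns) and then ``depth`` reads multinomially.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cols = {}
    for s in range(n_samples):
        p = rng.dirichlet(np.full(n_taxa, concentration))
        cols[f"sample{s + 1}"] = rng.multinomial(depth, p)
    counts = pd.DataFrame(cols, index=[f"T{k + 1}" for k in range(n_taxa)])
    return CountTable(counts)
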