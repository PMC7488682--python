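"""Hill numbers, diversity decomposition, and dissimilarity indices.

A Hill number (effective number of taxa) of order ``q`` for a community
with relative abundances ``p_i`` is

    qD = (sum_i p_i^q)^(1/(1-q))          for q != 1
    1D = exp(-sum_i p_i ln p_i)           for q  = 1

``q`` controls how much weight relative abundance gets: q=0 counts
detected taxa (richness), q=1 weights taxa exactly by abundance, q>1
emphasizes dominant taxa.

For N communities compared with equal weights, diversity decomposes
multiplicatively: gamma is the Hill number of the pooled community
(mean of the p-vectors), alpha is the effective number of taxa per
community, and beta = gamma / alpha is the effective number of distinct
communities, bounded by [1, N]. The equal-weight alpha used here is

    qD_alpha = (1/N) * [sum_ij (p_ij / N)^q]^(1/(1-q))     for q != 1

with the corresponding Shannon limit at q=1. This is the standard
equal-weight (Chiu/Jost/Chao) decomposition: it is the one for which
beta stays in [1, N] at every q, the local transform reduces to the
Sorensen dissimilarity at q=0, and the regional transform reduces to
the Jaccard dissimilarity at q=0.

Beta maps onto a dissimilarity in [0, 1] through two transforms:

    local:    qd = (beta^(1-q) - 1) / (N^(1-q) - 1)   (q != 1)
    regional: qd = (beta^(q-1) - 1) / (N^(q-1) - 1)   (q != 1)
    both:     qd = ln(beta) / ln(N)                   (q  = 1)

The local index is the effective average proportion of a community's taxa
not shared with the other communities; the regional index is the effective
proportion of the pooled community's taxa not shared by all communities.
Classic Jaccard, Sorensen, and Bray-Curtis indices are provided for
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io_tables import CountTable, RelativeAbundance, ValidationError

logger = logging.getLogger(__name__)

#: |q - 1| below this uses the exact Shannon-limit formulas.
Q_ONE_TOL = 1e-9
#: slack allowed before a bound violation (beta outside [1, N], qd outside
#: [0, 1]) is treated as an error rather than rounding noise.
_BOUND_TOL = 1e-9

#: default diversity-order grid for profiles: 0 to 2 inclusive, step 0.05.
DEFAULT_Q_GRID: np.ndarray = np.round(np.arange(0.0, 2.0 + 1e-9, 0.05), 10)

LOCAL = "local_hill"
REGIONAL = "regional_hill"
JACCARD = "jaccard"
SORENSEN = "sorensen"
BRAY_CURTIS = "bray_curtis"

HILL_INDICES = frozenset({LOCAL, REGIONAL})
CLASSIC_INDICES = frozenset({JACCARD, SORENSEN, BRAY_CURTIS})

_ALIASES = {
    "local": LOCAL,
    "local_hill": LOCAL,
    "regional": REGIONAL,
    "regional_hill": REGIONAL,
    "jaccard": JACCARD,
    "sorensen": SORENSEN,
    "braycurtis": BRAY_CURTIS,
    "bray_curtis": BRAY_CURTIS,
    "bray-curtis": BRAY_CURTIS,
}


def resolve_index(name: str) -> str:
    """Map an index name or alias to its canonical name."""
    try:
        return _ALIASES[name.lower()]
    except KeyError:
        raise ValidationError(
            f"unknown dissimilarity index {name!r}; choose from "
            f"{sorted(set(_ALIASES.values()))}"
        ) from None


@dataclass
class HillDecomposition:
    """Alpha/gamma/beta decomposition of N communities at order q."""

    q: float
    N: int
    alpha: float
    gamma: float
    beta: float


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarity matrix for a named index.

    ``q`` is the diversity order for the Hill-based indices and ``None``
    for the classic (Jaccard/Sorensen/Bray-Curtis) indices.
    """

    sample_ids: list[str]
    values: np.ndarray
    index_name: str
    q: float | None = None

    def __post_init__(self) -> None:
        ids = [str(s) for s in self.sample_ids]
        v = np.asarray(self.values, dtype=float)
        n = len(ids)
        if v.shape != (n, n):
            raise ValidationError(
                f"matrix shape {v.shape} does not match {n} sample ids"
            )
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValidationError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValidationError("dissimilarity matrix diagonal is not zero")
        if v.min() < -_BOUND_TOL or v.max() > 1 + _BOUND_TOL:
            raise ValidationError("dissimilarity values outside [0, 1]")
        v = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(v, 0.0)
        self.sample_ids = ids
        self.values = v

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) values in row-major order."""
        iu = np.triu_indices(self.n_samples, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def reorder(self, sample_ids: Sequence[str]) -> "DissimilarityMatrix":
        if set(sample_ids) != set(self.sample_ids):
            raise ValidationError("reorder requires the same sample set")
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids])
        return DissimilarityMatrix(
            list(sample_ids), self.values[np.ix_(idx, idx)], self.index_name, self.q
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(
            path, sep="\t", index_label="sample_id", float_format="%.12g"
        )

    @classmethod
    def read_tsv(
        cls, path: str | Path, index_name: str = "unknown", q: float | None = None
    ) -> "DissimilarityMatrix":
        df = pd.read_csv(path, sep="\t", header=0, index_col=0)
        return cls(list(df.columns.astype(str)), df.to_numpy(float), index_name, q)


@dataclass
class DissimilarityProfile:
    """Mean and sd of pairwise dissimilarity along a diversity-order grid."""

    q_grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    pair_count: int
    index_name: str = LOCAL
    #: raw per-pair values, shape (pair_count, len(q_grid))
    values: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"q": self.q_grid, "mean": self.mean, "sd": self.sd,
             "n_pairs": self.pair_count}
        )


# ---------------------------------------------------------------------------
# Hill numbers and decomposition
# ---------------------------------------------------------------------------

def _as_p(x) -> np.ndarray:
    """Coerce input to a validated relative-abundance vector."""
    if isinstance(x, RelativeAbundance):
        return x.p
    p = np.asarray(x, dtype=float)
    if p.ndim != 1:
        raise ValidationError("abundance input must be a 1-D vector")
    if (p < 0).any():
        raise ValidationError("relative abundances must be non-negative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValidationError(
            f"relative abundances sum to {p.sum()!r}; normalize counts first"
        )
    return p


def hill_number(p, q: float) -> float:
    """Effective number of taxa of order ``q`` for one community.

    Zero-abundance taxa contribute nothing at any order (0^0 is treated as
    0 in the q=0 sum, so richness counts only detected taxa). Powers are
    evaluated in log space for numerical stability.
    """
    if q < 0:
        raise ValidationError(f"diversity order must be >= 0, got {q}")
    p = _as_p(p)
    p = p[p > 0]
    if p.size == 0:
        raise ValidationError("community has no detected taxa")
    if abs(q - 1.0) < Q_ONE_TOL:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.exp(logsumexp(q * np.log(p)) / (1.0 - q)))


def decompose(abundances: Iterable, q: float) -> HillDecomposition:
    """Equal-weight alpha/gamma/beta decomposition of N >= 2 communities.

    ``abundances`` is a sequence of relative-abundance vectors over a common
    taxon ordering (or a 2-D array with communities as columns).
    """
    if q < 0:
        raise ValidationError(f"diversity order must be >= 0, got {q}")
    if isinstance(abundances, np.ndarray) and abundances.ndim == 2:
        cols = [abundances[:, j] for j in range(abundances.shape[1])]
    else:
        cols = list(abundances)
    P = np.column_stack([_as_p(c) for c in cols])
    N = P.shape[1]
    if N < 2:
        raise ValidationError(f"need at least 2 communities, got {N}")

    pooled = P.mean(axis=1)
    gamma = hill_number(pooled, q)

    w = (P / N).ravel()
    w = w[w > 0]
    if abs(q - 1.0) < Q_ONE_TOL:
        alpha = float(np.exp(-np.sum(w * np.log(w))) / N)
    else:
        alpha = float(np.exp(logsumexp(q * np.log(w)) / (1.0 - q)) / N)

    beta = gamma / alpha
    if beta < 1.0 - _BOUND_TOL or beta > N + _BOUND_TOL:
        raise ValidationError(
            f"beta diversity {beta} outside [1, {N}]; inputs are inconsistent"
        )
    beta = float(min(max(beta, 1.0), float(N)))
    return HillDecomposition(q=float(q), N=N, alpha=alpha, gamma=gamma, beta=beta)


def _clip01(value: float) -> float:
    if value < -_BOUND_TOL or value > 1 + _BOUND_TOL:
        raise ValidationError(f"dissimilarity {value} outside [0, 1]")
    return float(min(max(value, 0.0), 1.0))


def local_dissimilarity(decomp: HillDecomposition) -> float:
    """Local-class transform of beta onto [0, 1].

    Measures the effective average proportion of a community's taxa not
    shared with the other compared communities; equals the Sorensen
    dissimilarity at q=0.
    """
    q, beta, N = decomp.q, decomp.beta, decomp.N
    if abs(q - 1.0) < Q_ONE_TOL:
        return _clip01(np.log(beta) / np.log(N))
    return _clip01((beta ** (1.0 - q) - 1.0) / (N ** (1.0 - q) - 1.0))


def regional_dissimilarity(decomp: HillDecomposition) -> float:
    """Regional-class transform of beta onto [0, 1].

    Measures the effective proportion of the pooled community's taxa not
    shared among all compared communities; equals the Jaccard dissimilarity
    at q=0. Shares the ln(beta)/ln(N) limit with the local transform at q=1.
    """
    q, beta, N = decomp.q, decomp.beta, decomp.N
    if abs(q - 1.0) < Q_ONE_TOL:
        return _clip01(np.log(beta) / np.log(N))
    return _clip01((beta ** (q - 1.0) - 1.0) / (N ** (q - 1.0) - 1.0))


# ---------------------------------------------------------------------------
# classic indices
# ---------------------------------------------------------------------------

def _incidence(x) -> np.ndarray:
    if isinstance(x, RelativeAbundance):
        x = x.p
    arr = np.asarray(x)
    inc = arr > 0
    if not inc.any():
        raise ValidationError("sample has no detected taxa")
    return inc


def jaccard(x, y) -> float:
    """Jaccard dissimilarity 1 - |shared| / |union| on incidence data."""
    a, b = _incidence(x), _incidence(y)
    if a.size != b.size:
        raise ValidationError("incidence vectors must share a taxon universe")
    shared = int(np.sum(a & b))
    union = int(np.sum(a | b))
    return 1.0 - shared / union


def sorensen(x, y) -> float:
    """Sorensen dissimilarity 1 - 2|shared| / (S_x + S_y) on incidence data."""
    a, b = _incidence(x), _incidence(y)
    if a.size != b.size:
        raise ValidationError("incidence vectors must share a taxon universe")
    shared = int(np.sum(a & b))
    return 1.0 - 2.0 * shared / (int(a.sum()) + int(b.sum()))


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity (1/2) sum_i |p_ix - p_iy| on relative abundances.

    Computed on relative abundances (equal-weight samples); on rarefied
    equal-depth tables this coincides with the raw-count formulation.
    """
    p1, p2 = _as_p(x), _as_p(y)
    if p1.size != p2.size:
        raise ValidationError("abundance vectors must share a taxon universe")
    return _clip01(0.5 * float(np.abs(p1 - p2).sum()))


# ---------------------------------------------------------------------------
# pairwise application
# ---------------------------------------------------------------------------

def pair_dissimilarity(p1, p2, index_name: str = LOCAL, q: float | None = None) -> float:
    """Dissimilarity between two communities under a named index.

    Hill-based indices require a diversity order ``q`` and use the pairwise
    (N = 2) decomposition; classic indices ignore ``q``.
    """
    index = resolve_index(index_name)
    if index in HILL_INDICES:
        if q is None:
            raise ValidationError(f"index {index!r} requires a diversity order q")
        dec = decompose([_as_p(p1), _as_p(p2)], q)
        return local_dissimilarity(dec) if index == LOCAL else regional_dissimilarity(dec)
    if index == JACCARD:
        return jaccard(p1, p2)
    if index == SORENSEN:
        return sorensen(p1, p2)
    return bray_curtis(p1, p2)


def _relative_matrix(table: CountTable) -> np.ndarray:
    counts = table.counts.to_numpy(dtype=float)
    depths = counts.sum(axis=0)
    zero = np.flatnonzero(depths == 0)
    if zero.size:
        bad = table.sample_ids[zero[0]]
        raise ValidationError(f"sample {bad!r} has zero reads")
    return counts / depths


def dissimilarity_matrix(
    table: CountTable, index_name: str = LOCAL, q: float | None = None
) -> DissimilarityMatrix:
    """All pairwise dissimilarities between the samples of a count table.

    Hill-based entries use the pairwise N=2 decomposition; multi-community
    (N > 2) decompositions are exposed through :func:`decompose` instead of
    being averaged into a matrix.
    """
    index = resolve_index(index_name)
    ids = table.sample_ids
    if len(ids) < 2:
        raise ValidationError("need at least 2 samples for a dissimilarity matrix")
    P = _relative_matrix(table)
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pair_dissimilarity(P[:, i], P[:, j], index, q)
    return DissimilarityMatrix(ids, out, index, None if index in CLASSIC_INDICES else q)


def dissimilarity_profile(
    table: CountTable,
    pairs: Sequence[tuple[str, str]],
    q_grid: Sequence[float] | None = None,
    index_name: str = LOCAL,
) -> DissimilarityProfile:
    """Mean/sd of pairwise dissimilarity as a function of diversity order.

    ``sd`` is the population standard deviation over the listed pairs, so a
    single pair yields sd = 0 at every grid point.
    """
    index = resolve_index(index_name)
    if not pairs:
        raise ValidationError("empty pair list")
    grid = DEFAULT_Q_GRID if q_grid is None else np.asarray(list(q_grid), dtype=float)
    if grid.size == 0:
        raise ValidationError("empty diversity-order grid")
    if np.any(np.diff(grid) < 0):
        raise ValidationError("q grid must be sorted ascending")
    P = _relative_matrix(table)
    pos = {s: k for k, s in enumerate(table.sample_ids)}
    for a, b in pairs:
        if a not in pos or b not in pos:
            missing = a if a not in pos else b
            raise ValidationError(f"unknown sample id in pair list: {missing!r}")
    values = np.empty((len(pairs), grid.size))
    for r, (a, b) in enumerate(pairs):
        pa, pb = P[:, pos[a]], P[:, pos[b]]
        for c, q in enumerate(grid):
            values[r, c] = pair_dissimilarity(pa, pb, index, float(q))
    return DissimilarityProfile(
        q_grid=grid,
        mean=values.mean(axis=0),
        sd=values.std(axis=0),
        pair_count=len(pairs),
        index_name=index,
        values=values,
    )
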