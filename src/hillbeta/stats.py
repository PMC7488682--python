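"""Permutation tests on dissimilarity matrices: Mantel and permanova.

Both tests avoid distributional assumptions by building their null from
permutations, and both use the +1-corrected p-value

    p = (number of permuted statistics >= observed + 1) / (permutations + 1)

which counts the observed arrangement among the permutations and can never
be zero; with 999 permutations the smallest attainable p is 0.001.

The Mantel statistic is the Pearson (or Spearman) correlation between the
upper off-diagonal triangles of two dissimilarity matrices over the same
samples; the null permutes the rows and columns of one matrix
simultaneously. The permanova pseudo-F compares between-group to
within-group variability, computed directly from squared dissimilarities
(the Gower-centred one-way form):

    SS_total  = sum_{i<j} d_ij^2 / n
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    F = ((SS_total - SS_within) / (a - 1)) / (SS_within / (n - a))

with a groups and n samples; the null permutes the group labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .hill import DissimilarityMatrix
from .io_tables import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_PERMUTATIONS = 999


@dataclass
class PermutationTestResult:
    """Observed statistic and permutation p-value."""

    statistic: float
    p_value: float
    permutations: int
    method: str
    seed: int | None = None


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise ValidationError("constant dissimilarity matrix; correlation undefined")
    return float((xc * yc).sum() / denom)


def _rank_matrix(m: DissimilarityMatrix) -> DissimilarityMatrix:
    """Replace off-diagonal values by the ranks of the condensed entries."""
    n = m.n_samples
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(m.values[iu])
    ranks = ranks / ranks.max()  # keep values in [0, 1] for the container
    v = np.zeros_like(m.values)
    v[iu] = ranks
    v = v + v.T
    return DissimilarityMatrix(m.sample_ids, v, m.index_name, m.q)


def mantel(
    m1: DissimilarityMatrix,
    m2: DissimilarityMatrix,
    method: str = "pearson",
    permutations: int = DEFAULT_PERMUTATIONS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> PermutationTestResult:
    """Mantel permutation test of association between two matrices.

    The matrices must cover the same sample set; if their orderings differ,
    ``m2`` is reordered to match ``m1``. The test is one-sided for positive
    association (permuted r >= observed r).
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    if permutations < 99:
        raise ValidationError("use at least 99 permutations")
    if set(m1.sample_ids) != set(m2.sample_ids):
        raise ValidationError("matrices cover different sample sets")
    if m1.sample_ids != m2.sample_ids:
        m2 = m2.reorder(m1.sample_ids)
    if rng is None:
        rng = np.random.default_rng(seed)

    a, b = m1, m2
    if method == "spearman":
        a, b = _rank_matrix(m1), _rank_matrix(m2)
    n = a.n_samples
    iu = np.triu_indices(n, k=1)
    x = a.values[iu]
    r_obs = _pearson(x, b.values[iu])

    count = 0
    vb = b.values
    for _ in range(permutations):
        perm = rng.permutation(n)
        y = vb[np.ix_(perm, perm)][iu]
        if _pearson(x, y) >= r_obs:
            count += 1
    p = (count + 1) / (permutations + 1)
    return PermutationTestResult(
        statistic=r_obs, p_value=p, permutations=permutations,
        method=f"mantel_{method}", seed=seed,
    )


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, group_codes: np.ndarray) -> float:
    n = d2.shape[0]
    a = group_codes.size
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in group_codes:
        members = np.flatnonzero(labels == g)
        block = d2[np.ix_(members, members)]
        ss_within += block[np.triu_indices(members.size, k=1)].sum() / members.size
    ss_between = ss_total - ss_within
    if ss_within == 0:
        return np.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    d: DissimilarityMatrix,
    groups: dict[str, str],
    permutations: int = DEFAULT_PERMUTATIONS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> PermutationTestResult:
    """One-way permanova on a dissimilarity matrix.

    ``groups`` maps every sample id of ``d`` to a category label; at least
    two groups with at least two samples each are required. The null is
    built by permuting the labels.
    """
    if permutations < 1:
        raise ValidationError("need at least one permutation")
    missing = [s for s in d.sample_ids if s not in groups]
    if missing:
        raise ValidationError(f"no group label for sample(s): {missing}")
    labels_str = [groups[s] for s in d.sample_ids]
    uniq = sorted(set(labels_str))
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    code = {g: k for k, g in enumerate(uniq)}
    labels = np.array([code[g] for g in labels_str])
    sizes = np.bincount(labels)
    if (sizes < 2).any():
        small = uniq[int(np.argmin(sizes))]
        raise ValidationError(f"group {small!r} has fewer than 2 samples")
    if rng is None:
        rng = np.random.default_rng(seed)

    d2 = d.values ** 2
    codes = np.arange(len(uniq))
    with np.errstate(divide="ignore"):
        f_obs = _pseudo_f(d2, labels, codes)
        count = 0
        for _ in range(permutations):
            if _pseudo_f(d2, rng.permutation(labels), codes) >= f_obs:
                count += 1
    p = (count + 1) / (permutations + 1)
    return PermutationTestResult(
        statistic=f_obs, p_value=p, permutations=permutations,
        method="permanova", seed=seed,
    )
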