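# Methods

This note documents the models implemented in `hillbeta`, the defaults
and numerical choices, what the synthetic generators do and do not
emulate, and the design decisions taken where the literature leaves the
construction open.

## Hill numbers and the diversity decomposition

For one community with relative abundances `p_i`, the Hill number of
order `q ≥ 0` is `(Σ p_i^q)^(1/(1−q))` for `q ≠ 1` and
`exp(−Σ p_i ln p_i)` at `q = 1`. Zero-abundance taxa are excluded from
the sum at every order, including `q = 0` (`0^0` contributes nothing), so
richness counts only detected taxa. Powers are evaluated in log space
(`exp(logsumexp(q·log p)/(1−q))`) to avoid under/overflow for extreme
`q` or very small `p`; whenever `|q − 1| < 1e-9` the exact Shannon-limit
formulas are used instead, which keeps every transform continuous across
`q = 1` (verified to better than 1e-5 at `q = 1 ± 1e-6`).

For `N ≥ 2` communities compared with equal weights, gamma diversity is
the Hill number of the pooled vector `p̄_i = (1/N) Σ_j p_ij`, and alpha is
the equal-weight decomposition

```
qDα = (1/N) · [Σ_i Σ_j (p_ij / N)^q]^(1/(1−q))     (q ≠ 1)
```

with the corresponding entropy limit divided by `N` at `q = 1`. This is
the standard equal-weight (Chiu/Jost/Chao) alpha. It was chosen because
it is the only standard construction that simultaneously satisfies the
constraints the dissimilarity framework relies on: `β = γ/α ∈ [1, N]` at
every order, the local transform reduces exactly to Sørensen at `q = 0`,
and the regional transform reduces exactly to Jaccard at `q = 0`. The
test suite asserts all three properties, plus two-route agreement (to
1e-12) with a literal brute-force transcription of the defining sums on
enumerated small tables.

β is clamped into `[1, N]` only when it strays by less than 1e-9
(floating-point rounding); larger violations raise, since they indicate
invalid inputs. Dissimilarities are likewise clipped into `[0, 1]` within
the same tolerance.

The regional transform `(β^(q−1) − 1)/(N^(q−1) − 1)` is pinned by the
`q = 0` Jaccard equivalence; at `q = 1` it shares the `ln β / ln N`
limit with the local transform. Whether a distinct `q = 1` regional
limit is ever wanted is left open; both transforms use the shared limit
here.

Pairwise dissimilarity matrices always use `N = 2` per pair. Multi-way
(`N > 2`) decompositions are exposed through `decompose` but are never
averaged into a matrix, because a matrix cell is a statement about one
pair only.

Bray–Curtis is computed on relative abundances, `½ Σ |p_ix − p_iy|`
(equal-weight samples). On rarefied equal-depth tables this coincides
with the count formulation. When two samples have the same species
abundance distribution and every shared taxon has identical relative
abundance in both, Bray–Curtis equals the local index at `q = 1`; the
suite generates such matched pairs (shared part identical, unique parts
equal value-multisets on disjoint taxa) and asserts equality to 1e-10.

Default profile grid: `q` from 0 to 2 inclusive in steps of 0.05,
matching the range over which the weighting of rare-to-dominant taxa is
usually examined; overridable everywhere. Profile standard deviations
are population (ddof 0) over the listed pairs, so a single pair reports
sd = 0 rather than NaN.

## Raup–Crick null model

The null question is whether an observed pairwise dissimilarity could
arise from random assembly out of a regional pool. The pool defaults to
all samples of the supplied table and can be restricted to a subset
(e.g. one habitat). For each retained taxon the pool records its
occurrence frequency (number of pool samples containing it) and its
summed reads.

Per randomization, *both* members of the pair are independently
re-assembled — symmetric treatment of the two samples — each preserving
its own observed richness and read depth exactly:

1. richness-many taxa are drawn without replacement, weighted by
   occurrence frequency (`scheme="frequency"`, default) or pool read
   totals (`scheme="abundance"`);
2. each selected taxon receives one read; the remaining
   `depth − richness` reads are distributed multinomially with
   probabilities proportional to the selected taxa's pool-wide read
   totals, renormalized over the selected taxa.

The literature describes reads as "populated" with likelihood related to
pool abundance without fixing the mechanism; the seed-then-multinomial
construction above is the standard (Stegen-style) choice and guarantees
the richness constraint exactly. Renormalizing the read weights over the
selected taxa (rather than leaving probability mass on unselected pool
taxa) is this package's choice; the alternative is not equivalent and is
deliberately not implemented.

`qRC = (n_less + 0.5·n_equal)/N_TOT` with a tie tolerance of 1e-10 on
`|qd_exp − qd_obs|`. At `q = 0` dissimilarities take few discrete
values, so ties are real and frequent; strict float equality would
undercount them, biasing `qRC` away from 0.5 for incidence comparisons.
Defaults: 199 randomizations, frequency scheme. The assembly draws do
not depend on `q`, so one set of null assemblies is shared across a
whole `q` grid and is bit-identical to recomputing each order separately
under the same seed. Under self-null calibration (observed pairs drawn
from the null itself) `qRC` is approximately uniform on [0, 1], which
the suite checks with a Kolmogorov–Smirnov test. A linear rescaling
`2(qRC − 0.5)` onto [−1, 1] is provided for compatibility with the
older convention.

Each pair in a multi-pair run gets an independent child stream spawned
from the user seed, so adding or removing pairs never reshuffles the
draws of other pairs.

## Consensus tables

Matching across tables defaults to exact sequence equality after
uppercasing — the conservative reading of "detected in all tables".
Because pipelines trim reads differently, a `subsequence` mode treats
containment of one sequence in the other as a match, and an
`edit_distance` mode accepts Levenshtein distance ≤ k (via edlib,
default k = 0). Ambiguous multi-matches resolve to the minimal distance,
then the higher read count, and are logged; a taxon already claimed by
an earlier group cannot be claimed twice. Read fractions are computed on
raw counts, before any rarefaction, since the merge is a detection
filter, not an abundance statement. Fraction ties retain the table with
fewer taxa (the stronger filter), then the first by input order —
deterministic and logged. Identifier-based matching is available for
tables that already share an id space, but tables lacking sequences fail
loudly rather than silently falling back.

## Rarefaction and the depth simulation

Rarefaction draws each sample's reads without replacement
(multivariate hypergeometric per column), so every column sums exactly
to the target depth and no cell ever exceeds its original count. It is a
single stored-seed draw, not an average over draws. Sampling without
replacement is the standard choice for subsampling reads that were
actually observed; with-replacement resampling is reserved for the depth
simulation, where it correctly models re-sequencing a community.

The depth simulation draws `replicates` multinomial samples per depth
from a fixed truth distribution, so the true inter-replicate
dissimilarity is zero by construction and everything measured is
sampling noise. The default truth for demonstrations is a lognormal
rank-abundance curve (`S` taxa, shape `sigma`); `sigma = 0` degenerates
to a uniform community and larger `sigma` lowers evenness
monotonically. The default depth ladder is {10⁴, 3·10⁴, 10⁵, 3·10⁵,
10⁶}; the acceptance test uses {10⁴, 10⁵, 3·10⁵} with a 919-taxon,
`sigma = 2` truth and 6 replicates, which reproduces the qualitative
undersampling fingerprint (incidence dissimilarity far above zero and
decreasing with depth, dominance-weighted dissimilarity small at every
depth) at desk scale.

What the generators do *not* emulate: PCR/sequencing error (spurious
ASVs), chimeras, copy-number variation, or compositional biases between
extraction and sequencing. Passing tests therefore demonstrate the
sampling-theoretic behaviour of the indices, not robustness to
error-generating processes.

## Permutation statistics

Both tests use the +1-corrected p-value
`(count of permuted statistics ≥ observed + 1)/(permutations + 1)`,
which counts the observed arrangement among the permutations and cannot
be zero; with the default 999 permutations the smallest attainable p is
0.001. Mantel correlates the condensed upper triangles (Pearson default;
Spearman rank-transforms the condensed values first) and permutes rows
and columns of one matrix simultaneously; the test is one-sided for
positive association. Permanova is the one-way pseudo-F computed
directly from squared dissimilarities (Gower-centred form); group labels
are permuted. If all within-group distances are zero the pseudo-F is
infinite, which compares correctly against permuted values. Matrices
over the same sample set but different orderings are aligned
automatically; different sample sets raise. Both statistics are verified
in the test suite against scikit-bio's implementations on random
matrices, and their type-I error is checked by simulation.

## Structured toy table

The eight-sample structured table makes the index behaviours inspectable
by hand. Classes use per-taxon abundances (a, i, r) = (0.25, 0.075,
0.025) by default, constrained by `2a + 4i + 8r = 1` and `a > i > r > 0`;
cell counts must come out integral at the chosen depth (default 1000),
otherwise construction refuses rather than rounding. S4 reuses S0's taxa
under the distinct scheme (0.2, 0.1, 0.025) so that the Bray–Curtis/`¹d`
identity visibly fails when the distributions differ. The mutual overlap
among S1–S3 is not fixed by the published description; here their
non-S0 taxa are unique to each sample, which the generator documents and
its self-check enforces. S5–S7 split their reads equally between their
two taxa. Every sharing count and class size is asserted by a self-check
before the table is returned.

## Known limitations

* Phylogenetic and functional Hill indices (tree- or distance-weighted)
  are out of scope.
* Only one-way permanova is provided; no multi-factor or stratified
  designs, and no dispersion test.
* The null model implements the frequency/abundance randomization family
  only; fixed-fixed swap algorithms and beta-null-deviation metrics are
  not included.
* Consensus merging reconciles detection, not abundance: counts always
  come from the single retained table.
* Rarefaction is a single draw; repeated-rarefaction averaging is left
  to the caller.
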