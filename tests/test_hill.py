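import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hillbeta import (
    ValidationError,
    bray_curtis,
    decompose,
    dissimilarity_matrix,
    dissimilarity_profile,
    hill_number,
    jaccard,
    local_dissimilarity,
    pair_dissimilarity,
    regional_dissimilarity,
    sorensen,
    to_relative_abundance,
)
from hillbeta.hill import DEFAULT_Q_GRID, DissimilarityMatrix

from oracles import brute_decompose, brute_hill, brute_local, brute_regional


class TestHillNumber:
    @pytest.mark.parametrize("q", [0.0, 0.5, 1.0, 2.0, 3.5])
    def test_uniform_community_gives_richness(self, q):
        p = np.full(8, 1 / 8)
        assert hill_number(p, q) == pytest.approx(8.0, abs=1e-10)

    def test_richness_at_q0(self):
        assert hill_number([0.5, 0.25, 0.25], 0) == pytest.approx(3.0)

    def test_inverse_simpson_at_q2(self):
        # 1 / (0.25 + 0.0625 + 0.0625)
        assert hill_number([0.5, 0.25, 0.25], 2) == pytest.approx(8 / 3, abs=1e-12)

    def test_zero_abundance_taxa_excluded_at_every_q(self):
        for q in (0, 0.5, 1, 2):
            assert hill_number([0.5, 0.5, 0.0], q) == pytest.approx(
                hill_number([0.5, 0.5], q), abs=1e-12
            )

    def test_negative_order_rejected(self):
        with pytest.raises(ValidationError):
            hill_number([1.0], -0.5)

    @given(
        weights=st.lists(st.integers(min_value=0, max_value=20), min_size=2,
                         max_size=10).filter(lambda w: sum(w) > 0),
        q=st.sampled_from([0.0, 0.5, 1.0, 2.0]),
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounded_by_richness_and_label_invariant(self, weights, q):
        p = np.array(weights, float) / sum(weights)
        d = hill_number(p, q)
        s = int((p > 0).sum())
        assert 1 - 1e-9 <= d <= s + 1e-9
        perm = np.random.default_rng(0).permutation(len(p))
        assert hill_number(p[perm], q) == pytest.approx(d, abs=1e-12)


class TestDecompose:
    @pytest.mark.parametrize("q", [0.0, 0.5, 1.0, 2.0])
    def test_identical_samples_beta_one(self, q):
        p = np.array([0.5, 0.3, 0.2])
        dec = decompose([p, p], q)
        assert dec.beta == pytest.approx(1.0, abs=1e-12)
        assert local_dissimilarity(dec) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("q", [0.0, 0.5, 1.0, 2.0])
    def test_disjoint_samples_beta_n(self, q):
        p1 = np.array([0.6, 0.4, 0.0, 0.0])
        p2 = np.array([0.0, 0.0, 0.7, 0.3])
        dec = decompose([p1, p2], q)
        assert dec.beta == pytest.approx(2.0, abs=1e-12)
        assert local_dissimilarity(dec) == pytest.approx(1.0, abs=1e-12)
        assert regional_dissimilarity(dec) == pytest.approx(1.0, abs=1e-12)

    def test_structured_pair_richness_decomposition(self, structured):
        """21 pooled taxa over two 14-taxon samples sharing 7 gives beta 1.5."""
        p0 = to_relative_abundance(structured, "S0")
        p1 = to_relative_abundance(structured, "S1")
        dec = decompose([p0.p, p1.p], 0)
        assert dec.gamma == pytest.approx(21.0, abs=1e-9)
        assert dec.alpha == pytest.approx(14.0, abs=1e-9)
        assert dec.beta == pytest.approx(1.5, abs=1e-12)

    def test_single_community_rejected(self):
        with pytest.raises(ValidationError):
            decompose([np.array([1.0])], 1)

    def test_alpha_never_exceeds_gamma(self, rng):
        for _ in range(20):
            P = rng.dirichlet(np.full(6, 0.5), size=3).T
            for q in (0, 0.5, 1, 2):
                dec = decompose(P, q)
                assert dec.alpha <= dec.gamma + 1e-9
                assert 1 - 1e-9 <= dec.beta <= dec.N + 1e-9


class TestTransforms:
    @pytest.mark.parametrize("q", [0.0, 0.5, 1.0, 2.0])
    @pytest.mark.parametrize("transform", [local_dissimilarity, regional_dissimilarity])
    def test_endpoints(self, q, transform):
        from hillbeta.hill import HillDecomposition

        assert transform(HillDecomposition(q, 2, 1.0, 1.0, 1.0)) == pytest.approx(0.0)
        assert transform(HillDecomposition(q, 2, 1.0, 2.0, 2.0)) == pytest.approx(1.0)

    def test_regional_direct_evaluation(self):
        from hillbeta.hill import HillDecomposition

        # (1.5 - 1) / (2 - 1) at q=2, N=2
        dec = HillDecomposition(2.0, 2, 1.0, 1.5, 1.5)
        assert regional_dissimilarity(dec) == pytest.approx(0.5, abs=1e-12)

    def test_shared_equal_abundance_identity(self):
        """Two samples of S equally common taxa sharing C give qd = 1 - C/S."""
        S, C = 10, 4
        universe = S + (S - C)
        p1 = np.zeros(universe)
        p1[:S] = 1 / S
        p2 = np.zeros(universe)
        p2[:C] = 1 / S
        p2[S:] = 1 / S
        for q in (0, 0.5, 1, 2):
            d = pair_dissimilarity(p1, p2, "local", q)
            assert d == pytest.approx(1 - C / S, abs=1e-10)

    def test_continuity_at_q_one(self, rng):
        for _ in range(20):
            P = rng.dirichlet(np.full(8, 0.5), size=2).T
            for index in ("local", "regional"):
                mid = pair_dissimilarity(P[:, 0], P[:, 1], index, 1.0)
                lo = pair_dissimilarity(P[:, 0], P[:, 1], index, 1.0 - 1e-6)
                hi = pair_dissimilarity(P[:, 0], P[:, 1], index, 1.0 + 1e-6)
                assert abs(lo - mid) < 1e-5
                assert abs(hi - mid) < 1e-5


class TestClassicIndices:
    def test_identical_samples_zero(self):
        p = np.array([0.5, 0.3, 0.2])
        assert jaccard(p, p) == 0
        assert sorensen(p, p) == 0
        assert bray_curtis(p, p) == 0

    def test_disjoint_samples_one(self):
        x = np.array([0.5, 0.5, 0.0, 0.0])
        y = np.array([0.0, 0.0, 0.5, 0.5])
        assert jaccard(x, y) == 1
        assert sorensen(x, y) == 1
        assert bray_curtis(x, y) == 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            jaccard(np.zeros(3), np.array([1, 0, 0]))

    @pytest.mark.parametrize("q", [0.0])
    def test_q0_equivalences_random_incidence(self, rng, q):
        """At q=0 local equals Sorensen and regional equals Jaccard exactly."""
        for _ in range(50):
            x = rng.integers(0, 2, size=12)
            y = rng.integers(0, 2, size=12)
            if x.sum() == 0 or y.sum() == 0:
                continue
            px, py = x / x.sum(), y / y.sum()
            dec = decompose([px, py], q)
            assert local_dissimilarity(dec) == pytest.approx(
                sorensen(px, py), abs=1e-12)
            assert regional_dissimilarity(dec) == pytest.approx(
                jaccard(px, py), abs=1e-12)


def matched_distribution_pair(rng, n_shared, n_unique):
    """Two samples with equal abundance distributions whose shared taxa have
    identical relative abundance in both; unique taxa carry the same value
    multiset on disjoint taxon sets."""
    shared = rng.uniform(0.2, 1.0, size=n_shared)
    unique = rng.uniform(0.2, 1.0, size=n_unique)
    total = shared.sum() + unique.sum()
    shared, unique = shared / total, unique / total
    size = n_shared + 2 * n_unique
    p1 = np.zeros(size)
    p2 = np.zeros(size)
    p1[:n_shared] = shared
    p2[:n_shared] = shared
    p1[n_shared:n_shared + n_unique] = unique
    p2[n_shared + n_unique:] = unique
    return p1, p2


class TestBrayCurtisTheorem:
    def test_equals_d1_on_matched_distributions(self, rng):
        for _ in range(50):
            p1, p2 = matched_distribution_pair(
                rng, rng.integers(1, 6), rng.integers(1, 6))
            bc = bray_curtis(p1, p2)
            d1 = pair_dissimilarity(p1, p2, "local", 1.0)
            assert bc == pytest.approx(d1, abs=1e-10)

    def test_generally_differs_on_unmatched_pairs(self, rng):
        diffs = 0
        for _ in range(50):
            P = rng.dirichlet(np.full(8, 0.5), size=2)
            bc = bray_curtis(P[0], P[1])
            d1 = pair_dissimilarity(P[0], P[1], "local", 1.0)
            diffs += abs(bc - d1) > 1e-6
        assert diffs > 25

    def test_structured_s4_breaks_the_identity(self, structured):
        """S4 shares all of S0's taxa but with a different distribution."""
        p0 = to_relative_abundance(structured, "S0")
        p4 = to_relative_abundance(structured, "S4")
        assert abs(bray_curtis(p0, p4)
                   - pair_dissimilarity(p0, p4, "local", 1.0)) > 1e-4


class TestBruteForceOracle:
    """Two-route agreement with literal formula transcriptions."""

    Q_VALUES = (0.0, 0.5, 1.0, 2.0)

    def _assert_agreement(self, c1, c2):
        p1 = np.array(c1, float) / sum(c1)
        p2 = np.array(c2, float) / sum(c2)
        for q in self.Q_VALUES:
            assert hill_number(p1, q) == pytest.approx(
                brute_hill(p1, q), abs=1e-12, rel=1e-12)
            alpha, gamma, beta = brute_decompose([list(p1), list(p2)], q)
            dec = decompose([p1, p2], q)
            assert dec.alpha == pytest.approx(alpha, abs=1e-12, rel=1e-12)
            assert dec.gamma == pytest.approx(gamma, abs=1e-12, rel=1e-12)
            assert dec.beta == pytest.approx(beta, abs=1e-12, rel=1e-12)
            assert local_dissimilarity(dec) == pytest.approx(
                brute_local(beta, 2, q), abs=1e-12)
            assert regional_dissimilarity(dec) == pytest.approx(
                brute_regional(beta, 2, q), abs=1e-12)

    def test_exhaustive_two_taxon_tables(self):
        for c1 in itertools.product(range(7), repeat=2):
            if sum(c1) == 0:
                continue
            for c2 in itertools.product(range(7), repeat=2):
                if sum(c2) == 0:
                    continue
                self._assert_agreement(c1, c2)

    def test_sampled_larger_tables(self, rng):
        for _ in range(300):
            n = rng.integers(3, 6)
            c1 = rng.integers(0, 7, size=n)
            c2 = rng.integers(0, 7, size=n)
            if c1.sum() == 0 or c2.sum() == 0:
                continue
            self._assert_agreement(list(c1), list(c2))


class TestPairwiseMatrix:
    def test_two_sample_matrix(self, structured):
        t = structured.subset_samples(["S0", "S1"])
        dm = dissimilarity_matrix(t, "local", 0)
        assert dm.values[0, 1] == pytest.approx(0.5)
        assert dm.values[0, 0] == 0 == dm.values[1, 1]

    def test_sample_permutation_permutes_matrix(self, structured):
        dm = dissimilarity_matrix(structured, "local", 1.0)
        perm = ["S3", "S0", "S7", "S1", "S5", "S2", "S6", "S4"]
        dm2 = dissimilarity_matrix(structured.subset_samples(perm), "local", 1.0)
        assert np.allclose(dm.reorder(perm).values, dm2.values)

    def test_matrix_matches_per_pair_values(self, structured):
        dm = dissimilarity_matrix(structured, "local", 0)
        for i, a in enumerate(dm.sample_ids):
            for j, b in enumerate(dm.sample_ids):
                if i >= j:
                    continue
                pa = to_relative_abundance(structured, a)
                pb = to_relative_abundance(structured, b)
                assert dm.values[i, j] == pytest.approx(
                    pair_dissimilarity(pa, pb, "local", 0), abs=1e-12)

    def test_zero_read_sample_named_in_error(self, structured):
        from hillbeta import CountTable

        df = structured.counts.copy()
        df["empty"] = 0
        with pytest.raises(ValidationError, match="empty"):
            dissimilarity_matrix(CountTable(df), "local", 1.0)

    def test_classic_index_has_no_q(self, structured):
        dm = dissimilarity_matrix(structured, "jaccard")
        assert dm.q is None

    def test_matrix_tsv_round_trip(self, tmp_path, structured):
        dm = dissimilarity_matrix(structured, "local", 1.0)
        path = tmp_path / "m.tsv"
        dm.write_tsv(path)
        back = DissimilarityMatrix.read_tsv(path, "local_hill", 1.0)
        assert back.sample_ids == dm.sample_ids
        assert np.allclose(back.values, dm.values, atol=1e-10)


class TestProfile:
    def test_replicate_pair_count(self, rng):
        from hillbeta import make_lognormal_community, make_replicate_tables

        truth = make_lognormal_community(50, 1.0, seed=4)
        t = make_replicate_tables(truth, 6, 2000, seed=5)
        pairs = list(itertools.combinations(t.sample_ids, 2))
        prof = dissimilarity_profile(t, pairs, [0, 1, 2])
        assert prof.pair_count == 15
        assert prof.values.shape == (15, 3)

    def test_single_pair_sd_zero(self, structured):
        prof = dissimilarity_profile(structured, [("S0", "S2")], [0, 1, 2])
        assert np.all(prof.sd == 0)

    def test_structured_pair_flat_at_half(self, structured):
        prof = dissimilarity_profile(structured, [("S0", "S1")], DEFAULT_Q_GRID)
        assert np.allclose(prof.mean, 0.5, atol=1e-9)

    def test_empty_grid_rejected(self, structured):
        with pytest.raises(ValidationError):
            dissimilarity_profile(structured, [("S0", "S1")], [])
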