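"""NoB-LoC components: marginal likelihoods, partitions, Gibbs updates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import integrate
from scipy import stats as sps

from protstoich import biclust
from protstoich.biclust import (
    BiclusterPartition,
    GibbsState,
    MCMCTrace,
    PriorSettings,
    block_marginal_loglik,
    coclustering_indicator,
    enumerate_posterior,
    enumerate_sample_coassignment,
    gibbs_update_protein,
    gibbs_update_samples,
    init_partition,
    least_squares_partition,
    partition_distance,
    posterior_coclustering,
    run_mcmc,
    summarize_partition,
)

partition_strategy = hst.lists(hst.integers(min_value=0, max_value=3), min_size=2, max_size=8)


def normalize_labels(raw):
    """Map arbitrary positive labels to contiguous 1..K, keeping 0."""
    out = np.zeros(len(raw), dtype=int)
    seen = {}
    for i, v in enumerate(raw):
        if v > 0:
            out[i] = seen.setdefault(v, len(seen) + 1)
    return out


class TestBlockMarginalLoglik:
    def test_empty_block_is_log_one(self):
        assert block_marginal_loglik([]) == 0.0

    @pytest.mark.parametrize("y", [-2.0, -0.3, 0.0, 0.7, 3.5])
    def test_single_value_matches_student_t(self, y):
        pr = PriorSettings(m0=0.0, k0=1.0, a0=1.0, b0=1.0)
        scale = math.sqrt(pr.b0 * (pr.k0 + 1) / (pr.a0 * pr.k0))
        expected = sps.t.logpdf(y, df=2 * pr.a0, loc=pr.m0, scale=scale)
        assert block_marginal_loglik([y], pr) == pytest.approx(expected, abs=1e-8)

    def test_matches_numerical_integration(self):
        """Two-value marginal agrees with direct quadrature over (mu, var)."""
        pr = PriorSettings(m0=0.5, k0=2.0, a0=3.0, b0=1.5)
        ys = np.array([0.2, 1.1])

        def integrand(var, mu):
            lik = np.prod(sps.norm.pdf(ys, mu, np.sqrt(var)))
            p_mu = sps.norm.pdf(mu, pr.m0, np.sqrt(var / pr.k0))
            p_var = sps.invgamma.pdf(var, pr.a0, scale=pr.b0)
            return lik * p_mu * p_var

        val, _ = integrate.dblquad(integrand, -8, 8, 0.001, 60)
        assert block_marginal_loglik(ys, pr) == pytest.approx(math.log(val), abs=1e-5)

    def test_concentrated_beats_dispersed(self):
        pr = PriorSettings()
        same = block_marginal_loglik([1.0, 1.0], pr)
        far = block_marginal_loglik([-3.0, 5.0], pr)
        assert same > far

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            PriorSettings(a0=-1.0)


class TestCoclusteringIndicator:
    def test_hand_enumeration(self):
        d = coclustering_indicator(np.array([1, 1, 2]))
        assert d[0, 1] == 1 and d[0, 2] == 0 and d[1, 2] == 0
        assert np.array_equal(d, d.T) and (np.diag(d) == 1).all()

    def test_all_invariant_all_ones(self):
        assert coclustering_indicator(np.zeros(4, int)).all()

    def test_label_permutation_invariance(self):
        a = np.array([1, 2, 2, 0, 1])
        b = np.array([2, 1, 1, 0, 2])
        assert np.array_equal(coclustering_indicator(a), coclustering_indicator(b))


class TestPartitionDistance:
    def test_identity_zero(self):
        om = np.array([1, 2, 2, 0])
        assert partition_distance(om, om) == 0

    def test_hand_examples(self):
        assert partition_distance([1, 1, 2], [1, 2, 2]) == 2
        assert partition_distance([1, 1, 2, 0], [1, 2, 2, 0]) == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            partition_distance([1, 2], [1, 2, 3])

    @settings(deadline=None, max_examples=60)
    @given(partition_strategy, partition_strategy, partition_strategy)
    def test_pseudo_metric_axioms(self, a, b, c):
        n = min(len(a), len(b), len(c))
        a, b, c = (np.array(x[:n]) for x in (a, b, c))
        ab = partition_distance(a, b)
        assert ab >= 0
        assert ab == partition_distance(b, a)
        assert ab <= partition_distance(a, c) + partition_distance(c, b)


class TestLeastSquaresPartition:
    def trace_of(self, omegas):
        parts = []
        for om in omegas:
            om = np.asarray(om)
            K = om.max(initial=0)
            parts.append(BiclusterPartition(om, {k: np.ones(2, int) for k in range(1, K + 1)}))
        return MCMCTrace(parts, len(parts), 0, 1, 0, [0.0] * len(parts))

    def test_identical_trace(self):
        tr = self.trace_of([[1, 1, 2]] * 3)
        est, dist = least_squares_partition(tr)
        assert np.array_equal(est.omega, [1, 1, 2]) and np.allclose(dist, 0.0)

    def test_majority_wins(self):
        A = [1, 1, 2, 2]
        B = [1, 2, 1, 2]
        assert partition_distance(A, B) == 4
        est, _ = least_squares_partition(self.trace_of([A, A, B]))
        assert np.array_equal(est.omega, A)

    def test_matches_exhaustive_minimization(self):
        rng = np.random.default_rng(9)
        omegas = [normalize_labels(rng.integers(0, 3, size=6)) for _ in range(5)]
        est, _ = least_squares_partition(self.trace_of(omegas))
        costs = [sum(partition_distance(a, b) for b in omegas) for a in omegas]
        assert np.array_equal(est.omega, omegas[int(np.argmin(costs))])

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            least_squares_partition(MCMCTrace([], 0, 0, 1, 0, []))


class TestSummarize:
    def test_example(self):
        p = BiclusterPartition(np.array([0, 1, 1, 2]), {1: np.ones(3, int), 2: np.ones(3, int)})
        s = summarize_partition(p)
        assert s["n_biclusters"] == 2 and s["n_invariant"] == 1
        assert s["bicluster_sizes"] == {1: 2, 2: 1}

    def test_all_invariant(self):
        s = summarize_partition(BiclusterPartition(np.zeros(5, int), {}))
        assert s["n_biclusters"] == 0 and s["n_invariant"] == 5

    def test_planted_roundtrip(self, planted):
        _, st = planted
        p = BiclusterPartition(
            st.protein_membership.copy(),
            {k: st.sample_partitions[k].copy() for k in st.biclusters},
        )
        s = summarize_partition(p)
        assert s["n_biclusters"] == 3 and s["n_invariant"] == 15


class TestInitPartition:
    def test_two_separated_blocks(self):
        rng = np.random.default_rng(0)
        X = np.vstack([
            rng.normal(0, 0.1, (5, 6)) + np.array([3, 3, 3, -3, -3, -3]),
            rng.normal(0, 0.1, (5, 6)) + np.array([-3, -3, -3, 3, 3, 3]),
        ])
        p = init_partition(X, n_variant_sets=2)
        assert p.n_biclusters == 2 and p.n_invariant == 0
        assert len(set(p.omega[:5])) == 1 and len(set(p.omega[5:])) == 1

    def test_outlier_becomes_invariant(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (6, 4)), np.full((1, 4), 50.0)])
        p = init_partition(X, n_variant_sets=2)
        assert p.omega[-1] == 0

    def test_matches_reference_agglomerative(self):
        """Cutting the average-linkage tree agrees with scikit-learn's
        agglomerative clustering on the same data."""
        from sklearn.cluster import AgglomerativeClustering

        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (12, 5)) + np.repeat([[0], [4], [8]], 4, axis=0)
        p = init_partition(X, n_variant_sets=3)
        ref = AgglomerativeClustering(n_clusters=3, metric="euclidean", linkage="average").fit(X)
        assert biclust.recovery_ari(ref.labels_, p.omega) == 1.0

    def test_initial_sample_partition_single_subcluster(self):
        X = np.random.default_rng(3).normal(0, 1, (6, 4)) + np.repeat([[0], [5]], 3, axis=0)
        p = init_partition(X, n_variant_sets=2)
        for k in range(1, p.n_biclusters + 1):
            assert (p.sample_partitions[k] == 1).all()


class TestGibbsUpdates:
    def test_pi0_limit_forces_invariant(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(0, 1, (5, 6))
        pr = PriorSettings(pi0=1e-12)
        tr = run_mcmc(Y, pr, n_iter=20, burn_in=10, seed=1, standardize=False)
        assert all(p.n_biclusters == 0 for p in tr.partitions)

    def test_pi0_sample_one_keeps_all_samples_active(self):
        rng = np.random.default_rng(1)
        Y = np.vstack([rng.normal(3, 0.1, (4, 6)), rng.normal(-3, 0.1, (4, 6))])
        pr = PriorSettings(pi0=1.0, pi0_sample=1.0)
        tr = run_mcmc(Y, pr, n_iter=30, burn_in=20, seed=2, standardize=False)
        for p in tr.partitions:
            for part in p.sample_partitions.values():
                assert (part > 0).all()

    def test_single_bicluster_limit(self):
        """pi0=1 with tiny alpha on identical noise-free rows collapses to
        one bicluster."""
        Y = np.tile(np.array([1.0, -1.0, 1.0, -1.0]), (5, 1))
        pr = PriorSettings(pi0=1.0, alpha_protein=1e-8)
        tr = run_mcmc(Y, pr, n_iter=30, burn_in=20, seed=3, standardize=False)
        assert all(p.n_biclusters == 1 for p in tr.partitions)

    def test_strong_member_joins_its_bicluster(self):
        """A protein identical to a bicluster's members is assigned there
        with high empirical frequency."""
        rng = np.random.default_rng(4)
        pattern = np.array([2.0] * 3 + [-2.0] * 3)
        Y = np.vstack([pattern + rng.normal(0, 0.05, 6) for _ in range(4)]
                      + [rng.normal(0, 1.0, (3, 6))])
        pr = PriorSettings(pi0=0.5)
        tr = run_mcmc(Y, pr, n_iter=200, burn_in=50, seed=5, standardize=False)
        freq = np.mean([
            p.omega[0] > 0 and p.omega[0] == p.omega[1] == p.omega[2] == p.omega[3]
            for p in tr.partitions
        ])
        assert freq >= 0.95

    def test_same_seed_identical_traces(self):
        Y = np.random.default_rng(6).normal(0, 1, (6, 5))
        a = run_mcmc(Y, n_iter=25, burn_in=5, seed=42, standardize=False)
        b = run_mcmc(Y, n_iter=25, burn_in=5, seed=42, standardize=False)
        for pa, pb in zip(a.partitions, b.partitions):
            assert np.array_equal(pa.omega, pb.omega)
            for k in pa.sample_partitions:
                assert np.array_equal(pa.sample_partitions[k], pb.sample_partitions[k])
        assert a.loglik_trace == b.loglik_trace

    def test_n_iter_must_exceed_burnin(self):
        with pytest.raises(ValueError, match="burn_in"):
            run_mcmc(np.zeros((3, 3)), n_iter=10, burn_in=10, seed=0)

    def test_protein_coclustering_matches_enumeration(self):
        """Sampler co-clustering frequencies agree with the exact
        zero-enriched posterior on a 3×3 instance (±0.05)."""
        Y = np.array([[1.0, -1.2, 0.3], [0.9, -1.0, 0.4], [-0.8, 0.9, -1.5]])
        pr = PriorSettings(pi0=0.4, pi0_sample=0.6)
        exact = enumerate_posterior(Y, pr)["coclustering"]
        tr = run_mcmc(Y, pr, n_iter=6000, burn_in=1000, seed=7,
                      init="all_invariant", standardize=False, sample_init="single")
        est = posterior_coclustering(tr)
        assert np.abs(est - exact).max() < 0.05

    def test_sample_coassignment_matches_enumeration(self):
        """Sample-subcluster co-assignment inside a fixed 2-protein
        bicluster agrees with enumeration (±0.05)."""
        Y = np.array([[1.5, 1.4, -1.6], [1.3, 1.6, -1.4]])
        pr = PriorSettings(pi0_sample=0.5)
        exact = enumerate_sample_coassignment(Y, pr)
        part = BiclusterPartition(np.array([1, 1]), {1: np.ones(3, int)})
        state = GibbsState(Y, part)
        rng = np.random.default_rng(8)
        co = np.zeros((3, 3))
        n_keep = 0
        for it in range(6000):
            gibbs_update_samples(1, state, pr, rng)
            if it >= 1000:
                lab = state.parts[0]
                co += lab[:, None] == lab[None, :]
                n_keep += 1
        assert np.abs(co / n_keep - exact).max() < 0.05

    def test_zero_noise_two_sample_levels_recovered(self):
        Y = np.tile(np.array([2.0, 2.0, -2.0, -2.0]), (4, 1))
        pr = PriorSettings(pi0=1.0, pi0_sample=0.9)
        tr = run_mcmc(Y, pr, n_iter=60, burn_in=40, seed=9, standardize=False)
        modal = tr.partitions[-1]
        part = modal.sample_partitions[1]
        assert part[0] == part[1] and part[2] == part[3] and part[0] != part[2]


class TestLabelInvariance:
    def test_relabeling_changes_nothing(self):
        om = np.array([1, 1, 2, 0, 2])
        relab = np.array([2, 2, 1, 0, 1])
        assert partition_distance(om, relab) == 0
        sa, sb = (summarize_partition(
            BiclusterPartition(o, {1: np.ones(2, int), 2: np.ones(2, int)})
        ) for o in (om, relab))
        assert sa["n_biclusters"] == sb["n_biclusters"]
        assert sa["n_invariant"] == sb["n_invariant"]
        assert sorted(sa["bicluster_sizes"].values()) == sorted(sb["bicluster_sizes"].values())


class TestThinning:
    def test_thinned_trace_length(self):
        Y = np.random.default_rng(10).normal(0, 1, (4, 4))
        tr = run_mcmc(Y, n_iter=30, burn_in=10, thin=5, seed=11, standardize=False)
        assert len(tr.partitions) == 4
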