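import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isopanel import hmm
from isopanel.io_variants import WindowCounts, WindowGrid
from oracles import best_path_exhaustive, posterior_exhaustive


def params2(lam=(0.5, 20.0), stay=0.99):
    A = np.array([[stay, 1 - stay], [1 - stay, stay]])
    return hmm.PoissonHMMParams(np.array([0.5, 0.5]), A, np.array(lam))


def wc_from_counts(counts, window_size=10_000, sample_ids=None):
    counts = np.asarray(counts)
    if counts.ndim == 1:
        counts = counts[None, :]
    n, t = counts.shape
    grid = WindowGrid(window_size, {"chr1": t * window_size})
    ids = sample_ids or [f"l{i}" for i in range(n)]
    return WindowCounts(grid, ids, counts, np.full_like(counts, 10**6))


class TestParams:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            hmm.PoissonHMMParams([0.5, 0.5], [[0.9, 0.2], [0.1, 0.9]], [1, 2])

    def test_rates_must_ascend(self):
        with pytest.raises(ValueError, match="ascending"):
            hmm.PoissonHMMParams([0.5, 0.5], np.eye(2), [2.0, 1.0])

    def test_relabel_sorts_by_rate(self):
        p = hmm.PoissonHMMParams([0.3, 0.7], [[0.8, 0.2], [0.4, 0.6]], [1.0, 5.0])
        # permute then relabel: must restore ascending order and permute A
        perm = hmm.PoissonHMMParams.__new__(hmm.PoissonHMMParams)
        perm.pi0, perm.A, perm.lam = p.pi0[::-1], p.A[::-1, ::-1], p.lam[::-1]
        back = perm.relabelled()
        np.testing.assert_allclose(back.lam, p.lam)
        np.testing.assert_allclose(back.A, p.A)
        np.testing.assert_allclose(back.pi0, p.pi0)


class TestViterbi:
    @pytest.mark.parametrize("K,max_T,n_trials", [(2, 12, 40), (4, 7, 20)])
    def test_matches_exhaustive_argmax(self, K, max_T, n_trials):
        rng = np.random.default_rng(100 + K)
        for _ in range(n_trials):
            T = int(rng.integers(2, max_T + 1))
            lam = np.sort(rng.uniform(0.1, 25.0, K))
            A = rng.dirichlet(np.ones(K) * rng.uniform(0.3, 5), size=K)
            pi0 = rng.dirichlet(np.ones(K))
            params = hmm.PoissonHMMParams(pi0, A, lam)
            counts = rng.poisson(rng.choice(lam, T))
            wc = wc_from_counts(counts, sample_ids=["x"])
            path = hmm.viterbi_decode(params, wc, "x").states
            best, best_lp, margin = best_path_exhaustive(counts, pi0, A, lam)
            if margin > 1e-9:
                np.testing.assert_array_equal(path, best)
            # in all cases the decoded path must achieve the optimum
            from oracles import enumerate_paths_logprob
            _, lps = enumerate_paths_logprob(counts, pi0, A, lam)
            from scipy.stats import poisson as pois
            lp_path = (np.log(pi0[path[0]])
                       + sum(np.log(A[path[t - 1], path[t]]) for t in range(1, T))
                       + pois.logpmf(counts, lam[path]).sum())
            assert lp_path == pytest.approx(best_lp, abs=1e-9)

    def test_worked_two_state_example(self):
        params = params2()
        counts = np.array([0, 0, 25, 30, 0, 0])
        wc = wc_from_counts(counts, sample_ids=["x"])
        path = hmm.viterbi_decode(params, wc, "x").states
        np.testing.assert_array_equal(path, [0, 0, 1, 1, 0, 0])
        best, _, _ = best_path_exhaustive(counts, params.pi0, params.A, params.lam)
        np.testing.assert_array_equal(path, best)

    def test_tie_breaks_toward_lower_state(self):
        # identical rates and uniform transitions: every path is equally
        # likely, so the decoder must return all state 0
        params = hmm.PoissonHMMParams([0.5, 0.5], np.full((2, 2), 0.5), [1.0, 1.0])
        wc = wc_from_counts(np.zeros(6, dtype=int), sample_ids=["x"])
        path = hmm.viterbi_decode(params, wc, "x").states
        np.testing.assert_array_equal(path, np.zeros(6))

    def test_chromosomes_decoded_independently(self):
        params = params2()
        grid = WindowGrid(10_000, {"chr1": 30_000, "chr2": 30_000})
        counts = np.array([[0, 25, 25, 25, 25, 0]])
        wc = WindowCounts(grid, ["x"], counts, np.full_like(counts, 10**5))
        path = hmm.viterbi_decode(params, wc, "x")
        per = path.per_chromosome()
        np.testing.assert_array_equal(per["chr1"], [0, 1, 1])
        np.testing.assert_array_equal(per["chr2"], [1, 1, 0])


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(0, 2**32 - 1), st.integers(2, 10))
def test_viterbi_optimality_property(seed, T):
    """The decoded path always attains the exhaustive-path maximum."""
    rng = np.random.default_rng(seed)
    lam = np.sort(rng.uniform(0.1, 20.0, 2))
    A = rng.dirichlet([1.0, 1.0], size=2)
    pi0 = rng.dirichlet([1.0, 1.0])
    params = hmm.PoissonHMMParams(pi0, A, lam)
    counts = rng.poisson(rng.choice(lam, T))
    path = hmm.viterbi_decode(params, wc_from_counts(counts, sample_ids=["x"]),
                              "x").states
    _, best_lp, _ = best_path_exhaustive(counts, pi0, A, lam)
    from scipy.stats import poisson as pois
    lp = (np.log(pi0[path[0]])
          + sum(np.log(A[path[t - 1], path[t]]) for t in range(1, T))
          + pois.logpmf(counts, lam[path]).sum())
    assert lp == pytest.approx(best_lp, abs=1e-9)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.integers(0, 3), min_size=1, max_size=40),
       st.integers(1, 3))
def test_blocks_round_trip_property(states, n_chrom_windows):
    """Run-length encoding to blocks and back reproduces any state path."""
    n = len(states)
    grid = WindowGrid(10_000, {"chr1": n * 10_000})
    path = hmm.StatePath("x", grid, np.array(states))
    blocks = hmm.states_to_blocks(path)
    back = hmm.blocks_to_states(blocks, grid, "x")
    np.testing.assert_array_equal(back.states, path.states)
    df = blocks.for_line("x")
    assert df["start"].iloc[0] == 0 and df["end"].iloc[-1] == n * 10_000
    assert (df["end"] - df["start"] > 0).all()


class TestPosterior:
    def test_sums_to_one(self, small_counts):
        params, _ = hmm.fit_poisson_hmm(small_counts, K=2, seed=0)
        post = hmm.posterior_decode(params, small_counts, small_counts.sample_ids[0])
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_exhaustive_three_windows(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            lam = np.sort(rng.uniform(0.2, 15, 2))
            A = rng.dirichlet([2, 2], size=2)
            pi0 = rng.dirichlet([1, 1])
            params = hmm.PoissonHMMParams(pi0, A, lam)
            counts = rng.poisson(5.0, 3)
            wc = wc_from_counts(counts, sample_ids=["x"])
            post = hmm.posterior_decode(params, wc, "x")
            expect = posterior_exhaustive(counts, pi0, A, lam)
            np.testing.assert_allclose(post, expect, atol=1e-10)

    def test_identical_rates_give_chain_occupancy(self):
        # uninformative emissions: posteriors depend only on pi0 and A
        pi0 = np.array([0.9, 0.1])
        A = np.array([[0.7, 0.3], [0.2, 0.8]])
        params = hmm.PoissonHMMParams(pi0, A, [3.0, 3.0])
        p1 = hmm.posterior_decode(params, wc_from_counts([0, 5, 2], sample_ids=["x"]), "x")
        p2 = hmm.posterior_decode(params, wc_from_counts([9, 9, 9], sample_ids=["x"]), "x")
        np.testing.assert_allclose(p1, p2, atol=1e-12)
        # and equal the marginal occupancy of the Markov chain
        occ = pi0.copy()
        np.testing.assert_allclose(p1[0], occ, atol=1e-12)


class TestFit:
    def test_loglik_nondecreasing_and_recovery(self):
        rng = np.random.default_rng(21)
        true = params2(lam=(0.5, 20.0))
        n_lines, T = 40, 300
        counts = np.empty((n_lines, T), dtype=np.int64)
        for i in range(n_lines):
            s = rng.random() > 0.5
            states = np.empty(T, dtype=int)
            for t in range(T):
                if t:
                    s = s if rng.random() < 0.99 else not s
                states[t] = s
            counts[i] = rng.poisson(true.lam[states])
        wc = wc_from_counts(counts)
        params, trace = hmm.fit_poisson_hmm(wc, K=2, seed=0)
        assert np.all(np.diff(trace) >= -1e-6)
        np.testing.assert_allclose(params.lam, [0.5, 20.0], rtol=0.10)

    def test_constant_counts_degenerate(self):
        wc = wc_from_counts(np.full(50, 7))
        with pytest.warns(UserWarning, match="distinct"):
            params, trace = hmm.fit_poisson_hmm(wc, K=2, seed=0, max_iter=200)
        np.testing.assert_allclose(params.lam, [7.0, 7.0], rtol=0.02)
        # loglik equals the 1-state Poisson model's
        from scipy.stats import poisson
        assert trace[-1] == pytest.approx(poisson.logpmf(7, 7.0) * 50, rel=1e-6)

    def test_all_zero_counts_floor(self):
        wc = wc_from_counts(np.zeros(30, dtype=int))
        with pytest.warns(UserWarning, match="zero"):
            params, _ = hmm.fit_poisson_hmm(wc, K=2, seed=0)
        assert (params.lam > 0).all()

    def test_init_invariance(self, small_counts):
        p_default, _ = hmm.fit_poisson_hmm(small_counts, K=2, seed=0)
        custom = hmm.PoissonHMMParams([0.5, 0.5],
                                      [[0.9, 0.1], [0.1, 0.9]], [0.05, 80.0])
        p_custom, _ = hmm.fit_poisson_hmm(small_counts, K=2, init=custom)
        np.testing.assert_allclose(p_default.lam, p_custom.lam, rtol=0.05)

    def test_rates_match_hmmlearn(self):
        # independent implementation cross-check on the same count data
        hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(33)
        lam_true = np.array([0.5, 18.0])
        states = (rng.random((20, 200)) > 0.6).astype(int)
        # make runs sticky so both fitters see segmented data
        for row in states:
            for t in range(1, len(row)):
                if rng.random() < 0.95:
                    row[t] = row[t - 1]
        counts = rng.poisson(lam_true[states])
        ours, _ = hmm.fit_poisson_hmm(wc_from_counts(counts), K=2, seed=0)
        ref = hmmlearn_hmm.PoissonHMM(n_components=2, random_state=0, n_iter=200)
        ref.fit(counts.reshape(-1, 1), lengths=[200] * 20)
        ref_lam = np.sort(ref.lambdas_.ravel())
        np.testing.assert_allclose(ours.lam, ref_lam, rtol=0.05)

    def test_negative_counts_rejected(self):
        grid = WindowGrid(10, {"chr1": 50})
        with pytest.raises(ValueError):
            WindowCounts(grid, ["x"], -np.ones((1, 5), dtype=int),
                         np.ones((1, 5), dtype=int))


class TestBlocks:
    def test_run_length_encoding(self):
        grid = WindowGrid(10_000, {"chr1": 50_000})
        path = hmm.StatePath("x", grid, np.array([0, 0, 1, 1, 0]))
        blocks = hmm.states_to_blocks(path).for_line("x")
        assert blocks[["start", "end", "state"]].values.tolist() == [
            [0, 20_000, 0], [20_000, 40_000, 1], [40_000, 50_000, 0]]
        assert (np.diff(blocks["state"]) != 0).all()

    def test_single_state_one_block_per_chrom(self):
        grid = WindowGrid(10_000, {"chr1": 30_000, "chr2": 20_000})
        path = hmm.StatePath("x", grid, np.zeros(5, dtype=int))
        blocks = hmm.states_to_blocks(path).for_line("x")
        assert len(blocks) == 2
        assert blocks["end"].tolist() == [30_000, 20_000]

    def test_round_trip(self):
        rng = np.random.default_rng(3)
        grid = WindowGrid(10_000, {"chr1": 120_000, "chr2": 75_000})
        states = rng.integers(0, 3, grid.total_windows)
        path = hmm.StatePath("x", grid, states)
        back = hmm.blocks_to_states(hmm.states_to_blocks(path), grid, "x")
        np.testing.assert_array_equal(back.states, states)

    def test_homozygous_fraction(self):
        grid = WindowGrid(10_000, {"chr1": 40_000, "chr2": 40_000})
        states = np.array([0, 0, 1, 1, 0, 0, 0, 0])  # chr1 half hom, chr2 all hom
        blocks = hmm.states_to_blocks(hmm.StatePath("x", grid, states))
        assert hmm.homozygous_fraction(blocks, "x") == pytest.approx(0.75)
        assert hmm.homozygous_fraction(blocks, "x", {"chr1"}) == pytest.approx(1.0)
        assert hmm.homozygous_fraction(blocks, "x", {"chr2"}) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            hmm.homozygous_fraction(blocks, "x", {"chr1", "chr2"})


class TestHetTracks:
    def test_count_track_examples(self):
        wc = wc_from_counts(np.array([[0], [7], [3]]))
        assert hmm.het_proportion_by_count(wc, 5)[0] == pytest.approx(1 / 3)
        wc0 = wc_from_counts(np.zeros((3, 2), dtype=int))
        np.testing.assert_array_equal(hmm.het_proportion_by_count(wc0, 0), [0, 0])

    def test_count_track_matches_loop(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(4, size=(9, 30))
        wc = wc_from_counts(counts)
        got = hmm.het_proportion_by_count(wc, 5)
        expect = [(counts[:, w] > 5).sum() / 9 for w in range(30)]
        np.testing.assert_allclose(got, expect)

    def test_weighted_track_extremes(self):
        grid = WindowGrid(10_000, {"chr1": 20_000})
        lam = np.array([0.1, 1.0, 5.0, 20.0])
        params = hmm.PoissonHMMParams(np.full(4, 0.25),
                                      np.full((4, 4), 0.25), lam)
        top = [hmm.StatePath(f"l{i}", grid, np.array([3, 0])) for i in range(4)]
        track = hmm.het_proportion_weighted(top, params)
        assert track[0] == pytest.approx(1.0)
        assert track[1] == pytest.approx(0.0)
        half = [hmm.StatePath(f"l{i}", grid, np.array([3 if i < 2 else 0, 0]))
                for i in range(4)]
        assert hmm.het_proportion_weighted(half, params)[0] == pytest.approx(0.5)

    def test_degenerate_rates_error(self):
        params = hmm.PoissonHMMParams([0.5, 0.5], np.eye(2), [2.0, 2.0])
        with pytest.raises(ValueError, match="degenerate"):
            hmm.state_weights(params)


class TestRefineRegion:
    def grid(self, n=100):
        return WindowGrid(10_000, {"chr1": n * 10_000})

    def track(self, weighted):
        weighted = np.asarray(weighted, dtype=float)
        return hmm.HetProportionTrack(self.grid(len(weighted)), "chr1",
                                      np.zeros(len(weighted)), weighted)

    def test_flat_track_empty(self):
        assert hmm.refine_obligate_het_region(self.track(np.full(100, 0.3)),
                                              0.8, 50_000) is None

    def test_longest_run_wins(self):
        w = np.zeros(100)
        w[10:14] = 0.9    # 40 kb
        w[50:60] = 0.9    # 100 kb
        got = hmm.refine_obligate_het_region(self.track(w), 0.8, 50_000)
        assert got == ("chr1", 500_001, 600_000)

    def test_one_based_inclusive_coordinates(self):
        w = np.zeros(100)
        w[0:6] = 1.0
        got = hmm.refine_obligate_het_region(self.track(w), 0.8, 50_000)
        assert got == ("chr1", 1, 60_000)

    def test_min_span_filters_short_runs(self):
        w = np.zeros(100)
        w[10:14] = 1.0
        assert hmm.refine_obligate_het_region(self.track(w), 0.8, 50_000) is None
        assert hmm.refine_obligate_het_region(self.track(w), 0.8, 40_000) is not None
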