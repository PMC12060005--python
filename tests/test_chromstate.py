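"""Binarization, Baum-Welch fitting, decoding and model selection."""

import numpy as np
import pytest

from chromland import hmm
from chromland.core import BinnedTrack, GenomeModel, SampleKey
from chromland.simulate import MARKS, recovery_config, simulate_dataset
from oracles import binarization_threshold, poisson_upper_tail


def _track(values, bin_size=200):
    genome = GenomeModel(chromosomes=[("chr1", len(values) * bin_size)])
    return BinnedTrack(
        "m", SampleKey("f", "head"), bin_size,
        {"chr1": np.asarray(values, float)}, genome,
    )


class TestBinarize:
    @pytest.mark.parametrize("lam", [0.1, 0.5, 1.0, 5.0, 20.0])
    @pytest.mark.parametrize("alpha", [1e-2, 1e-4])
    def test_threshold_matches_tail_sum_oracle(self, lam, alpha):
        assert hmm.poisson_threshold(lam, alpha) == binarization_threshold(lam, alpha)

    def test_worked_tail_examples(self):
        # exact Poisson tails around the alpha = 1e-4 threshold at rate 1
        assert poisson_upper_tail(10, 1.0) < 1e-4
        assert poisson_upper_tail(3, 1.0) > 1e-4
        thr = hmm.poisson_threshold(1.0, 1e-4)
        assert thr <= 10 and thr > 3

    def test_all_zero_track_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="all-zero"):
            cols = hmm.binarize(_track(np.zeros(100)))
        assert cols["chr1"].sum() == 0

    def test_planted_mask_recovered_when_enrichment_is_sparse(self, rng):
        # 5% of bins enriched: threshold stays low, mask error < 1%
        mask = rng.random(50_000) < 0.05
        counts = rng.poisson(np.where(mask, 20.0, 0.5))
        cols = hmm.binarize(_track(counts), hmm.BinarizationConfig(alpha=1e-4))
        err = (cols["chr1"] != mask).mean()
        assert err < 0.01


class TestFitHMM:
    def test_single_state_closed_form(self, rng):
        X = (rng.random((500, 3)) < [0.2, 0.5, 0.8]).astype(np.uint8)
        mat = hmm.BinaryMatrix(["a", "b", "c"], 200, {"chr1": X})
        model = hmm.fit_hmm(mat, 1, n_restarts=1)
        np.testing.assert_allclose(model.transmat, [[1.0]])
        np.testing.assert_allclose(
            model.emissionprob[0], X.mean(axis=0), atol=1e-6
        )

    def test_two_state_generator_recovered(self, rng):
        # planted 2-state chain, emissions 0.9/0.05, self-transition 0.95
        T, p_on, p_off = 20_000, 0.9, 0.05
        states = np.zeros(T, dtype=int)
        for t in range(1, T):
            states[t] = states[t - 1] if rng.random() < 0.95 else 1 - states[t - 1]
        probs = np.where(states[:, None] == 0, p_on, p_off) * np.ones((T, 4))
        X = (rng.random((T, 4)) < probs).astype(np.uint8)
        mat = hmm.BinaryMatrix(list("abcd"), 200, {"chr1": X})
        model = hmm.fit_hmm(mat, 2, seed=0, n_restarts=3)
        truth = np.array([[p_on] * 4, [p_off] * 4])
        perm = hmm.match_states(truth, model.emissionprob)
        assert np.abs(model.emissionprob[perm] - truth).max() < 0.05

    def test_loglik_nondecreasing_over_iterations(self, rng):
        X = (rng.random((2000, 5)) < 0.3).astype(np.uint8)
        mat = hmm.BinaryMatrix(list("abcde"), 200, {"chr1": X})
        lls = []
        pi = np.full(3, 1 / 3)
        A = np.full((3, 3), 0.1)
        np.fill_diagonal(A, 0.8)
        E = rng.uniform(0.2, 0.8, size=(3, 5))
        for _ in range(15):
            model = hmm.fit_hmm(mat, 3, init=(pi, A, E), max_iter=1, tol=0)
            lls.append(hmm.log_likelihood(model, mat))
            pi, A, E = model.startprob, model.transmat, model.emissionprob
        diffs = np.diff(lls)
        assert (diffs > -1e-6).all()

    def test_more_states_than_bins_rejected(self, rng):
        X = (rng.random((5, 2)) < 0.5).astype(np.uint8)
        mat = hmm.BinaryMatrix(["a", "b"], 200, {"chr1": X})
        with pytest.raises(ValueError):
            hmm.fit_hmm(mat, 10)

    def test_loglik_agrees_with_hmmlearn_categorical_encoding(self, rng):
        """Forward algorithm cross-check: encode the 4-bit rows as one
        categorical variable whose emission table is the Bernoulli
        product; total log-likelihoods must agree."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        X = (rng.random((800, 4)) < 0.4).astype(np.uint8)
        mat = hmm.BinaryMatrix(list("abcd"), 200, {"chr1": X})
        model = hmm.fit_hmm(mat, 3, seed=1, n_restarts=1, max_iter=5)
        ours = hmm.log_likelihood(model, mat)

        codes = X @ (1 << np.arange(4))
        emission = np.ones((3, 16))
        for code in range(16):
            bits = (code >> np.arange(4)) & 1
            emission[:, code] = np.prod(
                np.where(bits, model.emissionprob, 1 - model.emissionprob), axis=1
            )
        ref = hmmlearn.CategoricalHMM(n_components=3)
        ref.startprob_ = model.startprob
        ref.transmat_ = model.transmat
        ref.emissionprob_ = emission
        ref.n_features = 16
        theirs = ref.score(codes.reshape(-1, 1))
        assert ours == pytest.approx(theirs, rel=1e-10)


class TestSegment:
    def test_deterministic_emissions_decode_exactly(self, rng):
        # distinct, near-deterministic per-state mark patterns
        E = np.array([[0.999, 0.001], [0.001, 0.999]])
        T = 3000
        states = np.zeros(T, dtype=int)
        for t in range(1, T):
            states[t] = states[t - 1] if rng.random() < 0.9 else 1 - states[t - 1]
        X = (rng.random((T, 2)) < E[states]).astype(np.uint8)
        # regenerate until exactly consistent (deterministic p in {0,1})
        X = E[states].round().astype(np.uint8)
        mat = hmm.BinaryMatrix(["a", "b"], 200, {"chr1": X})
        model = hmm.HMMModel(
            startprob=np.array([0.5, 0.5]),
            transmat=np.array([[0.9, 0.1], [0.1, 0.9]]),
            emissionprob=E,
            mark_names=["a", "b"],
        )
        seg = hmm.segment(model, mat)
        np.testing.assert_array_equal(seg.bin_states["chr1"], states)

    def test_intervals_tile_each_chromosome(self, small_dataset):
        ds = small_dataset
        tracks = {m: ds.tracks[(m, "male", "gonad", 1)] for m in MARKS}
        mat = hmm.binarize_tracks(tracks)
        model = hmm.fit_hmm(mat, 3, seed=0, n_restarts=1, max_iter=20)
        seg = hmm.segment(model, mat, genome=ds.genome)
        by_chrom = {}
        for iv, state in seg.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            assert ivs[0].start == 0
            assert ivs[-1].end == ds.genome.chrom_length(chrom)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end == b.start  # contiguous, non-overlapping

    def test_viterbi_and_posterior_agree_on_easy_data(self):
        ds = simulate_dataset(recovery_config(seed=21, n_autosomes=1))
        tracks = {m: ds.tracks[(m, "female", "head", 1)] for m in MARKS}
        mat = hmm.binarize_tracks(tracks)
        model = hmm.fit_hmm(mat, 5, seed=0, n_restarts=3)
        post = hmm.segment(model, mat, genome=ds.genome)
        vit = hmm.segment(model, mat, genome=ds.genome, algorithm="viterbi")
        agree = np.mean(post.bin_states["chr1"] == vit.bin_states["chr1"])
        assert agree > 0.98


class TestModelSelection:
    def test_three_state_truth_selected_from_range(self):
        cfg = recovery_config(seed=2, n_autosomes=2)
        E = np.full((3, 7), 0.02)
        E[0, [0, 1]] = 0.30
        E[1, [0, 1]] = 0.30
        E[1, [2, 6]] = 0.35
        E[2, 3] = 0.85
        cfg.emission_matrix = E
        cfg.stationary_weights = (0.4, 0.4, 0.2)
        ds = simulate_dataset(cfg)
        tracks = {m: ds.tracks[(m, "female", "head", 1)] for m in MARKS}
        mat = hmm.binarize_tracks(tracks)
        res = hmm.select_state_number(mat, k_min=2, k_max=6, seed=0, n_restarts=5)
        assert res.chosen_k == 3

    def test_richest_model_vs_itself_is_one(self):
        ds = simulate_dataset(recovery_config(seed=8, n_autosomes=1))
        tracks = {m: ds.tracks[(m, "female", "head", 1)] for m in MARKS}
        mat = hmm.binarize_tracks(tracks)
        res = hmm.select_state_number(mat, k_min=3, k_max=4, seed=0, n_restarts=2)
        assert res.curve[4] == pytest.approx(1.0)

    def test_signal_free_data_chooses_k_min(self, rng):
        """With no enrichment anywhere every fitted state is the same flat
        profile, the curve sits at 1 and the smallest K wins."""
        X = np.zeros((5000, 7), dtype=np.uint8)
        mat = hmm.BinaryMatrix(list(MARKS), 200, {"chr1": X})
        res = hmm.select_state_number(mat, k_min=2, k_max=4, seed=0, n_restarts=2)
        assert res.chosen_k == 2
        assert all(v == pytest.approx(1.0) for v in res.curve.values())

    def test_invalid_range_rejected(self, rng):
        X = (rng.random((100, 2)) < 0.5).astype(np.uint8)
        mat = hmm.BinaryMatrix(["a", "b"], 200, {"chr1": X})
        with pytest.raises(ValueError):
            hmm.select_state_number(mat, k_min=5, k_max=3)


def test_model_round_trip_serialization(tmp_path, rng):
    model = hmm.HMMModel(
        startprob=np.array([0.3, 0.7]),
        transmat=np.array([[0.9, 0.1], [0.2, 0.8]]),
        emissionprob=rng.random((2, 7)),
        mark_names=list(MARKS),
    )
    path = tmp_path / "model.txt"
    hmm.write_model(model, path)
    back = hmm.read_model(path)
    np.testing.assert_allclose(back.startprob, model.startprob)
    np.testing.assert_allclose(back.transmat, model.transmat)
    np.testing.assert_allclose(back.emissionprob, model.emissionprob, atol=1e-9)
    assert back.mark_names == model.mark_names
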