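"""Predictor mechanics: shape contracts, seeding, the training schedule,
the dataset split, successive halving, greedy soups and rank correlation.

Everything here runs on deliberately tiny models and datasets; the
full-scale behavior recovery lives in test_acceptance.py.
"""

import numpy as np
import pandas as pd
import pytest

from utropt import (MrlPredictor, build_predictor, evaluate_spearman,
                    greedy_soup, hyperband_search, make_oracle,
                    sample_library, split_dataset)
from utropt.predictor import DEFAULT_POOL_SIZE, DESK_EPOCH_SCHEDULE

TINY = dict(n_conv_blocks=1, conv_filters=4, conv_kernel=3, gru_dim=4,
            n_dense_blocks=1, dense_units=4)


@pytest.fixture(scope="module")
def tiny_library():
    oracle = make_oracle(noise_sd=0.0, seed=3)
    lib = sample_library(oracle, 300, (50, 50), seed=3)
    return split_dataset(lib, seed=3)


@pytest.fixture(scope="module")
def tiny_models(tiny_library):
    train, val, _ = tiny_library
    models = []
    for seed in (0, 1, 2):
        m = MrlPredictor(input_len=50, max_epochs=3, random_state=seed, **TINY)
        m.fit(train["seq"].tolist(), train["mrl"].to_numpy(),
              X_val=val["seq"].tolist(), y_val=val["mrl"].to_numpy())
        models.append(m)
    return models


class TestBuild:
    def test_batch_in_scores_out(self):
        m = build_predictor(seed=0, input_len=100, **TINY)
        rng = np.random.default_rng(0)
        seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
                for _ in range(4)]
        assert m.predict(seqs).shape == (4,)

    def test_same_seed_identical_initial_predictions(self):
        seqs = ["ACGT" * 10, "A" * 30]
        a = build_predictor(seed=7, input_len=50, **TINY).predict(seqs)
        b = build_predictor(seed=7, input_len=50, **TINY).predict(seqs)
        np.testing.assert_array_equal(a, b)

    def test_input_len_50_rejects_100_wide_input(self):
        m = build_predictor(seed=0, input_len=50, **TINY)
        with pytest.raises(ValueError):
            m.predict(np.zeros((2, 100, 5)))

    @pytest.mark.parametrize("bad", [dict(input_len=60), dict(conv_filters=0),
                                     dict(activation="swish"),
                                     dict(lr_factor=1.5),
                                     dict(stop_patience=3, plateau_patience=5)])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            build_predictor(seed=0, **{**TINY, **bad})


class TestPredict:
    def test_permutation_equivariance_and_batch_invariance(self, tiny_models):
        m = tiny_models[0]
        rng = np.random.default_rng(1)
        seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 50)])
                for _ in range(10)]
        scores = m.predict(seqs)
        perm = rng.permutation(10)
        np.testing.assert_allclose(m.predict([seqs[i] for i in perm]), scores[perm])
        np.testing.assert_allclose(m.predict(seqs[:1])[0], scores[0])

    def test_deterministic(self, tiny_models):
        m = tiny_models[0]
        seqs = ["ACGT" * 13 for _ in range(3)]
        np.testing.assert_array_equal(m.predict(seqs), m.predict(seqs))


class TestTrainingSchedule:
    def test_lr_drops_tenfold_after_five_epoch_plateau_then_stops_after_twelve(self):
        """With a zero learning rate the validation loss never improves past
        epoch 1, giving a deterministic plateau: the learning rate must be
        cut to 1/10 after 5 improvement-free epochs (and again after 5
        more), and training must stop after 12."""
        rng = np.random.default_rng(0)
        seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 50)])
                for _ in range(40)]
        y = rng.standard_normal(40)
        lr0 = 1e-15  # steps far below the improvement tolerance
        m = MrlPredictor(input_len=50, max_epochs=100, learning_rate=lr0,
                         random_state=0, **TINY)
        m.fit(seqs[:30], y[:30], X_val=seqs[30:], y_val=y[30:])
        h = m.history_
        assert len(h) == 13  # epoch of best loss + 12 improvement-free epochs
        assert h["lr"].iloc[:6].tolist() == [lr0] * 6
        assert h["lr"].iloc[6] == pytest.approx(lr0 * 0.1)   # after 5-epoch plateau
        assert h["lr"].iloc[11] == pytest.approx(lr0 * 0.01)  # after 5 more

    def test_constant_labels_converge_to_constant_predictor(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 50)])
                for _ in range(40)]
        y = np.full(40, 2.5)
        m = MrlPredictor(input_len=50, max_epochs=60, batch_size=8,
                         learning_rate=0.01, random_state=0, **TINY)
        m.fit(seqs[:30], y[:30], X_val=seqs[30:], y_val=y[30:])
        assert float(np.mean((m.predict(seqs[30:]) - 2.5) ** 2)) < 1e-2

    def test_empty_training_data_rejected(self):
        m = MrlPredictor(**TINY)
        with pytest.raises(ValueError):
            m.fit([], [])


class TestSplit:
    def test_sizes_1000(self):
        lib = pd.DataFrame({"id": range(1000), "seq": ["A"] * 1000,
                            "mrl": np.arange(1000.0)})
        train, val, test = split_dataset(lib, seed=0)
        assert (len(test), len(train), len(val)) == (100, 720, 180)

    def test_disjoint_and_exhaustive(self):
        lib = pd.DataFrame({"id": range(100), "seq": ["A"] * 100,
                            "mrl": np.arange(100.0)})
        train, val, test = split_dataset(lib, seed=1)
        ids = [set(part["id"]) for part in (train, val, test)]
        assert ids[0] | ids[1] | ids[2] == set(range(100))
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])

    def test_seeded_determinism(self):
        lib = pd.DataFrame({"id": range(50), "seq": ["A"] * 50,
                            "mrl": np.arange(50.0)})
        a = split_dataset(lib, seed=5)
        b = split_dataset(lib, seed=5)
        for x, y in zip(a, b):
            assert x.equals(y)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            split_dataset(pd.DataFrame({"id": [1], "seq": ["A"], "mrl": [1.0]}))


class TestSpearman:
    def test_perfect_and_inverted(self, tiny_models):
        m = tiny_models[0]
        rng = np.random.default_rng(2)
        seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 50)])
                for _ in range(20)]
        pred = m.predict(seqs)
        assert evaluate_spearman(m, seqs, pred) == pytest.approx(1.0)
        assert evaluate_spearman(m, seqs, -pred) == pytest.approx(-1.0)

    def test_toy_rank_vectors(self):
        # hand-computed: ranks (1,2,3,4) vs (1,3,2,4) -> rho = 1 - 6*2/(4*15) = 0.8
        from scipy import stats
        rho, _ = stats.spearmanr([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_constant_vector_rejected(self, tiny_models):
        m = tiny_models[0]
        with pytest.raises(ValueError):
            evaluate_spearman(m, ["ACGT" * 13, "ACGT" * 13], [1.0, 1.0])


class TestHyperband:
    def test_pool_of_nine_gives_survivor_counts_9_3_1(self, tiny_library):
        train, val, _ = tiny_library
        space = {"conv_filters": [2, 4], "gru_dim": [2, 4]}
        result = hyperband_search(
            space, train["seq"].tolist()[:60], train["mrl"].to_numpy()[:60],
            val["seq"].tolist()[:20], val["mrl"].to_numpy()[:20],
            pool_size=9, epoch_schedule=DESK_EPOCH_SCHEDULE, seed=0,
            base_params=dict(input_len=50, n_conv_blocks=1, conv_kernel=3,
                             n_dense_blocks=1, dense_units=4, batch_size=32))
        assert [r["n_candidates"] for r in result.rounds] == [9, 3, 1]
        assert [r["epochs"] for r in result.rounds] == [1, 2, 4]
        assert set(result.best_config) == {"conv_filters", "gru_dim"}

    def test_pool_of_one_returns_after_first_budget(self, tiny_library):
        train, val, _ = tiny_library
        result = hyperband_search(
            {"conv_filters": [4]}, train["seq"].tolist()[:40],
            train["mrl"].to_numpy()[:40], val["seq"].tolist()[:10],
            val["mrl"].to_numpy()[:10], pool_size=1,
            epoch_schedule=(1, 2), seed=0,
            base_params=dict(input_len=50, n_conv_blocks=1, conv_kernel=3,
                             gru_dim=4, n_dense_blocks=1, dense_units=4))
        assert [r["n_candidates"] for r in result.rounds] == [1]
        assert result.best_config == {"conv_filters": 4}

    def test_default_pool_size_is_8000(self):
        assert DEFAULT_POOL_SIZE == 8000

    def test_survivor_arithmetic(self):
        # ceil(n/3) per round for drop ratio 2/3
        n = 8000
        counts = [n]
        while counts[-1] > 1:
            counts.append(int(np.ceil(counts[-1] / 3)))
        assert counts[:4] == [8000, 2667, 889, 297]

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            hyperband_search({}, ["A" * 50], [1.0], ["A" * 50], [1.0])


class TestGreedySoup:
    def test_single_model_unchanged(self, tiny_models, tiny_library):
        _, val, _ = tiny_library
        soup = greedy_soup(tiny_models[:1], val["seq"].tolist(),
                           val["mrl"].to_numpy())
        for k, v in soup.net_.state_dict().items():
            np.testing.assert_array_equal(v, tiny_models[0].net_.state_dict()[k])

    def test_identical_members_leave_weights_unchanged(self, tiny_models,
                                                       tiny_library):
        _, val, _ = tiny_library
        m = tiny_models[0]
        soup = greedy_soup([m, m, m], val["seq"].tolist(), val["mrl"].to_numpy())
        for k, v in soup.net_.state_dict().items():
            np.testing.assert_allclose(v, m.net_.state_dict()[k])

    def test_soup_no_worse_than_best_single(self, tiny_models, tiny_library):
        _, val, _ = tiny_library
        Xv, yv = val["seq"].tolist(), val["mrl"].to_numpy()
        soup = greedy_soup(tiny_models, Xv, yv)
        best_single = min(float(np.mean((m.predict(Xv) - yv) ** 2))
                          for m in tiny_models)
        soup_mse = float(np.mean((soup.predict(Xv) - yv) ** 2))
        assert soup_mse <= best_single + 1e-12

    def test_corrupted_member_rejected(self, tiny_models, tiny_library):
        import copy
        _, val, _ = tiny_library
        Xv, yv = val["seq"].tolist(), val["mrl"].to_numpy()
        bad = copy.deepcopy(tiny_models[1])
        rng = np.random.default_rng(0)
        bad.net_.load_state_dict(
            {k: rng.standard_normal(v.shape) * 100
             for k, v in bad.net_.state_dict().items()})
        soup = greedy_soup([tiny_models[0], bad], Xv, yv)
        # the corrupted member must not enter the average
        assert soup.soup_size_ == 1
        for k, v in soup.net_.state_dict().items():
            np.testing.assert_array_equal(v, tiny_models[0].net_.state_dict()[k])

    def test_architecture_mismatch_rejected(self, tiny_models, tiny_library):
        _, val, _ = tiny_library
        other = MrlPredictor(input_len=50, conv_filters=8, n_conv_blocks=1,
                             conv_kernel=3, gru_dim=4, n_dense_blocks=1,
                             dense_units=4, max_epochs=1, random_state=0)
        train = val  # any data suffices for one epoch
        other.fit(train["seq"].tolist(), train["mrl"].to_numpy(),
                  X_val=val["seq"].tolist(), y_val=val["mrl"].to_numpy())
        with pytest.raises(ValueError):
            greedy_soup([tiny_models[0], other], val["seq"].tolist(),
                        val["mrl"].to_numpy())


class TestPersistence:
    def test_save_load_round_trip(self, tiny_models, tmp_path):
        m = tiny_models[0]
        m.save(tmp_path / "model")
        back = MrlPredictor.load(tmp_path / "model")
        seqs = ["ACGT" * 13, "A" * 50]
        np.testing.assert_allclose(back.predict(seqs), m.predict(seqs))
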