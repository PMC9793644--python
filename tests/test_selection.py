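import math

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mutual_info_score

from circstack.selection import (
    Discretizer,
    EncoderConfig,
    FeatureMatrix,
    InputError,
    assemble_features,
    discretize,
    discretize_matrix,
    mrmr_rank,
    mutual_information,
    sweep_dimensions,
)
from circstack.seqio import TranscriptRecord

from _oracles import brute_mrmr_order, mi_bits, random_dna


class TestMutualInformation:
    def test_perfect_dependence_balanced_binary(self):
        x = np.array([0, 1] * 10)
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_constant_series(self):
        assert mutual_information(np.zeros(10), np.arange(10)) == 0.0

    def test_hand_evaluated_joint(self):
        x = np.array([0, 0, 0, 1, 1, 1])
        y = np.array([0, 0, 1, 0, 1, 1])
        # joint counts {(0,0):2, (0,1):1, (1,0):1, (1,1):2}
        expected = 2 * (2 / 6) * math.log2((2 / 6) / (0.5 * 0.5)) + 2 * (
            1 / 6
        ) * math.log2((1 / 6) / (0.5 * 0.5))
        assert mutual_information(x, y) == pytest.approx(expected)

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(10):
            x = rng.integers(0, 4, 50)
            y = rng.integers(0, 3, 50)
            a, b = mutual_information(x, y), mutual_information(y, x)
            assert a == pytest.approx(b)
            assert a >= 0

    def test_self_information_is_entropy(self, rng):
        x = rng.integers(0, 5, 200)
        _, counts = np.unique(x, return_counts=True)
        p = counts / counts.sum()
        entropy = -(p * np.log2(p)).sum()
        assert mutual_information(x, x) == pytest.approx(entropy)

    def test_agrees_with_sklearn_estimator(self, rng):
        x = rng.integers(0, 6, 100)
        y = rng.integers(0, 4, 100)
        assert mutual_information(x, y) == pytest.approx(
            mutual_info_score(x, y) / math.log(2)
        )

    def test_length_mismatch_raises(self):
        with pytest.raises(InputError):
            mutual_information(np.zeros(3), np.zeros(4))


class TestDiscretize:
    def test_constant_series_single_level(self):
        assert len(np.unique(discretize(np.full(20, 3.3)))) == 1

    def test_binary_series_two_levels(self):
        x = np.array([0.0, 1.0] * 25)
        levels = discretize(x, bins=10)
        assert len(np.unique(levels)) == 2

    def test_uniform_series_balanced_occupancy(self, rng):
        x = rng.random(1000)
        levels = discretize(x, bins=10)
        _, counts = np.unique(levels, return_counts=True)
        assert len(counts) == 10
        assert counts.min() >= 90 and counts.max() <= 110

    def test_edges_fit_on_train_only(self, rng):
        train = rng.random((100, 1))
        test = train + 10.0  # out-of-range values all land in the top bin
        levels = discretize_matrix(train, bins=4, apply_to=test)
        assert set(np.unique(levels)) == {3}


def _labelled_matrix(columns: dict[str, np.ndarray], labels: np.ndarray) -> FeatureMatrix:
    names = list(columns)
    values = np.column_stack([columns[n] for n in names]).astype(float)
    return FeatureMatrix(values=values, feature_names=names,
                         ids=[f"r{i}" for i in range(len(labels))], labels=labels)


class TestMrmr:
    def test_label_copy_ranked_first(self, rng):
        y = rng.integers(0, 2, 60)
        m = _labelled_matrix(
            {"noise1": rng.random(60), "copy": y.astype(float), "noise2": rng.random(60)},
            y,
        )
        ranking = mrmr_rank(m, m=3)
        assert ranking.feature_names[ranking.order[0]] == "copy"

    def test_duplicate_feature_demoted(self, rng):
        y = rng.integers(0, 2, 400)
        a = (y + (rng.random(400) < 0.10)) % 2  # strong noisy copy of the label
        b = (y + (rng.random(400) < 0.25)) % 2  # weaker, independently noisy copy
        m = _labelled_matrix(
            {
                "a": a.astype(float),
                "a_dup": a.astype(float),  # exact duplicate column of a
                "b": b.astype(float),
                "noise": rng.random(400),
            },
            y,
        )
        ranking = mrmr_rank(m, m=4)
        names = [ranking.feature_names[i] for i in ranking.order]
        assert names[0] == "a"
        assert names[1] == "b"  # the exact duplicate must not come second

    @pytest.mark.parametrize("criterion", ["MID", "MIQ"])
    def test_matches_brute_force_greedy(self, rng, criterion):
        for _ in range(5):
            n, p = 40, 6
            y = rng.integers(0, 2, n)
            values = rng.integers(0, 3, (n, p)).astype(float)
            values[:, 0] = y  # ensure some relevance structure
            m = FeatureMatrix(values=values, feature_names=[f"f{j}" for j in range(p)],
                              ids=[str(i) for i in range(n)], labels=y)
            ranking = mrmr_rank(m, m=p, criterion=criterion)
            disc = discretize_matrix(values)
            expected = brute_mrmr_order(disc, y, m=p, criterion=criterion)
            assert ranking.order == expected

    def test_full_ranking_is_permutation(self, rng):
        y = rng.integers(0, 2, 30)
        values = rng.random((30, 5))
        m = FeatureMatrix(values=values, feature_names=list("abcde"),
                          ids=[str(i) for i in range(30)], labels=y)
        ranking = mrmr_rank(m, m=5)
        assert sorted(ranking.order) == list(range(5))

    def test_errors(self, rng):
        y = rng.integers(0, 2, 20)
        m = _labelled_matrix({"a": rng.random(20)}, y)
        with pytest.raises(InputError):
            mrmr_rank(m, m=2)
        single = _labelled_matrix({"a": rng.random(20)}, np.zeros(20, dtype=int))
        with pytest.raises(InputError):
            mrmr_rank(single, m=1)


class TestAssembleFeatures:
    def test_default_config_yields_170_columns(self, small_dataset):
        records, alu, _ = small_dataset
        matrix = assemble_features(records[:10], alu)
        assert matrix.n_features == 170
        assert sum(n.startswith("kmer_") for n in matrix.feature_names) == 64

    def test_missing_alu_annotation_zeroes_alu_feature(self, small_dataset):
        records, _, _ = small_dataset
        matrix = assemble_features(records[:3], None)
        col = matrix.feature_names.index("alu_total")
        assert (matrix.values[:, col] == 0).all()

    def test_identical_transcripts_identical_rows(self, rng):
        seq = random_dna(rng, 300)
        recs = [TranscriptRecord("a", seq, label=1), TranscriptRecord("b", seq, label=1)]
        matrix = assemble_features(recs)
        assert np.array_equal(matrix.values[0], matrix.values[1])

    def test_per_window_alu_columns(self, small_dataset):
        records, alu, _ = small_dataset
        cfg = EncoderConfig(alu_per_window=True)
        matrix = assemble_features(records[:5], alu, cfg)
        assert matrix.n_features == 171
        assert "alu_w1000" in matrix.feature_names

    def test_tsv_round_trip(self, small_dataset, tmp_path):
        records, alu, _ = small_dataset
        matrix = assemble_features(records[:8], alu)
        p = tmp_path / "features.tsv"
        matrix.to_tsv(p)
        back = FeatureMatrix.from_tsv(p)
        assert back.feature_names == matrix.feature_names
        assert np.allclose(back.values, matrix.values)
        assert np.array_equal(back.labels, matrix.labels)


class TestSweepDimensions:
    @staticmethod
    def _lr_builder(train: FeatureMatrix, test: FeatureMatrix) -> dict[str, float]:
        clf = LogisticRegression(max_iter=500).fit(train.values, train.labels)
        return {"acc": float(clf.score(test.values, test.labels))}

    def _planted_matrix(self, rng, n=300, informative=4, noise=60):
        y = rng.integers(0, 2, n)
        cols = {}
        for j in range(informative):
            cols[f"sig{j}"] = y + rng.normal(0, 0.4, n)
        for j in range(noise):
            cols[f"noise{j}"] = rng.normal(0, 1, n)
        return _labelled_matrix(cols, y)

    def test_signal_dimensions_beat_tiny_ones(self, rng):
        m = self._planted_matrix(rng)
        table = sweep_dimensions(m, self._lr_builder, dims=[1, 4, 64], seed=3)
        assert table.loc[4, "acc"] >= table.loc[1, "acc"] - 0.02
        assert table.loc[64, "acc"] >= table.loc[4, "acc"] - 0.08

    def test_oversized_dimension_rejected(self, rng):
        m = self._planted_matrix(rng, noise=6)
        with pytest.raises(InputError):
            sweep_dimensions(m, self._lr_builder, dims=[5, 500])

    def test_unsorted_dims_rejected(self, rng):
        m = self._planted_matrix(rng, noise=6)
        with pytest.raises(InputError):
            sweep_dimensions(m, self._lr_builder, dims=[8, 2])

    def test_planted_features_recovered_in_top_ranking(self, rng):
        m = self._planted_matrix(rng, informative=5, noise=40)
        ranking = mrmr_rank(m, m=10)
        top = set(ranking.top(10))
        assert sum(1 for n in top if n.startswith("sig")) == 5
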