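"""PCA and OPLS-DA: oracles, invariances, cross-validation, null models."""

import numpy as np
import pandas as pd
import pytest

from mslseq import kmer
from mslseq.errors import InputError, ParameterError, StateError
from mslseq.kmer import WordMatrix
from mslseq.multivariate import (
    cross_validate_q2,
    fit_oplsda,
    fit_pca,
    predict_scores,
    random_group_null,
)


def _wm(X, norm_state="raw", scale_state="unscaled", columns=None):
    cols = columns or [f"v{j}" for j in range(X.shape[1])]
    data = pd.DataFrame(X, columns=cols)
    return WordMatrix(data=data, norm_state=norm_state, scale_state=scale_state)


def _uv(X):
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def pls1_nipals_oracle(X, y):
    """Classic single-component PLS1 NIPALS, written independently."""
    u = y - y.mean()
    Xc = X - X.mean(axis=0)
    for _ in range(500):
        w = Xc.T @ u
        w = w / np.sqrt(w @ w)
        t = Xc @ w
        q = (u @ t) / (t @ t)
        u_new = y - y.mean()  # single y: u stays the centered response
        if np.allclose(u, u_new):
            break
        u = u_new
    return w, t


class TestPca:
    def test_rank_one_matrix_fully_explained(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=6)
        X = np.outer(u, v)
        X -= X.mean(axis=0)
        model = fit_pca(_wm(X, scale_state="centered"), 2)
        assert model.r2cum[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(10, 20))
        Xs = _uv(X)
        model = fit_pca(_wm(Xs, scale_state="uv_scaled"), 5)
        cov = Xs.T @ Xs / (Xs.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        for j in range(5):
            load = evecs[:, order[j]]
            if load[np.argmax(np.abs(load))] < 0:
                load = -load
            assert np.allclose(model.loadings.iloc[:, j], load, atol=1e-8)
            assert np.allclose(model.scores.iloc[:, j], Xs @ load, atol=1e-8)

    def test_reconstruction_with_all_components(self, rng):
        X = _uv(rng.normal(size=(8, 12)))
        model = fit_pca(_wm(X, scale_state="uv_scaled"), 7)
        recon = model.scores.to_numpy() @ model.loadings.to_numpy().T
        assert np.allclose(recon, X, atol=1e-8)

    def test_r2cum_monotone_bounded(self, rng):
        X = _uv(rng.normal(size=(12, 30)))
        model = fit_pca(_wm(X, scale_state="uv_scaled"), 6)
        assert np.all(np.diff(model.r2cum) >= -1e-12)
        assert model.r2cum[-1] <= 1.0 + 1e-12

    def test_unscaled_matrix_rejected(self, rng):
        with pytest.raises(StateError):
            fit_pca(_wm(rng.normal(size=(5, 4))), 2)

    def test_too_many_components_rejected(self, rng):
        X = _uv(rng.normal(size=(5, 4)))
        with pytest.raises(ParameterError):
            fit_pca(_wm(X, scale_state="uv_scaled"), 5)


def _two_cluster_data(rng, n_per=20, p=30, sep=4.0, orth_scale=0.0):
    """A predictive direction (cluster separation) plus optional strong
    orthogonal variation."""
    X = rng.normal(size=(2 * n_per, p))
    direction = np.zeros(p)
    direction[:5] = 1.0
    y = np.array(["pos"] * n_per + ["neg"] * n_per)
    X[:n_per] += sep * direction / np.sqrt(5)
    if orth_scale:
        orth = np.zeros(p)
        orth[5:10] = 1.0
        X += np.outer(rng.normal(scale=orth_scale, size=2 * n_per), orth)
    return X, y


class TestOplsda:
    def test_predictive_component_matches_pls_oracle(self, rng):
        # no orthogonal structure: OPLS-DA with n_orth=0 is single-component PLS
        X, y = _two_cluster_data(rng)
        model = fit_oplsda(_wm(X), y, n_orth=0, positive_class="pos", cv_folds=3)
        ycode = np.where(y == "pos", 1.0, -1.0)
        w_oracle, t_oracle = pls1_nipals_oracle(_uv(X), ycode)
        if np.sign(w_oracle @ model.predictive_weights) < 0:
            w_oracle, t_oracle = -w_oracle, -t_oracle
        assert np.allclose(model.predictive_weights, w_oracle, atol=1e-6)
        assert np.allclose(model.training_scores, t_oracle, atol=1e-6)

    def test_orthogonal_variation_does_not_move_scores(self, rng):
        # exact rank-2 construction: predictive direction plus an exactly
        # class-uncorrelated direction; doubling the orthogonal variance
        # leaves the predictive scores unchanged to 1e-6
        n, p = 30, 12
        y = np.array(["pos"] * (n // 2) + ["neg"] * (n // 2))
        ycode = np.where(y == "pos", 1.0, -1.0)
        t_orth = rng.normal(size=n)
        t_orth -= t_orth.mean()
        t_orth -= (t_orth @ ycode) / (ycode @ ycode) * ycode  # decorrelate
        p_vec = np.zeros(p)
        p_vec[:4] = 1.0
        p_orth = np.zeros(p)
        p_orth[4:8] = 1.0
        X1 = np.outer(ycode, p_vec) + np.outer(t_orth, p_orth)
        X2 = np.outer(ycode, p_vec) + 2.0 * np.outer(t_orth, p_orth)
        m1 = fit_oplsda(_wm(X1, norm_state="at_normalized"), y, n_orth=1,
                        positive_class="pos", cv_folds=3)
        m2 = fit_oplsda(_wm(X2, norm_state="at_normalized"), y, n_orth=1,
                        positive_class="pos", cv_folds=3)
        assert np.allclose(m1.training_scores, m2.training_scores, atol=1e-6)

    def test_orthogonal_scores_uncorrelated_with_labels(self, rng):
        X, y = _two_cluster_data(rng, orth_scale=2.0)
        model = fit_oplsda(_wm(X), y, n_orth=1, positive_class="pos", cv_folds=3)
        ycode = np.where(y == "pos", 1.0, -1.0)
        Xs = _uv(X)
        t_orth = Xs @ model.orthogonal_weights[0]
        r = np.corrcoef(t_orth, ycode)[0, 1]
        assert abs(r) < 1e-6

    def test_training_scores_reproduced_by_predict(self, rng):
        X, y = _two_cluster_data(rng)
        model = fit_oplsda(_wm(X), y, n_orth=1, positive_class="pos", cv_folds=3)
        scores = predict_scores(model, _wm(X))
        assert np.allclose(scores.to_numpy(), model.training_scores.to_numpy(),
                           atol=1e-10)

    def test_all_zero_row_scores_finite(self, rng):
        X, y = _two_cluster_data(rng)
        model = fit_oplsda(_wm(X), y, n_orth=0, positive_class="pos", cv_folds=3)
        zero = pd.DataFrame(np.zeros((1, X.shape[1])),
                            columns=model.variables)
        score = predict_scores(model, zero)
        assert np.isfinite(score.iloc[0])

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(InputError):
            fit_oplsda(_wm(X), ["a"] * 10)

    def test_tiny_class_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(InputError):
            fit_oplsda(_wm(X), ["a"] * 8 + ["b"] * 2)


class TestCrossValidation:
    def test_separable_clusters_high_q2(self, rng):
        X, y = _two_cluster_data(rng, sep=20.0)
        q2 = cross_validate_q2(_wm(X), y, folds=5, seed=1)
        assert q2 > 0.9

    def test_random_labels_negative_q2(self, rng):
        X = rng.normal(size=(40, 30))
        neg = 0
        for seed in range(20):
            y = np.array(["a", "b"] * 20)
            rng.shuffle(y)
            if cross_validate_q2(_wm(X), y, folds=5, seed=seed) <= 0:
                neg += 1
        assert neg >= 18

    def test_single_fold_rejected(self, rng):
        X, y = _two_cluster_data(rng)
        with pytest.raises(ParameterError):
            cross_validate_q2(_wm(X), y, folds=1)

    def test_folds_beyond_class_size_rejected(self, rng):
        X, y = _two_cluster_data(rng, n_per=4)
        with pytest.raises(ParameterError):
            cross_validate_q2(_wm(X), y, folds=5)

    def test_deterministic_per_seed(self, rng):
        X, y = _two_cluster_data(rng)
        a = cross_validate_q2(_wm(X), y, folds=5, seed=3)
        b = cross_validate_q2(_wm(X), y, folds=5, seed=3)
        assert a == b


class TestRandomGroupNull:
    @staticmethod
    def _pool(rng, n=120, length=400):
        return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]

    def test_two_groups_one_model(self, rng):
        null = random_group_null(self._pool(rng), n_groups=2, group_size=10,
                                 k_max=3, folds=5)
        assert len(null) == 1

    def test_pair_count_is_binomial_coefficient(self, rng):
        null = random_group_null(self._pool(rng), n_groups=4, group_size=10,
                                 k_max=3, folds=5)
        assert len(null) == 6
        assert {"q2", "spearman_at"} <= set(null.columns)

    def test_label_free_pool_gives_negative_q2(self, rng):
        null = random_group_null(self._pool(rng, n=80), n_groups=4,
                                 group_size=20, k_max=4, folds=5, seed=2)
        assert null["q2"].median() < 0

    def test_insufficient_sequences_rejected(self, rng):
        with pytest.raises(InputError):
            random_group_null(self._pool(rng, n=30), n_groups=7, group_size=10)


def test_oplsda_recovers_planted_word_loadings(rng):
    # strong promoters enriched 3x in 10 planted words: the top-20 positive
    # loadings are dominated by planted words or their substrings
    from mslseq.synth import SynthConfig, generate_dataset
    from mslseq import features as feat
    from mslseq._dna import revcomp

    cfg = SynthConfig(
        n_genes_per_class=60, seed=21, promoter_word_rate=1.0,
        motif_insert_prob={"strong": 0.0, "weak": 0.0, "unexpressed": 0.0},
    )
    ds = generate_dataset(cfg)
    genes = feat.parse_annotation(ds.gff3)
    coords = feat.derive_features(genes, {c: len(s) for c, s in ds.genome.items()})
    proms = {
        f.owner_gene: f.bases
        for f in feat.extract_sequences(coords, ds.genome)
        if f.feature_class == "promoter" and not f.excluded
    }
    cls = ds.truth.genes["gene_class"]
    keep = [g for g in sorted(proms) if cls[g] in ("strong", "weak")]
    matrix = kmer.build_word_matrix({g: proms[g] for g in keep}, layout="canonical")
    model = fit_oplsda(matrix, [cls[g] for g in keep], n_orth=0,
                       positive_class="strong", seed=1)
    top20 = model.sorted_loadings().head(20).index
    planted = cfg.promoter_enriched_words

    def is_planted(w):
        return any(w in pw or w in revcomp(pw) for pw in planted)

    assert np.mean([is_planted(w) for w in top20]) >= 0.8
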