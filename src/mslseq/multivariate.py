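"""PCA and OPLS-DA for word-frequency matrices.

OPLS-DA is implemented from scratch in the O-PLS NIPALS formulation: with a
single binary response there is exactly one predictive component; systematic
X-variation orthogonal to the response is removed by iterative deflation
before the predictive component is fit.  Predictive power is summarised by
the cross-validated Q2 = 1 - PRESS/SS over stratified held-out folds, with
the response centered on the training folds.  The number of orthogonal
components can be chosen automatically as the value (up to a cap of 5)
maximising the cross-validated Q2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from . import kmer
from .errors import InputError, ParameterError, SchemaError, StateError
from .kmer import WordMatrix

MAX_ORTH_DEFAULT = 5


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PcaModel:
    scores: pd.DataFrame  # observations x components
    loadings: pd.DataFrame  # variables x components
    r2cum: np.ndarray  # cumulative explained-variance fractions


def fit_pca(matrix: WordMatrix, n_components: int) -> PcaModel:
    """PCA of a scaled matrix via SVD.

    Sign convention: each loading vector's largest-magnitude entry is made
    positive, so loading lists are stable across runs.
    """
    if matrix.scale_state == "unscaled":
        raise StateError("PCA requires a centered or UV-scaled matrix")
    X = matrix.data.to_numpy(dtype=float)
    n_components = int(n_components)
    if n_components > min(X.shape[0] - 1, X.shape[1]):
        raise ParameterError(
            f"n_components={n_components} exceeds min(rows-1, cols)"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T
    for j in range(n_components):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PcaModel(
        scores=pd.DataFrame(scores, index=matrix.data.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.data.columns, columns=comp_names),
        r2cum=np.cumsum(pca.explained_variance_ratio_),
    )


# --------------------------------------------------------------------------
# OPLS-DA
# --------------------------------------------------------------------------

@dataclass
class OplsdaModel:
    variables: list[str]
    predictive_weights: np.ndarray
    predictive_loadings: np.ndarray
    y_loading: float
    orthogonal_weights: list[np.ndarray]
    orthogonal_loadings: list[np.ndarray]
    n_orth: int
    q2: float
    column_means: pd.Series
    column_sds: pd.Series
    scale_mode: str
    y_mean: float
    positive_class: object
    negative_class: object
    training_scores: pd.Series = field(repr=False, default=None)

    @property
    def training_column_stats(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.column_means, "sd": self.column_sds})

    def sorted_loadings(self) -> pd.Series:
        """Word loadings on the predictive component, sorted descending."""
        s = pd.Series(self.predictive_loadings, index=self.variables)
        return s.sort_values(ascending=False)

    def loadings_to_tsv(self, path) -> None:
        df = self.sorted_loadings().rename("loading").rename_axis("word")
        df.to_frame().to_csv(path, sep="\t")

    def to_json(self, path) -> None:
        payload = {
            "variables": list(self.variables),
            "predictive_weights": self.predictive_weights.tolist(),
            "predictive_loadings": self.predictive_loadings.tolist(),
            "y_loading": self.y_loading,
            "orthogonal_weights": [w.tolist() for w in self.orthogonal_weights],
            "orthogonal_loadings": [p.tolist() for p in self.orthogonal_loadings],
            "n_orth": self.n_orth,
            "q2": self.q2,
            "column_means": self.column_means.tolist(),
            "column_sds": self.column_sds.tolist(),
            "scale_mode": self.scale_mode,
            "y_mean": self.y_mean,
            "positive_class": str(self.positive_class),
            "negative_class": str(self.negative_class),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _code_labels(labels, positive_class):
    labels = pd.Series(list(labels))
    classes = sorted(labels.unique(), key=str)
    if len(classes) != 2:
        raise InputError(f"need exactly two classes, got {list(classes)}")
    counts = labels.value_counts()
    if counts.min() < 3:
        raise InputError("each class needs at least 3 members")
    if positive_class is None:
        positive_class = classes[0]
    if positive_class not in classes:
        raise InputError(f"positive class {positive_class!r} not among labels")
    negative_class = [c for c in classes if c != positive_class][0]
    y = np.where(labels == positive_class, 1.0, -1.0)
    return y, positive_class, negative_class


def _scaling_for(matrix: WordMatrix) -> str:
    return "centered" if matrix.norm_state == "at_normalized" else "uv_scaled"


def _column_stats(X: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    if mode == "uv_scaled":
        sds = X.std(axis=0, ddof=1)
        sds = np.where(sds > 0, sds, 1.0)
    else:
        sds = np.ones(X.shape[1])
    return means, sds


def _opls_core(X: np.ndarray, y: np.ndarray, n_orth: int):
    """O-PLS NIPALS on a centered/scaled X and centered y.

    Returns (w, p, q, orth_w, orth_p); w has unit norm, t = X_deflated @ w.
    """
    Xd = X.copy()
    orth_w: list[np.ndarray] = []
    orth_p: list[np.ndarray] = []
    for _ in range(n_orth):
        w = Xd.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-10:
            break  # no orthogonal structure left
        w_o /= n_o
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd -= np.outer(t_o, p_o)
        orth_w.append(w_o)
        orth_p.append(p_o)
    w = Xd.T @ y
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise InputError("response carries no covariance with the data")
    w /= nw
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    q = (y @ t) / (t @ t)
    return w, p, q, orth_w, orth_p, t


def _project(X: np.ndarray, w, orth_w, orth_p) -> np.ndarray:
    Xd = X.copy()
    for w_o, p_o in zip(orth_w, orth_p):
        t_o = Xd @ w_o
        Xd -= np.outer(t_o, p_o)
    return Xd @ w


def cross_validate_q2(
    matrix: WordMatrix,
    labels,
    folds: int = 7,
    seed: int = 0,
    n_orth: int = 0,
    positive_class=None,
) -> float:
    """Cross-validated Q2 = 1 - PRESS/SS over stratified folds.

    Scaling statistics and the response mean are recomputed on each
    training fold; deterministic for a fixed seed.
    """
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    if matrix.scale_state != "unscaled":
        raise StateError("cross-validation scales internally; pass unscaled data")
    y, pos, _ = _code_labels(labels, positive_class)
    counts = pd.Series(y).value_counts()
    if folds > counts.min():
        raise ParameterError(
            f"folds={folds} exceeds the smaller class size {counts.min()}"
        )
    X = matrix.data.to_numpy(dtype=float)
    mode = _scaling_for(matrix)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = 0.0
    ss = 0.0
    for train, test in skf.split(X, y):
        means, sds = _column_stats(X[train], mode)
        Xtr = (X[train] - means) / sds
        Xte = (X[test] - means) / sds
        y_mean = y[train].mean()
        ytr = y[train] - y_mean
        w, p, q, ow, op, _ = _opls_core(Xtr, ytr, n_orth)
        t_pred = _project(Xte, w, ow, op)
        y_hat = q * t_pred + y_mean
        press += float(((y[test] - y_hat) ** 2).sum())
        ss += float(((y[test] - y_mean) ** 2).sum())
    return 1.0 - press / ss


def fit_oplsda(
    matrix: WordMatrix,
    labels,
    n_orth="auto",
    positive_class=None,
    max_orth: int = MAX_ORTH_DEFAULT,
    cv_folds: int = 7,
    seed: int = 0,
) -> OplsdaModel:
    """Fit a binary OPLS-DA model (one predictive component).

    ``n_orth='auto'`` chooses the orthogonal-component count maximising the
    cross-validated Q2 (ties toward fewer components).  The matrix must be
    unscaled; UV scaling (raw data) or centering (AT-normalized data) is
    applied internally and the column statistics retained for prediction.
    """
    if matrix.scale_state != "unscaled":
        raise StateError("fit_oplsda scales internally; pass unscaled data")
    y, pos, neg = _code_labels(labels, positive_class)
    X = matrix.data.to_numpy(dtype=float)
    mode = _scaling_for(matrix)

    if n_orth == "auto":
        folds = min(cv_folds, int(pd.Series(y).value_counts().min()))
        q2s = [
            cross_validate_q2(matrix, labels, folds=folds, seed=seed, n_orth=n,
                              positive_class=pos)
            for n in range(max_orth + 1)
        ]
        n_orth = int(np.argmax(q2s))
        q2 = float(q2s[n_orth])
    else:
        n_orth = int(n_orth)
        folds = min(cv_folds, int(pd.Series(y).value_counts().min()))
        q2 = cross_validate_q2(
            matrix, labels, folds=folds, seed=seed, n_orth=n_orth,
            positive_class=pos,
        )

    means, sds = _column_stats(X, mode)
    Xs = (X - means) / sds
    y_mean = float(y.mean())
    w, p, q, ow, op, t = _opls_core(Xs, y - y_mean, n_orth)
    return OplsdaModel(
        variables=list(matrix.data.columns),
        predictive_weights=w,
        predictive_loadings=p,
        y_loading=float(q),
        orthogonal_weights=ow,
        orthogonal_loadings=op,
        n_orth=len(ow),
        q2=q2,
        column_means=pd.Series(means, index=matrix.data.columns),
        column_sds=pd.Series(sds, index=matrix.data.columns),
        scale_mode=mode,
        y_mean=y_mean,
        positive_class=pos,
        negative_class=neg,
        training_scores=pd.Series(t, index=matrix.data.index),
    )


def predict_scores(model: OplsdaModel, matrix) -> pd.Series:
    """Y-prediction scores (projection on the predictive component after
    removal of the stored orthogonal components).

    Positive scores indicate the positive (strong) class.  Accepts a
    :class:`WordMatrix` (unscaled) or a plain DataFrame of raw frequencies.
    """
    data = matrix.data if isinstance(matrix, WordMatrix) else matrix
    if isinstance(matrix, WordMatrix) and matrix.scale_state != "unscaled":
        raise StateError("prediction applies the training scaling; pass unscaled data")
    if list(data.columns) != list(model.variables):
        if not set(model.variables).issubset(data.columns):
            raise SchemaError("matrix lacks model variables")
        data = data[model.variables]
    Xs = ((data - model.column_means) / model.column_sds).to_numpy(dtype=float)
    t = _project(Xs, model.predictive_weights,
                 model.orthogonal_weights, model.orthogonal_loadings)
    return pd.Series(t, index=data.index, name="y_prediction_score")


def predicted_y(model: OplsdaModel, matrix) -> pd.Series:
    """Predicted (continuous) class code: q * t + training y mean."""
    t = predict_scores(model, matrix)
    return model.y_loading * t + model.y_mean


def random_group_null(
    sequences: list[str],
    n_groups: int = 7,
    group_size: int = 100,
    seed: int = 0,
    k_min: int = 2,
    k_max: int = 6,
    layout: str = "canonical",
    folds: int = 7,
    n_orth: int = 0,
) -> pd.DataFrame:
    """Null-model combinatorics: pairwise OPLS-DA over random groups.

    Draws ``n_groups`` non-overlapping groups of ``group_size`` sequences,
    fits one OPLS-DA per unordered pair (21 models for 7 groups) and
    returns each pair's cross-validated Q2 together with the Spearman
    correlation between the predictive scores and AT content.
    """
    need = n_groups * group_size
    if len(sequences) < need:
        raise InputError(
            f"need {need} sequences for {n_groups} groups of {group_size}, "
            f"got {len(sequences)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(sequences), size=need, replace=False)
    groups = chosen.reshape(n_groups, group_size)

    obs = {f"g{gi}_s{j}": sequences[idx]
           for gi, grp in enumerate(groups) for j, idx in enumerate(grp)}
    matrix = kmer.build_word_matrix(obs, k_min, k_max, layout)
    group_of = np.repeat(np.arange(n_groups), group_size)
    at = matrix.at_content.to_numpy()

    rows = []
    for a in range(n_groups):
        for b in range(a + 1, n_groups):
            sel = (group_of == a) | (group_of == b)
            sub = WordMatrix(
                data=matrix.data.loc[sel],
                k_min=k_min, k_max=k_max, layout=layout,
                norm_state=matrix.norm_state,
                base_probs=matrix.base_probs.loc[sel],
            )
            labels = [f"grp{g}" for g in group_of[sel]]
            model = fit_oplsda(
                sub, labels, n_orth=n_orth, positive_class=f"grp{a}",
                cv_folds=folds, seed=seed,
            )
            rho = sps.spearmanr(model.training_scores.to_numpy(), at[sel]).statistic
            rows.append(
                dict(group_a=a, group_b=b, q2=model.q2, spearman_at=float(rho))
            )
    return pd.DataFrame(rows)
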