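"""Single-block modelling and three-level data fusion.

Low-level fusion (LLDF) concatenates the standardized blocks as-is.
Mid-level fusion (MLDF) first reduces each block — PCA or PLS-DA
scores at a 95% cumulative-variance target, or the top-40 variables by
decision-tree / random-forest Gini importance — then concatenates the
per-block features and trains a second-stage classifier; models are
named "SELECTOR–CLASSIFIER" (e.g. RF–RF).  High-level fusion (HLDF)
runs a random forest per block, successively keeps the top 120 then
(after a refit) the top 40 variables, weights each block's Gini
importances by 1/n_blocks (0.25 for four blocks), merges the 4 × 40 =
160 ranked variables, and trains the final 100-tree forest on the
overall top 40.

All selection and fitting happens on training rows only; test and
external samples are transformed through the fitted objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core import FeatureBlock, SampleManifest, check_aligned, child_seed

SELECTORS = ("PCA_95", "PLSDA_95", "DT_top40", "RF_top40")
CLASSIFIERS = ("PCA", "PLSDA", "SVM", "KNN", "NN", "DT", "RF")
_CLASSIFIER_ALIASES = {
    "SVM_RBF": "SVM",
    "KNN_3": "KNN",
    "NN_500_200_10": "NN",
    "DT_GINI": "DT",
    "RF_100": "RF",
}


@dataclass
class FusionConfig:
    """Hyper-parameters of the fusion pipeline (defaults as used throughout).

    ``mid_budget``: variables kept per block by the DT/RF selectors.
    ``hldf_budgets``: successive per-block forest budgets (120 then 40).
    ``hldf_weight``: Gini weighting coefficient; None means 1/n_blocks
    (0.25 with four blocks).  ``variance_target``: cumulative-variance
    threshold for PCA/PLS-DA component counts.  ``hldf_refit``: whether
    stage-2 importances come from a forest refit on the surviving 120
    variables (default) or are reused from the stage-1 forest.
    """

    level: str = "high"
    selector: str = "RF_top40"
    classifier: str = "RF"
    mid_budget: int = 40
    hldf_budgets: tuple[int, int] = (120, 40)
    hldf_weight: float | None = None
    hldf_final_budget: int = 40
    variance_target: float = 0.95
    train_fraction: float = 0.7
    seed: int = 0
    hldf_refit: bool = True
    nn_max_iter: int = 300

    def __post_init__(self) -> None:
        a, b = self.hldf_budgets
        if not (a >= b > 0):
            raise ValueError("hldf_budgets must be positive and non-increasing")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if not (0.0 < self.variance_target <= 1.0):
            raise ValueError("variance_target must be in (0, 1]")


@dataclass
class RankedFeature:
    """One variable's position in an importance ranking."""

    block_id: str
    feature_id: str
    raw_importance: float
    fused_importance: float | None = None
    rank: int | None = None


# ---------------------------------------------------------------------------
# classifiers


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """Two-class PLS-DA: PLS regression on a 0/1 indicator, cut at 0.5."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("PLS-DA classifier is two-class only")
        y01 = (y == self.classes_[1]).astype(float)
        k = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self.pls_ = PLSRegression(n_components=max(k, 1)).fit(X, y01)
        return self

    def decision_function(self, X):
        return self.pls_.predict(np.asarray(X, dtype=float)).ravel() - 0.5

    def predict(self, X):
        return np.where(self.decision_function(X) > 0, self.classes_[1], self.classes_[0])


class PCACentroidClassifier(BaseEstimator, ClassifierMixin):
    """PCA score-space nearest-centroid: the scatter-plot model made predictive."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        k = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self.pca_ = PCA(n_components=max(k, 1)).fit(X)
        self.centroid_ = NearestCentroid().fit(self.pca_.transform(X), y)
        return self

    def decision_function(self, X):
        s = self.pca_.transform(np.asarray(X, dtype=float))
        c = self.centroid_.centroids_
        order = list(self.centroid_.classes_)
        d0 = np.linalg.norm(s - c[order.index(self.classes_[0])], axis=1)
        d1 = np.linalg.norm(s - c[order.index(self.classes_[1])], axis=1)
        return d0 - d1  # larger ⇒ closer to classes_[1]

    def predict(self, X):
        return np.where(self.decision_function(X) > 0, self.classes_[1], self.classes_[0])


def make_classifier(name: str, seed: int = 0, nn_max_iter: int = 300):
    """Instantiate a classifier by its pipeline name.

    SVM uses the radial-basis kernel; kNN uses k=3 with Euclidean
    distance; the neural network has hidden layers (500, 200, 10); the
    decision tree splits on Gini impurity; the random forest grows 100
    trees with the out-of-bag estimate enabled.
    """
    key = _CLASSIFIER_ALIASES.get(name, name)
    if key == "PCA":
        return PCACentroidClassifier(n_components=2)
    if key == "PLSDA":
        return PLSDAClassifier(n_components=2)
    if key == "SVM":
        return SVC(kernel="rbf", random_state=seed)
    if key == "KNN":
        return KNeighborsClassifier(n_neighbors=3, metric="euclidean")
    if key == "NN":
        return MLPClassifier(
            hidden_layer_sizes=(500, 200, 10), max_iter=nn_max_iter, random_state=seed
        )
    if key == "DT":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if key == "RF":
        return RandomForestClassifier(
            n_estimators=100, criterion="gini", oob_score=True, random_state=seed
        )
    raise ValueError(f"unknown classifier {name!r}")


def train_classifier(X: pd.DataFrame, y: Sequence, name: str, seed: int = 0, nn_max_iter: int = 300):
    """Fit one classifier on a finite design matrix with two-class labels."""
    Xv = np.asarray(X, dtype=float)
    if not np.isfinite(Xv).all():
        raise ValueError("design matrix contains non-finite values")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain two classes")
    clf = make_classifier(name, seed=seed, nn_max_iter=nn_max_iter)
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Xv, y)
    return clf


# ---------------------------------------------------------------------------
# partitioning


def partition_model_set(
    manifest: SampleManifest, train_fraction: float = 0.7, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Stratified random split of the model samples into train and test.

    70 model samples at the default 0.7 fraction yield 49 train and 21
    test samples.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be strictly between 0 and 1")
    ids = manifest.model_ids
    if len(ids) < 10:
        raise ValueError("need at least 10 model samples to split")
    groups = manifest.groups.loc[ids]
    if groups.nunique() < 2:
        raise ValueError("model set must contain at least two classes")
    train, test = train_test_split(
        ids, train_size=train_fraction, stratify=groups, random_state=seed
    )
    for part in (train, test):
        if manifest.groups.loc[part].nunique() < groups.nunique():
            raise ValueError("a class is absent from one side of the split")
    return list(train), list(test)


# ---------------------------------------------------------------------------
# low-level fusion


def lldf_concatenate(blocks: Sequence[FeatureBlock]) -> FeatureBlock:
    """Column-wise concatenation of aligned blocks, feature ids prefixed."""
    check_aligned(blocks)
    parts = []
    for b in blocks:
        d = b.data.copy()
        d.columns = [f"{b.platform}:{c}" for c in d.columns]
        parts.append(d)
    return FeatureBlock("FUSED", pd.concat(parts, axis=1))


# ---------------------------------------------------------------------------
# mid-level selectors


class PcaScores:
    """Fitted PCA projection keeping the fewest components reaching the
    cumulative explained-variance target."""

    def __init__(self, block_id: str, k: int, pca: PCA):
        self.block_id = block_id
        self.k = k
        self.pca = pca

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        s = self.pca.transform(np.asarray(data, dtype=float))[:, : self.k]
        cols = [f"{self.block_id}:PC{i + 1}" for i in range(self.k)]
        return pd.DataFrame(s, index=data.index, columns=cols)


def select_pca_features(train: pd.DataFrame, variance_target: float = 0.95, block_id: str = "X") -> PcaScores:
    """Fit PCA on training rows; keep the smallest k with cum. variance ≥ target."""
    X = np.asarray(train, dtype=float)
    pca = PCA().fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    reached = np.flatnonzero(cum >= variance_target - 1e-12)
    if reached.size:
        k = int(reached[0]) + 1
    else:
        k = cum.size
        warnings.warn(
            f"{block_id}: variance target {variance_target} unreachable; using rank {k}",
            stacklevel=2,
        )
    return PcaScores(block_id, k, pca)


class PlsdaScores:
    """Fitted PLS-DA latent-variable projection (X-variance criterion)."""

    def __init__(self, block_id: str, k: int, pls: PLSRegression):
        self.block_id = block_id
        self.k = k
        self.pls = pls

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        s = self.pls.transform(np.asarray(data, dtype=float))
        cols = [f"{self.block_id}:LV{i + 1}" for i in range(self.k)]
        return pd.DataFrame(s, index=data.index, columns=cols)


def select_plsda_features(
    train: pd.DataFrame,
    labels: Sequence,
    variance_target: float = 0.95,
    block_id: str = "X",
    max_components: int = 30,
) -> PlsdaScores:
    """Fit PLS-DA latent variables on training rows against the class indicator.

    The component count is the smallest k whose cumulative explained
    X-variance reaches the target (at least one component).
    """
    X = np.asarray(train, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("PLS-DA selection needs exactly two classes")
    y01 = (y == classes[1]).astype(float)
    m = min(max_components, X.shape[1], X.shape[0] - 1)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="y residual is constant")
        pls = PLSRegression(n_components=m).fit(X, y01)
    Xc = X - X.mean(axis=0)
    ss = float((Xc**2).sum())
    t, p = pls.x_scores_, pls.x_loadings_
    r2x = np.array([(t[:, i] @ t[:, i]) * (p[:, i] @ p[:, i]) for i in range(m)]) / ss
    cum = np.cumsum(r2x)
    reached = np.flatnonzero(cum >= variance_target - 1e-12)
    if reached.size:
        k = int(reached[0]) + 1
    else:
        k = m
        warnings.warn(
            f"{block_id}: PLS X-variance target {variance_target} not reached "
            f"within {m} components; using {m}",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="y residual is constant")
        pls_k = PLSRegression(n_components=max(k, 1)).fit(X, y01)
    return PlsdaScores(block_id, max(k, 1), pls_k)


def select_importance_features(
    train: pd.DataFrame,
    labels: Sequence,
    method: str = "RF",
    budget: int = 40,
    seed: int = 0,
    block_id: str = "X",
) -> list[RankedFeature]:
    """Rank variables by impurity (Gini) importance and keep the top ``budget``.

    Ties break toward the lower original column index.  A budget larger
    than the block width is capped with a warning.
    """
    if budget <= 0:
        raise ValueError("budget must be positive")
    if budget > train.shape[1]:
        warnings.warn(
            f"{block_id}: budget {budget} exceeds width {train.shape[1]}; capped",
            stacklevel=2,
        )
        budget = train.shape[1]
    model = train_classifier(train, labels, method, seed=seed)
    imp = model.feature_importances_
    order = np.lexsort((np.arange(len(imp)), -imp))
    cols = list(train.columns)
    return [
        RankedFeature(block_id, cols[j], float(imp[j]), rank=r + 1)
        for r, j in enumerate(order[:budget])
    ]


# ---------------------------------------------------------------------------
# mid-level fusion


@dataclass
class MLDFModel:
    """A fitted mid-level fusion model: per-block extractors + classifier."""

    name: str
    selector: str
    classifier_name: str
    extractors: dict[str, object]
    model: object
    fused_columns: list[str]
    column_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    def fuse(self, blocks: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
        parts = []
        for plat, ex in self.extractors.items():
            parts.append(ex.transform(blocks[plat]))
        fused = pd.concat(parts, axis=1)
        return fused[self.fused_columns]

    def predict(self, blocks: Mapping[str, pd.DataFrame]):
        return self.model.predict(np.asarray(self.fuse(blocks), dtype=float))

    def ranked_features(self) -> list[RankedFeature]:
        """Final-model Gini ranking over the fused columns.

        Only available for column-based selectors (DT/RF) combined with
        an impurity-based classifier, where each fused column is an
        original, traceable variable.
        """
        if not self.column_map:
            raise ValueError(
                f"{self.name}: score-based selector — fused columns are not "
                "original variables, no traceable ranking exists"
            )
        if not hasattr(self.model, "feature_importances_"):
            raise ValueError(f"{self.name}: classifier exposes no Gini importances")
        imp = self.model.feature_importances_
        order = np.lexsort((np.arange(len(imp)), -imp))
        out = []
        for r, j in enumerate(order):
            col = self.fused_columns[j]
            blk, feat = self.column_map[col]
            out.append(
                RankedFeature(blk, feat, float(imp[j]), fused_importance=float(imp[j]), rank=r + 1)
            )
        return out


class _ColumnSubset:
    def __init__(self, block_id: str, features: list[str]):
        self.block_id = block_id
        self.features = features

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        out = data[self.features].copy()
        out.columns = [f"{self.block_id}:{f}" for f in self.features]
        return out


def fit_extractors(
    train_blocks: Mapping[str, pd.DataFrame],
    labels: Sequence,
    selector: str,
    config: FusionConfig | None = None,
) -> dict[str, object]:
    """Fit one per-block feature extractor per the chosen selector."""
    config = config or FusionConfig()
    if selector not in SELECTORS:
        raise ValueError(f"unknown selector {selector!r}; pick one of {SELECTORS}")
    extractors: dict[str, object] = {}
    for plat, df in train_blocks.items():
        sd = child_seed(config.seed, f"mldf:{selector}:{plat}")
        if selector == "PCA_95":
            extractors[plat] = select_pca_features(df, config.variance_target, block_id=plat)
        elif selector == "PLSDA_95":
            extractors[plat] = select_plsda_features(
                df, labels, config.variance_target, block_id=plat
            )
        else:
            method = "DT" if selector == "DT_top40" else "RF"
            ranked = select_importance_features(
                df, labels, method=method, budget=config.mid_budget, seed=sd, block_id=plat
            )
            extractors[plat] = _ColumnSubset(plat, [rf.feature_id for rf in ranked])
    return extractors


def mldf_fuse(
    train_blocks: Mapping[str, pd.DataFrame],
    labels: Sequence,
    selector: str,
    classifier: str,
    config: FusionConfig | None = None,
    extractors: Mapping[str, object] | None = None,
) -> MLDFModel:
    """Mid-level fusion: reduce each block, merge, train the second stage.

    ``selector`` is one of PCA_95, PLSDA_95, DT_top40, RF_top40; the
    per-block outputs (scores or top-``mid_budget`` variables) are
    concatenated in block order before the classifier is trained.
    Pre-fitted ``extractors`` (from :func:`fit_extractors`) may be
    passed to reuse one selection across several classifiers.
    """
    config = config or FusionConfig()
    if len(train_blocks) < 2:
        raise ValueError("mid-level fusion needs at least two blocks")
    if extractors is None:
        extractors = fit_extractors(train_blocks, labels, selector, config)
    column_map: dict[str, tuple[str, str]] = {}
    for plat, ex in extractors.items():
        if isinstance(ex, _ColumnSubset):
            for f in ex.features:
                column_map[f"{plat}:{f}"] = (plat, f)
    parts = [extractors[plat].transform(train_blocks[plat]) for plat in train_blocks]
    fused = pd.concat(parts, axis=1)
    clf = train_classifier(
        fused, labels, classifier, seed=child_seed(config.seed, f"mldf:{selector}:{classifier}"),
        nn_max_iter=config.nn_max_iter,
    )
    sel_tag = {"PCA_95": "PCA", "PLSDA_95": "PLS-DA", "DT_top40": "DT", "RF_top40": "RF"}[selector]
    clf_tag = _CLASSIFIER_ALIASES.get(classifier, classifier)
    return MLDFModel(
        name=f"{sel_tag}–{clf_tag}",
        selector=selector,
        classifier_name=classifier,
        extractors=dict(extractors),
        model=clf,
        fused_columns=list(fused.columns),
        column_map=column_map,
    )


# ---------------------------------------------------------------------------
# high-level fusion


@dataclass
class HLDFResult:
    """Weighted-Gini high-level fusion output.

    ``merged``: the full merged ranking (n_blocks × stage-2 budget
    variables, fused importance = weight × per-block Gini, sorted).
    ``selected``: the overall top ``hldf_final_budget`` variables the
    final forest was trained on.
    """

    name: str
    merged: list[RankedFeature]
    selected: list[RankedFeature]
    model: RandomForestClassifier
    weight: float
    column_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def fused_columns(self) -> list[str]:
        return [f"{rf.block_id}:{rf.feature_id}" for rf in self.selected]

    def fuse(self, blocks: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
        cols = {}
        for rf in self.selected:
            cols[f"{rf.block_id}:{rf.feature_id}"] = blocks[rf.block_id][rf.feature_id]
        return pd.DataFrame(cols)

    def predict(self, blocks: Mapping[str, pd.DataFrame]):
        return self.model.predict(np.asarray(self.fuse(blocks), dtype=float))


def hldf_gini_fusion(
    train_blocks: Mapping[str, pd.DataFrame],
    labels: Sequence,
    config: FusionConfig | None = None,
) -> HLDFResult:
    """High-level fusion by weighted Gini importances.

    Per block: a 100-tree forest over all variables keeps the top 120;
    a second forest refit on those 120 keeps the top 40 with its refit
    importances (set ``config.hldf_refit=False`` to reuse the stage-1
    importances instead).  Each surviving variable's importance is then
    multiplied by the block weight (1/n_blocks, i.e. 0.25 for four
    blocks), the per-block lists are merged (4 × 40 = 160 variables)
    and sorted by fused importance, and the overall top 40 train the
    final forest.  Ties break by block order, then original column
    index.
    """
    config = config or FusionConfig()
    n_blocks = len(train_blocks)
    if n_blocks < 2:
        raise ValueError("high-level fusion needs at least two blocks")
    weight = config.hldf_weight if config.hldf_weight is not None else 1.0 / n_blocks
    b1, b2 = config.hldf_budgets

    merged: list[RankedFeature] = []
    sort_keys: list[tuple] = []
    for bi, (plat, df) in enumerate(train_blocks.items()):
        width = df.shape[1]
        stage1_budget = b1
        if stage1_budget > width:
            warnings.warn(
                f"{plat}: width {width} < stage-1 budget {b1}; capped", stacklevel=2
            )
            stage1_budget = width
        stage1 = select_importance_features(
            df, labels, method="RF", budget=stage1_budget,
            seed=child_seed(config.seed, f"hldf:{plat}:stage1"), block_id=plat,
        )
        surviving = [rf.feature_id for rf in stage1]
        stage2_budget = min(b2, len(surviving))
        if config.hldf_refit:
            stage2 = select_importance_features(
                df[surviving], labels, method="RF", budget=stage2_budget,
                seed=child_seed(config.seed, f"hldf:{plat}:stage2"), block_id=plat,
            )
        else:
            stage2 = stage1[:stage2_budget]
        col_index = {c: j for j, c in enumerate(df.columns)}
        for rf in stage2:
            fused = weight * rf.raw_importance
            merged.append(
                RankedFeature(plat, rf.feature_id, rf.raw_importance, fused_importance=fused)
            )
            sort_keys.append((-fused, bi, col_index[rf.feature_id]))

    order = sorted(range(len(merged)), key=lambda i: sort_keys[i])
    merged = [merged[i] for i in order]
    for r, rf in enumerate(merged):
        rf.rank = r + 1
    selected = merged[: config.hldf_final_budget]

    fused_cols = {}
    for rf in selected:
        fused_cols[f"{rf.block_id}:{rf.feature_id}"] = train_blocks[rf.block_id][rf.feature_id]
    design = pd.DataFrame(fused_cols)
    final = train_classifier(
        design, labels, "RF", seed=child_seed(config.seed, "hldf:final")
    )
    column_map = {f"{rf.block_id}:{rf.feature_id}": (rf.block_id, rf.feature_id) for rf in selected}
    return HLDFResult(
        name="RF–RF (HLDF)",
        merged=merged,
        selected=selected,
        model=final,
        weight=weight,
        column_map=column_map,
    )


def ranked_to_frame(ranked: Sequence[RankedFeature]) -> pd.DataFrame:
    """RankedFeature list → tidy table (rank, block, feature, importances)."""
    return pd.DataFrame(
        [
            {
                "rank": rf.rank,
                "block": rf.block_id,
                "feature": rf.feature_id,
                "raw_importance": rf.raw_importance,
                "fused_importance": rf.fused_importance,
            }
            for rf in ranked
        ]
    )
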