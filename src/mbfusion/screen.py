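"""Characteristic-variable screening and external-set validation.

The top-k (default 38) variables by fused Gini importance are exported
from the best fusion model and validated without labels: the external
samples — origins never seen during modelling — are restricted to the
screened variables and projected onto their own first two principal
components.  A scalar ``separation_index`` (mean between-group over
mean within-group pairwise distance in the 2-D scores) quantifies the
grouping that the original study assessed visually; screened variables
should separate the external origins better than the full concatenated
feature space does.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import FeatureBlock, SampleManifest
from .evaluate import ModelReport, compare_strategies, config_digest, score_model
from .fusion import (
    CLASSIFIERS,
    SELECTORS,
    FusionConfig,
    HLDFResult,
    MLDFModel,
    RankedFeature,
    hldf_gini_fusion,
    lldf_concatenate,
    mldf_fuse,
    partition_model_set,
    ranked_to_frame,
    train_classifier,
)
from .preprocess import (
    BucketingScheme,
    MirPipelineConfig,
    mir_to_block,
    nmr_to_block,
    zscore_block,
)
from .synthetic import StudyData, SyntheticSpec, generate_study


@dataclass
class CharacteristicVariableSet:
    """Ordered top-k variables screened from a fused model."""

    source_model: str
    k: int
    variables: list[RankedFeature]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        imps = [
            v.fused_importance if v.fused_importance is not None else v.raw_importance
            for v in self.variables
        ]
        if any(b > a + 1e-12 for a, b in zip(imps, imps[1:])):
            raise ValueError("screened variables must be in non-increasing importance order")

    def keys(self) -> list[tuple[str, str]]:
        return [(v.block_id, v.feature_id) for v in self.variables]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "importance": v.fused_importance
                    if v.fused_importance is not None
                    else v.raw_importance,
                    "block": v.block_id,
                    "feature": v.feature_id,
                }
                for i, v in enumerate(self.variables)
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def screen_top_k(
    ranked: Sequence[RankedFeature],
    k: int = 38,
    source_model: str = "RF–RF",
    provenance: dict | None = None,
) -> CharacteristicVariableSet:
    """Keep the first k variables of a fused importance ranking."""
    if k <= 0:
        raise ValueError("k must be positive")
    if not ranked:
        raise ValueError("empty ranking")
    ordered = sorted(
        ranked,
        key=lambda rf: rf.rank
        if rf.rank is not None
        else -(rf.fused_importance if rf.fused_importance is not None else rf.raw_importance),
    )
    if k > len(ordered):
        warnings.warn(f"k={k} exceeds pool of {len(ordered)}; returning the whole pool", stacklevel=2)
        k = len(ordered)
    return CharacteristicVariableSet(source_model, k, ordered[:k], provenance or {})


def separation_index(scores: np.ndarray, labels: Sequence) -> float:
    """Between-group over within-group mean pairwise distance in 2-D scores.

    Invariant under rotation and translation of the score cloud.  An
    epsilon guard keeps degenerate geometry (all within-group distances
    zero) finite.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = scores.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    d = np.linalg.norm(scores[:, None, :] - scores[None, :, :], axis=-1)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    within = d[iu][same[iu]]
    between = d[iu][~same[iu]]
    if between.size == 0:
        raise ValueError("separation index needs at least two groups")
    mb = float(between.mean())
    mw = float(within.mean()) if within.size else 0.0
    eps = 1e-12 * (mb + 1.0)
    return mb / (mw + eps)


@dataclass
class ProjectionReport:
    """2-D projection of the external set on screened variables."""

    scores: pd.DataFrame
    explained_variance: tuple[float, float]
    groups: pd.Series
    separation_index: float
    variable_count: int
    fit: str = "external"

    def to_dict(self) -> dict:
        return {
            "separation_index": self.separation_index,
            "explained_variance": list(self.explained_variance),
            "variable_count": self.variable_count,
            "fit": self.fit,
            "scores": {
                sid: [float(a), float(b)]
                for sid, (a, b) in self.scores.iterrows()
            },
            "groups": {k: str(v) for k, v in self.groups.items()},
        }


def project_external(
    external_blocks: Mapping[str, pd.DataFrame],
    variable_set: CharacteristicVariableSet,
    groups: pd.Series,
    fit: str = "external",
    model_blocks: Mapping[str, pd.DataFrame] | None = None,
) -> ProjectionReport:
    """PCA of the external samples restricted to the screened variables.

    The external blocks must already carry the model-set standardization.
    With ``fit="external"`` (default) the two PCs are fitted on the
    external samples themselves; ``fit="model"`` projects the external
    samples through loadings fitted on the model samples instead.
    Score-type features (PCA/PLS-DA scores) cannot be screened — every
    variable must resolve to an original block column.
    """
    if not variable_set.variables:
        raise ValueError("empty variable set")
    cols = {}
    for blk, feat in variable_set.keys():
        if blk not in external_blocks:
            raise KeyError(f"screened variable references unknown block {blk!r}")
        if feat not in external_blocks[blk].columns:
            raise KeyError(
                f"screened variable {blk}:{feat} missing from the external block — "
                "only original-variable selectors support screening"
            )
        cols[f"{blk}:{feat}"] = external_blocks[blk][feat]
    X = pd.DataFrame(cols)
    if fit == "model":
        if model_blocks is None:
            raise ValueError("fit='model' needs model_blocks")
        ref = pd.DataFrame(
            {f"{b}:{f}": model_blocks[b][f] for b, f in variable_set.keys()}
        )
        pca = PCA(n_components=2).fit(ref.to_numpy())
    elif fit == "external":
        pca = PCA(n_components=min(2, X.shape[0] - 1, X.shape[1])).fit(X.to_numpy())
    else:
        raise ValueError("fit must be 'external' or 'model'")
    s = pca.transform(X.to_numpy())[:, :2]
    if s.shape[1] < 2:  # rank-1 geometry
        s = np.column_stack([s[:, 0], np.zeros(s.shape[0])])
    scores = pd.DataFrame(s, index=X.index, columns=["PC1", "PC2"])
    scores -= scores.mean(axis=0)
    ev = tuple(pca.explained_variance_ratio_[:2]) + (0.0, 0.0)
    labels = groups.loc[X.index]
    return ProjectionReport(
        scores=scores,
        explained_variance=(float(ev[0]), float(ev[1])),
        groups=labels,
        separation_index=separation_index(scores.to_numpy(), labels.to_numpy()),
        variable_count=len(variable_set.variables),
        fit=fit,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces, for inspection or export."""

    manifest: SampleManifest
    blocks: dict[str, FeatureBlock]
    train_ids: list[str]
    test_ids: list[str]
    reports: list[ModelReport]
    comparison: pd.DataFrame
    best_model: str
    hldf: HLDFResult
    mldf_models: dict[str, MLDFModel]
    variable_set: CharacteristicVariableSet
    projection: ProjectionReport
    baseline_projection: ProjectionReport
    truth: dict | None = None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.comparison.to_csv(outdir / "comparison.csv", index_label="rank")
        ranked_to_frame(self.hldf.merged).to_csv(outdir / "ranked_features.csv", index=False)
        self.variable_set.to_csv(outdir / "characteristic_variables.csv")
        (outdir / "projection_report.json").write_text(
            json.dumps(
                {
                    "screened": self.projection.to_dict(),
                    "baseline": self.baseline_projection.to_dict(),
                },
                indent=2,
            )
        )
        reports_dir = outdir / "model_reports"
        reports_dir.mkdir(exist_ok=True)
        for r in self.reports:
            safe = r.model_name.replace("/", "_").replace(" ", "_")
            (reports_dir / f"{safe}.json").write_text(r.to_json())
        (outdir / "run_manifest.json").write_text(
            json.dumps(
                {
                    "best_model": self.best_model,
                    "n_train": len(self.train_ids),
                    "n_test": len(self.test_ids),
                    "n_external": len(self.manifest.external_ids),
                    "blocks": {p: b.width for p, b in self.blocks.items()},
                    "artifacts": [
                        "comparison.csv",
                        "ranked_features.csv",
                        "characteristic_variables.csv",
                        "projection_report.json",
                    ],
                },
                indent=2,
            )
        )


def preprocess_study(
    study: StudyData,
    scheme: BucketingScheme | None = None,
    mir_config: MirPipelineConfig | None = None,
) -> dict[str, FeatureBlock]:
    """Raw study → feature blocks (bucketed NMR, smoothed/masked MIR)."""
    blocks: dict[str, FeatureBlock] = {}
    order = list(study.truth["blocks"]) if study.truth else None
    plats = order or (list(study.tabular) + list(study.spectra))
    for plat in plats:
        if plat in study.tabular:
            blocks[plat] = study.tabular[plat]
        elif plat.upper() == "NMR":
            blocks[plat] = nmr_to_block(study.spectra[plat], scheme)
        else:
            blocks[plat] = mir_to_block(study.spectra[plat], mir_config)
    return blocks


def full_pipeline(
    study: StudyData | SyntheticSpec,
    config: FusionConfig | None = None,
    outdir=None,
    k: int = 38,
    classifiers: Sequence[str] = CLASSIFIERS,
    selectors: Sequence[str] = SELECTORS,
    scheme: BucketingScheme | None = None,
    mir_config: MirPipelineConfig | None = None,
) -> PipelineResult:
    """Run the whole discrimination workflow on one study.

    Preprocess → standardize (model statistics only) → 70/30 stratified
    split → single-block RF baselines, LLDF with every classifier, MLDF
    over every selector × classifier, HLDF weighted-Gini fusion →
    comparison table → top-k screening from the best traceable model →
    unsupervised external validation against the full-concatenation
    baseline.
    """
    config = config or FusionConfig()
    if isinstance(study, SyntheticSpec):
        study = generate_study(study)
    manifest = study.manifest
    digest = config_digest(config)

    raw_blocks = preprocess_study(study, scheme, mir_config)
    zblocks: dict[str, FeatureBlock] = {}
    for plat, blk in raw_blocks.items():
        zblocks[plat], _ = zscore_block(blk, manifest.model_ids)

    train_ids, test_ids = partition_model_set(manifest, config.train_fraction, config.seed)
    y = manifest.groups
    y_tr, y_te = y.loc[train_ids].to_numpy(), y.loc[test_ids].to_numpy()
    tr = {p: b.data.loc[train_ids] for p, b in zblocks.items()}
    te = {p: b.data.loc[test_ids] for p, b in zblocks.items()}
    ext_ids = manifest.external_ids
    ext = {p: b.data.loc[ext_ids] for p, b in zblocks.items()}

    reports: list[ModelReport] = []

    def _score(model, Xtr, Xte, name):
        reports.append(
            score_model(model, Xtr, y_tr, Xte, y_te, name=name, seed=config.seed, digest=digest)
        )

    # single-block baselines (RF on each platform)
    from .core import child_seed

    for plat in zblocks:
        m = train_classifier(tr[plat], y_tr, "RF", seed=child_seed(config.seed, f"single:{plat}"))
        _score(m, tr[plat], te[plat], f"Single-{plat} (RF)")

    # low-level fusion
    fused_train = lldf_concatenate([zblocks[p].restrict(train_ids) for p in zblocks])
    fused_test = lldf_concatenate([zblocks[p].restrict(test_ids) for p in zblocks])
    for clf in classifiers:
        m = train_classifier(
            fused_train.data, y_tr, clf, seed=child_seed(config.seed, f"lldf:{clf}"),
            nn_max_iter=config.nn_max_iter,
        )
        _score(m, fused_train.data, fused_test.data, f"LLDF {clf}")

    # mid-level fusion (one selector fit reused across classifiers)
    from .fusion import fit_extractors

    mldf_models: dict[str, MLDFModel] = {}
    for sel in selectors:
        extractors = fit_extractors(tr, y_tr, sel, config)
        for clf in classifiers:
            fm = mldf_fuse(tr, y_tr, sel, clf, config, extractors=extractors)
            name = f"MLDF {fm.name}"
            mldf_models[name] = fm
            _score(fm.model, fm.fuse(tr), fm.fuse(te), name)

    # high-level fusion
    hldf = hldf_gini_fusion(tr, y_tr, config)
    _score(hldf.model, hldf.fuse(tr), hldf.fuse(te), f"HLDF {hldf.name}")

    comparison, best = compare_strategies(reports)

    # screening: the best traceable importance ranking; the HLDF merged
    # ranking is the fallback when the best model has no original-variable
    # ranking (score-based selector or non-impurity classifier)
    ranked, source = hldf.merged, hldf.name
    if best in mldf_models:
        try:
            ranked = mldf_models[best].ranked_features()
            source = mldf_models[best].name
        except ValueError:
            pass
    varset = screen_top_k(ranked, k=k, source_model=source, provenance={"config": digest})

    projection = project_external(ext, varset, y)
    all_vars = [
        RankedFeature(p, c, 0.0, fused_importance=0.0, rank=i + 1)
        for i, (p, c) in enumerate(
            (p, c) for p in zblocks for c in zblocks[p].data.columns
        )
    ]
    baseline_set = CharacteristicVariableSet("full-concatenation", len(all_vars), all_vars)
    baseline = project_external(ext, baseline_set, y)

    result = PipelineResult(
        manifest=manifest,
        blocks=zblocks,
        train_ids=train_ids,
        test_ids=test_ids,
        reports=reports,
        comparison=comparison,
        best_model=best,
        hldf=hldf,
        mldf_models=mldf_models,
        variable_set=varset,
        projection=projection,
        baseline_projection=baseline,
        truth=study.truth,
    )
    if outdir is not None:
        result.write(outdir)
    return result


def planted_recall(variable_set: CharacteristicVariableSet, truth: dict) -> float:
    """Fraction of planted tabular features recovered by the screened set.

    Only tabular blocks have a one-to-one feature ↔ column mapping; for
    spectral blocks a screened bucket counts as a hit when its center
    lies within one peak width of a planted peak position.
    """
    screened = set(variable_set.keys())
    hits = total = 0
    for plat, entry in truth["blocks"].items():
        if entry["kind"] == "tabular":
            for feat in entry["informative"]:
                total += 1
                if (plat, feat) in screened:
                    hits += 1
        else:
            w = float(entry.get("peak_width", 0.0))
            centers = []
            for blk, feat in screened:
                if blk == plat and "_" in feat:
                    try:
                        centers.append(float(feat.split("_", 1)[1]))
                    except ValueError:
                        pass
            for pos in entry["informative_positions"]:
                total += 1
                if any(abs(c - pos) <= max(w, 1e-9) for c in centers):
                    hits += 1
    if total == 0:
        raise ValueError("truth lists no planted features")
    return hits / total
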