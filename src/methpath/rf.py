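"""Per-TE feature matrices and tree-ensemble classification.

The classifier asks which chromatin features predict whether a TE's CHH
methylation depends on CMT2 or on the RdDM pathway: rows are TEs, columns
are epigenomic summaries (methylation levels and densities, H3K9me1/2, H1,
sRNA rpkm, GC content, cytosine sequence-context densities), the label is
the assigned pathway class. A bagged decision-tree ensemble (random forest:
per-tree bootstrap, sqrt(p) feature subsampling) is fit on a random half of
the TEs and scored on the held-out half; variable importance is reported
both as permutation accuracy decrease and as impurity decrease.

The train/validation split is derived from a seeded hash of feature ids, so
results do not depend on row order, and is stratified by class.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .io import FeatureInterval, GenomeSequence
from .methylation import MethylationSummary, annotate_contexts

__all__ = [
    "ClassifierReport",
    "build_feature_matrix",
    "train_eval_classifier",
    "variable_importance",
    "hash_split",
    "sequence_context_densities",
]

SEQ_CONTEXT_COLUMNS = ["CG", "CCG", "CHG", "CHH", "CWG", "CWA", "nonCWA"]


@dataclass
class ClassifierReport:
    error_rate: float
    oob_error: float
    predictions: pd.Series
    importance: pd.DataFrame
    predictors: list[str]
    n_trees: int
    seed: int
    n_train: int
    n_validation: int


def sequence_context_densities(
    genome: GenomeSequence, features: Sequence[FeatureInterval]
) -> pd.DataFrame:
    """Cytosine context sites per bp of each feature (both strands).

    Columns: density of CG, CCG, CHG, CHH, CWG, CWA, nonCWA sites plus GC
    content. CHG/CHH columns count the full context; CCG/CWG and CWA/nonCWA
    are their subcontext partitions.
    """
    sites = annotate_contexts(genome, regions=list(features))
    rows = []
    pos_by_chrom = {
        chrom: grp.reset_index(drop=True) for chrom, grp in sites.groupby("chrom")
    }
    for f in features:
        grp = pos_by_chrom.get(f.chrom)
        row = {"id": f.id}
        if grp is None:
            for c in SEQ_CONTEXT_COLUMNS:
                row[f"density_{c}"] = 0.0
        else:
            p = grp["pos"].to_numpy()
            m = (p >= f.start) & (p < f.end)
            ctx = grp["context"].to_numpy()[m]
            sub = grp["subcontext"].to_numpy()[m]
            for c in SEQ_CONTEXT_COLUMNS:
                src = ctx if c in {"CG", "CHG", "CHH"} else sub
                row[f"density_{c}"] = float(np.count_nonzero(src == c)) / f.length
        seq = genome[f.chrom][f.start : f.end]
        gc = sum(1 for b in seq if b in "GC")
        row["gc_content"] = gc / f.length
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def build_feature_matrix(
    features: Sequence[FeatureInterval],
    summaries: dict[str, MethylationSummary],
    tracks: dict[str, pd.Series],
    genome: GenomeSequence | None = None,
) -> pd.DataFrame:
    """One row per feature: methylation levels/densities, named tracks, and
    (when a genome is given) sequence-context densities and GC content.

    ``tracks`` maps a column name (e.g. "H1", "H3K9me1", "sRNA_24") to a
    per-feature Series keyed by feature id; every feature must be present in
    every track. Rows with any undefined (NaN) methylation level are dropped
    and recorded in ``matrix.attrs["dropped_ids"]``.
    """
    ids = [f.id for f in features]
    missing = {
        name: sorted(set(ids) - set(series.index))
        for name, series in tracks.items()
    }
    missing = {k: v for k, v in missing.items() if v}
    if missing:
        raise KeyError(f"features missing from tracks: {missing}")
    cols: dict[str, pd.Series] = {}
    level_cols = []
    for c in ("CG", "CHG", "CHH", "CH"):
        cols[f"m{c}"] = pd.Series(
            {i: summaries[i].levels[c] for i in ids}, name=f"m{c}"
        )
        level_cols.append(f"m{c}")
        cols[f"d_{c}"] = pd.Series({i: summaries[i].densities[c] for i in ids})
    for name in sorted(tracks):
        cols[name] = tracks[name].reindex(ids)
    m = pd.DataFrame(cols, index=pd.Index(ids, name="id"))
    if genome is not None:
        m = m.join(sequence_context_densities(genome, features))
    dropped = m.index[m[level_cols].isna().any(axis=1)].tolist()
    m = m.drop(index=dropped)
    m.attrs["dropped_ids"] = dropped
    return m


def hash_split(
    ids: Sequence[str],
    labels: pd.Series,
    split_fraction: float,
    seed: int,
) -> np.ndarray:
    """Deterministic, row-order-independent, class-stratified train mask.

    Each id is ranked by a salted digest; within each class the first
    ``split_fraction`` of the ranking goes to training.
    """
    digests = {
        i: hashlib.sha256(f"{seed}:{i}".encode()).hexdigest() for i in ids
    }
    train = np.zeros(len(ids), dtype=bool)
    idx_of = {i: k for k, i in enumerate(ids)}
    for cls in pd.unique(labels):
        members = [i for i in ids if labels.loc[i] == cls]
        members.sort(key=lambda i: digests[i])
        n_train = int(round(split_fraction * len(members)))
        for i in members[:n_train]:
            train[idx_of[i]] = True
    return train


def _fit_forest(x, y, n_trees: int, seed: int) -> RandomForestClassifier:
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=seed % (2**32),
        n_jobs=1,
    )
    clf.fit(x, y)
    return clf


def train_eval_classifier(
    matrix: pd.DataFrame,
    labels: pd.Series,
    predictors: Sequence[str] | None = None,
    split_fraction: float = 0.5,
    n_trees: int = 500,
    seed: int = 0,
    compute_permutation_importance: bool = True,
) -> ClassifierReport:
    """Held-out error rate and variable importance of a random forest.

    ``labels`` must be keyed by feature id and binary for the pathway task
    (multiclass labels are accepted; error rate generalizes directly).
    """
    if predictors is None:
        predictors = list(matrix.columns)
    unknown = [p for p in predictors if p not in matrix.columns]
    if unknown:
        raise KeyError(f"predictors not in matrix: {unknown}")
    labels = labels.reindex(matrix.index)
    if labels.isna().any():
        raise KeyError("labels missing for some matrix rows")
    ids = list(matrix.index)
    train = hash_split(ids, labels, split_fraction, seed)
    y = labels.to_numpy()
    if len(np.unique(y[train])) < 2:
        raise ValueError("training split contains a single class")
    x = matrix[list(predictors)].to_numpy(dtype=float)
    clf = _fit_forest(x[train], y[train], n_trees, seed)
    pred = clf.predict(x[~train])
    err = float(np.mean(pred != y[~train]))
    oob_error = float(1.0 - clf.oob_score_)
    importance = _importance_frame(
        clf, x[~train], y[~train], predictors, seed, compute_permutation_importance
    )
    return ClassifierReport(
        error_rate=err,
        oob_error=oob_error,
        predictions=pd.Series(pred, index=matrix.index[~train], name="predicted"),
        importance=importance,
        predictors=list(predictors),
        n_trees=n_trees,
        seed=seed,
        n_train=int(train.sum()),
        n_validation=int((~train).sum()),
    )


def _importance_frame(clf, x_val, y_val, predictors, seed, permute=True):
    imp = pd.DataFrame(
        {"impurity_decrease": clf.feature_importances_},
        index=pd.Index(predictors, name="predictor"),
    )
    if permute:
        perm = permutation_importance(
            clf, x_val, y_val, n_repeats=10, random_state=seed % (2**32)
        )
        imp["accuracy_decrease"] = perm.importances_mean
    else:
        imp["accuracy_decrease"] = np.nan
    imp["rank_impurity"] = (
        imp["impurity_decrease"].rank(ascending=False, method="min").astype(int)
    )
    imp["rank_accuracy"] = (
        imp["accuracy_decrease"].rank(ascending=False, method="min").astype(int)
        if permute
        else -1
    )
    return imp


def variable_importance(
    matrix: pd.DataFrame,
    labels: pd.Series,
    predictors: Sequence[str] | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Importance table (permutation accuracy decrease + impurity decrease),
    sorted by accuracy decrease."""
    report = train_eval_classifier(
        matrix, labels, predictors=predictors, n_trees=n_trees, seed=seed
    )
    return report.importance.sort_values("accuracy_decrease", ascending=False)
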