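"""Random-forest fit-quality classification of localizations.

A user (or, on simulated data, a ground-truth oracle) labels ~300
localizations as ``good`` (a clean single-fluorophore fit), ``background``
(a fit to a noise fluctuation) or ``too_dense`` (a fit corrupted by
overlapping emitters).  A 300-tree random forest trained on the labelled
20-dim PCA features then classifies the rest of the acquisition, so the
classifier is tuned to that particular dataset and localization algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureMatrix

__all__ = [
    "LABELS",
    "LabelSet",
    "ForestModel",
    "stratified_sample",
    "oracle_label",
    "train_forest",
    "classify_all",
    "split_reconstruction",
]

LABELS = ("good", "background", "too_dense")
MISFIT_LABELS = ("background", "too_dense")


@dataclass
class LabelSet:
    """Labels for a subset (or all) of a localization table."""

    indices: np.ndarray  # row positions into the table
    labels: np.ndarray  # strings from LABELS
    provenance: str  # "user" | "oracle" | "predicted"
    vote_fractions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        bad = set(np.unique(self.labels)) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if len(self.indices) != len(self.labels):
            raise ValueError("indices and labels must align")

    def as_series(self, n: int) -> pd.Series:
        s = pd.Series(index=range(n), dtype=object)
        s.iloc[self.indices] = self.labels
        return s


@dataclass
class ForestModel:
    """300-tree random forest bound to the PCA basis it was trained with."""

    forest: RandomForestClassifier
    basis_fingerprint: str
    classes: tuple[str, ...] = field(default_factory=tuple)


def stratified_sample(
    table: pd.DataFrame,
    n: int = 300,
    rng_seed: int = 0,
    n_strata: int = 30,
) -> np.ndarray:
    """Pick ~n rows spread evenly across the acquisition period.

    Rows (ordered by frame) are split into ``n_strata`` contiguous time
    strata of near-equal size and an equal number (+-1) is drawn from each
    without replacement, so the labelled set spans the whole sequence
    without over-representing any period.
    """
    if len(table) == 0:
        raise ValueError("cannot sample from an empty table")
    rng = np.random.default_rng(rng_seed)
    if n >= len(table):
        return np.arange(len(table))
    order = np.argsort(table["frame"].to_numpy(), kind="stable")
    n_strata = min(n_strata, n, len(table))
    strata = np.array_split(order, n_strata)
    base, extra = divmod(n, n_strata)
    picks: list[np.ndarray] = []
    for i, stratum in enumerate(strata):
        want = base + (1 if i < extra else 0)
        want = min(want, len(stratum))
        picks.append(rng.choice(stratum, size=want, replace=False))
    out = np.concatenate(picks)
    out.sort()
    return out


def oracle_label(
    table: pd.DataFrame,
    sidecar: pd.DataFrame,
    match_radius_nm: float = 250.0,
    pair_radius_nm: float = 500.0,
    k_uncertainty: float = 3.0,
    indices: np.ndarray | None = None,
) -> LabelSet:
    """Ground-truth stand-in for the human labeller (simulated data only).

    Per localization, using the simulator's per-frame active-emitter sidecar:

    - ``too_dense`` if two or more active emitters lie within
      ``pair_radius_nm`` (the pair-resolution radius) of the localization;
    - ``good`` if exactly one active emitter lies within
      ``match_radius_nm`` and the position error is below
      ``k_uncertainty`` x the reported uncertainty;
    - ``background`` otherwise (no nearby emitter, or a match too far from
      the fit to be a faithful single-emitter localization).
    """
    if sidecar is None or len(sidecar) == 0:
        raise ValueError("ground-truth sidecar required for oracle labelling")
    idx = np.arange(len(table)) if indices is None else np.asarray(indices)
    by_frame = {f: g for f, g in sidecar.groupby("frame")}
    labels = []
    for i in idx:
        rec = table.iloc[i]
        g = by_frame.get(int(rec["frame"]))
        if g is None or len(g) == 0:
            labels.append("background")
            continue
        dx = g["x_nm"].to_numpy() - float(rec["x_nm"])
        dy = g["y_nm"].to_numpy() - float(rec["y_nm"])
        dist = np.hypot(dx, dy)
        n_pair = int((dist <= pair_radius_nm).sum())
        n_match = int((dist <= match_radius_nm).sum())
        if n_pair >= 2:
            labels.append("too_dense")
        elif n_match == 1:
            err = float(dist.min())
            tol = k_uncertainty * float(rec.get("uncertainty_nm", np.inf))
            labels.append("good" if err < tol else "background")
        else:
            labels.append("background")
    return LabelSet(indices=idx, labels=np.asarray(labels, dtype=object), provenance="oracle")


def train_forest(
    features: FeatureMatrix,
    labelset: LabelSet,
    n_trees: int = 300,
    rng_seed: int = 0,
    max_features: int = 5,
    class_weight: str | None = "balanced",
) -> ForestModel:
    """Train the per-dataset random forest on the labelled subset.

    Each tree is grown on a bootstrap resample with ``max_features``
    (default ceil(sqrt(20)) = 5) random candidate dimensions per split;
    prediction is the majority vote across trees.  Classes are weighted
    inversely to their training frequency by default: the background class
    is typically a few percent of a dense acquisition and would otherwise
    never be predicted at all.
    """
    y = labelset.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must cover at least two classes")
    x = features.reduced[labelset.indices]
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        bootstrap=True,
        random_state=rng_seed,
        class_weight=class_weight,
        n_jobs=1,
    )
    forest.fit(x, y)
    return ForestModel(
        forest=forest,
        basis_fingerprint=features.basis.fingerprint,
        classes=tuple(forest.classes_),
    )


def classify_all(model: ForestModel, features: FeatureMatrix) -> LabelSet:
    """Apply the trained forest to every localization's reduced features.

    Refuses to run if the features were reduced with a different PCA basis
    than the training set (silent train/apply skew would otherwise go
    unnoticed).  Per-class vote fractions are kept as confidences.
    """
    if features.basis.fingerprint != model.basis_fingerprint:
        raise ValueError(
            "PCA basis fingerprint mismatch between training and application; "
            "reduce both with the same fitted basis"
        )
    proba = model.forest.predict_proba(features.reduced)
    labels = np.asarray(model.forest.classes_)[proba.argmax(axis=1)]
    votes = pd.DataFrame(proba, columns=list(model.forest.classes_))
    return LabelSet(
        indices=np.arange(features.n),
        labels=labels.astype(object),
        provenance="predicted",
        vote_fractions=votes,
    )


def quality_pipeline(
    stack,
    table: pd.DataFrame,
    sidecar: pd.DataFrame | None = None,
    train_labels: LabelSet | None = None,
    n_training: int = 300,
    rng_seed: int = 0,
    oracle_kwargs: dict | None = None,
):
    """Features -> stratified training set -> forest -> full classification.

    Either supply ``train_labels`` (a user-labelled :class:`LabelSet`) or a
    simulation ``sidecar`` for oracle labelling of the stratified sample.
    Returns ``(predicted, model, features, train_indices)``.
    """
    from .features import build_features

    feats = build_features(stack, table)
    if train_labels is None:
        if sidecar is None:
            raise ValueError("need either train_labels or a ground-truth sidecar")
        idx = stratified_sample(table, n=n_training, rng_seed=rng_seed)
        train_labels = oracle_label(table, sidecar, indices=idx, **(oracle_kwargs or {}))
    model = train_forest(feats, train_labels, rng_seed=rng_seed)
    predicted = classify_all(model, feats)
    return predicted, model, feats, train_labels.indices


def split_reconstruction(
    table: pd.DataFrame, labelset: LabelSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition the table into (good, misfit) by predicted label.

    Misfit = background plus too_dense; the two tables together conserve the
    input rows, ready for two-colour rendering of accurate versus inaccurate
    localizations.
    """
    if len(labelset.indices) != len(table):
        raise ValueError("labels must cover the whole table")
    s = labelset.as_series(len(table)).to_numpy()
    good_mask = s == "good"
    return (
        table[good_mask].reset_index(drop=True),
        table[~good_mask].reset_index(drop=True),
    )
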