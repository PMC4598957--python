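"""Random-forest classification of grazing / resting / walking.

The classifier is trained on labelled movement-metric rows that are
balanced by random under-sampling (all classes reduced to the minority
count), and evaluated on *sequences* held out wholesale — row-level splits
would leak near-duplicate neighbouring fixes between training and
validation.  Accuracy is reported per class (recall) and as the macro
(unweighted) average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .metrics import compute_movement_metrics, metric_columns

log = logging.getLogger(__name__)

CLASSES = ("grazing", "resting", "walking")


def balance_undersample(table: pd.DataFrame, label_col: str = "label", seed: int = 0) -> pd.DataFrame:
    """Reduce every class to the minority-class row count by uniform
    sampling without replacement; deterministic per seed."""
    counts = table[label_col].value_counts()
    for c in CLASSES:
        if c not in counts:
            raise ValueError(f"class {c!r} absent from the training table")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for c, g in table.groupby(label_col, sort=False):
        idx = rng.choice(len(g), size=n_min, replace=False)
        parts.append(g.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


@dataclass
class ClassifierModel:
    """Fitted activity classifier with its training metadata."""

    forest: RandomForestClassifier
    features: list
    classes: tuple = CLASSES
    meta: dict = field(default_factory=dict)

    def importances(self) -> pd.Series:
        return pd.Series(self.forest.feature_importances_, index=self.features).sort_values(ascending=False)


def train_classifier(
    table: pd.DataFrame,
    features: list | None = None,
    n_estimators: int = 200,
    seed: int = 0,
    **rf_kwargs,
) -> ClassifierModel:
    """Train the random forest on complete, labelled metric rows."""
    features = features or [c for c in metric_columns() if c in table.columns]
    rows = table[table["complete"].astype(bool)] if "complete" in table else table
    rows = rows.dropna(subset=["label"])
    counts = rows["label"].value_counts()
    if counts.empty or counts.min() < 10:
        raise ValueError("need at least 10 labelled rows per class")
    Xf = rows[features].to_numpy(dtype=float)
    if np.all(Xf.std(axis=0) == 0):
        raise ValueError("all features are constant")
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1, **rf_kwargs)
    forest.fit(Xf, rows["label"].to_numpy())
    return ClassifierModel(
        forest=forest,
        features=list(features),
        meta={"seed": seed, "class_counts": counts.to_dict(), "n_rows": len(rows)},
    )


@dataclass
class ConfusionSummary:
    """3x3 confusion counts with per-class recall and macro accuracy (%)."""

    matrix: pd.DataFrame  # rows = truth, cols = prediction
    per_class_pct: pd.Series
    macro_pct: float

    def __str__(self) -> str:  # formatted like field reports of accuracy
        per = ", ".join(f"{c}: {v:.0f} %" for c, v in self.per_class_pct.dropna().items())
        return f"average accuracy of {self.macro_pct:.0f} % ({per})"


def confusion_summary(y_true, y_pred) -> ConfusionSummary:
    mat = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    totals = mat.sum(axis=1)
    per = pd.Series(np.nan, index=list(CLASSES))
    for c in CLASSES:
        if totals[c] > 0:
            per[c] = 100.0 * mat.loc[c, c] / totals[c]
        else:
            log.warning("class %r absent from the truth; excluded from macro accuracy", c)
    macro = float(per.dropna().mean())
    return ConfusionSummary(matrix=mat, per_class_pct=per, macro_pct=macro)


def evaluate_classifier(model: ClassifierModel, heldout: pd.DataFrame) -> ConfusionSummary:
    """Evaluate on held-out labelled metric rows (independent sequences)."""
    rows = heldout[heldout["complete"].astype(bool)] if "complete" in heldout else heldout
    rows = rows.dropna(subset=["label"])
    if len(rows) == 0:
        raise ValueError("empty held-out set")
    pred = model.forest.predict(rows[model.features].to_numpy(dtype=float))
    return confusion_summary(rows["label"].to_numpy(), pred)


def split_sequences(table: pd.DataFrame, test_fraction: float = 0.3, seed: int = 0):
    """Sequence-level train/validation split (whole segments, never rows)."""
    segs = table["segment"].unique()
    rng = np.random.default_rng(seed)
    rng.shuffle(segs)
    n_test = max(int(round(test_fraction * len(segs))), 1)
    test_ids = set(segs[:n_test])
    test = table[table["segment"].isin(test_ids)]
    train = table[~table["segment"].isin(test_ids)]
    return train, test


def _majority_smooth(labels: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling majority vote; isolated mislabels in an otherwise
    homogeneous bout are overruled by their neighbours."""
    if window < 2 or len(labels) < window:
        return labels
    out = labels.copy()
    half = window // 2
    for i in range(len(labels)):
        lo, hi = max(0, i - half), min(len(labels), i + half + 1)
        vals, counts = np.unique(labels[lo:hi], return_counts=True)
        out[i] = vals[np.argmax(counts)]
    return out


def classify_positions(model: ClassifierModel, trackset, smooth_window: int = 9, **metric_kwargs):
    """Predict an activity for every fix of an unlabelled track set.

    Complete metric rows are classified by the forest; edge rows with
    incomplete windows inherit the nearest (in time) prediction within
    their animal's sequence; a rolling majority vote (default 9 fixes =
    3 min) then smooths isolated single-fix flips, since behaviour bouts
    last minutes, not seconds.  Returns a new TrackSet with ``state``
    filled.
    """
    from .sim.tracks import TrackSet

    fixes = trackset.fixes.copy()
    if len(fixes) == 0:
        return TrackSet(fixes=fixes, devices=trackset.devices, nominal_interval=trackset.nominal_interval)
    table = compute_movement_metrics(trackset, **metric_kwargs)
    pred = pd.Series(pd.NA, index=table.index, dtype=object)
    comp = table["complete"].to_numpy(dtype=bool) if len(table) else np.array([], dtype=bool)
    if comp.any():
        pred[comp] = model.forest.predict(table.loc[comp, model.features].to_numpy(dtype=float))
    # edge rows: nearest complete prediction in time, per animal
    table = table.assign(_pred=pred)
    filled = []
    for aid, g in table.groupby("animal_id", sort=False):
        s = g.set_index("t")["_pred"]
        known = s.dropna()
        if known.empty:
            filled.append(g.assign(_pred=pd.NA))
            continue
        idx = known.index.get_indexer(s.index, method="nearest")
        lab = _majority_smooth(known.iloc[idx].to_numpy(), smooth_window)
        filled.append(g.assign(_pred=lab))
    table = pd.concat(filled)
    key = table.set_index(["animal_id", "t"])["_pred"]
    fixes = fixes.set_index(["animal_id", "t"])
    fixes["state"] = key.reindex(fixes.index)
    fixes = fixes.reset_index()
    return TrackSet(fixes=fixes, devices=trackset.devices, nominal_interval=trackset.nominal_interval)
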