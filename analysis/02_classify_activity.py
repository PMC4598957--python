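"""Classify the GPS fixes into grazing / resting / walking.

Trains the balanced random forest on the labelled movement metrics of half
of the sequences, evaluates on the held-out sequences, then predicts every
fix.  Writes the confusion matrix and the classified track set.
"""

import logging

import pandas as pd

from _common import AREA_DIR, SEED
from alpgraze import io
from alpgraze.classify import (
    balance_undersample,
    classify_positions,
    evaluate_classifier,
    split_sequences,
    train_classifier,
)
from alpgraze.metrics import compute_movement_metrics
from alpgraze.sim.tracks import TrackSet

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

tracks = io.read_tracks(AREA_DIR / "tracks.csv")
table = compute_movement_metrics(tracks)
train, heldout = split_sequences(table, test_fraction=0.5, seed=SEED)
balanced = balance_undersample(train[train["complete"].astype(bool)].dropna(subset=["label"]), seed=SEED)
model = train_classifier(balanced, seed=SEED)
confusion = evaluate_classifier(model, heldout)

unlabeled = TrackSet(fixes=tracks.fixes.assign(state=pd.NA), devices=tracks.devices,
                     nominal_interval=tracks.nominal_interval)
classified = classify_positions(model, unlabeled)
io.write_tracks(classified, AREA_DIR / "tracks_classified.csv", seed=SEED)
io.write_table(confusion.matrix.rename_axis("truth").reset_index(), AREA_DIR / "confusion.csv",
               seed=SEED, summary=str(confusion))
io.write_table(model.importances().rename("importance").rename_axis("metric").reset_index(),
               AREA_DIR / "feature_importances.csv", seed=SEED)

print(f"balanced training rows per class: {balanced['label'].value_counts().min()}")
print(f"held-out sequences: {confusion}")
print("top predictors:", ", ".join(model.importances().head(5).index))
print(f"wrote classified tracks to {AREA_DIR / 'tracks_classified.csv'}")
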