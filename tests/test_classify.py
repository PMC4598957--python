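import numpy as np
import pandas as pd
import pytest

from alpgraze.classify import (
    balance_undersample,
    confusion_summary,
    evaluate_classifier,
    train_classifier,
)


def _metric_frame(counts: dict, seed=0, sep=5.0):
    """Synthetic metric rows with class-separated speeds."""
    rng = np.random.default_rng(seed)
    rows = []
    centers = {"resting": 0.0, "grazing": sep, "walking": 2 * sep}
    for label, n in counts.items():
        rows.append(
            pd.DataFrame(
                {
                    "label": label,
                    "speed_lag1": rng.normal(centers[label], 0.5, n),
                    "speed_lag15": rng.normal(centers[label], 0.5, n),
                    "complete": True,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def test_undersampling_equalizes_to_minority():
    table = _metric_frame({"grazing": 1000, "resting": 300, "walking": 200})
    bal = balance_undersample(table, seed=0)
    assert bal["label"].value_counts().to_dict() == {"grazing": 200, "resting": 200, "walking": 200}


def test_undersampling_never_increases_and_is_idempotent_on_balanced():
    table = _metric_frame({"grazing": 50, "resting": 50, "walking": 50})
    bal = balance_undersample(table, seed=1)
    assert bal["label"].value_counts().to_dict() == {c: 50 for c in ("grazing", "resting", "walking")}


def test_undersampling_seed_changes_subset_not_counts():
    table = _metric_frame({"grazing": 500, "resting": 100, "walking": 100})
    b1 = balance_undersample(table, seed=1)
    b2 = balance_undersample(table, seed=2)
    assert b1["label"].value_counts().equals(b2["label"].value_counts())
    g1 = set(b1[b1["label"] == "grazing"]["speed_lag1"].round(6))
    g2 = set(b2[b2["label"] == "grazing"]["speed_lag1"].round(6))
    assert g1 != g2


def test_missing_class_named_in_error():
    table = _metric_frame({"grazing": 50, "resting": 50})
    with pytest.raises(ValueError, match="walking"):
        balance_undersample(table)


def test_separable_classes_train_perfectly_and_reproducibly():
    table = _metric_frame({"grazing": 60, "resting": 60, "walking": 60}, sep=10.0)
    feats = ["speed_lag1", "speed_lag15"]
    m1 = train_classifier(table, features=feats, seed=3)
    m2 = train_classifier(table, features=feats, seed=3)
    X = table[feats].to_numpy()
    p1 = m1.forest.predict(X)
    p2 = m2.forest.predict(X)
    assert (p1 == table["label"]).all()
    assert np.array_equal(p1, p2)


def test_constant_features_rejected():
    table = _metric_frame({"grazing": 30, "resting": 30, "walking": 30})
    table["speed_lag1"] = 1.0
    table["speed_lag15"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        train_classifier(table, features=["speed_lag1", "speed_lag15"])


def test_confusion_arithmetic():
    truth = ["grazing"] * 10 + ["resting"] * 10 + ["walking"] * 10
    pred = (
        ["grazing"] * 8 + ["resting", "walking"]
        + ["grazing"] * 2 + ["resting"] * 6 + ["walking"] * 2
        + ["walking"] * 10
    )
    cs = confusion_summary(truth, pred)
    assert cs.per_class_pct["grazing"] == pytest.approx(80.0)
    assert cs.per_class_pct["resting"] == pytest.approx(60.0)
    assert cs.per_class_pct["walking"] == pytest.approx(100.0)
    assert cs.macro_pct == pytest.approx(80.0)
    assert cs.matrix.sum(axis=1).tolist() == [10, 10, 10]


def test_absent_class_excluded_from_macro():
    cs = confusion_summary(["grazing", "grazing"], ["grazing", "resting"])
    assert np.isnan(cs.per_class_pct["walking"])
    assert cs.macro_pct == pytest.approx(50.0)


def test_empty_heldout_rejected():
    dummy = _metric_frame({"grazing": 20, "resting": 20, "walking": 20})
    m = train_classifier(dummy, features=["speed_lag1", "speed_lag15"], seed=0)
    table = pd.DataFrame(columns=["label", "complete"])
    with pytest.raises(ValueError, match="empty"):
        evaluate_classifier(m, table)


def test_perfect_predictions_give_100():
    truth = ["grazing", "resting", "walking"] * 5
    cs = confusion_summary(truth, truth)
    assert cs.macro_pct == pytest.approx(100.0)
    assert (cs.per_class_pct == 100.0).all()


def test_all_resting_herd_predicted_resting(landscape, rotation, classification_run):
    """A herd frozen in a stationary state is predicted resting throughout."""
    from alpgraze.classify import classify_positions
    from alpgraze.sim.tracks import BehaviourParams, TrackSet, simulate_tracks

    params = BehaviourParams(transition=np.eye(3), speed_mps=(0.005, 0.005, 0.005), preference={})
    ts, _ = simulate_tracks(
        landscape, rotation, n_animals=2, params=params, gps_sigma=3.0,
        duration=pd.Timedelta(hours=1), seed=123,
    )
    fixes = ts.fixes.copy()
    fixes["state"] = pd.NA
    unlabeled = TrackSet(fixes=fixes, devices=ts.devices, nominal_interval=ts.nominal_interval)
    out = classify_positions(classification_run["model"], unlabeled)
    assert (out.fixes["state"] == "resting").mean() >= 0.95


def test_classify_positions_empty_trackset(landscape):
    from alpgraze.classify import classify_positions, train_classifier
    from alpgraze.sim.tracks import TrackSet

    dummy = _metric_frame({"grazing": 20, "resting": 20, "walking": 20})
    model = train_classifier(dummy, features=["speed_lag1", "speed_lag15"], seed=0)
    empty = TrackSet(
        fixes=pd.DataFrame(columns=["animal_id", "device_id", "t", "x", "y", "state", "g_t"]),
        devices=[], nominal_interval=20.0,
    )
    out = classify_positions(model, empty)
    assert len(out.fixes) == 0
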