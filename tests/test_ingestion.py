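"""CSV dialects, epoch alignment, label filtering, capping, splitting."""

import numpy as np
import pandas as pd
import pytest

from felacc.features import FEATURE_NAMES
from felacc.ingestion import (
    STUDY_OBSERVATION_COUNTS,
    AnnotationTrack,
    RawTrace,
    align_epochs,
    cap_class_counts,
    default_ethogram,
    filter_behaviour_counts,
    normalise_label,
    preprocess_labels,
    read_annotation_csv,
    read_raw_csv,
    train_test_split_stratified,
    write_annotation_csv,
    write_raw_csv,
)


@pytest.fixture
def toy_trace():
    rng = np.random.default_rng(0)
    return RawTrace("cat01", "collar", 30, rng.normal(0, 1, size=(1800, 3)))


def make_track(labels, start=0):
    return AnnotationTrack("cat01", np.arange(start, start + len(labels)),
                           np.array(labels, dtype=object))


# ---------------------------------------------------------------------------
# CSV round trips


def test_raw_csv_round_trip(tmp_path, toy_trace):
    path = tmp_path / "trace.csv"
    write_raw_csv(toy_trace, path)
    back = read_raw_csv(path)
    assert back.cat_id == "cat01" and back.mount == "collar"
    assert back.sampling_rate == 30
    np.testing.assert_array_equal(back.samples, toy_trace.samples)


def test_raw_csv_sixty_seconds(tmp_path):
    trace = RawTrace("c", "harness", 30, np.zeros((60 * 30, 3)))
    path = tmp_path / "t.csv"
    write_raw_csv(trace, path)
    assert read_raw_csv(path).n_samples == 1800


def test_raw_csv_empty_data_section(tmp_path, toy_trace):
    path = tmp_path / "t.csv"
    write_raw_csv(toy_trace, path)
    lines = path.read_text().splitlines()
    sentinel = next(i for i, l in enumerate(lines) if l.startswith("Timestamp"))
    path.write_text("\n".join(lines[: sentinel + 1]) + "\n")
    with pytest.raises(ValueError, match="empty data section"):
        read_raw_csv(path)


def test_raw_csv_non_numeric_cell(tmp_path, toy_trace):
    path = tmp_path / "t.csv"
    write_raw_csv(toy_trace, path)
    text = path.read_text().splitlines()
    text[15] = text[15].rsplit(",", 1)[0] + ",oops"
    path.write_text("\n".join(text) + "\n")
    with pytest.raises(ValueError, match="non-numeric"):
        read_raw_csv(path)


def test_raw_csv_rate_mismatch(tmp_path, toy_trace):
    path = tmp_path / "t.csv"
    write_raw_csv(toy_trace, path)
    text = path.read_text().replace("Sample Rate: 30 Hz", "Sample Rate: 100 Hz")
    path.write_text(text)
    with pytest.raises(ValueError, match="does not match"):
        read_raw_csv(path)


def test_annotation_csv_round_trip(tmp_path):
    track = make_track(["lying"] * 5 + ["Sitting"] * 5)
    path = tmp_path / "ann.csv"
    write_annotation_csv(track, path)
    back = read_annotation_csv(path, default_ethogram())
    assert (back.labels == track.labels).all()
    assert (back.second_index == track.second_index).all()


def test_annotation_csv_unknown_label(tmp_path):
    path = tmp_path / "ann.csv"
    pd.DataFrame({"Time": [0, 1], "Subject": "c",
                  "Behavior": ["lying", "teleporting"]}).to_csv(path,
                                                                index=False)
    with pytest.raises(ValueError, match="teleporting"):
        read_annotation_csv(path, default_ethogram())


def test_annotation_csv_gap_rejected(tmp_path):
    path = tmp_path / "ann.csv"
    pd.DataFrame({"Time": [0, 1, 3], "Subject": "c",
                  "Behavior": ["lying"] * 3}).to_csv(path, index=False)
    with pytest.raises(ValueError, match="contiguous"):
        read_annotation_csv(path, default_ethogram())


def test_label_case_normalisation():
    assert normalise_label("  Lying ") == "lying"
    assert normalise_label("Out  of Sight") == "out of sight"
    track = make_track(["LYING", "lying"])
    assert set(track.labels) == {"lying"}


# ---------------------------------------------------------------------------
# alignment


def test_align_ten_seconds(toy_trace):
    track = make_track(["lying"] * 10)
    windows, labels = align_epochs(toy_trace, track)
    assert windows.shape == (60, 30, 3)
    assert sum(l is not None for l in labels) == 10
    assert all(l == "lying" for l in labels[:10])


def test_align_clock_offset():
    trace = RawTrace("c", "collar", 30, np.zeros((300, 3)), start_second=5)
    track = make_track(["lying"] * 3, start=7)
    _, labels = align_epochs(trace, track)
    assert labels[2] == "lying" and labels[0] is None


def test_align_trace_too_short(toy_trace):
    track = make_track(["lying"] * 100)
    with pytest.raises(ValueError, match="cover"):
        align_epochs(toy_trace, track)


def test_align_drops_partial_epoch():
    trace = RawTrace("c", "collar", 30, np.zeros((75, 3)))
    windows, labels = align_epochs(trace, make_track(["lying"] * 2))
    assert windows.shape[0] == 2


# ---------------------------------------------------------------------------
# preprocessing rules


def test_low_occurrence_behaviour_removed():
    track = make_track(["fighting"] * 10 + ["lying"] * 50)
    out, report = preprocess_labels(track, default_ethogram())
    assert "fighting" not in set(out.labels)
    frame = report.to_frame()
    row = frame[frame.behaviour == "fighting"].iloc[0]
    assert row.action == "removed" and "10 s" in row.reason


def test_jumping_variants_merged():
    track = make_track(["jumping horizontal"] * 53 + ["jumping vertical"] * 186
                       + ["lying"] * 20)
    out, _ = preprocess_labels(track, default_ethogram())
    assert sum(out.labels == "jumping") == 239
    assert not {"jumping horizontal", "jumping vertical"} & set(out.labels)


def test_bookkeeping_labels_removed_but_allogrooming_kept():
    track = make_track(["out of sight"] * 30 + ["other"] * 20
                       + ["allogrooming"] * 15 + ["lying"] * 15)
    out, report = preprocess_labels(track, default_ethogram())
    assert set(out.labels) == {"allogrooming", "lying"}
    assert report.removed_seconds() == 50


def test_preprocess_idempotent_on_clean_track():
    track = make_track(["lying"] * 40 + ["sitting"] * 30)
    out, _ = preprocess_labels(track, default_ethogram())
    assert (out.labels == track.labels).all()
    assert (out.second_index == track.second_index).all()


def test_preprocess_conserves_every_second():
    track = make_track(["fighting"] * 10 + ["out of sight"] * 25
                       + ["lying"] * 40 + ["playing"] * 1)
    out, report = preprocess_labels(track, default_ethogram())
    assert len(out) + report.removed_seconds() == len(track)


def test_study_counts_yield_15_classes():
    retained, report = filter_behaviour_counts(STUDY_OBSERVATION_COUNTS)
    assert len(retained) == 15
    assert "jumping" in retained and "allogrooming" in retained
    assert "fighting" not in retained and "out of sight" not in retained
    frame = report.to_frame()
    merged = frame[frame.action == "merged"]
    assert set(merged.behaviour) == {"jumping horizontal", "jumping vertical"}


# ---------------------------------------------------------------------------
# capping and splitting


def feature_df(labels, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(len(labels), 32)),
                      columns=list(FEATURE_NAMES))
    df.insert(0, "label", labels)
    df.insert(0, "mount", "collar")
    df.insert(0, "cat_id", "c")
    return df


def test_cap_class_counts():
    df = feature_df(["big"] * 20_000 + ["small"] * 100)
    capped = cap_class_counts(df, 7000, seed=1)
    counts = capped["label"].value_counts()
    assert counts["big"] == 7000 and counts["small"] == 100
    again = cap_class_counts(df, 7000, seed=1)
    pd.testing.assert_frame_equal(capped, again)
    different = cap_class_counts(df, 7000, seed=2)
    assert not capped.equals(different)


def test_split_sizes_and_conservation():
    df = feature_df(["a"] * 700 + ["b"] * 300)
    train, test = train_test_split_stratified(df, 0.7, seed=3)
    assert len(train) + len(test) == 1000
    assert abs(len(train) - 700) <= 2
    for label in ("a", "b"):
        n = (df.label == label).sum()
        n_train = (train.label == label).sum()
        assert abs(n_train - 0.7 * n) <= 1
    # disjoint and exhaustive on row identity
    key = lambda d: set(map(tuple, d[list(FEATURE_NAMES[:3])].round(9).values))
    assert key(train) | key(test) == key(df)
    assert not key(train) & key(test)


def test_split_extreme_fraction_keeps_test_nonempty():
    df = feature_df(["a"] * 10 + ["b"] * 10)
    train, test = train_test_split_stratified(df, 0.999, seed=4)
    assert set(test.label) == {"a", "b"}


def test_split_single_row_class_goes_to_train():
    df = feature_df(["a"] * 10 + ["solo"])
    train, test = train_test_split_stratified(df, 0.7, seed=5)
    assert (train.label == "solo").sum() == 1
    assert (test.label == "solo").sum() == 0
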