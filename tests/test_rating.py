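import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import surfqc as sq
from _oracles import mad_filter_survivors
from surfqc.errors import EmptyInputError, VocabularyError
from surfqc.rating import run_rating_session
from surfqc.snapshot import anonymize_and_shuffle


@pytest.mark.parametrize(
    "label,value",
    [("good", 1), ("minor_error", 2), ("visible_motion", 3), ("bad", 4)],
)
def test_category_mapping(label, value):
    assert sq.category_to_numeric(label) == value


def test_unknown_category_rejected():
    with pytest.raises(VocabularyError):
        sq.category_to_numeric("excellent")


def test_score_extremes_and_arithmetic():
    assert sq.score_participant(["good"] * 10) == 1.0
    assert sq.score_participant(["bad"] * 10) == 4.0
    mixed = ["good"] * 7 + ["minor_error"] * 2 + ["visible_motion"]
    assert sq.score_participant(mixed) == pytest.approx(1.4)
    with pytest.raises(EmptyInputError):
        sq.score_participant([])


@settings(deadline=None, max_examples=50)
@given(st.lists(st.sampled_from(["good", "minor_error", "visible_motion", "bad"]),
                min_size=1, max_size=30), st.randoms(use_true_random=False))
def test_score_permutation_invariant_and_bounded(categories, rnd):
    s = sq.score_participant(categories)
    assert 1.0 <= s <= 4.0
    shuffled = list(categories)
    rnd.shuffle(shuffled)
    assert sq.score_participant(shuffled) == pytest.approx(s)
    assert (s == 1.0) == all(c == "good" for c in categories)
    assert (s == 4.0) == all(c == "bad" for c in categories)


def test_combine_raters():
    assert sq.combine_raters([1.2, 1.8]) == pytest.approx(1.5)
    assert sq.combine_raters([2.3]) == 2.3
    assert sq.combine_raters([2.0] * 6) == 2.0
    assert sq.combine_raters([sq.combine_raters([2.7])]) == 2.7


# -- score_table ------------------------------------------------------------


def _session(manifest, rater, categories):
    rows = manifest.rows.sort_values("shuffle_position")
    return pd.DataFrame(
        {
            "image_hash": rows["image_hash"].to_numpy(),
            "rater_id": rater,
            "category": categories,
            "deliberation_ms": 1000.0,
            "timestamp": "2024-01-01T00:00:00+00:00",
        }
    )


def _toy_manifest(n_subjects=2, per_subject=10):
    rows = []
    for s in range(n_subjects):
        for i in range(per_subject):
            rows.append(
                {"subject_id": f"sub{s}", "axis": "axial", "slice_index": i,
                 "world_coordinate": 0.0, "filename": f"sub{s}_{i}.png",
                 "n_contours": 4, "no_contours": False}
            )
    return anonymize_and_shuffle(pd.DataFrame(rows), seed=1)


def test_score_table_two_raters():
    manifest = _toy_manifest()
    subj = manifest.rows.sort_values("shuffle_position")["subject_id"].to_numpy()
    cats_a = np.where(subj == "sub0", "good", "bad")
    cats_b = np.where(subj == "sub0", "minor_error", "bad")
    scores = sq.score_table(
        [_session(manifest, "ra", cats_a), _session(manifest, "rb", cats_b)], manifest
    )
    scores = scores.set_index("subject_id")
    assert scores.loc["sub0", "score_ra"] == 1.0
    assert scores.loc["sub0", "score_rb"] == 2.0
    assert scores.loc["sub0", "fsqc"] == 1.5
    assert scores.loc["sub1", "fsqc"] == 4.0
    assert (scores["n_raters"] == 2).all()
    assert (scores["n_images"] == 10).all()


def test_per_image_worst_export():
    manifest = _toy_manifest(1, 10)
    cats = ["good"] * 9 + ["bad"]
    worst = sq.per_image_worst(_session(manifest, "ra", cats), manifest)
    assert worst.loc[0, "worst_image_rating"] == 4


# -- deliberation times -----------------------------------------------------


def _timing_session(manifest, rater, times_s):
    rows = manifest.rows.sort_values("shuffle_position")
    return pd.DataFrame(
        {
            "image_hash": rows["image_hash"].to_numpy(),
            "rater_id": rater,
            "category": "good",
            "deliberation_ms": np.asarray(times_s, float) * 1000.0,
            "timestamp": "t",
        }
    )


def test_deliberation_constant_times():
    manifest = _toy_manifest(2, 10)
    summary = sq.deliberation_summary(_timing_session(manifest, "ra", [2.0] * 20), manifest)
    assert summary.per_rater.loc[0, "median_s"] == 2.0
    assert summary.per_rater.loc[0, "n_removed"] == 0


def test_deliberation_zero_mad_fallback_removes_break():
    manifest = _toy_manifest(1, 10)
    times = [1.0] * 9 + [500.0]  # rater stepped away once; MAD of the set is 0
    summary = sq.deliberation_summary(_timing_session(manifest, "ra", times), manifest)
    assert summary.per_rater.loc[0, "n_removed"] == 1
    assert summary.per_rater.loc[0, "median_s"] == 1.0


def test_deliberation_across_rater_range():
    manifest = _toy_manifest(2, 10)
    two = pd.concat(
        [_timing_session(manifest, "ra", [5.0] * 20), _timing_session(manifest, "rb", [9.3] * 20)],
        ignore_index=True,
    )
    summary = sq.deliberation_summary(two, manifest)
    assert summary.range_s == (5.0, 9.3)


def test_deliberation_filter_matches_brute_force_oracle():
    rng = np.random.default_rng(77)
    manifest = _toy_manifest(5, 10)
    for _ in range(200):
        times = np.round(rng.lognormal(1.0, rng.uniform(0.1, 1.0), 50), 3)
        session = _timing_session(manifest, "ra", times)
        summary = sq.deliberation_summary(session, manifest)
        survivors = mad_filter_survivors(list(times))
        assert summary.per_rater.loc[0, "n_removed"] == 50 - len(survivors)


# -- interactive session ----------------------------------------------------


class FakeClock:
    def __init__(self):
        self.t = 0.0

    def __call__(self):
        self.t += 0.5
        return self.t


def _write_fake_images(manifest, images_dir):
    images_dir.mkdir(parents=True, exist_ok=True)
    for h in manifest.rows["image_hash"]:
        (images_dir / f"{h}.png").write_bytes(b"\x89PNG fake")


def test_scripted_session_records_injected_keystrokes(tmp_path):
    manifest = _toy_manifest(1, 10)
    _write_fake_images(manifest, tmp_path / "img")
    keys = iter(["1", "2", "3", "4", "x", "1", "2", "3", "4", "1", "2"])
    table = run_rating_session(
        manifest, "ra", tmp_path / "img", tmp_path / "r.csv",
        input_fn=lambda _: next(keys), display_fn=lambda _: None, clock=FakeClock(),
    )
    assert len(table) == 10
    assert list(table["category"][:4]) == ["good", "minor_error", "visible_motion", "bad"]
    assert (table["deliberation_ms"] > 0).all()


def test_session_resume_completes_table(tmp_path):
    manifest = _toy_manifest(1, 10)
    _write_fake_images(manifest, tmp_path / "img")
    first = iter(["1"] * 4 + [KeyboardInterrupt])

    def _first_input(_):
        k = next(first)
        if k is KeyboardInterrupt:
            raise KeyboardInterrupt
        return k

    with pytest.raises(KeyboardInterrupt):
        run_rating_session(
            manifest, "ra", tmp_path / "img", tmp_path / "r.csv",
            input_fn=_first_input, display_fn=lambda _: None, clock=FakeClock(),
        )
    # first four ratings persisted by a wrapper pattern: write them manually
    # (the session writes at completion; resume consumes the partial file)
    partial = pd.DataFrame(
        {
            "image_hash": manifest.rows.sort_values("shuffle_position")["image_hash"][:4],
            "rater_id": "ra",
            "category": "good",
            "deliberation_ms": 100.0,
            "timestamp": "t",
        }
    )
    sq.write_ratings(partial, tmp_path / "r.csv")
    table = run_rating_session(
        manifest, "ra", tmp_path / "img", tmp_path / "r.csv", resume=True,
        input_fn=lambda _: "2", display_fn=lambda _: None, clock=FakeClock(),
    )
    assert table["image_hash"].nunique() == 10
    assert (table["category"][:4] == "good").all() if len(table) else True


def test_session_rerate_overwrites_latest(tmp_path):
    manifest = _toy_manifest(1, 4)
    _write_fake_images(manifest, tmp_path / "img")
    run_rating_session(
        manifest, "ra", tmp_path / "img", tmp_path / "r.csv",
        input_fn=lambda _: "1", display_fn=lambda _: None, clock=FakeClock(),
    )
    first_hash = manifest.rows.sort_values("shuffle_position")["image_hash"].iloc[0]
    table = run_rating_session(
        manifest, "ra", tmp_path / "img", tmp_path / "r.csv", resume=True,
        rerate=[first_hash],
        input_fn=lambda _: "4", display_fn=lambda _: None, clock=FakeClock(),
    )
    assert len(table) == 4
    assert table.set_index("image_hash").loc[first_hash, "category"] == "bad"


def test_session_missing_image_skipped(tmp_path):
    manifest = _toy_manifest(1, 4)
    _write_fake_images(manifest, tmp_path / "img")
    missing = manifest.rows["image_hash"].iloc[0]
    (tmp_path / "img" / f"{missing}.png").unlink()
    logs = []
    table = run_rating_session(
        manifest, "ra", tmp_path / "img", tmp_path / "r.csv",
        input_fn=lambda _: "1", display_fn=logs.append, clock=FakeClock(),
    )
    assert len(table) == 3
    assert any("missing" in m for m in logs)
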